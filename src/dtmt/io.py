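"""File I/O: NIfTI volumes, manifests, checkpoints and training logs."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .config import FrameworkConfig
from .synthetic import Volume

__all__ = [
    "read_volume",
    "write_volume",
    "write_cohort",
    "read_manifest",
    "save_checkpoint",
    "load_checkpoint",
]


def _load_raw(path: Path) -> tuple[np.ndarray, tuple, np.ndarray | None]:
    """(array, spacing, affine) from NIfTI or NRRD."""
    if path.suffix.lower() == ".nrrd":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        # SimpleITK arrays come (z, y, x); our convention keeps Z last
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return data, tuple(float(s) for s in img.GetSpacing()), None
    img = nib.load(str(path))
    return (np.asanyarray(img.dataobj),
            tuple(float(z) for z in img.header.get_zooms()[:3]),
            np.asarray(img.affine))


def read_volume(path, label_path=None, id: str | None = None) -> Volume:
    """Load a 3D NIfTI/NRRD image (and optional integer mask) as a Volume.

    Intensities are min-max rescaled to [0, 1]; any nonzero mask voxel is
    foreground.  Spacing and affine come from the image header.
    """
    path = Path(path)
    try:
        data, spacing, affine = _load_raw(path)
    except ValueError:
        raise
    except Exception as exc:
        raise ValueError(f"cannot read volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D")
    data = data.astype(np.float32)
    lo, hi = float(data.min()), float(data.max())
    if hi > lo:
        data = (data - lo) / (hi - lo)
    else:
        data = np.zeros_like(data)
    label = None
    if label_path is not None:
        lab, _, _ = _load_raw(Path(label_path))
        if lab.shape != data.shape:
            raise ValueError(f"{label_path}: label shape {lab.shape} != image {data.shape}")
        label = (lab != 0).astype(np.uint8)
    return Volume(data, label, voxel_spacing=spacing,
                  id=id if id is not None else path.name.split(".")[0],
                  affine=affine)


def write_volume(vol_or_array, path, spacing=None, affine=None,
                 dtype=None) -> None:
    """Write a Volume (or bare array) as NIfTI, preserving spacing/affine."""
    if isinstance(vol_or_array, Volume):
        arr = vol_or_array.intensities
        spacing = spacing if spacing is not None else vol_or_array.voxel_spacing
        affine = affine if affine is not None else vol_or_array.affine
    else:
        arr = np.asarray(vol_or_array)
    if affine is None:
        s = spacing if spacing is not None else (1.0, 1.0, 1.0)
        affine = np.diag(list(s) + [1.0])
    if dtype is not None:
        arr = arr.astype(dtype)
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def write_cohort(volumes: list[Volume], out_dir, labeled_flags=None) -> pd.DataFrame:
    """Write image/label NIfTI pairs plus a CSV manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, vol in enumerate(volumes):
        img_path = out_dir / f"{vol.id}_image.nii.gz"
        write_volume(vol, img_path)
        lbl_path = ""
        if vol.label is not None:
            lbl_path = str(out_dir / f"{vol.id}_label.nii.gz")
            write_volume(vol.label, lbl_path, spacing=vol.voxel_spacing,
                         affine=vol.affine, dtype=np.uint8)
        labeled = bool(labeled_flags[i]) if labeled_flags is not None else vol.label is not None
        rows.append(dict(id=vol.id, image=str(img_path), label=lbl_path, labeled=labeled))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_manifest(path) -> list[Volume]:
    """Load every volume listed in a manifest CSV (labels where present)."""
    df = pd.read_csv(path)
    vols = []
    for row in df.itertuples():
        label_path = row.label if isinstance(row.label, str) and row.label else None
        vols.append(read_volume(row.image, label_path, id=str(row.id)))
    return vols


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(state, cfg: FrameworkConfig, path) -> None:
    """Named-parameter archive + JSON sidecar capturing the full run state.

    Stores student/teacher parameters, optimizer velocities, the iteration
    counter, every RNG stream and the batch-iterator position, so training
    resumes bit-identically under fixed seeds.
    """
    path = Path(path)
    arrays = {}
    for prefix, net in (("student", state.student), ("teacher1", state.teacher1),
                        ("teacher2", state.teacher2)):
        if net is None:
            continue
        for name, arr in net.state_dict().items():
            arrays[f"{prefix}/{name}"] = arr
    for name, v in state.optimizer.state_dict().items():
        arrays[f"velocity/{name}"] = v
    if state.teacher2_optimizer is not None:
        for name, v in state.teacher2_optimizer.state_dict().items():
            arrays[f"velocity2/{name}"] = v
    np.savez(path, **arrays)
    meta = {
        "config": cfg.to_dict(),
        "iteration": state.iteration,
        "rngs": {k: g.bit_generator.state for k, g in state.rngs.items()},
        "batches": state.batches.state_dict(),
        "history": [r.as_dict() for r in state.history],
        "dr_history": [r.__dict__ for r in state.dr_history],
    }
    Path(str(path) + ".json").write_text(json.dumps(meta))


def load_checkpoint(path, dataset) -> tuple:
    """Rebuild (state, cfg) from a checkpoint; needs the training dataset."""
    from .discrepancy import DiscrepancyRateRecord
    from .losses import LossReport
    from .trainer import init_state

    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    cfg = FrameworkConfig.from_dict(meta["config"])
    state = init_state(dataset, cfg)
    with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz") as arc:
        groups: dict[str, dict[str, np.ndarray]] = {}
        for key in arc.files:
            prefix, name = key.split("/", 1)
            groups.setdefault(prefix, {})[name] = arc[key]
    state.student.load_state_dict(groups["student"])
    state.teacher1.load_state_dict(groups["teacher1"])
    if state.teacher2 is not None:
        state.teacher2.load_state_dict(groups["teacher2"])
    state.optimizer.load_state_dict(groups["velocity"])
    if state.teacher2_optimizer is not None:
        state.teacher2_optimizer.load_state_dict(groups["velocity2"])
    state.iteration = int(meta["iteration"])
    for k, g in state.rngs.items():
        g.bit_generator.state = meta["rngs"][k]
    state.batches.load_state_dict(meta["batches"])
    state.history = [LossReport(**r) for r in meta["history"]]
    state.dr_history = [DiscrepancyRateRecord(**r) for r in meta["dr_history"]]
    return state, cfg
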