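"""Volume-level evaluation: overlap and surface-distance metrics.

Predictions made slice-by-slice are reassembled along Z into a volume,
binarised, and scored with Dice, Jaccard, the average symmetric surface
distance (ASD) and the 95th-percentile Hausdorff distance (HD95).  Boundary
voxels are foreground voxels with at least one background face-neighbour
(6-connectivity, with everything outside the array treated as background);
nearest-boundary distances use the exact Euclidean distance transform and
honour anisotropic voxel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import FrameworkConfig
from .data import prepare_volume
from .nn import Tensor
from .synthetic import Volume

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "EmptyMaskError",
    "reassemble_volume",
    "binarize",
    "overlap_metrics",
    "surface_distance_metrics",
    "boundary_mask",
    "evaluate",
    "predict_volume",
]


class EmptyMaskError(ValueError):
    """Surface distances are undefined when either mask has no boundary."""


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class MetricsReport:
    """Per-volume metric table plus means; NaN marks undefined surface metrics."""

    per_volume: pd.DataFrame

    @property
    def n_volumes(self) -> int:
        return len(self.per_volume)

    @property
    def means(self) -> pd.Series:
        return self.per_volume[["dice", "jaccard", "asd", "hd95"]].mean()


def reassemble_volume(slice_preds: list[np.ndarray], original_shape: tuple[int, int, int],
                      z_indices: list[int] | None = None,
                      is_mask: bool = False) -> np.ndarray:
    """Stack per-slice predictions back into an (H, W, Z) volume.

    Exactly one prediction per Z plane must be supplied, in Z order (enforced
    through ``z_indices`` when given).  In-plane shapes are resized back to
    the original: nearest-neighbour for masks, linear for probability maps.
    """
    h, w, z = original_shape
    if len(slice_preds) != z:
        raise ValueError(f"expected {z} slices, got {len(slice_preds)}")
    if z_indices is not None:
        if list(z_indices) != list(range(z)):
            raise ValueError("slice predictions are not in Z order 0..Z-1")
    out = np.empty(original_shape, dtype=np.uint8 if is_mask else np.float32)
    for k, plane in enumerate(slice_preds):
        plane = np.asarray(plane)
        if plane.shape != (h, w):
            plane = (_resize_mask_rect(plane, (h, w)) if is_mask
                     else _resize_prob_rect(plane, (h, w)))
        out[:, :, k] = plane
    return out


def _resize_prob_rect(plane: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    from skimage.transform import resize

    return resize(plane, shape, order=1, preserve_range=True,
                  anti_aliasing=plane.shape[0] > shape[0]).astype(np.float32)


def _resize_mask_rect(plane: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    from skimage.transform import resize

    out = resize(plane, shape, order=0, preserve_range=True, anti_aliasing=False)
    return (out > 0.5).astype(np.uint8)


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """indicator(p >= threshold), as uint8."""
    return (np.asarray(prob) >= threshold).astype(np.uint8)


def overlap_metrics(pred: np.ndarray, label: np.ndarray
                    ) -> tuple[float, float, ConfusionCounts]:
    """Dice = 2TP/(FN+TP+TP+FP), Jaccard = TP/(FN+TP+FP); both-empty -> 1."""
    pred = np.asarray(pred).astype(bool)
    label = np.asarray(label).astype(bool)
    if pred.shape != label.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {label.shape}")
    tp = int(np.count_nonzero(pred & label))
    fp = int(np.count_nonzero(pred & ~label))
    fn = int(np.count_nonzero(~pred & label))
    tn = int(np.count_nonzero(~pred & ~label))
    counts = ConfusionCounts(tp, fp, fn, tn)
    if tp + fp + fn == 0:
        return 1.0, 1.0, counts
    dice = 2.0 * tp / (fn + tp + tp + fp)
    jaccard = tp / (fn + tp + fp)
    return dice, jaccard, counts


def boundary_mask(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with a background face-neighbour (outside = background)."""
    mask = np.asarray(mask).astype(bool)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def surface_distance_metrics(pred: np.ndarray, label: np.ndarray,
                             spacing=(1.0, 1.0, 1.0),
                             hd95_convention: str = "percentile"
                             ) -> tuple[float, float]:
    """ASD and HD95 between the two boundary voxel sets.

    ``hd95_convention='percentile'`` (default) takes the 95th percentile of
    the pooled symmetric nearest-boundary distances, the convention of the
    segmentation literature; ``'scaled_max'`` takes the literal
    max[d(X,Y), d(Y,X)] * 0.95 reading instead.
    """
    bp = boundary_mask(pred)
    bl = boundary_mask(label)
    if not bp.any() or not bl.any():
        raise EmptyMaskError("surface distances undefined: a mask has no boundary")
    spacing = np.asarray(spacing, dtype=np.float64)
    # exact Euclidean distance to the other set's boundary
    dt_to_label = ndimage.distance_transform_edt(~bl, sampling=spacing)
    dt_to_pred = ndimage.distance_transform_edt(~bp, sampling=spacing)
    d_pred = dt_to_label[bp]
    d_label = dt_to_pred[bl]
    asd = (d_pred.sum() + d_label.sum()) / (d_pred.size + d_label.size)
    if hd95_convention == "percentile":
        hd95 = float(np.percentile(np.concatenate([d_pred, d_label]), 95))
    elif hd95_convention == "scaled_max":
        hd95 = 0.95 * max(d_pred.max(), d_label.max())
    else:
        raise ValueError(f"unknown hd95_convention {hd95_convention!r}")
    return float(asd), float(hd95)


def predict_volume(model, vol: Volume, cfg: FrameworkConfig,
                   batch_size: int = 8) -> np.ndarray:
    """Probability volume for one input: slice, predict, reassemble.

    ``model`` maps a (N, H', W') image batch to per-pixel probabilities
    (anything exposing ``.final`` works, as do bare arrays).
    """
    samples = prepare_volume(vol, cfg, training=False)
    preds = []
    for i in range(0, len(samples), batch_size):
        chunk = np.stack([s.image for s in samples[i:i + batch_size]])
        out = model(chunk)
        out = out.final if hasattr(out, "final") else out
        arr = out.data if isinstance(out, Tensor) else np.asarray(out)
        preds.extend(arr)
    return reassemble_volume(preds, vol.shape,
                             z_indices=[s.z_index for s in samples], is_mask=False)


def evaluate(model, test_volumes: list[Volume], cfg: FrameworkConfig,
             threshold: float | None = None) -> MetricsReport:
    """Score a model on labelled test volumes with all four metrics.

    Undefined surface distances (empty predicted or reference boundary) are
    recorded as NaN in the per-volume table rather than failing the whole
    evaluation.
    """
    rows = []
    thr = cfg.binarize_threshold if threshold is None else threshold
    for vol in test_volumes:
        if vol.label is None:
            raise ValueError(f"test volume {vol.id!r} has no label")
        prob = predict_volume(model, vol, cfg)
        mask = binarize(prob, thr)
        dice, jaccard, counts = overlap_metrics(mask, vol.label)
        try:
            asd, hd95 = surface_distance_metrics(mask, vol.label, vol.voxel_spacing)
        except EmptyMaskError:
            asd, hd95 = float("nan"), float("nan")
        rows.append(dict(volume_id=vol.id, dice=dice, jaccard=jaccard,
                         asd=asd, hd95=hd95, tp=counts.TP, fp=counts.FP,
                         fn=counts.FN, tn=counts.TN))
    return MetricsReport(pd.DataFrame(rows))
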