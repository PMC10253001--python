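"""Slicing, preprocessing, pseudo-3D assembly and semi-supervised splits.

Volumes are cut along Z into 2D slices; each slice is min-max normalised,
gamma-brightened, resized to the network input size and bundled with its
neighbouring planes into a pseudo-3D stack.  Training slices whose label
plane is empty are dropped; at inference every slice is kept so the
predicted volume can be reassembled completely.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import resize

from .config import FrameworkConfig
from .synthetic import Volume

__all__ = [
    "SliceSample",
    "SemiSupervisedDataset",
    "Batch",
    "BatchIterator",
    "slice_volume",
    "preprocess_slices",
    "make_pseudo3d",
    "attach_stacks",
    "prepare_volume",
    "split_dataset",
    "make_batch",
]


@dataclass
class SliceSample:
    """One 2D training/inference sample cut from a volume at ``z_index``."""

    image: np.ndarray
    label: np.ndarray | None
    volume_id: str
    z_index: int
    stack: np.ndarray | None = None  # (2r+1, H, W); centre plane == image


@dataclass
class SemiSupervisedDataset:
    """Slice pools for training plus held-out test volumes.

    The three partitions come from disjoint volume sets; unlabeled samples
    have had their labels stripped at the volume level.
    """

    labeled: list[SliceSample]
    unlabeled: list[SliceSample]
    test: list[Volume]
    partition: dict[str, list[str]] | None = None

    def __post_init__(self):
        ids = [set(s.volume_id for s in self.labeled),
               set(s.volume_id for s in self.unlabeled),
               set(v.id for v in self.test)]
        for i in range(3):
            for j in range(i + 1, 3):
                common = ids[i] & ids[j]
                if common:
                    raise ValueError(f"volume(s) {sorted(common)} appear in two partitions")


def slice_volume(vol: Volume) -> list[SliceSample]:
    """Cut a volume into Z ordered slices, carrying label planes when present."""
    if vol.intensities.size == 0:
        raise ValueError(f"volume {vol.id!r} is empty")
    out = []
    for k in range(vol.shape[2]):
        lbl = vol.label[:, :, k] if vol.label is not None else None
        out.append(SliceSample(vol.intensities[:, :, k], lbl, vol.id, k))
    return out


def _normalize_brighten(img: np.ndarray, gamma: float) -> np.ndarray:
    img = np.asarray(img, dtype=np.float32)
    lo, hi = float(img.min()), float(img.max())
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        img = np.zeros_like(img)
    # gamma < 1 brightens the mid-range
    return np.power(img, gamma, dtype=np.float32)


def _resize_image(img: np.ndarray, size: int) -> np.ndarray:
    if img.shape == (size, size):
        return img.astype(np.float32)
    out = resize(img, (size, size), order=1, preserve_range=True,
                 anti_aliasing=img.shape[0] > size)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _resize_label(lbl: np.ndarray, size: int) -> np.ndarray:
    if lbl.shape == (size, size):
        return lbl.astype(np.uint8)
    out = resize(lbl, (size, size), order=0, preserve_range=True, anti_aliasing=False)
    return (out > 0.5).astype(np.uint8)


def preprocess_slices(samples: list[SliceSample], cfg: FrameworkConfig,
                      training: bool = False) -> list[SliceSample]:
    """Normalise, brighten and resize slices; drop empty-label training slices."""
    out = []
    for s in samples:
        img = _normalize_brighten(s.image, cfg.gamma)
        img = _resize_image(img, cfg.input_size)
        lbl = _resize_label(s.label, cfg.input_size) if s.label is not None else None
        if training and lbl is not None and not lbl.any():
            continue
        out.append(SliceSample(img, lbl, s.volume_id, s.z_index, stack=None))
    return out


def make_pseudo3d(slices: list[SliceSample], index: int, radius: int) -> np.ndarray:
    """Stack planes index-radius .. index+radius, replicate-padded at the ends."""
    if not slices:
        raise ValueError("empty slice list")
    if not 0 <= index < len(slices):
        raise IndexError(f"index {index} out of range for {len(slices)} slices")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    planes = [slices[min(max(index + d, 0), len(slices) - 1)].image
              for d in range(-radius, radius + 1)]
    return np.stack(planes, axis=0).astype(np.float32)


def attach_stacks(samples: list[SliceSample], radius: int) -> list[SliceSample]:
    return [replace(s, stack=make_pseudo3d(samples, i, radius))
            for i, s in enumerate(samples)]


def prepare_volume(vol: Volume, cfg: FrameworkConfig, training: bool) -> list[SliceSample]:
    """Full slice pipeline: cut, preprocess, attach pseudo-3D context, filter.

    Stacks are assembled before empty-slice filtering so that a kept slice's
    context still includes its true neighbours in the volume.
    """
    samples = preprocess_slices(slice_volume(vol), cfg, training=False)
    samples = attach_stacks(samples, cfg.context_radius)
    if training:
        samples = [s for s in samples if s.label is None or s.label.any()]
    return samples


def split_dataset(volumes: list[Volume], labeled_fraction: float, seed: int,
                  test_fraction: float = 0.1,
                  cfg: FrameworkConfig | None = None) -> SemiSupervisedDataset:
    """Partition volumes (never slices) into labeled / unlabeled / test pools."""
    if not 0.0 < labeled_fraction < 1.0:
        raise ValueError("labeled_fraction must lie in (0, 1)")
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must lie in [0, 1)")
    cfg = cfg if cfg is not None else FrameworkConfig()
    order = np.random.default_rng(seed).permutation(len(volumes))
    shuffled = [volumes[i] for i in order]
    n_test = int(round(test_fraction * len(volumes))) if test_fraction else 0
    if test_fraction and n_test == 0:
        n_test = 1
    train = shuffled[n_test:]
    n_labeled = int(round(labeled_fraction * len(train)))
    if n_labeled < 1:
        raise ValueError(
            f"labeled_fraction {labeled_fraction} yields no labeled volume "
            f"out of {len(train)} training volumes")
    if n_labeled >= len(train):
        raise ValueError("labeled_fraction leaves no unlabeled volumes")
    labeled_vols = train[:n_labeled]
    unlabeled_vols = [v.without_label() for v in train[n_labeled:]]
    test_vols = shuffled[:n_test]
    for v in test_vols:
        if v.label is None:
            raise ValueError(f"test volume {v.id!r} has no label")
    labeled = [s for v in labeled_vols for s in prepare_volume(v, cfg, training=True)]
    unlabeled = [s for v in unlabeled_vols for s in prepare_volume(v, cfg, training=True)]
    return SemiSupervisedDataset(
        labeled, unlabeled, test_vols,
        partition={"labeled": [v.id for v in labeled_vols],
                   "unlabeled": [v.id for v in unlabeled_vols],
                   "test": [v.id for v in test_vols]})


@dataclass
class Batch:
    labeled: list[SliceSample]
    unlabeled: list[SliceSample]

    def labeled_images(self) -> np.ndarray:
        return np.stack([s.image for s in self.labeled])

    def labeled_labels(self) -> np.ndarray:
        return np.stack([s.label for s in self.labeled]).astype(np.float32)

    def labeled_stacks(self) -> np.ndarray:
        return np.stack([s.stack for s in self.labeled])

    def unlabeled_images(self) -> np.ndarray:
        return np.stack([s.image for s in self.unlabeled])

    def unlabeled_stacks(self) -> np.ndarray:
        return np.stack([s.stack for s in self.unlabeled])


class _EpochCycler:
    """Without-replacement index stream, reshuffled at every epoch boundary."""

    def __init__(self, n: int, rng: np.random.Generator):
        if n == 0:
            raise ValueError("empty sample pool")
        self.n = n
        self.rng = rng
        self.order = rng.permutation(n)
        self.pos = 0

    def take(self, k: int) -> list[int]:
        out: list[int] = []
        while len(out) < k:
            if self.pos >= self.n:
                self.order = self.rng.permutation(self.n)
                self.pos = 0
            out.append(int(self.order[self.pos]))
            self.pos += 1
        return out

    def state_dict(self) -> dict:
        return {"order": self.order.tolist(), "pos": self.pos,
                "rng": self.rng.bit_generator.state}

    def load_state_dict(self, state: dict) -> None:
        self.order = np.asarray(state["order"], dtype=np.int64)
        self.pos = int(state["pos"])
        self.rng.bit_generator.state = state["rng"]


class BatchIterator:
    """Yields batches of labeled + unlabeled slices per the training protocol."""

    def __init__(self, dataset: SemiSupervisedDataset, cfg: FrameworkConfig,
                 rng: np.random.Generator):
        if not dataset.labeled:
            raise ValueError("labeled pool is empty")
        self.dataset = dataset
        self.cfg = cfg
        # independent child streams: the labeled sampling sequence is identical
        # whether or not the unlabeled pool is consumed (supervised ablations)
        labeled_rng, unlabeled_rng = rng.spawn(2)
        self.labeled_cycler = _EpochCycler(len(dataset.labeled), labeled_rng)
        self.unlabeled_cycler = None
        if not cfg.supervised_only:
            if not dataset.unlabeled:
                raise ValueError("unlabeled pool is empty")
            self.unlabeled_cycler = _EpochCycler(len(dataset.unlabeled), unlabeled_rng)

    def next_batch(self) -> Batch:
        labeled = [self.dataset.labeled[i]
                   for i in self.labeled_cycler.take(self.cfg.labeled_per_batch)]
        unlabeled = []
        if self.unlabeled_cycler is not None:
            unlabeled = [self.dataset.unlabeled[i]
                         for i in self.unlabeled_cycler.take(self.cfg.unlabeled_per_batch)]
        return Batch(labeled, unlabeled)

    def __next__(self):
        return self.next_batch()

    def state_dict(self) -> dict:
        return {"labeled": self.labeled_cycler.state_dict(),
                "unlabeled": (self.unlabeled_cycler.state_dict()
                              if self.unlabeled_cycler is not None else None)}

    def load_state_dict(self, state: dict) -> None:
        self.labeled_cycler.load_state_dict(state["labeled"])
        if self.unlabeled_cycler is not None and state["unlabeled"] is not None:
            self.unlabeled_cycler.load_state_dict(state["unlabeled"])


def make_batch(dataset: SemiSupervisedDataset, cfg: FrameworkConfig,
               rng: np.random.Generator) -> Batch:
    """Draw one batch; stateful epoch bookkeeping lives in :class:`BatchIterator`."""
    return BatchIterator(dataset, cfg, rng).next_batch()
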