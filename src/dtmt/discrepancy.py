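"""Inter-model discrepancy maps: the framework's uncertainty signal.

The student's three heads are compared against each teacher's final map by
weighted absolute differences.  Against the 2D teacher the comparison is
partitioned by the confidence anchor A — the batch-average probability the
student assigns to true target pixels of the labeled half — into
high-confidence (teacher probability >= A) and low-confidence regions,
giving the isomorphic map D1.  Against the hybrid teacher no partition is
applied (heterogeneous map D2).  The combined map D = m*D1 + n*D2 is driven
toward the all-zero image by the discrepancy loss and gates the
region-weighted consistency losses; its mean pixel value is the discrepancy
rate Dr, a scalar training diagnostic.

All functions accept either plain numpy arrays or autodiff tensors; maps
keep per-pixel, per-sample resolution so they can gate the consistency loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DiscrepancyConfig
from .nn import NetworkOutputs, Tensor, absolute, mean
from .nn.autodiff import power

__all__ = [
    "ConfidenceAnchor",
    "DiscrepancyRateRecord",
    "compute_anchor",
    "partition_confidence",
    "compute_d1",
    "compute_d2",
    "combine_discrepancy",
    "discrepancy_loss",
    "discrepancy_rate",
    "export_map_png",
]


def _data(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _abs(x):
    return absolute(x) if isinstance(x, Tensor) else np.abs(x)


def _mean(x):
    return mean(x) if isinstance(x, Tensor) else float(np.mean(x))


def _square(x):
    return power(x, 2.0) if isinstance(x, Tensor) else np.square(x)


@dataclass
class ConfidenceAnchor:
    """Batch-level average predicted probability over true target pixels."""

    A: float
    masked_predictions: np.ndarray  # S_i = f_s(x_i) * y_i, per labeled sample
    target_pixel_sum: float

    def __post_init__(self):
        if not 0.0 <= self.A <= 1.0:
            raise ValueError(f"anchor A={self.A} outside [0, 1]")


@dataclass
class DiscrepancyRateRecord:
    """Dr = sum(D) / (pixels per map x number of maps) = mean pixel value of D."""

    Dr: float
    pixel_sum: float
    denominator: float
    iteration: int = 0


def compute_anchor(student_final, labels) -> ConfidenceAnchor:
    """A = sum_i Sum(f_s(x_i) * y_i) / sum_i Sum(y_i) over the labeled batch."""
    preds = _data(student_final).astype(np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if preds.shape != y.shape:
        raise ValueError(f"shape mismatch {preds.shape} vs {y.shape}")
    masked = preds * y
    denom = float(y.sum())
    if denom == 0:
        raise ValueError("anchor undefined: no target pixel in the labeled batch")
    return ConfidenceAnchor(A=float(masked.sum() / denom),
                            masked_predictions=masked,
                            target_pixel_sum=denom)


def partition_confidence(teacher1_final, anchor: ConfidenceAnchor | float
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Split the teacher map into high (p >= A) and low (p < A) confidence masks."""
    t1 = _data(teacher1_final)
    a = anchor.A if isinstance(anchor, ConfidenceAnchor) else float(anchor)
    high = (t1 >= a).astype(t1.dtype)
    return high, 1.0 - high


def _head_difference(student: NetworkOutputs, teacher_final, cfg: DiscrepancyConfig):
    """a|f_s - f_t| + b|f_s1 - f_t| + c|f_s2 - f_t|, per pixel."""
    t = teacher_final
    for m in (student.final, student.aux_last, student.aux_penult):
        if m.shape != _data(t).shape:
            raise ValueError(f"shape mismatch {m.shape} vs {_data(t).shape}")
    return (cfg.a * _abs(student.final - t)
            + cfg.b * _abs(student.aux_last - t)
            + cfg.c * _abs(student.aux_penult - t))


def compute_d1(student: NetworkOutputs, teacher1_final,
               anchor: ConfidenceAnchor | None, cfg: DiscrepancyConfig):
    """Isomorphic discrepancy, partitioned by the anchor.

    With ``anchor=None`` (prediction optimisation disabled) the whole image
    counts as high-confidence, so D1 is independent of A.
    Returns ``(D1h, D1l, D1)``.
    """
    t1 = _data(teacher1_final)
    if anchor is None:
        high = np.ones_like(t1)
        low = np.zeros_like(t1)
    else:
        high, low = partition_confidence(t1, anchor)
        if cfg.binarize_teacher1_at_anchor:
            # alternative reading: the anchor rewrites the teacher map itself
            teacher1_final = high.copy()
    diff = _head_difference(student, teacher1_final, cfg)
    d1h = diff * high
    d1l = diff * low
    d1 = cfg.high * d1h + cfg.low * d1l
    return d1h, d1l, d1


def compute_d2(student: NetworkOutputs, teacher2_final, cfg: DiscrepancyConfig):
    """Heterogeneous discrepancy between the student heads and the hybrid teacher."""
    return _head_difference(student, teacher2_final, cfg)


def combine_discrepancy(d1, d2, cfg: DiscrepancyConfig):
    """D = m * D1 + n * D2; with ``d2=None`` the map reduces to D1 exactly."""
    if d2 is None:
        return d1
    if _data(d1).shape != _data(d2).shape:
        raise ValueError(f"shape mismatch {_data(d1).shape} vs {_data(d2).shape}")
    return cfg.m * d1 + cfg.n * d2


def discrepancy_loss(d):
    """MSE between D and the all-zero image: mean over pixels and samples of D^2."""
    return _mean(_square(d))


def discrepancy_rate(d, iteration: int = 0) -> DiscrepancyRateRecord:
    """Mean pixel value of D: sum(D) / (pixels per map x number of maps)."""
    arr = _data(d).astype(np.float64)
    total = float(arr.sum())
    denom = float(arr.size)
    return DiscrepancyRateRecord(Dr=total / denom, pixel_sum=total,
                                 denominator=denom, iteration=iteration)


def export_map_png(d, path) -> None:
    """Write a discrepancy (or probability) map as an 8-bit grayscale PNG."""
    from PIL import Image

    arr = _data(d).astype(np.float64)
    if arr.ndim == 3:
        arr = arr[0]
    hi = arr.max()
    if hi > 0:
        arr = arr / hi
    Image.fromarray((arr * 255).astype(np.uint8), mode="L").save(path)
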