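"""Training objective: supervised Dice, gated consistency, and their mixture.

The supervised term is the Dice loss summed over the labeled samples of the
batch.  The consistency terms compare student and teacher final maps with a
mean-squared error split by the discrepancy gate II(D > TH): the
high-discrepancy region is weighted by alpha, the rest by beta, each MSE
normalised by its own pixel count so the region weights are not confounded
with region size.  The unsupervised terms are scaled by a Gaussian warm-up
ramp for the first ``ramp_length`` iterations — with freshly initialised
teachers the early consistency targets are noise, and the ramp keeps them
from swamping the supervised signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DiscrepancyConfig, LossWeights
from .nn import Tensor, tensor_sum
from .nn.autodiff import power

__all__ = [
    "LossReport",
    "dice_loss",
    "gated_consistency_loss",
    "combine_consistency",
    "ramp_factor",
    "total_objective",
    "total_loss",
]


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _data(x) -> np.ndarray:
    return x.data if _is_tensor(x) else np.asarray(x)


def _sum(x, axis=None):
    return tensor_sum(x, axis=axis) if _is_tensor(x) else np.sum(x, axis=axis)


def _square(x):
    return power(x, 2.0) if _is_tensor(x) else np.square(x)


def _scalar(x) -> float:
    return float(x.data) if _is_tensor(x) else float(x)


@dataclass
class LossReport:
    """Per-iteration loss components (floats, for logging)."""

    l_sup: float
    l_D: float
    l_Dcon1: float
    l_Dcon2: float
    l_Dcon: float
    l_total: float
    iteration: int
    ramp: float = 1.0
    anchor: float = float("nan")
    d1_high_sum: float = 0.0
    d1_low_sum: float = 0.0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def dice_loss(pred, label, smooth: float = 1e-5):
    """1 - (2 |P∩Y| + s) / (|P| + |Y| + s), summed over the batch samples.

    ``pred`` is a probability map (H, W) or a batch (N, H, W); ``label`` is a
    same-shaped binary map.  Returns a scalar (autodiff tensor when ``pred``
    is one).
    """
    y = np.asarray(label, dtype=np.float64)
    if _data(pred).shape != y.shape:
        raise ValueError(f"shape mismatch {_data(pred).shape} vs {y.shape}")
    if not np.isin(np.unique(y), (0.0, 1.0)).all():
        raise ValueError("label must be binary")
    y = y.astype(np.float32)
    batched = y.ndim == 3
    axis = (1, 2) if batched else None
    inter = _sum(pred * y, axis=axis)
    psum = _sum(pred, axis=axis)
    lsum = y.sum(axis=axis)
    per_sample = 1.0 - (2.0 * inter + smooth) / (psum + lsum + smooth)
    return _sum(per_sample) if batched else per_sample


def gated_consistency_loss(student_final, teacher_final, d_map,
                           cfg: DiscrepancyConfig):
    """alpha * MSE on {D > TH} + beta * MSE on {D <= TH}, each per-region-normalised."""
    t = _data(teacher_final)
    dm = _data(d_map)
    if _data(student_final).shape != t.shape or dm.shape != t.shape:
        raise ValueError("student, teacher and D maps must share one shape")
    hi = (dm > cfg.th).astype(np.float32)
    lo = 1.0 - hi
    sq = _square(student_final - t)
    loss = 0.0
    n_hi, n_lo = float(hi.sum()), float(lo.sum())
    if n_hi > 0:
        loss = loss + cfg.alpha * _sum(sq * hi) * (1.0 / n_hi)
    if n_lo > 0:
        loss = loss + cfg.beta * _sum(sq * lo) * (1.0 / n_lo)
    return loss


def combine_consistency(l1, l2, cfg: DiscrepancyConfig):
    """l_Dcon = w * l_Dcon1 + v * l_Dcon2."""
    return cfg.w * l1 + cfg.v * l2


def ramp_factor(iteration: int, ramp_length: int) -> float:
    """Gaussian warm-up exp(-5 (1 - t/L)^2) for t < L, then exactly 1."""
    if ramp_length <= 0 or iteration >= ramp_length:
        return 1.0
    frac = max(float(iteration), 0.0) / float(ramp_length)
    return float(np.exp(-5.0 * (1.0 - frac) ** 2))


def total_objective(l_sup, l_d, l_dcon, weights: LossWeights, iteration: int):
    """X * l_sup + ramp(t) * (Y * l_D + Z * l_Dcon); tensor-aware."""
    r = ramp_factor(iteration, weights.ramp_length)
    return weights.X * l_sup + r * (weights.Y * l_d + weights.Z * l_dcon)


def total_loss(l_sup, l_d, l_dcon, weights: LossWeights, iteration: int,
               l_dcon1=0.0, l_dcon2=0.0, **extra) -> LossReport:
    """Assemble the logged report for one iteration."""
    ls, ld, lc = _scalar(l_sup), _scalar(l_d), _scalar(l_dcon)
    return LossReport(
        l_sup=ls, l_D=ld, l_Dcon1=_scalar(l_dcon1), l_Dcon2=_scalar(l_dcon2),
        l_Dcon=lc,
        l_total=_scalar(total_objective(ls, ld, lc, weights, iteration)),
        iteration=iteration,
        ramp=ramp_factor(iteration, weights.ramp_length),
        **extra,
    )
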