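"""Configuration objects for the double-teacher framework.

Every constant the training objective leaves symbolic lives here with an
explicit default, and round-trips losslessly through YAML so a saved run
snapshot reproduces the run bit-for-bit under fixed seeds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "DiscrepancyConfig",
    "LossWeights",
    "FrameworkConfig",
    "PRESETS",
    "preset",
    "load_config",
    "save_config",
]


@dataclass
class DiscrepancyConfig:
    """Coefficients of the discrepancy maps and gated consistency losses.

    ``a``, ``b``, ``c`` weight the three student heads (final, last-upsampling
    auxiliary, penultimate-upsampling auxiliary) inside D1/D2; ``high``/``low``
    weight the confidence partition of D1; ``m``/``n`` mix D1 and D2 into the
    combined map D.  ``th`` is the gate threshold on D; ``alpha``/``beta``
    weight the high-/low-discrepancy regions of the consistency losses and
    ``w``/``v`` mix the two teachers' consistency terms.
    """

    a: float = 1.0 / 3.0
    b: float = 1.0 / 3.0
    c: float = 1.0 / 3.0
    high: float = 1.0
    low: float = 1.0
    m: float = 0.5
    n: float = 0.5
    th: float = 0.1
    alpha: float = 0.6
    beta: float = 0.4
    w: float = 0.5
    v: float = 0.5
    binarize_teacher1_at_anchor: bool = False

    def __post_init__(self):
        for name in ("a", "b", "c", "high", "low", "m", "n", "th", "alpha", "beta", "w", "v"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.a + self.b + self.c <= 0:
            raise ValueError("a + b + c must be positive")
        if self.m + self.n <= 0:
            raise ValueError("m + n must be positive")


@dataclass
class LossWeights:
    """Objective mixing: total = X * sup + ramp(t) * (Y * disc + Z * consistency)."""

    X: float = 1.0
    Y: float = 1.0
    Z: float = 1.0
    ramp_length: int = 100

    def __post_init__(self):
        if self.X <= 0:
            raise ValueError("X must be positive")
        if self.Y < 0 or self.Z < 0:
            raise ValueError("Y and Z must be nonnegative")


@dataclass
class FrameworkConfig:
    """Everything needed to reproduce a training run."""

    discrepancy: DiscrepancyConfig = field(default_factory=DiscrepancyConfig)
    loss_weights: LossWeights = field(default_factory=LossWeights)
    # optimisation
    ema_decay: float = 0.99
    learning_rate: float = 0.02
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 8
    labeled_per_batch: int = 4
    iterations: int = 400
    # data / architecture
    input_size: int = 128
    context_radius: int = 1
    gamma: float = 0.8
    base_channels: int = 16
    depth: int = 4
    perturbation_sd: float = 0.1
    binarize_threshold: float = 0.5
    # seeds
    data_seed: int = 0
    init_seed: int = 0
    perturbation_seed: int = 0
    # ablation switches
    use_teacher2: bool = True
    use_prediction_optimization: bool = True
    supervised_only: bool = False

    def __post_init__(self):
        if not (0.0 <= self.ema_decay < 1.0 or self.ema_decay == 1.0):
            raise ValueError("ema_decay must lie in [0, 1]")
        if not 0 < self.labeled_per_batch <= self.batch_size:
            raise ValueError("labeled_per_batch must be in (0, batch_size]")
        if self.labeled_per_batch == self.batch_size and not self.supervised_only:
            raise ValueError("semi-supervised runs need labeled_per_batch < batch_size")
        if self.iterations <= 0:
            raise ValueError("iterations must be positive")
        if self.context_radius < 1:
            raise ValueError("context_radius must be >= 1")
        if self.input_size % 2 ** (self.depth - 1):
            raise ValueError("input_size must be divisible by 2**(depth-1)")

    @property
    def unlabeled_per_batch(self) -> int:
        return self.batch_size - self.labeled_per_batch

    @property
    def stack_planes(self) -> int:
        return 2 * self.context_radius + 1

    # -- serialisation --------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FrameworkConfig":
        d = dict(d)
        d["discrepancy"] = DiscrepancyConfig(**d.get("discrepancy", {}))
        d["loss_weights"] = LossWeights(**d.get("loss_weights", {}))
        return cls(**d)


def save_config(cfg: FrameworkConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def load_config(path) -> FrameworkConfig:
    return FrameworkConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def _preset(use_teacher2: bool, use_po: bool, **overrides) -> FrameworkConfig:
    disc = DiscrepancyConfig(**({} if use_teacher2 else {"m": 1.0, "n": 0.0}))
    return FrameworkConfig(discrepancy=disc, use_teacher2=use_teacher2,
                           use_prediction_optimization=use_po, **overrides)


#: The four ablation variants of the framework: the plain 2D teacher, with
#: anchor-based prediction optimisation, with the hybrid teacher, and the
#: complete double-teacher configuration.
PRESETS = {
    "teacher1": (False, False),
    "teacher1_po": (False, True),
    "teacher1_teacher2": (True, False),
    "full": (True, True),
}


def preset(name: str, **overrides) -> FrameworkConfig:
    try:
        use_teacher2, use_po = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return _preset(use_teacher2, use_po, **overrides)
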