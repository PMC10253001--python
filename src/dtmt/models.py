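"""Segmentation network builders and input perturbation.

The student and the 2D teacher are the same U-Net architecture (the teacher
starts as a parameter copy of the student and is thereafter updated only by
EMA).  The hybrid teacher additionally carries a plane-collapsing 3D stem
fused with the centre-plane 2D features; all of its student-shaped
parameters share names with the student's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import HybridUNet, NetworkOutputs, UNet2D

__all__ = [
    "NetworkOutputs",
    "PerturbationSpec",
    "build_student",
    "build_teacher2d",
    "build_teacher_hybrid",
    "perturb",
    "perturb_with_rng",
]


@dataclass
class PerturbationSpec:
    """Additive i.i.d. Gaussian input noise, clipped back to [0, 1]."""

    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def build_student(channels_base: int = 16, depth: int = 4, seed: int = 0,
                  input_size: int = 128) -> UNet2D:
    """2D student U-Net with two auxiliary heads; deterministic init per seed."""
    if depth < 2:
        raise ValueError("depth must be >= 2")
    if input_size % 2 ** (depth - 1):
        raise ValueError(
            f"input size {input_size} not divisible by 2**(depth-1)={2 ** (depth - 1)}")
    return UNet2D(in_channels=1, base_channels=channels_base, depth=depth,
                  rng=np.random.default_rng(seed))


def build_teacher2d(like: UNet2D) -> UNet2D:
    """Architecture and parameters copied from the student; frozen for EMA."""
    teacher = UNet2D(in_channels=like.in_channels, base_channels=like.base_channels,
                     depth=like.depth, rng=np.random.default_rng(0))
    teacher.load_state_dict(like.state_dict())
    teacher.set_requires_grad(False)
    return teacher


def build_teacher_hybrid(stack_planes: int = 3, channels_base: int = 16,
                         depth: int = 4, seed: int = 0) -> HybridUNet:
    """Hybrid 2D/3D teacher over pseudo-3D stacks; deterministic init per seed."""
    return HybridUNet(stack_planes=stack_planes, base_channels=channels_base,
                      depth=depth, rng=np.random.default_rng(seed))


def perturb_with_rng(x: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian noise drawn from an existing stream, clipped to [0, 1]."""
    x = np.asarray(x, dtype=np.float32)
    if noise_sd == 0:
        return x.copy()
    noisy = x + noise_sd * rng.standard_normal(size=x.shape, dtype=np.float32)
    return np.clip(noisy, 0.0, 1.0)


def perturb(x: np.ndarray, spec: PerturbationSpec) -> np.ndarray:
    """Deterministic perturbation of an image or stack, seeded by ``spec.seed``."""
    return perturb_with_rng(x, spec.noise_sd, np.random.default_rng(spec.seed))
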