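"""Synthetic 3D phantom volumes emulating a contrast-enhanced atrium scan.

A phantom is one large bright quasi-spherical blob (the chamber) plus a few
small bright satellites (vessel stumps / appendage) on a darker background,
blurred to soften boundaries and corrupted with i.i.d. Gaussian noise.  The
binary label is the exact union of the rasterised blobs, so slices of the
phantom behave like the real training material: most Z planes contain a
target cross-section whose size varies along Z, and some end planes are
empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["PhantomParams", "Volume", "generate_phantom", "generate_cohort"]


@dataclass
class Volume:
    """A 3D grayscale image with an optional voxel-wise binary label.

    ``intensities`` is (H, W, Z) in [0, 1]; ``label`` (if present) is a
    same-shaped {0,1} array.  ``voxel_spacing`` is (sx, sy, sz) in physical
    units, used only by the surface-distance metrics.
    """

    intensities: np.ndarray
    label: np.ndarray | None = None
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    id: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.ndim != 3:
            raise ValueError(f"volume {self.id!r}: intensities must be 3D")
        if self.label is not None:
            self.label = np.asarray(self.label)
            if self.label.shape != self.intensities.shape:
                raise ValueError(f"volume {self.id!r}: label shape mismatch")
            vals = np.unique(self.label)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"volume {self.id!r}: label values must be 0/1")
            self.label = self.label.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def without_label(self) -> "Volume":
        return Volume(self.intensities, None, self.voxel_spacing, self.id, self.affine)


@dataclass
class PhantomParams:
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    main_blob_radius_range: tuple[float, float] = (9.0, 13.0)
    n_satellites: int = 2
    satellite_radius_range: tuple[float, float] = (2.0, 4.0)
    fg_intensity: float = 0.8
    bg_intensity: float = 0.3
    noise_sd: float = 0.05
    smooth_sigma: float = 1.0
    seed: int = 0

    @classmethod
    def scaled_to(cls, grid_shape, seed: int = 0, **overrides) -> "PhantomParams":
        """Defaults with blob radii scaled to the smallest grid dimension
        (main blob ~0.28-0.4x, satellites ~0.06-0.12x)."""
        m = min(int(d) for d in grid_shape)
        params = dict(grid_shape=tuple(int(d) for d in grid_shape),
                      main_blob_radius_range=(0.28 * m, 0.4 * m),
                      satellite_radius_range=(0.06 * m, 0.12 * m),
                      seed=seed)
        params.update(overrides)
        return cls(**params)

    def __post_init__(self):
        if any(int(d) < 8 for d in self.grid_shape):
            raise ValueError(f"grid_shape {self.grid_shape}: every dimension must be >= 8")
        lo, hi = self.main_blob_radius_range
        if not 0 < lo <= hi:
            raise ValueError("main_blob_radius_range must satisfy 0 < lo <= hi")
        if 2 * hi >= min(self.grid_shape):
            raise ValueError("main blob does not fit inside the grid")
        slo, shi = self.satellite_radius_range
        if self.n_satellites and not 0 < slo <= shi:
            raise ValueError("satellite_radius_range must satisfy 0 < lo <= hi")
        if self.n_satellites < 0:
            raise ValueError("n_satellites must be nonnegative")
        if not self.fg_intensity > self.bg_intensity:
            raise ValueError("fg_intensity must exceed bg_intensity")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _rasterize_sphere(mask: np.ndarray, center: np.ndarray, radius: float) -> None:
    """Set voxels whose centre lies inside the sphere (||x - c|| <= r)."""
    h, w, z = mask.shape
    xi, yi, zi = np.ogrid[:h, :w, :z]
    d2 = (xi - center[0]) ** 2 + (yi - center[1]) ** 2 + (zi - center[2]) ** 2
    mask[d2 <= radius * radius] = 1


def generate_phantom(params: PhantomParams) -> Volume:
    """Deterministically generate one labelled phantom volume.

    The label is the union of the rasterised blobs; the image is
    ``bg + (fg - bg) * label`` smoothed by a Gaussian of ``smooth_sigma``
    voxels, plus ``noise_sd`` Gaussian noise, clipped to [0, 1].
    """
    rng = np.random.default_rng(params.seed)
    shape = tuple(int(d) for d in params.grid_shape)
    label = np.zeros(shape, dtype=np.uint8)

    radius = rng.uniform(*params.main_blob_radius_range)
    centre_lo = np.array([radius + 1.0] * 3)
    centre_hi = np.asarray(shape) - radius - 1.0
    centre = rng.uniform(centre_lo, centre_hi)
    _rasterize_sphere(label, centre, radius)

    for _ in range(params.n_satellites):
        r = rng.uniform(*params.satellite_radius_range)
        # satellites hug the main blob surface so they read as attached vessels
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        c = centre + direction * (radius + 0.5 * r)
        c = np.clip(c, r + 1.0, np.asarray(shape) - r - 1.0)
        _rasterize_sphere(label, c, r)

    img = params.bg_intensity + (params.fg_intensity - params.bg_intensity) * label
    img = img.astype(np.float32)
    if params.smooth_sigma > 0:
        img = gaussian_filter(img, params.smooth_sigma)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=shape).astype(np.float32)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return Volume(img, label, id=f"phantom-{params.seed:05d}")


def generate_cohort(n_volumes: int, seed: int = 0,
                    params: PhantomParams | None = None) -> list[Volume]:
    """Generate ``n_volumes`` phantoms with per-volume seeds derived from ``seed``."""
    base = params if params is not None else PhantomParams()
    seeds = np.random.SeedSequence(seed).generate_state(n_volumes) % (2 ** 31)
    out = []
    for i, s in enumerate(seeds):
        p = PhantomParams(**{**base.__dict__, "seed": int(s)})
        vol = generate_phantom(p)
        vol.id = f"phantom-{i:03d}"
        out.append(vol)
    return out
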