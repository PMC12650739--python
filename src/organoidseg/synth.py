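"""Seeded synthetic bright-field organoid images with exact ground truth.

A generated frame emulates the salient features of transmitted-light
organoid micrographs: a bright, slightly uneven background; a single
darker, roughly elliptical organoid with an irregular star-convex
boundary; a dark rim (halo) along the organoid edge; mild optics blur;
and Gaussian sensor noise. The organoid interior is known analytically,
so every downstream stage can be scored against an exact mask.

The boundary is a radial-harmonic star-convex curve

    r(theta) = r0 * (1 + irregularity * sum_k a_k cos(k*theta + phi_k))

with seeded coefficients normalised so the total perturbation never
exceeds ``irregularity`` — the mask (the exact curve interior) is then
well defined for any draw.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ParameterError
from .io import DatasetItem, PairedDataset, split_dataset, write_image, write_mask

__all__ = ["SynthParams", "generate_organoid_image", "generate_dataset"]


@dataclass(frozen=True)
class SynthParams:
    """Generation parameters; defaults define the package's study conditions.

    Intensities are unit-interval; radii are fractions of the image side.
    ``halo_width`` is the thickness in pixels of the dark rim occupying the
    band just inside the true boundary, and ``blur_sigma`` models optics
    blur (applied before noise).
    """

    background_level: float = 0.82
    organoid_level: float = 0.45
    radius_range: tuple[float, float] = (0.15, 0.35)
    irregularity: float = 0.15
    n_harmonics: int = 6
    halo_width: float = 3.0
    noise_sigma: float = 0.03
    illum_gradient: float = 0.10
    blur_sigma: float = 0.7
    halo_level_factor: float = 0.6  # halo intensity = factor * organoid_level
    rgb: bool = False

    def __post_init__(self):
        if not (0.0 < self.organoid_level < self.background_level <= 1.0):
            raise ParameterError(
                "need 0 < organoid_level < background_level <= 1, got "
                f"{self.organoid_level}, {self.background_level}"
            )
        if not (0.0 <= self.irregularity < 1.0):
            raise ParameterError(f"irregularity must be in [0, 1), got {self.irregularity}")
        if self.noise_sigma < 0:
            raise ParameterError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        lo, hi = self.radius_range
        if not (0 < lo <= hi < 0.5):
            raise ParameterError(f"radius_range must satisfy 0 < lo <= hi < 0.5, got {self.radius_range}")
        if self.n_harmonics < 1:
            raise ParameterError("n_harmonics must be >= 1")


def _boundary_radius(theta: np.ndarray, r0: float, params: SynthParams,
                     rng: np.random.Generator) -> np.ndarray:
    k = np.arange(1, params.n_harmonics + 1)
    a = rng.normal(size=params.n_harmonics)
    norm = np.sum(np.abs(a))
    a = a / norm if norm > 0 else a
    phi = rng.uniform(0.0, 2.0 * np.pi, size=params.n_harmonics)
    pert = np.sum(
        a[:, None] * np.cos(k[:, None] * theta[None, :] + phi[:, None]), axis=0
    )
    return r0 * (1.0 + params.irregularity * pert)


def generate_organoid_image(side: int, params: SynthParams | None = None,
                            seed: int = 0):
    """Generate one frame; returns ``(image, mask)``.

    The mask is the exact discrete interior of the star-convex boundary
    curve. Deterministic for a given ``(side, params, seed)``.
    """
    if side < 32:
        raise ParameterError(f"side must be >= 32, got {side}")
    params = params or SynthParams()
    rng = np.random.default_rng(seed)

    r0 = rng.uniform(*params.radius_range) * side
    r_max = r0 * (1.0 + params.irregularity)
    slack = max(0.0, side / 2.0 - r_max - params.halo_width - 2.0)
    jitter = min(slack, 0.1 * side)
    cy = side / 2.0 + rng.uniform(-jitter, jitter)
    cx = side / 2.0 + rng.uniform(-jitter, jitter)

    yy, xx = np.mgrid[0:side, 0:side]
    dy = yy - cy
    dx = xx - cx
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx).ravel()
    r_theta = _boundary_radius(theta, r0, params, rng).reshape(side, side)

    mask = dist <= r_theta

    # illumination gradient along a seeded random direction
    ang = rng.uniform(0.0, 2.0 * np.pi)
    proj = (np.cos(ang) * xx + np.sin(ang) * yy)
    proj = (proj - proj.min()) / max(proj.max() - proj.min(), 1e-12)
    illum = 1.0 - params.illum_gradient * proj

    image = np.full((side, side), params.background_level, dtype=np.float64)
    image[mask] = params.organoid_level
    # dark rim occupying the band just inside the boundary
    signed = dist - r_theta  # < 0 inside
    halo = (signed < 0) & (signed >= -params.halo_width)
    image[halo] = params.halo_level_factor * params.organoid_level
    image *= illum

    if params.blur_sigma > 0:
        image = gaussian_filter(image, params.blur_sigma, mode="nearest")
    if params.noise_sigma > 0:
        image = image + rng.normal(0.0, params.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    if params.rgb:
        # green carries the clean signal; red/blue are dimmed copies with
        # extra noise, mimicking the colour-camera images the green channel
        # is extracted from
        r = np.clip(image * 0.92 + rng.normal(0, 0.02, image.shape), 0, 1)
        b = np.clip(image * 0.88 + rng.normal(0, 0.02, image.shape), 0, 1)
        image = np.stack([r, image, b], axis=-1).astype(np.float32)

    return image, mask


def generate_dataset(n: int, side: int, params: SynthParams | None = None,
                     seed: int = 0, out_dir=None, image_format: str = "tif"
                     ) -> PairedDataset:
    """Write ``n`` seeded image/mask pairs plus a CSV manifest.

    Per-image seeds are derived deterministically from the master seed, so
    two runs with the same arguments produce identical datasets.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    params = params or SynthParams()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)

    items = []
    width = max(4, len(str(n - 1)))
    for i in range(n):
        image, mask = generate_organoid_image(side, params, int(child_seeds[i]))
        img_path = out_dir / f"img_{i:0{width}d}.{image_format}"
        msk_path = out_dir / f"mask_{i:0{width}d}.png"
        write_image(img_path, image)
        write_mask(msk_path, mask)
        items.append(DatasetItem(f"{i:0{width}d}", img_path, msk_path))

    ds = PairedDataset(items=items, patch_size=side)
    ds.to_manifest(out_dir / "manifest.csv")
    return ds


def dataset_with_split(n: int, side: int, params: SynthParams | None = None,
                       seed: int = 0, out_dir=None):
    """Convenience: generate a dataset and its default 70/10/20 split."""
    ds = generate_dataset(n, side, params, seed, out_dir)
    split = split_dataset(ds, seed=seed)
    ds.to_manifest(Path(out_dir) / "manifest.csv", split)
    return ds, split
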