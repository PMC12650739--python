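"""Comparison segmentation methods: Hölder-mean thresholding, 1-D K-means
intensity clustering, and the plain deep-learning semantic-segmentation
path (the same backbone with every refinement switched off)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classical import extract_green_channel
from .errors import DegenerateInputError, FormatError, ParameterError
from .nn import UNet
from .refine import RefineConfig, segment

__all__ = [
    "HolderParams", "KMeansParams", "holder_mean", "holder_segment",
    "kmeans_segment", "plain_semantic_segment",
]


@dataclass(frozen=True)
class HolderParams:
    """Power-mean exponent and foreground polarity for Hölder segmentation."""

    p: float = 2.0
    polarity: str = "dark_foreground"

    def __post_init__(self):
        if not np.isfinite(self.p):
            raise ParameterError("p must be finite")
        if self.polarity not in {"dark_foreground", "bright_foreground"}:
            raise ParameterError(f"unknown polarity {self.polarity!r}")


@dataclass(frozen=True)
class KMeansParams:
    """1-D two-class k-means parameters.

    ``init="exact"`` (default) computes the global SSE optimum directly:
    in one dimension the optimal clusters are intervals, so an exhaustive
    search over the n-1 sorted split points finds the exact k-means
    solution deterministically. ``init="extremes"`` (centres at the
    minimum and maximum intensity, deterministic) and ``init="random"``
    (seeded) instead run classical Lloyd iterations from that start,
    which can settle in a local optimum.
    """

    k: int = 2
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0
    init: str = "exact"  # or "extremes" / "random"

    def __post_init__(self):
        if self.k != 2:
            raise ParameterError("this application uses k = 2")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")
        if self.init not in {"exact", "extremes", "random"}:
            raise ParameterError(f"unknown init {self.init!r}")


def holder_mean(values, p: float) -> float:
    """Generalised power mean ``M_p = ((1/n) sum v^p)^(1/p)``.

    ``p = 0`` takes the geometric-mean limit ``exp(mean(log v))``. All
    values must be strictly positive.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ParameterError("holder_mean of an empty collection")
    if np.any(v <= 0):
        raise ParameterError("holder_mean requires strictly positive values")
    if p == 0:
        return float(np.exp(np.mean(np.log(v))))
    return float(np.mean(v ** p) ** (1.0 / p))


def holder_segment(image: np.ndarray, params: HolderParams | None = None):
    """Threshold at the Hölder mean of all pixel intensities.

    Foreground is the set of pixels strictly below the threshold
    (``dark_foreground``) or strictly above it (``bright_foreground``).
    Zero intensities are offset by 1/255 before the mean is taken.
    Returns ``(mask, degenerate)`` where ``degenerate`` flags a constant
    image whose mask is trivially empty or full.
    """
    params = params or HolderParams()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise FormatError("holder_segment expects a single-channel image")
    vals = np.maximum(image, 1.0 / 255.0)
    thr = holder_mean(vals, params.p)
    if params.polarity == "dark_foreground":
        mask = vals < thr
    else:
        mask = vals > thr
    degenerate = bool(image.max() == image.min())
    return mask, degenerate


def _exact_split_centres(vals: np.ndarray) -> np.ndarray:
    """Global 1-D two-means optimum via exhaustive interval-split search.

    Optimal k-means clusters on a line are intervals, so scanning the
    n-1 split points of the sorted sample with prefix sums yields the
    exact SSE minimiser in O(n log n).
    """
    s = np.sort(vals)
    n = s.size
    csum = np.cumsum(s)
    csq = np.cumsum(s * s)
    k = np.arange(1, n)  # size of the lower cluster
    lo_sse = csq[:-1] - csum[:-1] ** 2 / k
    hi_sum = csum[-1] - csum[:-1]
    hi_sse = (csq[-1] - csq[:-1]) - hi_sum ** 2 / (n - k)
    best = int(np.argmin(lo_sse + hi_sse))
    return np.array([csum[best] / (best + 1), hi_sum[best] / (n - best - 1)])


def kmeans_segment(image: np.ndarray, params: KMeansParams | None = None):
    """Two-class k-means on raw 1-D intensities.

    The darker-centred cluster is foreground. The default ``init="exact"``
    finds the global SSE optimum directly (see :class:`KMeansParams`);
    all modes then run Lloyd assignment/update iterations until the
    centre shift falls below ``tol`` or ``max_iter`` is reached (a no-op
    from the exact start, which is already a fixed point). Deterministic
    except under ``init="random"`` with varying seeds.
    """
    params = params or KMeansParams()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise FormatError("kmeans_segment expects a single-channel image")
    vals = image.ravel()
    uniq = np.unique(vals)
    if uniq.size < 2:
        raise DegenerateInputError("constant image: k-means needs >= 2 distinct values")
    if params.init == "exact":
        centres = _exact_split_centres(vals)
    elif params.init == "extremes":
        centres = np.array([vals.min(), vals.max()])
    else:
        rng = np.random.default_rng(params.seed)
        centres = np.sort(rng.choice(uniq, size=2, replace=False))
    for _ in range(params.max_iter):
        # assign to the nearest centre (ties to the lower centre)
        assign = np.abs(vals[:, None] - centres[None, :]).argmin(axis=1)
        new = centres.copy()
        for c in range(2):
            sel = vals[assign == c]
            if sel.size:
                new[c] = sel.mean()
        shift = np.abs(new - centres).max()
        centres = new
        if shift < params.tol:
            break
    assign = np.abs(vals[:, None] - centres[None, :]).argmin(axis=1)
    dark = int(np.argmin(centres))
    return (assign == dark).reshape(image.shape)


def plain_semantic_segment(model: UNet, image: np.ndarray) -> np.ndarray:
    """Forward pass plus a 0.5 threshold: no ROI stage, no refinement.

    Identical by construction to :func:`organoidseg.refine.segment` with
    ``use_roi_stage=False`` and ``morphological_cleanup=False``.
    """
    cfg = RefineConfig(use_roi_stage=False, morphological_cleanup=False)
    return segment(model, image, refine=cfg)
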