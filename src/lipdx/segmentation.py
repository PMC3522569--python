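"""Hybrid lip segmentation: mean-shift smoothing, Otsu initialization,
Chan-Vese level-set refinement, plus the saturation-gated background rule.

The pipeline assumes lips photographed against a (near-)white background:
the lip is the chromatic, high-Cr region.  The stage order is

    mean_shift_smooth -> chroma plane (default Cr) -> otsu_threshold
    -> chan_vese_evolve -> largest-component / hole-fill cleanup

and every stage is deterministic given its configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import chan_vese as _sk_chan_vese

from .colorspace import as_float_rgb, color_planes, rgb_to_hsi
from .errors import DegenerateInputError, ParameterError, SegmentationError

#: HSI saturation above which a pixel counts as lip rather than background.
SATURATION_THRESHOLD = 0.1


@dataclass(frozen=True)
class LipMask:
    """A binary lip mask plus the stage that produced it."""

    mask: np.ndarray
    provenance: str = "unknown"  # otsu | chanvese | saturation-gate | ...
    converged: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the hybrid segmenter.

    ``plane`` picks the scalar image the threshold/level-set stages run on;
    Cr has the strongest lip/skin and lip/background contrast in practice.
    The Chan-Vese defaults follow the original level-set literature.
    """

    plane: str = "Cr"
    spatial_radius: int = 8           # px, mean-shift spatial window
    range_radius: float = 16.0 / 255  # color units on the [0,1] scale
    smooth_iters: int = 5
    mu: float = 0.25                  # contour-length penalty
    lambda1: float = 1.0
    lambda2: float = 1.0
    dt: float = 0.5
    max_iters: int = 200
    tol: float = 1e-3
    postprocess: bool = True          # largest component + hole fill


def mean_shift_smooth(
    img: np.ndarray,
    spatial_radius: int = 8,
    range_radius: float = 16.0 / 255,
    max_iters: int = 5,
    tol: float = 1e-4,
) -> np.ndarray:
    """Edge-preserving mean-shift filtering of an RGB image.

    Each pixel is iteratively replaced by the mean color of its spatial
    neighbors (Euclidean window of ``spatial_radius``) whose color lies
    within ``range_radius`` of the pixel's current color.  Pixels on
    opposite sides of a strong color edge never average together, so
    uniform regions are flattened while edges survive.
    """
    if spatial_radius <= 0 or range_radius <= 0:
        raise ParameterError("mean-shift radii must be positive")
    rgb = as_float_rgb(img)
    r = int(spatial_radius)
    offsets = [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dy * dy + dx * dx <= r * r
    ]
    rr2 = float(range_radius) ** 2
    cur = rgb.copy()
    h, w, _ = cur.shape
    for _ in range(max_iters):
        padded = np.pad(cur, ((r, r), (r, r), (0, 0)), mode="edge")
        acc = np.zeros_like(cur)
        cnt = np.zeros((h, w), dtype=np.float64)
        for dy, dx in offsets:
            nb = padded[r + dy : r + dy + h, r + dx : r + dx + w]
            within = ((nb - cur) ** 2).sum(axis=2) <= rr2
            acc += nb * within[..., None]
            cnt += within
        new = acc / cnt[..., None]  # cnt >= 1: the center always qualifies
        delta = np.abs(new - cur).max()
        cur = new
        if delta < tol:
            break
    return cur


def otsu_threshold(gray: np.ndarray) -> tuple[float, LipMask]:
    """Otsu's threshold (maximal between-class variance) and the upper mask.

    Returns ``(threshold, mask)`` with ``mask = gray > threshold``.
    """
    gray = np.asarray(gray)
    if np.unique(gray).size < 2:
        raise DegenerateInputError("Otsu requires at least two distinct gray values")
    # integer input keeps its exact per-level histogram; floats use 256 bins
    if np.issubdtype(gray.dtype, np.integer):
        t = float(threshold_otsu(gray))
    else:
        t = float(threshold_otsu(gray.astype(np.float64), nbins=256))
    return t, LipMask(gray > t, provenance="otsu")


def chan_vese_evolve(
    gray: np.ndarray,
    init: LipMask | np.ndarray,
    mu: float = 0.25,
    lambda1: float = 1.0,
    lambda2: float = 1.0,
    dt: float = 0.5,
    max_iters: int = 200,
    tol: float = 1e-3,
) -> LipMask:
    """Two-phase piecewise-constant level-set refinement of an initial mask.

    The level set is initialized as the signed distance to the boundary of
    ``init`` and evolved until the change falls below ``tol`` or
    ``max_iters`` is reached (in which case the best mask so far is
    returned with ``converged=False`` and a warning).  The output polarity
    is aligned to the initial mask.
    """
    gray = np.asarray(gray, dtype=np.float64)
    init_mask = init.mask if isinstance(init, LipMask) else np.asarray(init, bool)
    if init_mask.shape != gray.shape:
        raise ParameterError("init mask and image shapes differ")
    if not init_mask.any() or init_mask.all():
        raise DegenerateInputError("Chan-Vese init must be nonempty and not full-frame")

    phi0 = ndimage.distance_transform_edt(init_mask) - ndimage.distance_transform_edt(
        ~init_mask
    )
    seg, _phi, energies = _sk_chan_vese(
        gray,
        mu=mu,
        lambda1=lambda1,
        lambda2=lambda2,
        tol=tol,
        max_num_iter=max_iters,
        dt=dt,
        init_level_set=phi0,
        extended_output=True,
    )
    seg = np.asarray(seg, bool)
    # keep the phase that overlaps the initialization
    if (seg & init_mask).sum() < ((~seg) & init_mask).sum():
        seg = ~seg
    converged = len(energies) < max_iters
    if not converged:
        warnings.warn("Chan-Vese did not converge within max_iters", stacklevel=2)
    return LipMask(seg, provenance="chanvese", converged=converged)


def saturation_gate(img: np.ndarray) -> LipMask:
    """Mask of pixels with HSI saturation strictly above 0.1.

    A white background has saturation 0 and is excluded; the rule is the
    strict inequality S > 0.1, so S == 0.1 exactly is background.
    """
    _, sat, _ = rgb_to_hsi(img)
    return LipMask(sat > SATURATION_THRESHOLD, provenance="saturation-gate")


def _cleanup(mask: np.ndarray) -> np.ndarray:
    """Keep the largest connected component and fill its holes."""
    if not mask.any():
        return mask
    labels = cc_label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    largest = labels == counts.argmax()
    return ndimage.binary_fill_holes(largest)


def segment_lip(img: np.ndarray, cfg: SegmentationConfig | None = None) -> LipMask:
    """Full hybrid lip segmentation of an RGB image.

    Raises :class:`SegmentationError` when no lip region can be found
    (e.g. an image that is entirely background).
    """
    cfg = cfg or SegmentationConfig()
    rgb = as_float_rgb(img)
    smoothed = mean_shift_smooth(
        rgb, cfg.spatial_radius, cfg.range_radius, cfg.smooth_iters
    )
    planes = color_planes(smoothed)
    if cfg.plane not in planes:
        raise ParameterError(f"unknown plane {cfg.plane!r}")
    scalar = planes[cfg.plane]
    try:
        _, init = otsu_threshold(scalar)
    except DegenerateInputError as exc:
        raise SegmentationError(f"no contrast in plane {cfg.plane}: {exc}") from exc
    if not init.mask.any() or init.mask.all():
        raise SegmentationError("Otsu initialization is empty or full-frame")
    refined = chan_vese_evolve(
        scalar,
        init,
        mu=cfg.mu,
        lambda1=cfg.lambda1,
        lambda2=cfg.lambda2,
        dt=cfg.dt,
        max_iters=cfg.max_iters,
        tol=cfg.tol,
    )
    final = _cleanup(refined.mask) if cfg.postprocess else refined.mask
    if not final.any() or final.all():
        raise SegmentationError("segmentation produced an empty or full-frame mask")
    return replace(refined, mask=final)


def dice(a: np.ndarray | LipMask, b: np.ndarray | LipMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two masks."""
    ma = a.mask if isinstance(a, LipMask) else np.asarray(a, bool)
    mb = b.mask if isinstance(b, LipMask) else np.asarray(b, bool)
    denom = ma.sum() + mb.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((ma & mb).sum()) / float(denom)
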