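"""The 84-dimensional lip descriptor: 24 color statistics, 13 Haralick
co-occurrence features, 47 Zernike moment magnitudes.

Color features are the mean and population variance of each of the 12
color planes over the lip pixels.  Texture features come from masked,
symmetrized gray-level co-occurrence matrices (G = 64 levels, distance-1
offsets at 0/45/90/135 degrees, features averaged over the offsets).
Moment features are the Zernike magnitudes of the masked luminance image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colorspace import PLANE_NAMES, color_planes, luminance
from .errors import DegenerateInputError, ParameterError
from .segmentation import LipMask, saturation_gate
from .zernike import ZernikeBasis, zernike_features

HARALICK_NAMES = (
    "asm",                 # angular second moment
    "contrast",
    "correlation",
    "sum_of_squares",      # variance
    "idm",                 # inverse difference moment
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",                # information measure of correlation
    "max_corr_coeff",      # maximal correlation coefficient
)

#: Default offsets: distance 1 at 0, 45, 90, 135 degrees, as (dy, dx).
DEFAULT_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

DEFAULT_GLCM_LEVELS = 64

COLOR_NAMES = tuple(
    f"{plane}_{stat}" for plane in PLANE_NAMES for stat in ("mean", "var")
)


def feature_names(basis: ZernikeBasis | None = None) -> tuple[str, ...]:
    """Canonical ordered names of the full descriptor (84 by default)."""
    basis = basis or ZernikeBasis()
    return COLOR_NAMES + HARALICK_NAMES + basis.names


def feature_groups(basis: ZernikeBasis | None = None) -> tuple[str, ...]:
    basis = basis or ZernikeBasis()
    return (
        ("color",) * len(COLOR_NAMES)
        + ("texture",) * len(HARALICK_NAMES)
        + ("moment",) * len(basis)
    )


@dataclass(frozen=True)
class FeatureVector:
    """Named, ordered feature values with per-entry group tags."""

    values: np.ndarray
    names: tuple[str, ...]
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if len(self.values) != len(self.names) or len(self.names) != len(self.groups):
            raise ParameterError("values, names and groups must align")
        if not np.isfinite(self.values).all():
            raise ParameterError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g in self.groups:
            counts[g] = counts.get(g, 0) + 1
        return counts


def color_features(planes: dict[str, np.ndarray], mask: np.ndarray) -> np.ndarray:
    """Mean and population variance of each plane over the masked pixels.

    Returns 2 * len(planes) values in plane order (mean, var per plane).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise DegenerateInputError("empty mask")
    out = []
    for name in planes:
        vals = planes[name][mask]
        out.append(vals.mean())
        out.append(vals.var())  # population variance (divide by N)
    return np.asarray(out)


@dataclass(frozen=True)
class GLCM:
    """Normalized, symmetrized gray-level co-occurrence matrix."""

    P: np.ndarray
    levels: int
    offset: tuple[int, int]
    symmetric: bool = True


def quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    """Quantize a [0, 1] gray image into ``levels`` integer bins."""
    g = np.clip(np.asarray(gray, dtype=np.float64), 0.0, 1.0)
    return np.minimum((g * levels).astype(np.intp), levels - 1)


def compute_glcm(
    gray: np.ndarray,
    mask: np.ndarray,
    levels: int = DEFAULT_GLCM_LEVELS,
    offset: tuple[int, int] = (0, 1),
) -> GLCM:
    """Masked co-occurrence matrix: only pairs with BOTH pixels inside the
    mask are counted; the matrix is symmetrized and normalized to sum 1.
    """
    if levels < 2:
        raise ParameterError("levels must be >= 2")
    dy, dx = offset
    if dy == 0 and dx == 0:
        raise ParameterError("offset must be nonzero")
    q = quantize(gray, levels)
    mask = np.asarray(mask, bool)
    h, w = q.shape

    y0a, y1a = max(0, -dy), min(h, h - dy)
    x0a, x1a = max(0, -dx), min(w, w - dx)
    a = q[y0a:y1a, x0a:x1a]
    b = q[y0a + dy : y1a + dy, x0a + dx : x1a + dx]
    valid = mask[y0a:y1a, x0a:x1a] & mask[y0a + dy : y1a + dy, x0a + dx : x1a + dx]
    if not valid.any():
        raise DegenerateInputError("no co-occurring pixel pair lies inside the mask")

    p = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(p, (a[valid], b[valid]), 1.0)
    p = p + p.T  # symmetrize: count each pair in both directions
    p /= p.sum()
    return GLCM(P=p, levels=levels, offset=(dy, dx))


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def haralick_features(glcm: GLCM) -> np.ndarray:
    """The 13 classic co-occurrence statistics of one GLCM, in
    :data:`HARALICK_NAMES` order.  Logarithms are base 2.

    For a degenerate matrix (all mass on a single gray level) the
    correlation-type features (correlation, IMC1, maximal correlation
    coefficient) are defined as 0.
    """
    p = glcm.P
    g = glcm.levels
    idx = np.arange(g, dtype=np.float64)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(idx @ px)
    mu_y = float(idx @ py)
    sd_x = float(np.sqrt(((idx - mu_x) ** 2) @ px))
    sd_y = float(np.sqrt(((idx - mu_y) ** 2) @ py))

    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    # p_{x+y}(k), k = 0..2G-2 and p_{x-y}(k), k = 0..G-1
    p_sum = np.zeros(2 * g - 1)
    np.add.at(p_sum, (ii + jj).astype(np.intp).ravel(), p.ravel())
    p_diff = np.zeros(g)
    np.add.at(p_diff, np.abs(ii - jj).astype(np.intp).ravel(), p.ravel())
    ks = np.arange(2 * g - 1, dtype=np.float64)
    kd = np.arange(g, dtype=np.float64)

    asm = float((p**2).sum())
    contrast = float((kd**2) @ p_diff)
    if sd_x > 0 and sd_y > 0:
        correlation = float(((ii - mu_x) * (jj - mu_y) * p).sum() / (sd_x * sd_y))
    else:
        correlation = 0.0
    sum_of_squares = float(((ii - mu_x) ** 2 * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sum_average = float(ks @ p_sum)
    sum_variance = float(((ks - sum_average) ** 2) @ p_sum)
    sum_entropy = _entropy(p_sum)
    entropy = _entropy(p)
    diff_mean = float(kd @ p_diff)
    difference_variance = float(((kd - diff_mean) ** 2) @ p_diff)
    difference_entropy = _entropy(p_diff)

    hx, hy = _entropy(px), _entropy(py)
    outer = np.outer(px, py)
    nz = (p > 0) & (outer > 0)
    hxy1 = float(-(p[nz] * np.log2(outer[nz])).sum())
    imc1 = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0

    # maximal correlation coefficient: sqrt of the 2nd-largest eigenvalue of
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k)), on the support of px
    support = px > 0
    if support.sum() < 2:
        mcc = 0.0
    else:
        ps = p[np.ix_(support, support)]
        pxs = px[support]
        pys = py[support]
        q = (ps / pxs[:, None]) @ (ps.T / pys[:, None])
        eig = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(eig[-2], 0.0)))

    return np.array(
        [
            asm,
            contrast,
            correlation,
            sum_of_squares,
            idm,
            sum_average,
            sum_variance,
            sum_entropy,
            entropy,
            difference_variance,
            difference_entropy,
            imc1,
            mcc,
        ]
    )


def texture_features(
    gray: np.ndarray,
    mask: np.ndarray,
    levels: int = DEFAULT_GLCM_LEVELS,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
) -> np.ndarray:
    """Haralick features averaged over the configured offsets."""
    feats = [haralick_features(compute_glcm(gray, mask, levels, off)) for off in offsets]
    return np.mean(feats, axis=0)


@dataclass(frozen=True)
class FeatureConfig:
    glcm_levels: int = DEFAULT_GLCM_LEVELS
    glcm_offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    zernike_basis: ZernikeBasis = field(default_factory=ZernikeBasis)
    apply_saturation_gate: bool = True


def extract_all(
    img: np.ndarray,
    mask: LipMask | np.ndarray,
    cfg: FeatureConfig | None = None,
) -> FeatureVector:
    """Full descriptor of a lip image: color(24) || texture(13) || moment(47).

    Features are computed inside the intersection of the segmentation mask
    and the saturation gate (background pixels never contaminate the
    statistics), on the BT.601 luminance for texture and moments.
    """
    cfg = cfg or FeatureConfig()
    m = mask.mask if isinstance(mask, LipMask) else np.asarray(mask, bool)
    if cfg.apply_saturation_gate:
        m = m & saturation_gate(img).mask
    if not m.any():
        raise DegenerateInputError("no lip pixel survives the saturation gate")
    planes = color_planes(img)
    gray = luminance(img)
    values = np.concatenate(
        [
            color_features(planes, m),
            texture_features(gray, m, cfg.glcm_levels, cfg.glcm_offsets),
            zernike_features(gray, m, cfg.zernike_basis),
        ]
    )
    return FeatureVector(
        values=values,
        names=feature_names(cfg.zernike_basis),
        groups=feature_groups(cfg.zernike_basis),
    )
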