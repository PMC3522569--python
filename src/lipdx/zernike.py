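"""Zernike moment magnitudes of the masked lip region.

The lip's pixels are centered on the mask's center of mass, scaled by the
mean pixel radius R so they map into the unit disk, and projected onto the
complex Zernike polynomials V_nl(rho, theta) = R_nl(rho) e^{i l theta}:

    Z_nl = (n+1)/pi * sum_{x'^2+y'^2 <= 1} R_nl(rho) e^{-i l theta} I(x', y')

Only pixels whose mapped coordinates fall inside the unit circle
contribute.  The returned descriptors are the magnitudes |Z_nl|: they are
exactly invariant to translation (the centering is intrinsic), invariant
to rotation up to discretization, and homogeneous of degree 1 in the
intensity.

The default basis uses every (n, l) with 2 <= n <= 12, 0 <= l <= n and
n - l even: 47 pairs.  Orders 0 and 1 are omitted as uninformative — the
n=0 moment is the plain intensity sum and the n=1 moments vanish by the
center-of-mass normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial, pi

import numpy as np

from .errors import DegenerateInputError, ParameterError


def default_pairs(n_min: int = 2, n_max: int = 12) -> tuple[tuple[int, int], ...]:
    """All (n, l) with n_min <= n <= n_max, 0 <= l <= n, n - l even."""
    return tuple(
        (n, l) for n in range(n_min, n_max + 1) for l in range(n % 2, n + 1, 2)
    )


def radial_poly(n: int, l: int, rho: np.ndarray) -> np.ndarray:
    """Zernike radial polynomial R_nl evaluated at rho in [0, 1]."""
    if not (0 <= l <= n) or (n - l) % 2:
        raise ParameterError(f"invalid Zernike pair (n={n}, l={l})")
    out = np.zeros_like(rho, dtype=np.float64)
    for m in range((n - l) // 2 + 1):
        coeff = (
            (-1) ** m
            * factorial(n - m)
            / (factorial(m) * factorial((n + l) // 2 - m) * factorial((n - l) // 2 - m))
        )
        out += coeff * rho ** (n - 2 * m)
    return out


@dataclass(frozen=True)
class ZernikeBasis:
    """The (n, l) pair set and the unit-circle mapping convention."""

    pairs: tuple[tuple[int, int], ...] = field(default_factory=default_pairs)

    def __post_init__(self) -> None:
        for n, l in self.pairs:
            if not (0 <= l <= n) or (n - l) % 2:
                raise ParameterError(f"invalid Zernike pair (n={n}, l={l})")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f"zernike_n{n}_l{l}" for n, l in self.pairs)


def zernike_features(
    gray: np.ndarray,
    mask: np.ndarray,
    basis: ZernikeBasis | None = None,
) -> np.ndarray:
    """Magnitudes |Z_nl| of the masked gray image, in the basis pair order.

    The center is the mask's center of mass; the mapping radius R is the
    mean distance of mask pixels from that center.  A mask whose R is zero
    (a single pixel) is degenerate.
    """
    basis = basis or ZernikeBasis()
    gray = np.asarray(gray, dtype=np.float64)
    mask = np.asarray(mask, bool)
    if mask.shape != gray.shape:
        raise ParameterError("mask and image shapes differ")
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise DegenerateInputError("empty mask")
    cy, cx = ys.mean(), xs.mean()
    dy, dx = ys - cy, xs - cx
    radii = np.hypot(dy, dx)
    big_r = radii.mean()
    if big_r <= 0.0:
        raise DegenerateInputError("mask radius is zero (single-pixel mask)")

    rho = radii / big_r
    inside = rho <= 1.0
    rho = rho[inside]
    theta = np.arctan2(dy[inside], dx[inside])
    vals = gray[ys[inside], xs[inside]]

    out = np.empty(len(basis.pairs), dtype=np.float64)
    # cache e^{-il theta} per distinct l
    phase_cache: dict[int, np.ndarray] = {}
    for k, (n, l) in enumerate(basis.pairs):
        if l not in phase_cache:
            phase_cache[l] = np.exp(-1j * l * theta)
        z = (n + 1) / pi * np.sum(radial_poly(n, l, rho) * phase_cache[l] * vals)
        out[k] = abs(z)
    return out
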