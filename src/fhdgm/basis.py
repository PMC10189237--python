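"""Functional bases over the within-day domain.

The model expresses every functional object (fixed-effect coefficient
curves, the latent random-effect loadings, and the error-variance profile)
as a linear combination of ``K`` basis functions ``B_k(h)`` over a closed
interval, typically hours ``[0, 24]``.  Two families are supported:

* clamped B-splines with equally spaced interior knots — the default for
  simulation studies; they do not wrap around midnight;
* periodic Fourier bases (constant plus sine/cosine pairs at integer
  multiples of the fundamental frequency) — natural for diurnal profiles
  that must be continuous from 23:59 to 00:00.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "BasisSystem",
    "make_bspline_basis",
    "make_fourier_basis",
    "make_constant_basis",
    "eval_basis",
    "functional_coefficient",
]


class BasisSpecificationError(ValueError):
    """Raised when a basis specification is internally inconsistent."""


@dataclass(frozen=True)
class BasisSystem:
    """A finite functional basis over a closed interval.

    Parameters
    ----------
    family
        ``"bspline"`` or ``"fourier"``.
    n_bases
        Number of basis functions ``K``.
    domain
        Closed interval ``(h1, h2)`` on which curves live.
    degree
        Polynomial degree (B-splines only; cubic = 3).
    knots
        Interior knots, strictly inside the domain (B-splines only).
    period
        Period of the Fourier system (Fourier only).
    """

    family: str
    n_bases: int
    domain: tuple[float, float]
    degree: int | None = None
    knots: tuple[float, ...] = field(default=())
    period: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not hi > lo:
            raise BasisSpecificationError("domain must be a non-degenerate interval")
        if self.n_bases < 1:
            raise BasisSpecificationError("n_bases must be positive")
        if self.family == "bspline":
            if self.degree is None or self.degree < 0:
                raise BasisSpecificationError("bspline basis requires degree >= 0")
            if len(self.knots) != self.n_bases - self.degree - 1:
                raise BasisSpecificationError(
                    "interior knot count must equal n_bases - degree - 1"
                )
            if any(not lo < k < hi for k in self.knots):
                raise BasisSpecificationError("interior knots must lie strictly inside domain")
            if list(self.knots) != sorted(self.knots):
                raise BasisSpecificationError("interior knots must be sorted")
        elif self.family == "fourier":
            if self.n_bases % 2 == 0:
                raise BasisSpecificationError("fourier basis requires an odd number of bases")
            if self.period is None or self.period <= 0:
                raise BasisSpecificationError("fourier basis requires a positive period")
        else:
            raise BasisSpecificationError(f"unknown basis family {self.family!r}")

    @property
    def full_knots(self) -> np.ndarray:
        """Clamped knot vector (B-splines only)."""
        if self.family != "bspline":
            raise BasisSpecificationError("full_knots defined for bspline bases only")
        lo, hi = self.domain
        d = int(self.degree)  # type: ignore[arg-type]
        return np.concatenate([[lo] * (d + 1), self.knots, [hi] * (d + 1)])


def make_bspline_basis(
    domain: tuple[float, float], n_bases: int, degree: int = 3
) -> BasisSystem:
    """Clamped B-spline basis with equally spaced interior knots.

    ``n_bases - degree - 1`` interior knots are placed at equal spacing
    strictly inside ``domain``; e.g. 7 cubic bases on [0, 24] put knots at
    6, 12 and 18.
    """
    if n_bases < degree + 1:
        raise BasisSpecificationError(
            f"n_bases={n_bases} requires at least degree+1={degree + 1} bases"
        )
    lo, hi = domain
    n_interior = n_bases - degree - 1
    interior = tuple(np.linspace(lo, hi, n_interior + 2)[1:-1]) if n_interior else ()
    return BasisSystem(
        family="bspline", n_bases=n_bases, domain=(float(lo), float(hi)),
        degree=degree, knots=interior,
    )


def make_fourier_basis(period: float, n_bases: int) -> BasisSystem:
    """Periodic Fourier basis: constant, then (sin, cos) pairs.

    The pair ``(2m, 2m+1)`` oscillates at ``m`` cycles per period, so with
    five bases the fourth/fifth pair has twice the frequency of the
    second/third.  ``n_bases`` must be odd.
    """
    if n_bases % 2 == 0:
        raise BasisSpecificationError("fourier basis requires an odd number of bases")
    return BasisSystem(
        family="fourier", n_bases=n_bases, domain=(0.0, float(period)), period=float(period)
    )


def make_constant_basis(domain: tuple[float, float] = (0.0, 24.0)) -> BasisSystem:
    """Single constant-1 basis (degree-0 B-spline); handy for flat variance profiles."""
    return make_bspline_basis(domain, n_bases=1, degree=0)


def eval_basis(basis: BasisSystem, h_grid: np.ndarray) -> np.ndarray:
    """Dense evaluation matrix of shape ``(len(h_grid), n_bases)``.

    B-splines must be evaluated inside their domain (the right endpoint is
    included, using the usual half-open-interval fix-up); Fourier bases
    accept any real ``h`` and wrap by the period.
    """
    h = np.asarray(h_grid, dtype=float)
    if h.ndim != 1:
        h = h.ravel()
    if basis.family == "bspline":
        lo, hi = basis.domain
        if np.any(h < lo) or np.any(h > hi):
            raise ValueError("bspline basis evaluated outside its domain")
        d = int(basis.degree)  # type: ignore[arg-type]
        # Clamp the right endpoint into the last half-open knot span.
        h_eval = np.where(h == hi, np.nextafter(hi, lo), h)
        mat = BSpline.design_matrix(h_eval, basis.full_knots, d).toarray()
        return mat
    # Fourier
    p = float(basis.period)  # type: ignore[arg-type]
    out = np.empty((h.size, basis.n_bases))
    out[:, 0] = 1.0
    for m in range(1, (basis.n_bases - 1) // 2 + 1):
        arg = 2.0 * np.pi * m * h / p
        out[:, 2 * m - 1] = np.sin(arg)
        out[:, 2 * m] = np.cos(arg)
    return out


def functional_coefficient(
    basis: BasisSystem, coeffs: np.ndarray, h_grid: np.ndarray
) -> np.ndarray:
    """Evaluate ``f(h) = sum_k B_k(h) c_k`` on a grid."""
    c = np.asarray(coeffs, dtype=float)
    if c.shape != (basis.n_bases,):
        raise ValueError(
            f"coefficient vector has length {c.shape}, expected ({basis.n_bases},)"
        )
    return eval_basis(basis, h_grid) @ c
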