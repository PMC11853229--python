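"""Power-law scaling of the equivalent volume fraction with cell diameter.

The equivalent volume fraction of a trapped cell does not track diameter
(1D), cross-section (2D) or volume (3D) directly; it follows

    phi = k * D**a

with a geometry-dependent scaling exponent ``a`` between 1 and 3.  The
exponent is selected by explicit grid search: for each candidate ``a`` the
prefactor ``k`` is the no-intercept least-squares slope of phi against
``x = D**a``, and the ``a`` minimizing the SSE (equivalently maximizing
R^2) wins, ties broken toward the smaller exponent.  Diameters are carried
in micrometers here, so ``k`` has units of phi per um^a.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .fitting import r_squared

__all__ = [
    "PowerLawFit",
    "GeometryVariantResult",
    "PowerLawScaling",
    "fit_power_law",
    "exponent_sweep",
    "default_exponent_grid",
]


def default_exponent_grid(
    start: float = 1.0, stop: float = 3.0, step: float = 0.1
) -> np.ndarray:
    """Candidate exponents, inclusive of both ends (default 1.0:3.0:0.1,
    matching the one-decimal precision the exponent is reported at)."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


@dataclass(frozen=True)
class PowerLawFit:
    """Selected power law phi = k * D**a.

    ``k`` in units of phi (fraction or percent, as supplied) per um^a;
    ``r2`` is the coefficient of determination of the selected no-intercept
    linear fit of phi vs D**a; ``grid`` records the exponents searched and
    ``intercept`` the optional intercept (0 for the default no-intercept
    fit).
    """

    k: float
    a: float
    r2: float
    grid: np.ndarray
    intercept: float = 0.0


@dataclass(frozen=True)
class GeometryVariantResult:
    geometry_label: str
    fit: PowerLawFit


class PowerLawScaling(BaseEstimator, RegressorMixin):
    """Grid-search estimator for the scaling exponent.

    Parameters
    ----------
    a_grid : array-like, optional
        Candidate exponents; defaults to 1.0:3.0 step 0.1.
    with_intercept : bool
        Allow an intercept in the linear fit of phi vs D**a (off by
        default; the scaling law passes through the origin).

    Attributes
    ----------
    exponent_ : float
        Selected scaling exponent a.
    prefactor_ : float
        Fitted k (phi units per um^a).
    r2_ : float
        R^2 of the selected fit.
    """

    def __init__(self, a_grid=None, with_intercept: bool = False):
        self.a_grid = a_grid
        self.with_intercept = with_intercept

    def fit(self, X, y):
        """X: diameters in micrometers (1-D); y: volume fractions."""
        D = np.asarray(X, dtype=float).reshape(-1)
        phi = np.asarray(y, dtype=float).reshape(-1)
        if D.shape != phi.shape:
            raise ValueError("diameters and fractions must match in length")
        if D.size < 3:
            raise ValueError("need at least 3 (D, phi) points")
        if np.any(D <= 0) or np.any(phi <= 0):
            raise ValueError("diameters and fractions must be positive")
        if np.unique(D).size != D.size:
            raise ValueError("diameters must be distinct")
        grid = (
            default_exponent_grid()
            if self.a_grid is None
            else np.asarray(self.a_grid, dtype=float).reshape(-1)
        )
        if grid.size == 0:
            raise ValueError("exponent grid must be non-empty")
        grid = np.sort(grid)

        best = None  # (sse, a, k, c)
        for a in grid:
            x = D**a
            if self.with_intercept:
                A = np.column_stack([x, np.ones_like(x)])
                coef, *_ = np.linalg.lstsq(A, phi, rcond=None)
                k, c = float(coef[0]), float(coef[1])
            else:
                k, c = float((x @ phi) / (x @ x)), 0.0
            sse = float(np.sum((phi - (k * x + c)) ** 2))
            # ties (to floating-point noise) keep the smaller exponent,
            # since the grid is sorted ascending
            if best is None or sse < best[0] * (1.0 - 1e-9):
                best = (sse, float(a), k, c)
        sse, a, k, c = best
        self.exponent_ = a
        self.prefactor_ = k
        self.intercept_ = c
        self.r2_ = r_squared(phi, k * D**a + c)
        self.grid_ = grid
        self.fit_ = PowerLawFit(k=k, a=a, r2=self.r2_, grid=grid, intercept=c)
        return self

    def predict(self, X) -> np.ndarray:
        D = np.asarray(X, dtype=float).reshape(-1)
        return self.prefactor_ * D**self.exponent_ + self.intercept_


def fit_power_law(
    points: Sequence[tuple[float, float]], a_grid=None, with_intercept=False
) -> PowerLawFit:
    """Fit phi = k * D**a to (D_um, phi) pairs by exponent grid search."""
    pts = list(points)
    D = [p[0] for p in pts]
    phi = [p[1] for p in pts]
    est = PowerLawScaling(a_grid=a_grid, with_intercept=with_intercept)
    return est.fit(D, phi).fit_


def exponent_sweep(
    variants: Sequence[tuple[str, Sequence[tuple[float, float]]]],
    a_grid=None,
) -> list[GeometryVariantResult]:
    """One power-law fit per geometry variant, preserving input order."""
    variants = list(variants)
    if not variants:
        raise ValueError("no geometry variants supplied")
    out = []
    for label, points in variants:
        try:
            fit = fit_power_law(points, a_grid=a_grid)
        except Exception as exc:
            raise ValueError(f"variant {label!r}: {exc}") from exc
        out.append(GeometryVariantResult(geometry_label=str(label), fit=fit))
    return out
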