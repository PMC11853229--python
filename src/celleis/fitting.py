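"""Staged least-squares estimation of ECM components from spectra.

The staged pipeline mirrors how the sensing unit is calibrated in practice:

1. :class:`EmptyUnitFit` — fit the medium-only unit for the geometric
   constant ``G_f`` and double-layer capacitance ``C_dl``.
2. :class:`BeadPhiFit` — with ``G_f``/``C_dl`` frozen, fit the equivalent
   volume fraction ``phi`` of an insulating bead.
3. :class:`CellSeriesFit` — with the same constants frozen, fit ``phi`` per
   diameter for a series of cell-occupied spectra (intracellular branch
   active).

Estimators follow the scikit-learn protocol: constructor parameters are
plain fields, ``fit`` validates input and sets trailing-underscore
attributes, ``predict`` evaluates the fitted forward model on a frequency
grid.  Module-level ``fit_*`` functions are thin wrappers.

The objective operates on the complex response current with per-frequency
weights ``1/|I_obs|`` so that amplitude decades contribute comparably; a
stacked amplitude/phase residual is available via ``residual_mode``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from . import ecm
from .dielectric import sigma_tilde as _sigma_tilde_eval
from .spectra import ComplexSpectrum

__all__ = [
    "FitResult",
    "r_squared",
    "EmptyUnitFit",
    "BeadPhiFit",
    "CellSeriesFit",
    "fit_empty_unit",
    "fit_bead_phi",
    "fit_cell_series",
]


@dataclass
class FitResult:
    """Point estimates plus per-curve goodness of fit.

    ``r2_amplitude`` / ``r2_phase`` are coefficients of determination of
    the amplitude and phase curves, computed after the complex-residual
    fit; ``residual_norm`` is the final objective value.
    """

    params: dict
    r2_amplitude: float
    r2_phase: float
    residual_norm: float
    n_evaluations: int
    converged: bool
    at_bound: bool = False
    message: str = ""

    def __post_init__(self) -> None:
        if self.residual_norm < 0:
            raise ValueError("residual norm cannot be negative")


def r_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot about the observed
    mean.  Undefined (error) for a constant observed series."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape or obs.ndim != 1:
        raise ValueError("observed and fitted must be equal-length 1-D series")
    if obs.size < 3:
        raise ValueError("need at least 3 points for R^2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for a constant observed series")
    ss_res = float(np.sum((obs - fit) ** 2))
    return 1.0 - ss_res / ss_tot


def _as_current_spectrum(X, y) -> ComplexSpectrum:
    if isinstance(X, ComplexSpectrum):
        if y is not None:
            raise ValueError("pass either a spectrum or (frequencies, values)")
        return X
    f = np.asarray(X, dtype=float).reshape(-1)
    v = np.asarray(y, dtype=complex).reshape(-1)
    return ComplexSpectrum(f, v, "current")


def _check_span(spectrum: ComplexSpectrum) -> None:
    f = spectrum.frequencies
    if f.size < 10:
        raise ValueError("need at least 10 frequency points")
    if np.log10(f[-1] / f[0]) < 2:
        raise ValueError("frequency grid must span at least two decades")


def _residuals(
    model: np.ndarray, observed: np.ndarray, mode: str
) -> np.ndarray:
    w = 1.0 / np.abs(observed)
    if mode == "complex":
        d = (model - observed) * w
        return np.concatenate([d.real, d.imag])
    if mode == "amp_phase":
        da = (np.abs(model) - np.abs(observed)) * w
        dp = np.angle(model) - np.angle(observed)
        return np.concatenate([da, dp])
    raise ValueError(f"unknown residual_mode {mode!r}")


def _curve_r2(model: np.ndarray, observed: np.ndarray) -> tuple[float, float]:
    r2_a = r_squared(np.abs(observed), np.abs(model))
    r2_p = r_squared(
        np.degrees(np.angle(observed)), np.degrees(np.angle(model))
    )
    return r2_a, r2_p


class EmptyUnitFit(BaseEstimator):
    """Fit ``G_f`` and ``C_dl`` to the response current of the empty unit.

    Parameters
    ----------
    medium : ecm.MediumProperties
        Known medium conductivity and permittivity.
    v_amplitude : float
        Stimulus amplitude in volts (standard sweep uses 1 V).
    residual_mode : {"complex", "amp_phase"}
        Residual construction; complex (real/imag stacked) by default.
    tol, max_nfev
        Relative step/objective tolerances and evaluation budget of the
        trust-region least-squares solver.

    Attributes
    ----------
    g_f_, c_dl_ : float
        Fitted geometric constant (m) and double-layer capacitance (F).
    result_ : FitResult
    """

    def __init__(
        self,
        medium: ecm.MediumProperties,
        v_amplitude: float = 1.0,
        residual_mode: str = "complex",
        tol: float = 1e-10,
        max_nfev: int = 10_000,
    ):
        self.medium = medium
        self.v_amplitude = v_amplitude
        self.residual_mode = residual_mode
        self.tol = tol
        self.max_nfev = max_nfev

    def _model(self, f: np.ndarray, g_f: float, c_dl: float) -> np.ndarray:
        geom = ecm.SensingUnitGeometry(g_f=g_f)
        z = ecm.empty_unit_impedance(self.medium, geom, c_dl, f)
        return ecm.response_current(z, self.v_amplitude).values

    def _initial_guess(self, spectrum: ComplexSpectrum) -> tuple[float, float]:
        # Deterministic data-driven start: C_dl from the low-frequency end
        # (double layer dominates: |Z| ~ 2/(w C_dl)), G_f from the
        # high-frequency plateau (bulk dominates: |Z| ~ 1/(|s| G_f)).
        z_obs = self.v_amplitude / spectrum.values
        f = spectrum.frequencies
        w_lo, w_hi = 2 * np.pi * f[0], 2 * np.pi * f[-1]
        c_dl0 = 2.0 / (w_lo * np.abs(z_obs[0]))
        s_hi = self.medium.sigma_m + 1j * w_hi * ecm.EPS0 * self.medium.eps_r_m
        g_f0 = 1.0 / (np.abs(s_hi) * np.abs(z_obs[-1]))
        return float(g_f0), float(c_dl0)

    def fit(self, X, y=None):
        spectrum = _as_current_spectrum(X, y)
        _check_span(spectrum)
        amp = spectrum.amplitude
        if np.ptp(amp) <= 1e-9 * amp.max():
            raise ValueError(
                "frequency-independent spectrum is inconsistent with the "
                "empty-unit model (series double layer forces dispersion)"
            )
        g_f0, c_dl0 = self._initial_guess(spectrum)
        x0 = np.log([g_f0, c_dl0])
        lo, hi = x0 - 2 * np.log(10), x0 + 2 * np.log(10)
        obs = spectrum.values
        f = spectrum.frequencies

        def fun(x):
            return _residuals(
                self._model(f, np.exp(x[0]), np.exp(x[1])), obs,
                self.residual_mode,
            )

        res = least_squares(
            fun, x0, bounds=(lo, hi), xtol=self.tol, ftol=self.tol,
            gtol=self.tol, max_nfev=self.max_nfev,
        )
        self.g_f_, self.c_dl_ = np.exp(res.x)
        model = self._model(f, self.g_f_, self.c_dl_)
        r2_a, r2_p = _curve_r2(model, obs)
        self.result_ = FitResult(
            params={"g_f": float(self.g_f_), "c_dl": float(self.c_dl_)},
            r2_amplitude=r2_a,
            r2_phase=r2_p,
            residual_norm=float(res.cost),
            n_evaluations=int(res.nfev),
            converged=bool(res.success),
            message=res.message,
        )
        return self

    def predict(self, X) -> np.ndarray:
        f = X.frequencies if isinstance(X, ComplexSpectrum) else np.asarray(X, float)
        return self._model(f, self.g_f_, self.c_dl_)


class _PhiFitBase(BaseEstimator):
    """Shared single-parameter phi fit against a frozen forward model."""

    phi_bounds = (0.0, 0.5)

    def _fit_phi(
        self,
        spectrum: ComplexSpectrum,
        forward: Callable[[float], np.ndarray],
        residual_mode: str,
        tol: float,
        max_nfev: int,
    ) -> FitResult:
        obs = spectrum.values

        def fun(x):
            return _residuals(forward(x[0]), obs, residual_mode)

        res = least_squares(
            fun, x0=[1e-3], bounds=([self.phi_bounds[0]], [self.phi_bounds[1]]),
            xtol=tol, ftol=tol, gtol=tol, max_nfev=max_nfev,
        )
        phi = float(res.x[0])
        at_bound = bool(
            np.isclose(phi, self.phi_bounds[0], atol=1e-12)
            or np.isclose(phi, self.phi_bounds[1], rtol=1e-9)
        )
        model = forward(phi)
        r2_a, r2_p = _curve_r2(model, obs)
        return FitResult(
            params={"phi": phi},
            r2_amplitude=r2_a,
            r2_phase=r2_p,
            residual_norm=float(res.cost),
            n_evaluations=int(res.nfev),
            converged=bool(res.success),
            at_bound=at_bound,
            message=res.message,
        )


class BeadPhiFit(_PhiFitBase):
    """Single-parameter fit of the bead equivalent volume fraction.

    ``g_f`` and ``c_dl`` come frozen from a prior :class:`EmptyUnitFit`;
    the bead is an insulating particle (no intracellular branch) of
    relative permittivity ``particle_eps_r``.

    Attributes
    ----------
    phi_ : float
        Fitted equivalent volume fraction (fraction, not percent).
    result_ : FitResult
    """

    def __init__(
        self,
        g_f: float,
        c_dl: float,
        medium: ecm.MediumProperties,
        particle_eps_r: float = 3.0,
        v_amplitude: float = 1.0,
        residual_mode: str = "complex",
        tol: float = 1e-10,
        max_nfev: int = 10_000,
    ):
        self.g_f = g_f
        self.c_dl = c_dl
        self.medium = medium
        self.particle_eps_r = particle_eps_r
        self.v_amplitude = v_amplitude
        self.residual_mode = residual_mode
        self.tol = tol
        self.max_nfev = max_nfev

    def _forward(self, f: np.ndarray) -> Callable[[float], np.ndarray]:
        geom = ecm.SensingUnitGeometry(g_f=self.g_f)

        def forward(phi: float) -> np.ndarray:
            comps = ecm.compute_components(
                self.medium, None, None, geom, phi, self.c_dl,
                particle_eps_r=self.particle_eps_r,
            ) if phi > 0 else ecm.compute_components(
                self.medium, None, None, geom, 0.0, self.c_dl
            )
            z = ecm.mixture_impedance(comps, f)
            return ecm.response_current(z, self.v_amplitude).values

        return forward

    def fit(self, X, y=None):
        spectrum = _as_current_spectrum(X, y)
        _check_span(spectrum)
        self.result_ = self._fit_phi(
            spectrum, self._forward(spectrum.frequencies),
            self.residual_mode, self.tol, self.max_nfev,
        )
        self.phi_ = self.result_.params["phi"]
        return self

    def predict(self, X) -> np.ndarray:
        f = X.frequencies if isinstance(X, ComplexSpectrum) else np.asarray(X, float)
        return self._forward(f)(self.phi_)


class CellSeriesFit(_PhiFitBase):
    """Per-diameter phi fits for a series of cell-occupied spectra.

    The intracellular branch is active: the cytoplasm resistance uses the
    diameter-dependent effective conductivity ``sigma~(D)`` and the
    membrane capacitance the specific capacitance ``c_mem0``.

    Parameters
    ----------
    g_f, c_dl : float
        Frozen from the empty-unit stage.
    sigma_tilde : callable or table of (D_m, sigma) pairs
        Effective cell conductivity vs diameter (D in meters).
    eps_r_c : float or callable
        Effective relative permittivity of the cell entering the mixture
        bracket (scalar, or callable of D in meters).

    Attributes
    ----------
    results_ : list of (D, FitResult), ordered by D
    phi_ : ndarray of fitted fractions, ordered by D
    """

    def __init__(
        self,
        g_f: float,
        c_dl: float,
        medium: ecm.MediumProperties,
        membrane: ecm.MembraneSpec,
        sigma_tilde: Union[Callable[[float], float], Sequence[tuple[float, float]]],
        eps_r_c: Union[float, Callable[[float], float]] = 60.0,
        v_amplitude: float = 1.0,
        residual_mode: str = "complex",
        tol: float = 1e-10,
        max_nfev: int = 10_000,
    ):
        self.g_f = g_f
        self.c_dl = c_dl
        self.medium = medium
        self.membrane = membrane
        self.sigma_tilde = sigma_tilde
        self.eps_r_c = eps_r_c
        self.v_amplitude = v_amplitude
        self.residual_mode = residual_mode
        self.tol = tol
        self.max_nfev = max_nfev

    def _forward_for(self, D: float, f: np.ndarray) -> Callable[[float], np.ndarray]:
        geom = ecm.SensingUnitGeometry(g_f=self.g_f)
        sigma_c = _sigma_tilde_eval(D, self.sigma_tilde)
        eps_c = self.eps_r_c(D) if callable(self.eps_r_c) else float(self.eps_r_c)
        cell = ecm.EffectiveCellProperties(D=D, sigma_c=sigma_c, eps_r_c=eps_c)

        def forward(phi: float) -> np.ndarray:
            comps = (
                ecm.compute_components(
                    self.medium, cell, self.membrane, geom, phi, self.c_dl
                )
                if phi > 0
                else ecm.compute_components(
                    self.medium, None, None, geom, 0.0, self.c_dl
                )
            )
            z = ecm.mixture_impedance(comps, f)
            return ecm.response_current(z, self.v_amplitude).values

        return forward

    def fit(self, X, y=None):
        """X: sequence of (D_meters, ComplexSpectrum) pairs."""
        if y is not None:
            raise ValueError("CellSeriesFit takes a single list of (D, spectrum)")
        pairs = list(X)
        if not pairs:
            raise ValueError("empty diameter series")
        ds = [float(d) for d, _ in pairs]
        if any(d <= 0 for d in ds):
            raise ValueError("diameters must be positive")
        if len(set(ds)) != len(ds):
            raise ValueError("duplicated diameters in series")
        results: list[tuple[float, FitResult]] = []
        for D, spectrum in sorted(pairs, key=lambda p: p[0]):
            try:
                _check_span(spectrum)
                res = self._fit_phi(
                    spectrum, self._forward_for(D, spectrum.frequencies),
                    self.residual_mode, self.tol, self.max_nfev,
                )
            except Exception as exc:  # report per item, never abort the series
                res = FitResult(
                    params={}, r2_amplitude=-np.inf, r2_phase=-np.inf,
                    residual_norm=0.0, n_evaluations=0, converged=False,
                    message=f"{type(exc).__name__}: {exc}",
                )
            results.append((D, res))
        self.results_ = results
        self.phi_ = np.array(
            [r.params.get("phi", np.nan) for _, r in results]
        )
        self.diameters_ = np.array([d for d, _ in results])
        return self


def fit_empty_unit(
    spectrum: ComplexSpectrum,
    medium: ecm.MediumProperties,
    v_amplitude: float = 1.0,
    init: Optional[tuple[float, float]] = None,
    **kwargs,
) -> FitResult:
    est = EmptyUnitFit(medium, v_amplitude=v_amplitude, **kwargs)
    if init is not None:
        est._initial_guess = lambda s: init  # type: ignore[assignment]
    return est.fit(spectrum).result_


def fit_bead_phi(spectrum: ComplexSpectrum, fixed: dict, **kwargs) -> FitResult:
    """``fixed`` must contain g_f, c_dl and medium (plus optional
    particle_eps_r / v_amplitude)."""
    return BeadPhiFit(**fixed, **kwargs).fit(spectrum).result_


def fit_cell_series(
    spectra: Sequence[tuple[float, ComplexSpectrum]], fixed: dict, **kwargs
) -> list[tuple[float, FitResult]]:
    """``fixed`` must contain g_f, c_dl, medium, membrane and sigma_tilde."""
    return CellSeriesFit(**fixed, **kwargs).fit(spectra).results_
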