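"""Lumped parameter model (LPM) of the full impedance measurement chain.

The sensing device sits between a stimulus source and a transimpedance
readout.  The normative topology is:

    V_in --[L_w + R_w]-- A --[DUT]-- B --[L_R]-- (virtual ground, TIA)

with parasitic C_p from A to ground and, honoring the symmetric-parasitics
assumption, an identical C_p from B to ground; the readout residuals are a
shunt C_R at the recording node B and a series L_R from B into the ideal
inverting transimpedance stage (feedback R_ac || C_ac), whose output is
V_out = -I * Z_f.  This placement keeps every parameter observable: C_p
acts through its interaction with the wire impedance on the stimulus side
(and pins the recording-side copy), while C_R and L_R shape the current
divider at node B.  The two free nodes A and B are solved exactly per
frequency:

    (V_in - V_A)/Z_w = V_A j w C_p + (V_A - V_B)/Z_dut
    (V_A - V_B)/Z_dut = V_B j w (C_p + C_R) + V_B/(j w L_R)
    V_out = -(V_B/(j w L_R)) * Z_f,    Z_f = R_ac || C_ac

with the obvious degenerate forms when the wire branch or L_R vanish
(V_A = V_in, respectively V_B = 0).

The device under test (DUT) is a fixed calibration resistor or the
sensing-unit circuit of :mod:`celleis.ecm` with the double layer expressed
per unit electrode-window area.  Peripheral parameters are estimated by a
seeded genetic algorithm (:mod:`celleis.ga`) on resistor spectra, then the
device parameters on medium/cell spectra, mirroring the staged calibration
of the instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from . import ecm
from .ga import GAConfig, GAResult, minimize_ga
from .fitting import FitResult, r_squared, _curve_r2
from .spectra import (
    ComplexSpectrum,
    RelativeSpectrum,
    validate_grid,
    wrap_phase_deg,
)

__all__ = [
    "PeripheralParams",
    "ResistorDUT",
    "DeviceMediumDUT",
    "DeviceCellDUT",
    "GAConfig",
    "dut_impedance",
    "transfer",
    "fit_peripheral",
    "fit_device",
    "PeripheralFit",
    "DeviceFit",
    "growth_components",
    "interpolate_growth",
    "predict_growth_response",
]


@dataclass(frozen=True)
class PeripheralParams:
    """Measurement-chain components (SI units).

    ``c_p``: parasitic capacitance to ground on each side of the DUT;
    ``l_w``/``r_w``: wire inductance/resistance; ``r_ac``/``c_ac``:
    transimpedance feedback; ``l_r``/``c_r``: residual series inductance
    and shunt capacitance of the readout path; ``v_in``: stimulus
    amplitude.
    """

    c_p: float = 0.0
    l_w: float = 0.0
    r_w: float = 0.0
    r_ac: float = 100e3
    c_ac: float = 0.0
    l_r: float = 0.0
    c_r: float = 0.0
    v_in: float = 1.0

    def __post_init__(self) -> None:
        for name in ("c_p", "l_w", "r_w", "r_ac", "c_ac", "l_r", "c_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.v_in <= 0:
            raise ValueError("v_in must be positive")
        if self.r_ac == 0 and self.c_ac == 0:
            raise ValueError("feedback branch is all-zero (singular network)")


@dataclass(frozen=True)
class ResistorDUT:
    """Fixed calibration resistor."""

    R: float

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("resistance must be positive")


@dataclass(frozen=True)
class DeviceMediumDUT:
    """Sensing device filled with pure medium: series double layers
    (``c_dl_per_area`` times ``window_area`` per electrode window) around
    R_m || C_m."""

    c_dl_per_area: float
    window_area: float
    c_m: float
    r_m: float

    def __post_init__(self) -> None:
        for name in ("c_dl_per_area", "window_area", "c_m", "r_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def c_dl(self) -> float:
        return self.c_dl_per_area * self.window_area

    def components(self) -> ecm.ECMComponents:
        return ecm.ECMComponents(
            r_m=self.r_m, c_m=self.c_m, c_dl=self.c_dl, phi=0.0
        )


@dataclass(frozen=True)
class DeviceCellDUT(DeviceMediumDUT):
    """Sensing device with a trapped cell: adds the R_c - C_mem branch."""

    r_c: float = 1.0
    c_mem: float = 1.0
    phi: float = 1e-4  # nominal occupancy tag; not used electrically

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.r_c <= 0 or self.c_mem <= 0:
            raise ValueError("r_c and c_mem must be positive")

    def components(self) -> ecm.ECMComponents:
        return ecm.ECMComponents(
            r_m=self.r_m, c_m=self.c_m, c_dl=self.c_dl, phi=self.phi,
            r_c=self.r_c, c_mem=self.c_mem,
        )


DUTModel = Union[ResistorDUT, DeviceMediumDUT, DeviceCellDUT]


def dut_impedance(dut: DUTModel, frequencies: np.ndarray) -> ComplexSpectrum:
    """Impedance of the device under test on the grid."""
    f = validate_grid(frequencies)
    if isinstance(dut, ResistorDUT):
        return ComplexSpectrum(f, np.full(f.shape, dut.R, dtype=complex),
                               "impedance")
    return ecm.mixture_impedance(dut.components(), f)


def transfer(
    peripheral: PeripheralParams, dut: DUTModel, frequencies: np.ndarray
) -> ComplexSpectrum:
    """Output voltage V_out(f) of the full measurement chain."""
    f = validate_grid(frequencies)
    w = 2.0 * np.pi * f
    p = peripheral
    z_dut = dut_impedance(dut, f).values
    if np.any(z_dut == 0):
        raise ValueError("DUT impedance is zero (singular network)")
    y_dut = 1.0 / z_dut
    z_w = 1j * w * p.l_w + p.r_w
    has_wire = p.l_w > 0 or p.r_w > 0
    has_lr = p.l_r > 0
    y_lr = 1.0 / (1j * w * p.l_r) if has_lr else None

    # 2x2 nodal system in (V_A, V_B)
    n = f.size
    A = np.zeros((n, 2, 2), dtype=complex)
    b = np.zeros((n, 2), dtype=complex)
    if has_wire:
        A[:, 0, 0] = 1.0 / z_w + 1j * w * p.c_p + y_dut
        A[:, 0, 1] = -y_dut
        b[:, 0] = p.v_in / z_w
    else:  # ideal source at node A
        A[:, 0, 0] = 1.0
        b[:, 0] = p.v_in
    if has_lr:
        A[:, 1, 0] = -y_dut
        A[:, 1, 1] = y_dut + 1j * w * (p.c_p + p.c_r) + y_lr
    else:  # node B is the virtual ground itself
        A[:, 1, 1] = 1.0
    v = np.linalg.solve(A, b[..., None])[..., 0]
    v_a, v_b = v[:, 0], v[:, 1]
    i_tia = y_lr * v_b if has_lr else (v_a - v_b) * y_dut
    if p.c_ac > 0:
        z_f = p.r_ac / (1.0 + 1j * w * p.r_ac * p.c_ac)
    else:
        z_f = np.full(f.shape, p.r_ac, dtype=complex)
    return ComplexSpectrum(f, -i_tia * z_f, "voltage")


def _shared_grid(spectra: Sequence[ComplexSpectrum]) -> np.ndarray:
    f0 = spectra[0].frequencies
    for s in spectra[1:]:
        if not np.array_equal(s.frequencies, f0):
            raise ValueError("all spectra must share one frequency grid")
    return f0


def _log_bounds(value: float, decades: float = 2.0) -> tuple[float, float]:
    if value <= 0:
        raise ValueError("log-scaled bounds need a positive initial value")
    return value * 10.0**-decades, value * 10.0**decades


class PeripheralFit:
    """GA estimation of {l_r, c_r, c_p, c_ac} from calibration-resistor
    spectra.

    Parameters
    ----------
    base : PeripheralParams
        Known chain parameters (``r_ac``, ``v_in``, wires) and initial
        guesses for the four fitted components (used to build log-scaled
        GA bounds spanning +/- 2 decades when ``ga.bounds`` is empty).
    ga : GAConfig
    polish : bool
        Refine the GA optimum with a bounded local least-squares step.

    Attributes
    ----------
    params_ : PeripheralParams with fitted values substituted
    result_ : FitResult (per-spectrum R^2 in ``result_.params['per_curve']``)
    """

    FITTED = ("l_r", "c_r", "c_p", "c_ac")

    def __init__(self, base: PeripheralParams, ga: GAConfig, polish: bool = True):
        self.base = base
        self.ga = ga
        self.polish = polish

    def _objective_parts(self, spectra):
        f = _shared_grid([s for _, s in spectra])
        obs = [s.values for _, s in spectra]
        weights = [1.0 / np.abs(o) for o in obs]
        duts = [ResistorDUT(R) for R, _ in spectra]

        def model(x: np.ndarray) -> list[np.ndarray]:
            p = replace(
                self.base,
                **{name: float(v) for name, v in zip(self.FITTED, x)},
            )
            return [transfer(p, d, f).values for d in duts]

        def residuals(x: np.ndarray) -> np.ndarray:
            out = []
            for m, o, w_ in zip(model(x), obs, weights):
                d = (m - o) * w_
                out.append(d.real)
                out.append(d.imag)
            return np.concatenate(out)

        return model, residuals

    def fit(self, spectra: Sequence[tuple[float, ComplexSpectrum]]):
        spectra = list(spectra)
        rs = [float(R) for R, _ in spectra]
        if len(set(rs)) < 2:
            raise ValueError(
                "need spectra for at least two distinct resistor values"
            )
        if any(R <= 0 for R in rs):
            raise ValueError("resistances must be positive")
        model, residuals = self._objective_parts(spectra)

        ga = self.ga
        if not ga.bounds:
            ga = replace(
                ga, bounds=tuple(
                    _log_bounds(getattr(self.base, n)) for n in self.FITTED
                ),
            )
        ga_res = minimize_ga(lambda x: float(np.sum(residuals(x) ** 2)), ga)
        x = ga_res.x
        n_eval = ga_res.n_evaluations
        if self.polish:
            lo = np.log10([b[0] for b in ga.bounds])
            hi = np.log10([b[1] for b in ga.bounds])
            loc = least_squares(
                lambda u: residuals(10.0**u), np.log10(x),
                bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            x = 10.0**loc.x
            n_eval += int(loc.nfev)

        fitted = model(x)
        per_curve = []
        for (R, s), m in zip(spectra, fitted):
            r2a, r2p = _curve_r2(m, s.values)
            per_curve.append({"R": R, "r2_amplitude": r2a, "r2_phase": r2p})
        params = {n: float(v) for n, v in zip(self.FITTED, x)}
        params["per_curve"] = per_curve
        self.params_ = replace(
            self.base, **{n: float(v) for n, v in zip(self.FITTED, x)}
        )
        self.result_ = FitResult(
            params=params,
            r2_amplitude=float(np.mean([c["r2_amplitude"] for c in per_curve])),
            r2_phase=float(np.mean([c["r2_phase"] for c in per_curve])),
            residual_norm=float(np.sum(residuals(x) ** 2)),
            n_evaluations=n_eval,
            converged=bool(ga_res.improved),
        )
        return self


class DeviceFit:
    """GA estimation of device (DUT) parameters with the peripheral chain
    frozen.

    ``variant="medium"`` fits {c_dl_per_area, c_m, r_m} (``window_area``
    required in ``fixed``); ``variant="cell"`` fits {c_m, r_m, r_c, c_mem}
    (``c_dl_per_area`` and ``window_area`` required in ``fixed``).  The
    ``fixed`` map also supplies initial values for the fitted parameters
    (keyed by name) used to build GA bounds when ``ga.bounds`` is empty.
    """

    VARIANTS = {
        "medium": ("c_dl_per_area", "c_m", "r_m"),
        "cell": ("c_m", "r_m", "r_c", "c_mem"),
    }

    def __init__(
        self,
        peripheral: PeripheralParams,
        variant: str,
        fixed: dict,
        ga: GAConfig,
        polish: bool = True,
    ):
        if variant not in self.VARIANTS:
            raise ValueError(f"variant must be one of {set(self.VARIANTS)}")
        self.peripheral = peripheral
        self.variant = variant
        self.fixed = dict(fixed)
        self.ga = ga
        self.polish = polish

    def _require(self, *keys: str) -> None:
        missing = [k for k in keys if k not in self.fixed]
        if missing:
            raise ValueError(
                f"variant {self.variant!r} requires fixed inputs {missing}"
            )

    def _make_dut(self, names, x) -> DUTModel:
        kw = dict(zip(names, (float(v) for v in x)))
        if self.variant == "medium":
            return DeviceMediumDUT(window_area=self.fixed["window_area"], **kw)
        return DeviceCellDUT(
            c_dl_per_area=self.fixed["c_dl_per_area"],
            window_area=self.fixed["window_area"],
            **kw,
        )

    def fit(self, spectrum: ComplexSpectrum):
        names = self.VARIANTS[self.variant]
        if self.variant == "medium":
            self._require("window_area")
        else:
            self._require("c_dl_per_area", "window_area")
        self._require(*names)  # initial values for every fitted parameter
        f = spectrum.frequencies
        obs = spectrum.values
        weight = 1.0 / np.abs(obs)

        def residuals(x: np.ndarray) -> np.ndarray:
            m = transfer(self.peripheral, self._make_dut(names, x), f).values
            d = (m - obs) * weight
            return np.concatenate([d.real, d.imag])

        ga = self.ga
        if not ga.bounds:
            ga = replace(
                ga,
                bounds=tuple(_log_bounds(self.fixed[n]) for n in names),
            )
        ga_res = minimize_ga(lambda x: float(np.sum(residuals(x) ** 2)), ga)
        x = ga_res.x
        n_eval = ga_res.n_evaluations
        if self.polish:
            lo = np.log10([b[0] for b in ga.bounds])
            hi = np.log10([b[1] for b in ga.bounds])
            loc = least_squares(
                lambda u: residuals(10.0**u), np.log10(x),
                bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            x = 10.0**loc.x
            n_eval += int(loc.nfev)

        self.dut_ = self._make_dut(names, x)
        m = transfer(self.peripheral, self.dut_, f).values
        r2a, r2p = _curve_r2(m, obs)
        self.result_ = FitResult(
            params={n: float(v) for n, v in zip(names, x)},
            r2_amplitude=r2a,
            r2_phase=r2p,
            residual_norm=float(np.sum(residuals(x) ** 2)),
            n_evaluations=n_eval,
            converged=bool(ga_res.improved),
        )
        return self


def fit_peripheral(
    spectra: Sequence[tuple[float, ComplexSpectrum]],
    ga: GAConfig,
    base: Optional[PeripheralParams] = None,
    polish: bool = True,
) -> FitResult:
    est = PeripheralFit(base if base is not None else PeripheralParams(), ga,
                        polish=polish)
    return est.fit(spectra).result_


def fit_device(
    spectrum: ComplexSpectrum,
    peripheral: PeripheralParams,
    variant: str,
    fixed: dict,
    ga: GAConfig,
    polish: bool = True,
) -> FitResult:
    est = DeviceFit(peripheral, variant, fixed, ga, polish=polish)
    return est.fit(spectrum).result_


def growth_components(
    D_um: float, phi: float, fixed: dict
) -> ecm.ECMComponents:
    """ECM components of a cell of diameter ``D_um`` (micrometers) at
    equivalent volume fraction ``phi``.

    ``fixed`` supplies g_f, c_dl, medium, membrane, sigma_tilde (callable
    or table over D in meters) and optionally eps_r_c (default 60).
    """
    from .dielectric import sigma_tilde as _sig

    geom = ecm.SensingUnitGeometry(g_f=fixed["g_f"])
    eps_r_c = fixed.get("eps_r_c", 60.0)
    D_m = float(D_um) * 1e-6
    sigma_c = _sig(D_m, fixed["sigma_tilde"])
    eps_c = eps_r_c(D_m) if callable(eps_r_c) else float(eps_r_c)
    cell = ecm.EffectiveCellProperties(D=D_m, sigma_c=sigma_c, eps_r_c=eps_c)
    return ecm.compute_components(
        fixed["medium"], cell, fixed["membrane"], geom, phi, fixed["c_dl"]
    )


def interpolate_growth(
    k: float,
    a: float,
    D_range: tuple[float, float],
    step: float,
    fixed: dict,
) -> list[tuple[float, ecm.ECMComponents]]:
    """ECM components along a growth trajectory phi(D) = k * D**a.

    ``D_range`` and ``step`` are in micrometers and ``k`` in phi per um^a
    (matching the scaling module); ``fixed`` as in
    :func:`growth_components`.
    """
    if a <= 0:
        raise ValueError("scaling exponent must be positive")
    if step <= 0 or D_range[1] <= D_range[0]:
        raise ValueError("need increasing D_range and positive step")
    if k <= 0:
        raise ValueError("prefactor k must be positive (phi would vanish)")
    n = int(round((D_range[1] - D_range[0]) / step)) + 1
    out = []
    for D_um in D_range[0] + step * np.arange(n):
        phi = float(k * float(D_um) ** a)
        out.append((float(D_um), growth_components(float(D_um), phi, fixed)))
    return out


def _dut_from_components(c: ecm.ECMComponents) -> DUTModel:
    if c.has_cell_branch:
        return DeviceCellDUT(
            c_dl_per_area=c.c_dl, window_area=1.0, c_m=c.c_m, r_m=c.r_m,
            r_c=c.r_c, c_mem=c.c_mem, phi=c.phi,
        )
    return DeviceMediumDUT(
        c_dl_per_area=c.c_dl, window_area=1.0, c_m=c.c_m, r_m=c.r_m
    )


def predict_growth_response(
    peripheral: PeripheralParams,
    components_series: Sequence[tuple[float, ecm.ECMComponents]],
    frequencies: np.ndarray,
    reference: Optional[ecm.ECMComponents] = None,
) -> list[tuple[float, RelativeSpectrum]]:
    """Relative amplitude/phase of V_out per diameter, against the
    medium-only device.

    ``reference`` is the phi = 0 component set of the same unit; when not
    given it is derived from the first series entry by removing the cell
    branch and undoing the mixture scaling of R_m (exact) while keeping
    C_m (whose mixture correction is O(phi)).
    """
    series = list(components_series)
    if not series:
        raise ValueError("empty components series")
    f = validate_grid(frequencies)
    if reference is None:
        d0, c0 = series[0]
        reference = ecm.ECMComponents(
            r_m=c0.r_m * (1.0 - 1.5 * c0.phi), c_m=c0.c_m, c_dl=c0.c_dl,
            phi=0.0,
        )
    v_ref = transfer(peripheral, _dut_from_components(reference), f)
    out = []
    for D, comps in sorted(series, key=lambda p: p[0]):
        v = transfer(peripheral, _dut_from_components(comps), f)
        rel = RelativeSpectrum(
            f, v.amplitude / v_ref.amplitude,
            wrap_phase_deg(v.phase_deg - v_ref.phase_deg),
        )
        out.append((D, rel))
    return out
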