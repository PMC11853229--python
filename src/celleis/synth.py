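"""Seeded generator of synthetic wide-band spectra.

Field simulations and instrument recordings of the sensing unit are not
portable, so calibration and recovery workflows are exercised on spectra
produced by the package's own forward models plus a simple measurement
noise model: per-frequency multiplicative lognormal amplitude noise (unit
mean, coefficient of variation ``amplitude_cv``) and additive Gaussian
phase noise (``phase_sd`` degrees).  Zero noise reproduces the forward
model bit for bit, and every random draw flows from the configured seed —
there is no global RNG state.

Defaults (cv = 0.01, 0.5 degrees) are small enough to preserve the model's
qualitative features — the ~80 kHz relative-phase extremum and the
mid-frequency amplitude separation between cell sizes — while still
exercising the robustness of the fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import ecm, lpm
from .spectra import ComplexSpectrum, default_grid, validate_grid

__all__ = [
    "NoiseModel",
    "GrowthTrajectory",
    "gen_unit_spectrum",
    "gen_resistor_spectra",
    "gen_growth_timelapse",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: amplitude CV (lognormal, unit mean) and phase
    standard deviation in degrees, driven entirely by ``seed``."""

    amplitude_cv: float = 0.01
    phase_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_cv < 0 or self.phase_sd < 0:
            raise ValueError("noise levels must be non-negative")

    def apply(
        self, spectrum: ComplexSpectrum, seed: Optional[int] = None
    ) -> ComplexSpectrum:
        if self.amplitude_cv == 0 and self.phase_sd == 0:
            return spectrum
        rng = np.random.default_rng(self.seed if seed is None else seed)
        n = len(spectrum)
        if self.amplitude_cv > 0:
            s = np.sqrt(np.log1p(self.amplitude_cv**2))
            gain = rng.lognormal(mean=-0.5 * s**2, sigma=s, size=n)
        else:
            gain = np.ones(n)
        dphi = (
            np.radians(rng.normal(0.0, self.phase_sd, size=n))
            if self.phase_sd > 0
            else 0.0
        )
        values = spectrum.values * gain * np.exp(1j * dphi)
        return ComplexSpectrum(spectrum.frequencies, values, spectrum.quantity)


@dataclass(frozen=True)
class GrowthTrajectory:
    """Mother-cell diameter vs time (minutes, micrometers)."""

    times: np.ndarray
    diameters: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.diameters, dtype=float)
        if t.ndim != 1 or t.shape != d.shape or t.size == 0:
            raise ValueError("times and diameters must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(d <= 0):
            raise ValueError("diameters must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "diameters", d)

    @classmethod
    def linear(
        cls, d_start: float = 4.0, d_end: float = 6.0,
        duration: float = 45.0, interval: float = 2.0,
    ) -> "GrowthTrajectory":
        """Linear growth, by default 4 to 6 um over a 45 min watch sampled
        every 2 min."""
        t = np.arange(0.0, duration + 1e-9, interval)
        d = d_start + (d_end - d_start) * t / t[-1]
        return cls(times=t, diameters=d)


def gen_unit_spectrum(
    scenario: str,
    params: dict,
    frequencies: Optional[np.ndarray] = None,
    noise: Optional[NoiseModel] = None,
) -> ComplexSpectrum:
    """Forward ECM response current for one sensing-unit scenario.

    ``scenario`` is ``"empty"``, ``"bead"`` or ``"cell"``.  ``params``
    supplies medium, g_f, c_dl and v_amplitude (default 1 V), plus
    phi / particle_eps_r for a bead, or phi / cell
    (:class:`~celleis.ecm.EffectiveCellProperties`) / membrane for a cell.
    """
    f = default_grid() if frequencies is None else validate_grid(frequencies)
    medium: ecm.MediumProperties = params["medium"]
    geom = ecm.SensingUnitGeometry(g_f=params["g_f"])
    c_dl = params["c_dl"]
    v = params.get("v_amplitude", 1.0)
    if scenario == "empty":
        comps = ecm.compute_components(medium, None, None, geom, 0.0, c_dl)
    elif scenario == "bead":
        comps = ecm.compute_components(
            medium, None, None, geom, params["phi"], c_dl,
            particle_eps_r=params.get("particle_eps_r", 3.0),
        )
    elif scenario == "cell":
        comps = ecm.compute_components(
            medium, params["cell"], params["membrane"], geom,
            params["phi"], c_dl,
        )
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    clean = ecm.response_current(ecm.mixture_impedance(comps, f), v)
    return clean if noise is None else noise.apply(clean)


def gen_resistor_spectra(
    R_values: Sequence[float],
    peripheral: lpm.PeripheralParams,
    frequencies: Optional[np.ndarray] = None,
    noise: Optional[NoiseModel] = None,
) -> list[tuple[float, ComplexSpectrum]]:
    """Measurement-chain output for each calibration resistor, with an
    independent noise realization per resistor (seed + index)."""
    f = default_grid() if frequencies is None else validate_grid(frequencies)
    out = []
    for i, R in enumerate(R_values):
        if R <= 0:
            raise ValueError("resistances must be positive")
        clean = lpm.transfer(peripheral, lpm.ResistorDUT(float(R)), f)
        if noise is not None:
            clean = noise.apply(clean, seed=noise.seed + i)
        out.append((float(R), clean))
    return out


def gen_growth_timelapse(
    trajectory: GrowthTrajectory,
    k: float,
    a: float,
    peripheral: lpm.PeripheralParams,
    fixed: dict,
    frequencies: Optional[np.ndarray] = None,
    noise: Optional[NoiseModel] = None,
) -> list[tuple[float, ComplexSpectrum]]:
    """Time-lapse chain output of a growing cell.

    Per time point, phi = k * D(t)**a (D in um), ECM components via
    :func:`celleis.lpm.growth_components`, and the chain output via
    :func:`celleis.lpm.transfer`; noise is seeded per time point
    (seed + index).
    """
    f = default_grid() if frequencies is None else validate_grid(frequencies)
    out = []
    for i, (t, D_um) in enumerate(
        zip(trajectory.times, trajectory.diameters)
    ):
        comps = lpm.growth_components(D_um, float(k * D_um**a), fixed)
        v = lpm.transfer(peripheral, lpm._dut_from_components(comps), f)
        if noise is not None:
            v = noise.apply(v, seed=noise.seed + i)
        out.append((float(t), v))
    return out
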