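"""Equivalent circuit model (ECM) of the single-cell sensing unit.

The sensing unit — a pair of coplanar microelectrodes under a bowl-shaped
single-cell trap — is represented by a lumped network derived from
Maxwell's mixture theory: the culture medium as a resistor R_m in parallel
with a capacitor C_m, the trapped cell as a cytoplasm resistance R_c in
series with a membrane capacitance C_mem (that branch in parallel with the
medium), and the two electrode double layers as series capacitors C_dl.

All component values follow from the dielectric properties of medium and
particle, the equivalent volume fraction ``phi`` (the effective fraction of
the sensing region occupied by the particle), and a single geometric
constant ``G_f`` (effective electrode area over path length, in meters):

    R_m   = 1 / (sigma_m (1 - 3 phi / 2) G_f)
    C_m   = eps0 eps_m G_f (2 eps_m + eps_p - 2 phi (eps_m - eps_p))
                        / (2 eps_m + eps_p + phi (eps_m - eps_p))
    R_c   = 4 (1/(2 sigma_m) + 1/sigma_c) / (9 phi G_f)
    C_mem = 9 phi (D/2) c_mem0 G_f / 4

An insulating bead is a particle with phi > 0 and no intracellular branch.
The dilute-mixture resistance expression requires phi < 2/3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constants import EPS0
from .spectra import ComplexSpectrum, RelativeSpectrum, validate_grid, wrap_phase_deg

__all__ = [
    "MediumProperties",
    "EffectiveCellProperties",
    "MembraneSpec",
    "SensingUnitGeometry",
    "ECMComponents",
    "compute_components",
    "mixture_impedance",
    "empty_unit_impedance",
    "response_current",
    "relative_spectrum",
]

#: phi at which the dilute-mixture medium resistance denominator vanishes.
PHI_MAX = 2.0 / 3.0


@dataclass(frozen=True)
class MediumProperties:
    """Culture medium: conductivity (S/m) and relative permittivity."""

    sigma_m: float
    eps_r_m: float

    def __post_init__(self) -> None:
        if self.sigma_m <= 0:
            raise ValueError("medium conductivity must be positive")
        if self.eps_r_m < 1:
            raise ValueError("relative permittivity must be >= 1")


@dataclass(frozen=True)
class EffectiveCellProperties:
    """Homogeneous-sphere equivalent of the cell.

    ``sigma_c`` and ``eps_r_c`` are the effective conductivity (S/m) and
    relative permittivity of the single-shell reduction; ``D`` the diameter
    in meters.
    """

    D: float
    sigma_c: float
    eps_r_c: float

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("cell diameter must be positive")
        if self.sigma_c <= 0:
            raise ValueError("effective cell conductivity must be positive")


@dataclass(frozen=True)
class MembraneSpec:
    """Membrane capacitance per unit area (F/m^2)."""

    c_mem0: float = 1.4e-3

    def __post_init__(self) -> None:
        if self.c_mem0 <= 0:
            raise ValueError("membrane specific capacitance must be positive")


@dataclass(frozen=True)
class SensingUnitGeometry:
    """Geometry of the sensing unit (all lengths in meters).

    ``g_f`` is the lumped geometric constant; the remaining fields describe
    the trap and electrode layout and are carried for labeling geometry
    variants in scaling sweeps.
    """

    g_f: float
    trap_height: float = 8.3e-6
    orifice_width: float = 3.0e-6
    stimulus_electrode_width: float = 30e-6
    recording_electrode_width: float = 15e-6

    def __post_init__(self) -> None:
        for name in (
            "g_f",
            "trap_height",
            "orifice_width",
            "stimulus_electrode_width",
            "recording_electrode_width",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ECMComponents:
    """Lumped components of the sensing-unit circuit (SI units).

    ``r_c`` and ``c_mem`` are ``None`` exactly when no intracellular branch
    exists (empty unit or insulating bead).  ``phi`` is stored as a
    fraction, never percent.
    """

    r_m: float
    c_m: float
    c_dl: float
    phi: float
    r_c: Optional[float] = None
    c_mem: Optional[float] = None

    def __post_init__(self) -> None:
        if self.r_m <= 0 or self.c_m <= 0 or self.c_dl <= 0:
            raise ValueError("r_m, c_m and c_dl must be positive")
        if not 0 <= self.phi < 1:
            raise ValueError("phi must lie in [0, 1)")
        has_cell = self.r_c is not None or self.c_mem is not None
        if has_cell and (self.r_c is None or self.c_mem is None):
            raise ValueError("r_c and c_mem must be given together")
        if has_cell and (self.r_c <= 0 or self.c_mem <= 0):
            raise ValueError("r_c and c_mem must be positive when present")

    @property
    def has_cell_branch(self) -> bool:
        return self.r_c is not None


def compute_components(
    medium: MediumProperties,
    cell: Optional[EffectiveCellProperties],
    membrane: Optional[MembraneSpec],
    geom: SensingUnitGeometry,
    phi: float,
    c_dl: float,
    particle_eps_r: Optional[float] = None,
) -> ECMComponents:
    """Populate the lumped components from mixture theory.

    Parameters
    ----------
    cell : EffectiveCellProperties or None
        ``None`` represents an insulating bead (or, with ``phi == 0``, the
        empty unit): no intracellular branch is produced.
    phi : float
        Equivalent volume fraction, as a fraction in ``[0, 2/3)``.
    particle_eps_r : float, optional
        Relative permittivity entering the medium-capacitance mixture
        bracket.  Defaults to the cell's effective permittivity when a cell
        is given, else is required for a bead with ``phi > 0``.
    """
    if not 0 <= phi < PHI_MAX:
        raise ValueError(
            f"phi={phi} outside [0, 2/3): mixture resistance denominator "
            "1 - 3 phi/2 must stay positive"
        )
    if c_dl <= 0:
        raise ValueError("c_dl must be positive")

    g_f = geom.g_f
    r_m = 1.0 / (medium.sigma_m * (1.0 - 1.5 * phi) * g_f)

    if phi == 0:
        c_m = EPS0 * medium.eps_r_m * g_f
        return ECMComponents(r_m=r_m, c_m=c_m, c_dl=c_dl, phi=0.0)

    if cell is not None:
        eps_p = cell.eps_r_c if particle_eps_r is None else particle_eps_r
    else:
        if particle_eps_r is None:
            raise ValueError(
                "particle_eps_r is required for a bead (phi > 0, no cell)"
            )
        eps_p = particle_eps_r

    em, ep = medium.eps_r_m, eps_p
    bracket = (2 * em + ep - 2 * phi * (em - ep)) / (2 * em + ep + phi * (em - ep))
    c_m = EPS0 * em * bracket * g_f

    if cell is None:
        return ECMComponents(r_m=r_m, c_m=c_m, c_dl=c_dl, phi=phi)

    if membrane is None:
        raise ValueError("a membrane spec is required for a cell-occupied unit")
    r_c = 4.0 * (1.0 / (2.0 * medium.sigma_m) + 1.0 / cell.sigma_c) / (
        9.0 * phi * g_f
    )
    c_mem = 9.0 * phi * (cell.D / 2.0) * membrane.c_mem0 * g_f / 4.0
    return ECMComponents(
        r_m=r_m, c_m=c_m, c_dl=c_dl, phi=phi, r_c=r_c, c_mem=c_mem
    )


def mixture_impedance(
    components: ECMComponents, frequencies: np.ndarray
) -> ComplexSpectrum:
    """Equivalent complex impedance of the sensing unit.

    Z(w) = 2/(j w C_dl) + [ 1/R_m + j w C_m + 1/(R_c + 1/(j w C_mem)) ]^-1

    with the intracellular branch an open circuit when absent.  Convention
    ``exp(+j w t)``, ``Z_C = 1/(j w C)``.
    """
    f = validate_grid(frequencies)
    w = 2.0 * np.pi * f
    y = 1.0 / components.r_m + 1j * w * components.c_m
    if components.has_cell_branch:
        y = y + 1.0 / (components.r_c + 1.0 / (1j * w * components.c_mem))
    z = 1.0 / y + 2.0 / (1j * w * components.c_dl)
    return ComplexSpectrum(f, z, "impedance")


def empty_unit_impedance(
    medium: MediumProperties,
    geom: SensingUnitGeometry,
    c_dl: float,
    frequencies: np.ndarray,
) -> ComplexSpectrum:
    """Impedance of the empty (medium-only) unit.

    Z(w) = 1/((sigma_m + j w eps0 eps_m) G_f) + 2/(j w C_dl)
    """
    if c_dl <= 0:
        raise ValueError("c_dl must be positive")
    f = validate_grid(frequencies)
    w = 2.0 * np.pi * f
    z = 1.0 / (
        (medium.sigma_m + 1j * w * EPS0 * medium.eps_r_m) * geom.g_f
    ) + 2.0 / (1j * w * c_dl)
    return ComplexSpectrum(f, z, "impedance")


def response_current(
    z: ComplexSpectrum, v_amplitude: float = 1.0
) -> ComplexSpectrum:
    """Response current I(f) = V / Z(f) for a stimulus of ``v_amplitude``
    volts (the standard sweep uses 1 V)."""
    if z.quantity != "impedance":
        raise ValueError("response_current expects an impedance spectrum")
    if v_amplitude <= 0:
        raise ValueError("stimulus amplitude must be positive")
    if np.any(z.values == 0):
        raise ValueError("impedance contains zeros; current is undefined")
    return ComplexSpectrum(z.frequencies, v_amplitude / z.values, "current")


def relative_spectrum(
    test: ComplexSpectrum, reference: ComplexSpectrum
) -> RelativeSpectrum:
    """Relative amplitude A_r = |test|/|reference| and relative phase
    theta_r = phase(test) - phase(reference), wrapped to (-180, 180]."""
    if not test.same_grid(reference):
        raise ValueError("test and reference spectra must share a grid")
    a_r = test.amplitude / reference.amplitude
    theta_r = wrap_phase_deg(test.phase_deg - reference.phase_deg)
    return RelativeSpectrum(test.frequencies, a_r, theta_r)
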