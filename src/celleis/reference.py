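"""Canned models of the calibrated reference sensing unit.

These helpers assemble the empty and bead-occupied ECMs from the
calibration constants in :mod:`celleis.constants` (G_f = 5.280e-6 m,
C_dl = 1.844e-11 F, sigma_m = 0.9 S/m, eps_m = 81, bead eps = 3,
phi_bead = 0.042 %) and expose the derived relative response of the bead,
whose phase extremum near 80 kHz and unity low-frequency amplitude are
the unit's signature features.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import constants as C
from . import ecm
from .spectra import ComplexSpectrum, RelativeSpectrum, default_grid, validate_grid

__all__ = [
    "reference_medium",
    "reference_geometry",
    "reference_empty_components",
    "reference_bead_components",
    "bead_relative_response",
    "phase_extremum_frequency",
]


def reference_medium() -> ecm.MediumProperties:
    return ecm.MediumProperties(
        sigma_m=C.SIGMA_M_REFERENCE, eps_r_m=C.EPS_R_MEDIUM_REFERENCE
    )


def reference_geometry() -> ecm.SensingUnitGeometry:
    return ecm.SensingUnitGeometry(g_f=C.GF_REFERENCE)


def reference_empty_components() -> ecm.ECMComponents:
    return ecm.compute_components(
        reference_medium(), None, None, reference_geometry(), 0.0,
        C.CDL_REFERENCE,
    )


def reference_bead_components(
    phi: float = C.PHI_BEAD_REFERENCE,
) -> ecm.ECMComponents:
    return ecm.compute_components(
        reference_medium(), None, None, reference_geometry(), phi,
        C.CDL_REFERENCE, particle_eps_r=C.EPS_R_BEAD_REFERENCE,
    )


def bead_relative_response(
    frequencies: Optional[np.ndarray] = None,
    phi: float = C.PHI_BEAD_REFERENCE,
    v_amplitude: float = 1.0,
) -> RelativeSpectrum:
    """Relative amplitude/phase of the bead-occupied unit against the
    empty unit, via the 1 V response currents."""
    f = default_grid() if frequencies is None else validate_grid(frequencies)
    z_empty = ecm.empty_unit_impedance(
        reference_medium(), reference_geometry(), C.CDL_REFERENCE, f
    )
    z_bead = ecm.mixture_impedance(reference_bead_components(phi), f)
    i_empty = ecm.response_current(z_empty, v_amplitude)
    i_bead = ecm.response_current(z_bead, v_amplitude)
    return ecm.relative_spectrum(i_bead, i_empty)


def phase_extremum_frequency(rel: RelativeSpectrum) -> float:
    """Frequency (Hz) at which the relative phase attains its minimum."""
    return float(rel.frequencies[int(np.argmin(rel.theta_r))])
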