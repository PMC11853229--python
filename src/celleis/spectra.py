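"""Frequency grids and complex spectra.

A :class:`ComplexSpectrum` holds one complex value per frequency together
with a quantity tag (impedance, current or voltage).  Amplitude is the
modulus, phase the argument in degrees; the time-harmonic convention is
``exp(+j w t)`` with capacitor impedance ``1/(j w C)``, so capacitive
current leads voltage by +90 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "default_grid",
    "ComplexSpectrum",
    "RelativeSpectrum",
    "wrap_phase_deg",
]

#: Valid quantity tags and their SI units.
QUANTITIES = {"impedance": "ohm", "current": "A", "voltage": "V"}


def default_grid(
    f_min: float = 1e4, f_max: float = 1e7, n: int = 100
) -> np.ndarray:
    """Standard sweep: ``n`` points equidistant in log10(f) over
    ``[f_min, f_max]`` (default 100 points, 10 kHz to 10 MHz)."""
    if not (f_min > 0 and f_max > f_min and n >= 2):
        raise ValueError("need 0 < f_min < f_max and n >= 2")
    return np.logspace(np.log10(f_min), np.log10(f_max), n)


def validate_grid(frequencies: np.ndarray) -> np.ndarray:
    f = np.asarray(frequencies, dtype=float)
    if f.ndim != 1 or f.size == 0:
        raise ValueError("frequency grid must be a non-empty 1-D array")
    if np.any(f <= 0):
        raise ValueError("frequencies must be strictly positive")
    if np.any(np.diff(f) <= 0):
        raise ValueError("frequencies must be strictly increasing")
    return f


def wrap_phase_deg(theta: np.ndarray) -> np.ndarray:
    """Wrap phase differences to the half-open interval (-180, 180]."""
    wrapped = np.mod(-np.asarray(theta, dtype=float) + 180.0, 360.0)
    return -(wrapped - 180.0)


@dataclass(frozen=True)
class ComplexSpectrum:
    """Complex-valued response sampled on a strictly increasing grid.

    Parameters
    ----------
    frequencies : array of float
        Strictly increasing frequencies in Hz.
    values : array of complex
        One complex value per frequency.
    quantity : {"impedance", "current", "voltage"}
        What the values represent (ohm, A or V respectively).
    """

    frequencies: np.ndarray
    values: np.ndarray
    quantity: str = "impedance"

    def __post_init__(self) -> None:
        f = validate_grid(self.frequencies)
        v = np.asarray(self.values, dtype=complex)
        if v.shape != f.shape:
            raise ValueError("values and frequencies must have equal length")
        if self.quantity not in QUANTITIES:
            raise ValueError(f"unknown quantity tag {self.quantity!r}")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.frequencies.size

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase_deg(self) -> np.ndarray:
        return np.degrees(np.angle(self.values))

    def same_grid(self, other: "ComplexSpectrum") -> bool:
        return self.frequencies.shape == other.frequencies.shape and np.array_equal(
            self.frequencies, other.frequencies
        )


@dataclass(frozen=True)
class RelativeSpectrum:
    """Occupied-unit response normalized by the empty-unit reference.

    ``a_r`` is the amplitude ratio |test|/|reference| and ``theta_r`` the
    phase difference in degrees, wrapped to (-180, 180].
    """

    frequencies: np.ndarray
    a_r: np.ndarray
    theta_r: np.ndarray

    def __post_init__(self) -> None:
        f = validate_grid(self.frequencies)
        a = np.asarray(self.a_r, dtype=float)
        t = np.asarray(self.theta_r, dtype=float)
        if a.shape != f.shape or t.shape != f.shape:
            raise ValueError("a_r / theta_r length must match the grid")
        if np.any(a <= 0):
            raise ValueError("relative amplitude must be positive")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "a_r", a)
        object.__setattr__(self, "theta_r", t)

    def __len__(self) -> int:
        return self.frequencies.size
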