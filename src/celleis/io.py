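"""Spectrum CSV I/O, parameter JSON, and packaged reference data.

Spectrum files are plain UTF-8 CSV with a ``# quantity=<tag>`` comment
line followed by one of two headers:

    frequency_hz,amplitude,phase_deg
    frequency_hz,real,imag

Floats are written with 12 significant digits, so a write/read round trip
is value-identical at that precision and two writes of the same spectrum
are byte-identical.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import QUANTITIES, ComplexSpectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "load_table1_fixture",
    "read_params_json",
]

_DIALECTS = {
    "amp_phase": ("frequency_hz", "amplitude", "phase_deg"),
    "real_imag": ("frequency_hz", "real", "imag"),
}


class SpectrumFormatError(ValueError):
    """Malformed spectrum file (header, monotonicity or value errors)."""


def read_spectrum(path) -> ComplexSpectrum:
    """Read a spectrum CSV in either dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    quantity = "impedance"
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        s = line.strip()
        if s.startswith("#"):
            body = s.lstrip("#").strip()
            if body.startswith("quantity="):
                quantity = body.split("=", 1)[1].strip()
        elif s:
            data_lines.append(s)
    if not data_lines:
        raise SpectrumFormatError(f"{path}: no data")
    header = tuple(h.strip() for h in data_lines[0].split(","))
    for dialect, cols in _DIALECTS.items():
        if header == cols:
            break
    else:
        raise SpectrumFormatError(
            f"{path}: unrecognized header {header!r}; expected one of "
            f"{list(_DIALECTS.values())}"
        )
    try:
        arr = np.array(
            [[float(x) for x in row.split(",")] for row in data_lines[1:]]
        )
    except ValueError as exc:
        raise SpectrumFormatError(f"{path}: non-numeric value ({exc})") from exc
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] == 0:
        raise SpectrumFormatError(f"{path}: expected 3 columns of data")
    if np.any(~np.isfinite(arr)):
        raise SpectrumFormatError(f"{path}: NaN or infinite values")
    f = arr[:, 0]
    if np.any(np.diff(f) <= 0):
        raise SpectrumFormatError(f"{path}: frequencies not strictly increasing")
    if dialect == "amp_phase":
        values = arr[:, 1] * np.exp(1j * np.radians(arr[:, 2]))
    else:
        values = arr[:, 1] + 1j * arr[:, 2]
    if quantity not in QUANTITIES:
        raise SpectrumFormatError(f"{path}: unknown quantity tag {quantity!r}")
    return ComplexSpectrum(f, values, quantity)


def write_spectrum(
    spectrum: ComplexSpectrum, path, dialect: str = "amp_phase"
) -> None:
    """Write a spectrum CSV deterministically (12 significant digits)."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; use {set(_DIALECTS)}")
    path = Path(path)
    cols = _DIALECTS[dialect]
    if dialect == "amp_phase":
        c1, c2 = spectrum.amplitude, spectrum.phase_deg
    else:
        c1, c2 = spectrum.values.real, spectrum.values.imag
    try:
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# quantity={spectrum.quantity}\n")
            fh.write(",".join(cols) + "\n")
            for f, a, b in zip(spectrum.frequencies, c1, c2):
                fh.write(f"{f:.12g},{a:.12g},{b:.12g}\n")
    except OSError as exc:
        raise OSError(f"cannot write spectrum to {path}: {exc}") from exc


def load_table1_fixture() -> list[tuple[float, float]]:
    """The five packaged (diameter um, phi percent) calibration pairs of
    the reference sensing unit."""
    with resources.files("celleis.data").joinpath("table1_phi.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        df = pd.read_csv(fh)
    return [
        (float(d), float(p))
        for d, p in zip(df["diameter_um"], df["phi_percent"])
    ]


def read_params_json(path) -> dict:
    """Flat JSON parameter file (SI units), unknown structure preserved."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        return json.load(fh)
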