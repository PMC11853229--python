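"""Effective homogeneous dielectric description of the cell.

A walled cell is reduced to a single-shelled sphere (thin membrane around a
homogeneous cytoplasm) and then to one complex permittivity via the
Maxwell-Wagner single-shell formula.  Under the ``exp(+j w t)`` convention
the complex permittivity is ``eps~ = eps - j sigma / w``, so dielectric
loss makes the imaginary part non-positive.

The diameter-dependent effective conductivity ``sigma~(D)`` that enters the
cytoplasm-resistance expression is exposed as a user-supplied table or
callable (:func:`sigma_tilde`); the shipped :data:`DEFAULT_YEAST_SHELL` is
a documented default drawn from typical budding-yeast literature values,
not a fitted quantity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence, Union

import numpy as np

from .constants import EPS0
from .ecm import EffectiveCellProperties

__all__ = [
    "ShellModelParams",
    "DEFAULT_YEAST_SHELL",
    "effective_cell_properties",
    "sigma_tilde",
]


@dataclass(frozen=True)
class ShellModelParams:
    """Single-shell parameters: membrane thickness (m), membrane and
    cytoplasm conductivities (S/m) and relative permittivities."""

    membrane_thickness: float
    sigma_mem: float
    eps_r_mem: float
    sigma_cyt: float
    eps_r_cyt: float

    def __post_init__(self) -> None:
        if self.membrane_thickness <= 0:
            raise ValueError("membrane thickness must be positive")
        if self.sigma_mem < 0 or self.sigma_cyt < 0:
            raise ValueError("conductivities must be non-negative")
        if self.eps_r_mem < 1 or self.eps_r_cyt < 1:
            raise ValueError("relative permittivities must be >= 1")


#: Default single-shell parameterization for budding yeast (typical
#: literature values; membrane 7 nm, nearly insulating, cytoplasm moderately
#: conductive).  A default, not a device-fitted quantity.
DEFAULT_YEAST_SHELL = ShellModelParams(
    membrane_thickness=7e-9,
    sigma_mem=1e-7,
    eps_r_mem=6.0,
    sigma_cyt=0.5,
    eps_r_cyt=60.0,
)


def _complex_permittivity(eps_r: float, sigma: float, w: float) -> complex:
    return EPS0 * eps_r - 1j * sigma / w


def effective_cell_properties(
    shell: ShellModelParams, D: float, f: float
) -> EffectiveCellProperties:
    """Collapse a single-shelled sphere to homogeneous effective properties.

    eps~_eff = eps~_mem (g^3 + 2 K) / (g^3 - K),
    g = D / (D - 2 d),  K = (eps~_cyt - eps~_mem) / (eps~_cyt + 2 eps~_mem)

    with ``d`` the membrane thickness and eps~ = eps - j sigma / w.  The
    real part maps to the effective relative permittivity, the imaginary
    part to the effective conductivity ``sigma_c = -w * imag``.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    if D <= 2 * shell.membrane_thickness:
        raise ValueError("diameter must exceed twice the membrane thickness")
    w = 2.0 * np.pi * f
    e_mem = _complex_permittivity(shell.eps_r_mem, shell.sigma_mem, w)
    e_cyt = _complex_permittivity(shell.eps_r_cyt, shell.sigma_cyt, w)
    gamma3 = (D / (D - 2.0 * shell.membrane_thickness)) ** 3
    K = (e_cyt - e_mem) / (e_cyt + 2.0 * e_mem)
    denom = gamma3 - K
    if abs(denom) < 1e-300:
        raise ValueError("degenerate shell: gamma^3 == K")
    e_eff = e_mem * (gamma3 + 2.0 * K) / denom
    sigma_c = -w * e_eff.imag
    if sigma_c <= 0:
        raise ValueError("effective conductivity is non-positive; check shell")
    return EffectiveCellProperties(D=D, sigma_c=sigma_c, eps_r_c=e_eff.real / EPS0)


SigmaTable = Sequence[tuple[float, float]]


def sigma_tilde(
    D: float, table_or_callable: Union[SigmaTable, Callable[[float], float]]
) -> float:
    """Diameter-dependent effective cell conductivity sigma~(D) in S/m.

    Accepts either a callable ``D -> sigma`` or a table of ``(D, sigma)``
    pairs, interpolated linearly in D; evaluation outside the table domain
    is an error (no extrapolation).
    """
    if callable(table_or_callable):
        return float(table_or_callable(D))
    pts = sorted((float(d), float(s)) for d, s in table_or_callable)
    if len(pts) < 2:
        raise ValueError("sigma~ table needs at least two points")
    ds = np.array([p[0] for p in pts])
    ss = np.array([p[1] for p in pts])
    if D < ds[0] or D > ds[-1]:
        raise ValueError(
            f"D={D} outside sigma~ table domain [{ds[0]}, {ds[-1]}]"
        )
    return float(np.interp(D, ds, ss))
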