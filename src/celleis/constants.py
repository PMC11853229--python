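"""Reference-device calibration constants.

The reduced empty-unit / bead-unit circuit expressions used throughout the
package are parameterized by the constants below, obtained by fitting the
equivalent circuit to wide-band simulations of one particular sensing-unit
geometry (8.3 um high trap, 30 um stimulus / 15 um recording electrodes).
They are collected here, once, with their provenance; nothing else in the
package hard-codes them.

Some constants appear in the reduced expressions only as published digit
strings whose units could not be recovered (see ``CMEM_REDUCED_PREFACTOR``);
those are stored verbatim for reference but the dimensional component
equations are always used for computation.
"""

from __future__ import annotations

#: Vacuum permittivity (F/m), CODATA 2018.
EPS0 = 8.8541878128e-12

#: Geometric constant of the reference sensing unit (m): effective
#: electrode-area-to-path-length factor fitted on the empty unit.
GF_REFERENCE = 5.280e-6

#: Double-layer capacitance per electrode window of the reference unit (F),
#: fitted jointly with GF_REFERENCE on the empty unit.
CDL_REFERENCE = 1.844e-11

#: Product sigma_m * G_f (S) as it appears in the reduced medium-resistance
#: expression R_m = 1 / (4.752e-6 * (1 - 1.5 phi)).
SIGMA_M_GF_PRODUCT = 4.752e-6

#: Medium conductivity implied by the product above (S/m).
SIGMA_M_REFERENCE = SIGMA_M_GF_PRODUCT / GF_REFERENCE  # 0.9 S/m

#: Relative permittivity of the culture medium implied by the reduced
#: medium-capacitance bracket (165 + 78 phi) = 2 eps_m + eps_p + phi (eps_m
#: - eps_p), which solves uniquely to eps_m = 81, eps_p = 3.
EPS_R_MEDIUM_REFERENCE = 81.0

#: Relative permittivity of the polystyrene bead implied by the same bracket.
EPS_R_BEAD_REFERENCE = 3.0

#: Membrane capacitance per unit area (F/m^2), reference value used for the
#: budding-yeast cell membrane.
CMEM0_REFERENCE = 1.4e-3

#: Equivalent volume fraction of a 6 um polystyrene bead in the reference
#: unit (fraction, i.e. 0.042 %).
PHI_BEAD_REFERENCE = 4.2e-4

#: Prefactor digit string of the reduced membrane-capacitance expression
#: ("119.5 * phi * D") as published for the reference device.  Its units are
#: not recoverable from the source; stored for reference only and never used
#: in computation (the dimensional mixture equation is).
CMEM_REDUCED_PREFACTOR = 119.5

#: Double-layer capacitance per unit electrode-window area of the
#: experimental device: 0.131 pF/um^2 = 0.131 F/m^2.
CDL_PER_AREA_EXPERIMENTAL = 0.131
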