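# Methods

## The sensing problem

A single budding-yeast cell is held at the orifice of a bowl-shaped
SU-8 trap above a pair of coplanar gold microelectrodes (30 µm stimulus,
15 µm recording, exposed through windows in a SiNx passivation layer). A
1 V sinusoid swept over 10 kHz–10 MHz drives a response current whose
amplitude and phase encode the occupancy of the sensing region. Because
raw spectra are dominated by the electrode double layer at low frequency
and by the bulk medium at high frequency, occupancy is read from the
*relative* response — amplitude ratio `A_r = A/A_e` and phase difference
`θ_r = θ − θ_e` against the empty (medium-only) unit.

## Equivalent circuit of the sensing unit

The unit is lumped into `2×C_dl` (series electrode double layers) around
`R_m ∥ C_m ∥ (R_c – C_mem)`, with component values given by Maxwell's
mixture theory for a dilute spherical inclusion of equivalent volume
fraction `φ` (see README for the four component equations). Conventions
and numerical choices:

- Time-harmonic `e^{+jωt}`, `Z_C = 1/(jωC)`; phases in degrees, wrapped to
  `(−180°, 180°]` (half-open at −180, so the wrap is deterministic).
- All internal computation in SI; `φ` is a fraction internally and appears
  as percent only at I/O boundaries (`phi_percent` columns).
- `ε_m` enters `C_m = ε G_f` as an absolute permittivity (`ε₀ε_r`), which
  is the only reading that yields farads with `G_f` in meters.
- The mixture resistance requires `φ < 2/3`; larger values are rejected.
- The impedance is evaluated as the admittance sum of the stated network.
  An independent stepwise series/parallel reduction serves as a test
  oracle (agreement < 1e−10 relative); the network, not any particular
  printed algebraic rearrangement, is the ground truth.
- The membrane term uses the standard mixture mapping
  `C_mem = 9φ(D/2)c_mem,0·G_f/4` with radius `D/2`; this is the only
  dimensionally consistent form of the lumped membrane capacitance.

Calibrated constants of the reference unit (`celleis.constants`, one
table with per-constant provenance): `G_f = 5.280e−6 m`,
`C_dl = 1.844e−11 F`, `σ_m·G_f = 4.752e−6 S` (hence `σ_m = 0.9 S/m`), and
the mixture bracket `165 + 78φ`, which pins `ε_m = 81` and the bead
permittivity `ε_p = 3` (`2ε_m + ε_p = 165`, `ε_m − ε_p = 78`). The
membrane reference capacitance is `c_mem,0 = 1.4e−3 F/m²`; note this is an
order of magnitude below the textbook 1.4 µF/cm², so it is exposed as a
configurable default (`MembraneSpec`), not a hard constant.

## Single-shell cell dielectric

The walled cell is reduced to a homogeneous sphere by the Maxwell–Wagner
single-shell formula
`ε̃_eff = ε̃_mem (γ³ + 2K)/(γ³ − K)`, `γ = D/(D − 2d)`,
`K = (ε̃_cyt − ε̃_mem)/(ε̃_cyt + 2ε̃_mem)`, `ε̃ = ε − jσ/ω`, whose real and
imaginary parts map to the effective permittivity and conductivity fed to
the mixture equations. The diameter-dependent effective conductivity
`σ̃(D)` used by the cytoplasm-resistance expression is a user-supplied
table (linear interpolation, no extrapolation) or callable. The shipped
`DEFAULT_YEAST_SHELL` (7 nm membrane, `σ_mem = 1e−7 S/m`, `ε_mem = 6`,
`σ_cyt = 0.5 S/m`, `ε_cyt = 60`) is a typical-literature default for
budding yeast, clearly a default rather than a device-fitted value.

## Staged fitting

Calibration mirrors the experiment: (1) the empty unit fixes `G_f` and
`C_dl`; (2) an insulating bead fixes `φ_bead` with those frozen; (3) a
diameter series of cell spectra yields `φ(D)` with the intracellular
branch active. Choices:

- Objective: residuals on the complex current `I(f) = V/Z(f)`, real and
  imaginary stacked, each frequency weighted by `1/|I_obs|` so that
  amplitude decades contribute comparably. An amplitude/phase residual
  mode is available behind `residual_mode="amp_phase"`; the default is the
  complex mode.
- `R²` is reported separately for the amplitude and the phase curve,
  computed after the complex fit.
- Initialization is deterministic and data-driven: `C_dl` from the
  low-frequency end (where `|Z| ≈ 2/(ωC_dl)`), `G_f` from the
  high-frequency plateau (where the bulk dominates); solver bounds span
  ±2 decades around the start. No hidden randomness in least squares.
- Convergence tolerances 1e−10 (step and objective), budget 1e4
  evaluations; non-convergence is reported in `FitResult.converged`, never
  silently. `φ` estimates at the `[0, 0.5]` search bound are flagged
  (`at_bound`).

Identifiability under noise: `G_f` and `C_dl` shape the whole curve and
are recovered to ~0.1% under the default noise model. A single bead or
cell, however, perturbs the sweep only by `≈1.5φ` in relative amplitude —
about 0.06% for `φ ≈ 4e−4` — which is *below* a 1% per-point amplitude
noise floor; `φ` estimated from one noisy absolute sweep is therefore
noise-limited, with a standard error of order `cv/(1.5√N) ≈ 7e−4`. This
is a property of the measurement physics, not the estimator. In practice
the relative normalization exists precisely because the dominant noise is
common-mode between the occupied and reference sweeps; when the two share
a noise realization the ratio is exact (demonstrated as a property test).

## Power-law scaling

`φ = k·D^a` is fitted by explicit grid search: for each candidate `a`
(default grid 1.0–3.0, step 0.1, matching the one-decimal precision the
exponent is meaningful at), `k` is the no-intercept least-squares slope of
`φ` on `x = D^a`, and the smallest-SSE exponent wins, ties to the smaller
`a`. Grid search was chosen over continuous optimization for
reproducibility and because it avoids the log–log-vs-linear regression
ambiguity (log–log regression on the calibration table gives ≈1.55 and
would round differently). The no-intercept form reflects that the law
passes through the origin; an intercept variant is available behind
`with_intercept=True`. Diameters are carried in µm in this module, and the
unit of `k` is recorded accordingly. On the reference calibration table
the selected exponent is 1.6 with R² = 0.996; synthetic geometry variants
exercise the sweep across exponents (physically, shallower traps and
wider orifices push the exponent toward the volume-like limit of 3).

## Lumped model of the measurement chain

Topology (normative for this package; the schematic is in the `lpm`
module docstring): stimulus `V_in` through wire `L_w + R_w` to node A;
parasitic `C_p` from A to ground; the device under test (DUT) from A to
node B; an identical `C_p` from B to ground (the symmetric-parasitics
assumption); readout residuals as shunt `C_R` at B and series `L_R` from B
into the virtual ground of an ideal inverting transimpedance stage with
feedback `R_ac ∥ C_ac`; `V_out = −I·Z_f`. The two free nodes are solved
exactly in complex arithmetic per frequency; an independent full-MNA
(nullor op-amp) solver is the test oracle (< 1e−9 relative).

The placement of `L_R`/`C_R` inside the recording loop — rather than after
the amplifier output — is deliberate: behind an ideal (zero-impedance)
output only the product `ω²L_R C_R` would be observable, whereas in the
recording loop all four GA-fitted parameters (`L_R`, `C_R`, `C_p`,
`C_ac`) are separately identifiable from resistor calibration spectra
(verified by noiseless round-trip recovery to machine precision). Under
measurement noise the residuals' *separate* signatures (~0.1% of `V_out`)
drop below a 1% noise floor and only their joint effect is well
determined; `C_p` and `C_ac` remain individually recoverable. This
mirrors the documented high-frequency limitations of simplified chain
models; no corrections beyond the stated topology are invented, and the
amplifier is ideal (infinite gain and bandwidth).

GA settings (defaults): population 100, 200 generations, tournament
selection (size 3), BLX-α crossover (rate 0.9, α 0.3), Gaussian mutation
(rate 0.1, σ 0.15 in log10 units), elitism of one, genome in log10 of the
physical parameters, bounds spanning ±2 decades around the initial
values, fixed seed 20250214. A bounded local least-squares polish of the
best individual (default on) sharpens point estimates; all of it is
deterministic for a fixed seed. Calibration uses fixed resistors of 50,
100 and 220 kΩ as DUTs, then the device filled with pure medium (fitting
`C_dl` per unit window area, `C_m`, `R_m`), then the cell-occupied device
(fitting `C_m`, `R_m`, `R_c`, `C_mem`). The default window area,
1.41e−10 m², makes 0.131 pF/µm² correspond to the reference unit's `C_dl`.

Growth prediction: `φ(D) = k·D^a` (with `k`, `a` from the scaling fit)
generates ECM components on a 4–6 µm grid in 0.05 µm steps (41 sizes);
each is pushed through the chain and normalized by the medium-only device
to give relative amplitude/phase per size. Along this sweep `R_c` falls
strictly, `C_mem` rises strictly, and `A_r` at 1 MHz falls strictly with
diameter.

## Synthetic data

The generator emulates the forward models plus measurement noise:
per-frequency multiplicative lognormal amplitude noise (unit mean,
CV = `amplitude_cv`) and additive Gaussian phase noise (`phase_sd`
degrees). Defaults `cv = 0.01`, `0.5°` keep the qualitative features (the
~80 kHz phase extremum, mid-frequency amplitude separation between cell
sizes) intact while exercising fit robustness. Zero noise reproduces the
forward model exactly; every draw flows from the configured seed, with
per-item seeds (`seed + index`) for resistor and time-lapse series. The
default frequency grid is 100 points equidistant in `log10 f` from 10 kHz
to 10 MHz (the sweep spans three decades, so logarithmic spacing is the
natural reading of an equidistant 100-point sweep).

What the generator does *not* emulate: spatial field distributions and
electrode current-density maps, frequency-dependent (constant-phase)
double layers, drift and fouling over long experiments, nonlinear or
distributed (transmission-line) chain elements, and electromagnetic
interference. Passing recovery tests on these synthetics therefore shows
the estimators are correct for the stated models and noise structure, not
that the models capture every feature of real recordings — in particular
the high-frequency regime, where simplified chain models are known to
deviate.

## Problem sizes and determinism

Test and reproduction workloads are desk-scale by design: 100-point
sweeps (2001 points for locating the phase extremum), 25 replicates for
noisy-recovery medians, 100 random draws for solver-oracle equivalence,
and the default GA budget for chain fits. All stochastic paths are
seeded; identical seeds give identical results.

## Known limitations

- The mixture equations are dilute-limit (`φ ≪ 1`) and the trap geometry
  enters only through `G_f` and the empirical exponent `a`; no field
  solving is performed.
- Single-sweep `φ` estimates are noise-limited at sub-permille occupancy
  (see staged fitting above).
- The readout residuals `L_R`, `C_R` are only jointly identified under
  realistic noise.
- The scaling exponent is descriptive, not derived from trap geometry.
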