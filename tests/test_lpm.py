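"""Measurement-chain lumped model: solvers, GA fits, growth prediction."""

import numpy as np
import pytest

from celleis import constants as C
from celleis import ecm, lpm, synth
from celleis.ga import GAConfig, minimize_ga
from celleis.spectra import default_grid

from conftest import random_components
from test_ecm import network_reduction_oracle


def mna_oracle(p: lpm.PeripheralParams, z_dut: np.ndarray, f: np.ndarray):
    """Full modified-nodal-analysis solve, element-by-element stamping.

    Unknowns per frequency: node voltages V_A, V_B, V_T (amplifier input),
    V_out, plus branch currents of the source-side wire, of L_R and of the
    op-amp output.  The ideal op-amp is a nullor: V_T = 0 and no current
    into the input; the feedback impedance connects V_T to V_out.
    Independent of the 2x2 reduced solve in lpm.transfer.
    """
    out = np.zeros(f.size, dtype=complex)
    for i, fi in enumerate(f):
        w = 2 * np.pi * fi
        zw = 1j * w * p.l_w + p.r_w
        zlr = 1j * w * p.l_r
        zf = p.r_ac / (1 + 1j * w * p.r_ac * p.c_ac) if p.c_ac > 0 else p.r_ac
        # unknowns: [V_A, V_B, V_T, V_out, I_w, I_lr, I_amp]
        A = np.zeros((7, 7), dtype=complex)
        b = np.zeros(7, dtype=complex)
        ydut = 1 / z_dut[i]
        # KCL at A: I_w = V_A*jwC_p + (V_A - V_B)*ydut
        A[0] = [1j * w * p.c_p + ydut, -ydut, 0, 0, -1, 0, 0]
        # KCL at B: (V_A - V_B)*ydut = V_B*jw(C_p + C_r) + I_lr
        A[1] = [ydut, -(ydut + 1j * w * (p.c_p + p.c_r)), 0, 0, 0, -1, 0]
        # KCL at T: I_lr = (V_T - V_out)/zf  (no op-amp input current)
        A[2] = [0, 0, 1 / zf, -1 / zf, 0, -1, 0]
        # source branch: V_in - V_A = zw * I_w
        A[3] = [1, 0, 0, 0, zw, 0, 0]
        b[3] = p.v_in
        # L_R branch: V_B - V_T = zlr * I_lr
        A[4] = [0, 1, -1, 0, 0, -zlr, 0]
        # nullor: V_T = 0
        A[5] = [0, 0, 1, 0, 0, 0, 0]
        # KCL at output node: (V_T - V_out)/zf + I_amp = 0
        A[6] = [0, 0, 1 / zf, -1 / zf, 0, 0, 1]
        v = np.linalg.solve(A, b)
        out[i] = v[3]
    return out


class TestDUTImpedance:
    def test_resistor_is_flat_and_real(self, grid100):
        z = lpm.dut_impedance(lpm.ResistorDUT(100e3), grid100)
        assert np.allclose(z.values, 1e5)
        assert np.allclose(z.phase_deg, 0.0)

    def test_medium_device_equals_empty_unit_model(
        self, ref_medium, ref_geom, grid100
    ):
        comps = ecm.compute_components(
            ref_medium, None, None, ref_geom, 0.0, C.CDL_REFERENCE
        )
        dut = lpm.DeviceMediumDUT(
            c_dl_per_area=C.CDL_REFERENCE / 1.41e-10, window_area=1.41e-10,
            c_m=comps.c_m, r_m=comps.r_m,
        )
        z_dut = lpm.dut_impedance(dut, grid100).values
        z_unit = ecm.empty_unit_impedance(
            ref_medium, ref_geom, C.CDL_REFERENCE, grid100
        ).values
        assert np.max(np.abs(z_dut - z_unit) / np.abs(z_unit)) < 1e-12

    def test_cell_device_matches_network_oracle_at_1mhz(self):
        # experimentally fitted 4-um-cell components (column-corrected:
        # capacitances in pF, resistances in kOhm/MOhm)
        dut = lpm.DeviceCellDUT(
            c_dl_per_area=0.131, window_area=1.41e-10,
            c_m=0.98e-12, r_m=997e3, r_c=1.75e6, c_mem=0.13e-12,
        )
        f = np.array([1e6])
        z = lpm.dut_impedance(dut, f).values[0]
        z_oracle = network_reduction_oracle(dut.components(), f)[0]
        assert abs(z - z_oracle) / abs(z_oracle) < 1e-12

    def test_variant_completeness_enforced(self):
        with pytest.raises(ValueError):
            lpm.DeviceCellDUT(
                c_dl_per_area=0.131, window_area=1.41e-10,
                c_m=1e-12, r_m=1e5, r_c=-1.0, c_mem=1e-13,
            )


class TestTransfer:
    def test_ideal_transimpedance_limit(self, grid100):
        p = lpm.PeripheralParams(r_ac=100e3)
        v = lpm.transfer(p, lpm.ResistorDUT(50e3), grid100)
        assert np.allclose(np.abs(v.values), 2.0, rtol=1e-12)
        assert np.allclose(np.abs(v.phase_deg), 180.0)  # inverting stage

    def test_small_wire_impedance_is_negligible(self, grid100):
        """Micro-henry / tens-of-ohm wires barely move V_out when the DUT
        impedance dominates."""
        kw = dict(c_p=1e-12, r_ac=100e3, c_ac=2e-12, l_r=1e-6, c_r=10e-12)
        p0 = lpm.PeripheralParams(l_w=0.0, r_w=0.0, **kw)
        p1 = lpm.PeripheralParams(l_w=1e-6, r_w=100.0, **kw)
        dut = lpm.ResistorDUT(100e3)
        v0 = lpm.transfer(p0, dut, grid100).values
        v1 = lpm.transfer(p1, dut, grid100).values
        assert np.max(np.abs(v1 - v0) / np.abs(v0)) < 0.01

    def test_nodal_solve_matches_mna_oracle(self, chain):
        rng = np.random.default_rng(11)
        f = default_grid(n=40)
        for _ in range(20):
            p = lpm.PeripheralParams(
                c_p=10 ** rng.uniform(-13, -11),
                l_w=10 ** rng.uniform(-7, -5),
                r_w=10 ** rng.uniform(0, 2),
                r_ac=10 ** rng.uniform(4, 6),
                c_ac=10 ** rng.uniform(-13, -11),
                l_r=10 ** rng.uniform(-7, -5),
                c_r=10 ** rng.uniform(-12, -10),
            )
            dut = lpm.ResistorDUT(10 ** rng.uniform(4, 5.5))
            v = lpm.transfer(p, dut, f).values
            v_oracle = mna_oracle(p, lpm.dut_impedance(dut, f).values, f)
            assert np.max(np.abs(v - v_oracle) / np.abs(v_oracle)) < 1e-9

    def test_mna_oracle_on_device_dut(self, chain, grid100):
        dut = lpm.DeviceCellDUT(
            c_dl_per_area=0.131, window_area=1.41e-10,
            c_m=0.98e-12, r_m=997e3, r_c=1.75e6, c_mem=0.13e-12,
        )
        v = lpm.transfer(chain, dut, grid100).values
        v_oracle = mna_oracle(chain, lpm.dut_impedance(dut, grid100).values,
                              grid100)
        assert np.max(np.abs(v - v_oracle) / np.abs(v_oracle)) < 1e-9

    def test_all_zero_feedback_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            lpm.PeripheralParams(r_ac=0.0, c_ac=0.0)


SMALL_GA = GAConfig(population_size=40, generations=40, seed=20250214)


class TestGA:
    def test_determinism_same_seed_identical(self):
        cfg = GAConfig(bounds=((1e-7, 1e-5), (1e-13, 1e-11)),
                       population_size=30, generations=25, seed=5)

        def obj(x):
            return float((np.log10(x[0]) + 6) ** 2 + (np.log10(x[1]) + 12) ** 2)

        r1, r2 = minimize_ga(obj, cfg), minimize_ga(obj, cfg)
        np.testing.assert_array_equal(r1.x, r2.x)
        assert r1.fun == r2.fun

    def test_different_seeds_explore_differently(self):
        cfg1 = GAConfig(bounds=((1e-7, 1e-5),), population_size=20,
                        generations=5, seed=1)
        cfg2 = GAConfig(bounds=((1e-7, 1e-5),), population_size=20,
                        generations=5, seed=2)
        obj = lambda x: float(np.sin(1e6 * x[0]) ** 2 + x[0] * 1e3)
        assert minimize_ga(obj, cfg1).x[0] != minimize_ga(obj, cfg2).x[0]


class TestPeripheralFit:
    def test_noiseless_round_trip_recovers_all_four(self, chain):
        spectra = synth.gen_resistor_spectra([50e3, 100e3, 220e3], chain)
        init = lpm.PeripheralParams(
            c_p=2e-12, l_w=1e-6, r_w=50.0, r_ac=100e3, c_ac=1e-12,
            l_r=3e-6, c_r=4e-12,
        )
        res = lpm.fit_peripheral(spectra, SMALL_GA, base=init)
        assert res.converged
        for name, truth in [("l_r", 1e-6), ("c_r", 10e-12),
                            ("c_p", 5e-12), ("c_ac", 2e-12)]:
            assert res.params[name] == pytest.approx(truth, rel=0.10), name
        for curve in res.params["per_curve"]:
            assert curve["r2_amplitude"] > 0.999

    def test_same_seed_twice_identical(self, chain):
        spectra = synth.gen_resistor_spectra([50e3, 100e3], chain)
        init = lpm.PeripheralParams(
            c_p=2e-12, l_w=1e-6, r_w=50.0, r_ac=100e3, c_ac=1e-12,
            l_r=3e-6, c_r=4e-12,
        )
        cfg = GAConfig(population_size=20, generations=10, seed=9)
        r1 = lpm.fit_peripheral(spectra, cfg, base=init)
        r2 = lpm.fit_peripheral(spectra, cfg, base=init)
        assert r1.params == r2.params

    def test_single_resistor_underdetermined(self, chain):
        spectra = synth.gen_resistor_spectra([100e3], chain)
        with pytest.raises(ValueError, match="two distinct"):
            lpm.fit_peripheral(spectra, SMALL_GA)

    def test_noisy_recovery_of_identifiable_parameters(self, chain):
        """c_p and c_ac have order-unity signatures in V_out and stay
        recoverable under measurement noise (the readout residuals l_r/c_r
        are only jointly identified; see methods note)."""
        errs = {"c_p": [], "c_ac": []}
        init = lpm.PeripheralParams(
            c_p=2e-12, l_w=1e-6, r_w=50.0, r_ac=100e3, c_ac=1e-12,
            l_r=3e-6, c_r=4e-12,
        )
        for s in range(11):
            noise = synth.NoiseModel(0.01, 0.5, seed=7000 + s)
            spectra = synth.gen_resistor_spectra(
                [50e3, 100e3, 220e3], chain, noise=noise
            )
            res = lpm.fit_peripheral(spectra, SMALL_GA, base=init)
            errs["c_p"].append(abs(res.params["c_p"] / 5e-12 - 1))
            errs["c_ac"].append(abs(res.params["c_ac"] / 2e-12 - 1))
        assert np.median(errs["c_p"]) < 0.25
        assert np.median(errs["c_ac"]) < 0.25


class TestDeviceFit:
    def test_medium_variant_recovers_double_layer_density(self, chain, grid100):
        truth = lpm.DeviceMediumDUT(
            c_dl_per_area=0.131, window_area=1.41e-10, c_m=0.98e-12, r_m=997e3
        )
        spec = lpm.transfer(chain, truth, grid100)
        res = lpm.fit_device(
            spec, chain, "medium",
            fixed={"window_area": 1.41e-10, "c_dl_per_area": 0.3,
                   "c_m": 0.5e-12, "r_m": 500e3},
            ga=SMALL_GA,
        )
        assert res.params["c_dl_per_area"] == pytest.approx(0.131, rel=0.10)
        assert res.params["r_m"] == pytest.approx(997e3, rel=0.10)
        assert res.params["c_m"] == pytest.approx(0.98e-12, rel=0.10)

    @pytest.mark.parametrize(
        "row",
        [
            {"c_m": 0.98e-12, "r_m": 997e3, "r_c": 1.75e6, "c_mem": 0.13e-12},
            {"c_m": 0.78e-12, "r_m": 991e3, "r_c": 1.09e6, "c_mem": 0.20e-12},
        ],
        ids=["cell_4um", "cell_6um"],
    )
    def test_cell_variant_recovers_fitted_components(self, chain, grid100, row):
        truth = lpm.DeviceCellDUT(
            c_dl_per_area=0.131, window_area=1.41e-10, **row
        )
        spec = lpm.transfer(chain, truth, grid100)
        init = {k: v * 2.5 for k, v in row.items()}
        res = lpm.fit_device(
            spec, chain, "cell",
            fixed={"c_dl_per_area": 0.131, "window_area": 1.41e-10, **init},
            ga=SMALL_GA,
        )
        for name, v in row.items():
            assert res.params[name] == pytest.approx(v, rel=0.10), name

    def test_missing_fixed_inputs_rejected(self, chain, grid100):
        spec = lpm.transfer(chain, lpm.ResistorDUT(1e5), grid100)
        with pytest.raises(ValueError, match="requires fixed"):
            lpm.fit_device(spec, chain, "cell",
                           fixed={"window_area": 1.41e-10}, ga=SMALL_GA)


def growth_fixed(ref_medium):
    return {
        "g_f": C.GF_REFERENCE, "c_dl": C.CDL_REFERENCE, "medium": ref_medium,
        "membrane": ecm.MembraneSpec(), "sigma_tilde": lambda D: 0.5,
        "eps_r_c": 60.0,
    }


class TestGrowthPrediction:
    K_TABLE1 = 2.187e-5  # fraction per um^1.6, from the calibration fit

    def test_diameter_sweep_count(self, ref_medium):
        series = lpm.interpolate_growth(
            self.K_TABLE1, 1.6, (4.0, 6.0), 0.05, growth_fixed(ref_medium)
        )
        assert len(series) == 41
        assert series[0][0] == pytest.approx(4.0)
        assert series[-1][0] == pytest.approx(6.0)

    def test_cytoplasm_resistance_falls_membrane_capacitance_rises(
        self, ref_medium
    ):
        series = lpm.interpolate_growth(
            self.K_TABLE1, 1.6, (4.0, 6.0), 0.05, growth_fixed(ref_medium)
        )
        rc = np.array([c.r_c for _, c in series])
        cm = np.array([c.c_mem for _, c in series])
        assert np.all(np.diff(rc) < 0)
        assert np.all(np.diff(cm) > 0)

    def test_zero_prefactor_rejected(self, ref_medium):
        with pytest.raises(ValueError, match="k"):
            lpm.interpolate_growth(0.0, 1.6, (4.0, 6.0), 0.05,
                                   growth_fixed(ref_medium))

    def test_relative_amplitude_at_1mhz_decreases_with_size(
        self, ref_medium, chain, grid100
    ):
        fixed = growth_fixed(ref_medium)
        series = lpm.interpolate_growth(
            self.K_TABLE1, 1.6, (4.0, 6.0), 0.5, fixed
        )
        ref = ecm.compute_components(
            ref_medium, None, None,
            ecm.SensingUnitGeometry(g_f=C.GF_REFERENCE), 0.0, C.CDL_REFERENCE,
        )
        rels = lpm.predict_growth_response(chain, series, grid100,
                                           reference=ref)
        i_1mhz = int(np.argmin(np.abs(grid100 - 1e6)))
        a_r = [rel.a_r[i_1mhz] for _, rel in rels]
        assert np.all(np.diff(a_r) < 0)
        assert all(v < 1 for v in a_r)

    def test_medium_only_components_give_identity_response(
        self, ref_medium, chain, grid100
    ):
        ref = ecm.compute_components(
            ref_medium, None, None,
            ecm.SensingUnitGeometry(g_f=C.GF_REFERENCE), 0.0, C.CDL_REFERENCE,
        )
        rels = lpm.predict_growth_response(
            chain, [(5.0, ref)], grid100, reference=ref
        )
        _, rel = rels[0]
        assert np.allclose(rel.a_r, 1.0, rtol=1e-12)
        assert np.allclose(rel.theta_r, 0.0, atol=1e-9)

    def test_stimulus_amplitude_cancels_in_relative_response(
        self, ref_medium, chain, grid100
    ):
        from dataclasses import replace

        fixed = growth_fixed(ref_medium)
        series = lpm.interpolate_growth(self.K_TABLE1, 1.6, (4.0, 6.0), 1.0,
                                        fixed)
        ref = ecm.compute_components(
            ref_medium, None, None,
            ecm.SensingUnitGeometry(g_f=C.GF_REFERENCE), 0.0, C.CDL_REFERENCE,
        )
        r1 = lpm.predict_growth_response(chain, series, grid100, reference=ref)
        r2 = lpm.predict_growth_response(
            replace(chain, v_in=2.0), series, grid100, reference=ref
        )
        for (_, a), (_, b) in zip(r1, r2):
            assert np.allclose(a.a_r, b.a_r, rtol=1e-12)
            assert np.allclose(a.theta_r, b.theta_r, atol=1e-9)
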