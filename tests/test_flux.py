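"""Indicator calibration, buffer equilibrium, flux slope, Nernst/chord
conductance arithmetic, and the conductance-vs-[Ca2+] curve."""

import numpy as np
import pytest
from scipy.optimize import bisect

from mcugate import flux as fx
from mcugate import synthetic as syn
from mcugate.synthetic import Buffer, FARADAY


class TestFuraCalibration:
    def test_rmin_maps_to_zero(self):
        cal = syn.FuraCalibration()
        assert fx.calibrate_fura(cal.r_min, cal) == 0.0

    def test_midpoint_with_unit_beta_gives_kd(self):
        cal = syn.FuraCalibration(kd_nM=224.0, beta=1.0)
        mid = 0.5 * (cal.r_min + cal.r_max)
        assert fx.calibrate_fura(mid, cal) == pytest.approx(224.0)

    def test_round_trip_with_forward_map(self):
        cal = syn.FuraCalibration()
        for ca in (10.0, 224.0, 1000.0, 5000.0):
            assert fx.calibrate_fura(cal.ratio(ca), cal) == pytest.approx(ca, rel=1e-12)

    def test_saturation_and_clamp(self):
        cal = syn.FuraCalibration()
        with pytest.raises(ValueError, match="saturated"):
            fx.calibrate_fura(cal.r_max, cal)
        with pytest.warns(UserWarning, match="clamped"):
            assert fx.calibrate_fura(cal.r_min - 0.1, cal) == 0.0


class TestSingleWavelength:
    def test_limits_and_midpoint(self):
        cal = syn.Indicator("dye", kd_uM=1.0, f_min=100.0, f_max=900.0)
        assert fx.calibrate_single_wavelength(100.0, cal) == 0.0
        assert fx.calibrate_single_wavelength(500.0, cal) == pytest.approx(1.0)

    def test_inverse_round_trip(self):
        cal = syn.FLUO4
        for ca in (0.05, 0.345, 2.0):
            f = cal.fluorescence(ca)
            assert fx.calibrate_single_wavelength(float(f), cal) == pytest.approx(
                ca, rel=1e-12
            )


class TestFreeCaSolver:
    def test_no_buffers_free_equals_total(self):
        free, bound = fx.solve_free_ca(5.0, [])
        assert free == 5.0 and bound == {}

    def test_zero_total(self):
        free, _ = fx.solve_free_ca(0.0, [Buffer("EGTA", 40.0, 0.15)])
        assert free == 0.0

    def test_single_buffer_quadratic_closed_form(self):
        # free + B*free/(kd+free) = total  ->  positive quadratic root
        total, B, kd = 3.0, 3.0, 0.345
        a, b, c = 1.0, B + kd - total, -kd * total
        root = (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a)
        free, bound = fx.solve_free_ca(total, [Buffer("Fluo-4", B, kd)])
        assert free == pytest.approx(root, rel=1e-9)
        assert free + bound["Fluo-4"] == pytest.approx(total, rel=1e-9)

    def test_agrees_with_bisection_oracle_random_sets(self):
        """Solver vs plain bisection on 100 random buffer sets (1e-9)."""
        rng = np.random.default_rng(8)
        for _ in range(100):
            n_buf = int(rng.integers(1, 4))
            bufs = [
                Buffer(f"b{i}", float(rng.uniform(0.5, 100)), float(rng.uniform(0.05, 20)))
                for i in range(n_buf)
            ]
            total = float(rng.uniform(0.01, 50))
            free, bound = fx.solve_free_ca(total, bufs)

            def g(f):
                return f + sum(b.total_uM * f / (b.kd_uM + f) for b in bufs) - total

            oracle = bisect(g, 0.0, total, xtol=1e-15)
            assert free == pytest.approx(oracle, rel=1e-9, abs=1e-12)
            assert free + sum(bound.values()) == pytest.approx(total, rel=1e-9)


class TestEstimateFlux:
    def test_exact_line(self):
        t = np.arange(0, 25, 0.5)
        y = 10.0 - 0.2 * t
        j, _ = fx.estimate_flux(t, y, volume_ul=200.0, protein_mg_ml=0.5)
        # 0.2 µM/s decline in 200 µl over 0.1 mg
        expected = 0.2 * 1e-6 * 200e-6 / 0.1
        assert j == pytest.approx(expected, rel=1e-12)

    def test_flat_trace_zero(self):
        t = np.arange(0, 25, 0.5)
        j, _ = fx.estimate_flux(t, np.full_like(t, 5.0))
        assert j == 0.0

    def test_noisy_slope_within_three_se(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 25, 0.05)
        y = 10.0 - 0.05 * t + rng.normal(0, 0.02, t.size)
        j, se = fx.estimate_flux(t, y)
        expected = 0.05 * 1e-6 * 200e-6 / 0.1
        assert abs(j - expected) < 3 * se

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="4 samples"):
            fx.estimate_flux(np.array([0.0, 10, 30]), np.array([1.0, 0.9, 0.8]))


class TestNernst:
    def test_symmetric_zero(self):
        assert fx.nernst_eca(1.0, 1000.0) == pytest.approx(0.0, abs=1e-12)

    def test_half_gradient_closed_form(self):
        # 1 mM out vs 2 mM in: (RT/2F) ln 0.5 = -8.90 mV at 298.15 K
        assert fx.nernst_eca(1000.0, 2e6) == pytest.approx(-8.90, abs=0.01)

    def test_decade_29_6_mV(self):
        assert abs(fx.nernst_eca(10.0, 1000.0)) == pytest.approx(29.58, abs=0.05)
        assert abs(fx.nernst_eca(1.0, 10000.0)) == pytest.approx(29.58, abs=0.05)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fx.nernst_eca(0.0, 100.0)


class TestChordConductance:
    def test_zero_flux_zero_conductance(self):
        i, g = fx.chord_conductance(0.0, -160.0, 0.0)
        assert i == 0.0 and g == 0.0

    def test_faraday_arithmetic(self):
        i, _ = fx.chord_conductance(1e-9, -160.0, 0.0)
        assert abs(i) == pytest.approx(2 * FARADAY * 1e-9, rel=1e-12)
        assert abs(i) == pytest.approx(1.93e-4, rel=5e-3)

    def test_small_driving_force_rejected(self):
        with pytest.raises(ValueError, match="driving force"):
            fx.chord_conductance(1e-9, -100.0, -99.5)

    def test_unit_round_trip_invariance(self):
        # converting J through nmol instead of mol and back leaves G fixed
        j = 2.5e-10
        _, g1 = fx.chord_conductance(j, -160.0, 10.0)
        j_nmol = j * 1e9
        _, g2 = fx.chord_conductance(j_nmol * 1e-9, -160.0, 10.0)
        assert g1 == g2

    def test_closed_loop_recovery(self):
        model = syn.default_flux_model(10.0, noise_sd=0.0)
        rec, _ = syn.simulate_flux_assay(model, 10.0, seed=0)
        pt = fx.analyze_flux_assay(
            rec, model.indicator, model.buffers, psi_m_mV=model.psi_m_mV
        )
        assert pt.g_nS_mg == pytest.approx(model.true_G_nS_mg, rel=0.05)

    def test_conductance_point_invariant_enforced(self):
        with pytest.raises(ValueError, match="G must equal"):
            fx.ConductancePoint(
                ca_i_free_uM=1.0, ca_m_free_nM=200.0, psi_m_mV=-160.0,
                j_mol_s_mg=1e-10, i_A_mg=-1.93e-5, e_ca_mV=10.0, g_S_mg=1.0,
            )


class TestGvsCaCurve:
    def _point(self, ca, g_nS, geno):
        e = fx.nernst_eca(ca, 200.0)
        i = g_nS * 1e-9 * (-160.0 - e) * 1e-3
        return fx.ConductancePoint(
            ca_i_free_uM=ca, ca_m_free_nM=200.0, psi_m_mV=-160.0,
            j_mol_s_mg=-i / (2 * FARADAY), i_A_mg=i, e_ca_mV=e,
            g_S_mg=i / ((-160.0 - e) * 1e-3), genotype=geno,
        )

    def test_single_point_is_itself(self):
        df = fx.g_vs_ca_curve([self._point(1.0, 5.0, "WT")])
        assert len(df) == 1
        assert df["mean"].iloc[0] == pytest.approx(5.0)

    def test_identical_genotypes_identical_curves(self):
        pts = [self._point(ca, 5.0, g) for ca in (0.5, 2.0, 10.0) for g in ("A", "B")]
        df = fx.g_vs_ca_curve(pts)
        a = df[df.genotype == "A"]["mean"].to_numpy()
        b = df[df.genotype == "B"]["mean"].to_numpy()
        np.testing.assert_allclose(a, b)

    def test_programmed_crossover_detected(self):
        """KO above WT at low [Ca2+]i, below at high; crossover near 8 µM."""
        cas = np.array([0.5, 1.5, 2.5, 4.0, 6.0, 10.0, 15.0, 20.0])

        def g_wt(ca):
            return 2.0 + 8.0 * ca / (ca + 8.0)

        def g_ko(ca):  # crosses g_wt exactly at 8 µM
            return 4.0 + 4.0 * ca / (ca + 8.0)

        pts = [self._point(ca, g_wt(ca), "WT") for ca in cas]
        pts += [self._point(ca, g_ko(ca), "MICU1-KO") for ca in cas]
        df = fx.g_vs_ca_curve(pts, bin_edges_uM=[0, 1, 2, 3, 5, 8, 12, 18, 25])
        piv = df.pivot_table(index="ca_bin", columns="genotype", values="mean",
                             observed=True)
        diff = (piv["MICU1-KO"] - piv["WT"]).to_numpy()
        assert diff[0] > 0 and diff[-1] < 0
        sign_change = np.nonzero(np.diff(np.sign(diff)))[0]
        crossover_bin = df["ca_bin"].cat.categories[sign_change[0] + 1]
        assert crossover_bin.left <= 8.0 <= crossover_bin.right


class TestDepolarizationIndex:
    def _traces(self, d_event, d_fccp):
        t = np.arange(0, 1200.0, 5.0)
        r_ev = np.where(t >= 300, 2.0 + d_event, 2.0)
        r_fc = np.where(t >= 300, 2.0 + d_fccp, 2.0)
        return t, r_ev, r_fc

    def test_half_of_fccp(self):
        t, r_ev, r_fc = self._traces(0.3, 0.6)
        assert fx.depolarization_index(t, r_ev, 300.0, 300.0, r_fc) == pytest.approx(50.0)

    def test_no_event_zero_percent(self):
        t, r_ev, r_fc = self._traces(0.0, 0.6)
        assert fx.depolarization_index(t, r_ev, 300.0, 300.0, r_fc) == pytest.approx(0.0)

    def test_equal_changes_hundred_percent(self):
        t, r_ev, r_fc = self._traces(0.3, 0.3)
        assert fx.depolarization_index(t, r_ev, 300.0, 300.0, r_fc) == pytest.approx(100.0)

    def test_same_trace_sequential_injections(self):
        t = np.arange(0, 1200.0, 5.0)
        r = np.full_like(t, 2.0)
        r[t >= 300] = 2.3  # RuR at 300 s
        r[t >= 700] = 2.9  # FCCP at 700 s, from the partially depolarized level
        assert fx.depolarization_index(t, r, 300.0, 700.0) == pytest.approx(50.0)
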