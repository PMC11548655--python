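"""Tests of trace smoothing, baselining, response summaries, group
comparisons and the Hill dose-response fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flarekit as fk
from flarekit.traces import RegionTrace


def trace(values, t=None, kind="negR", cell=1):
    values = np.asarray(values, dtype=float)
    t = np.asarray(t, dtype=float) if t is not None else np.arange(values.size) * 0.5
    return RegionTrace(cell, t, values, kind)


class TestSmoothTrace:
    def test_window_one_is_identity(self):
        tr = trace([1.0, 2.0, 3.0])
        out = fk.smooth_trace(tr, 1)
        assert np.array_equal(out.value, tr.value)

    def test_constant_unchanged_any_window(self):
        tr = trace(np.full(9, 0.3))
        for w in (1, 3, 5, 9):
            assert np.allclose(fk.smooth_trace(tr, w).value, 0.3)

    def test_hand_computed_shrinking_ends(self):
        """[0, 3, 0] with window 3: ends average 2 samples -> [1.5, 1, 1.5]."""
        out = fk.smooth_trace(trace([0.0, 3.0, 0.0]), 3)
        assert np.allclose(out.value, [1.5, 1.0, 1.5])

    def test_length_preserved_and_linear(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=12), rng.normal(size=12)
        sa = fk.smooth_trace(trace(a), 5).value
        sb = fk.smooth_trace(trace(b), 5).value
        sab = fk.smooth_trace(trace(2 * a + 3 * b), 5).value
        assert sa.size == 12
        assert np.allclose(sab, 2 * sa + 3 * sb)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            fk.smooth_trace(trace([1, 2, 3]), 2)


class TestDeltaOverBaseline:
    def test_constant_trace_all_zero(self):
        t = np.arange(-6, 14) * 0.5
        out = fk.delta_over_baseline(trace(np.full(t.size, -0.30), t))
        assert out.value_kind == "negdR"
        assert np.allclose(out.value, 0.0)

    def test_hand_computed_example(self):
        """Baseline negR mean -0.30; R at 2 min = 0.29 -> -dR = 0.01."""
        t = np.array([-3.0, -2.5, -2.0, -1.5, -1.0, -0.5, 0.0, 2.0])
        R = np.array([0.30, 0.30, 0.32, 0.30, 0.30, 0.28, 0.30, 0.29])
        out = fk.delta_over_baseline(trace(R, t, kind="R"))
        assert out.value[-1] == pytest.approx(0.01, abs=1e-12)

    def test_baseline_window_mean_exactly_zero(self):
        rng = np.random.default_rng(1)
        t = np.arange(-6, 14) * 0.5
        out = fk.delta_over_baseline(trace(rng.normal(-0.3, 0.01, t.size), t))
        sel = (t >= -3) & (t < 0)
        assert abs(out.value[sel].mean()) < 1e-14

    def test_t0_excluded_from_baseline(self):
        t = np.array([-1.0, -0.5, 0.0, 0.5])
        out = fk.delta_over_baseline(trace([-0.3, -0.3, -1.0, -0.3], t),
                                     baseline_minutes=3.0)
        assert out.meta["baseline_negR"] == pytest.approx(-0.3)

    def test_no_pre_drug_samples_rejected(self):
        with pytest.raises(ValueError, match="pre-drug"):
            fk.delta_over_baseline(trace([1.0, 2.0], t=[0.0, 0.5]))


class TestRatioOverT0:
    def test_definition_at_t0(self):
        t = np.arange(-2, 6) * 0.5
        out = fk.ratio_over_t0(trace(np.linspace(-0.30, -0.28, t.size), t))
        assert out.value_kind == "R_over_R0"
        assert out.value[t == 0][0] == pytest.approx(1.0)

    def test_constant_trace_all_ones(self):
        t = np.arange(-2, 6) * 0.5
        out = fk.ratio_over_t0(trace(np.full(t.size, -0.30), t))
        assert np.allclose(out.value, 1.0)

    def test_hand_computed(self):
        """-R(0) = 0.30, -R(t) = 0.309 -> 1.03."""
        t = np.array([0.0, 1.0])
        out = fk.ratio_over_t0(trace([0.30, 0.309], t))
        assert out.value[1] == pytest.approx(1.03, abs=1e-12)

    def test_missing_t0_sample_rejected(self):
        with pytest.raises(ValueError, match="T = 0"):
            fk.ratio_over_t0(trace([-0.3, -0.3], t=[2.0, 2.5]))

    def test_zero_r0_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            fk.ratio_over_t0(trace([0.0, -0.3], t=[0.0, 0.5]))


class TestPeakResponse:
    def test_monotone_trace_peak_at_window_end(self):
        t = np.arange(0, 10) * 0.5
        out = fk.peak_response(trace(np.linspace(0, 0.01, t.size), t, kind="negdR"),
                               (0.0, 4.5))
        assert out["peak"] == pytest.approx(0.01)
        assert out["t_peak"] == pytest.approx(4.5)

    def test_constant_ratio_zero_percent_change(self):
        t = np.arange(0, 6) * 0.5
        out = fk.peak_response(trace(np.ones(t.size), t, kind="R_over_R0"), (0, 2.5))
        assert out["percent_change"] == 0.0

    def test_ratio_peak_is_extremal_deviation_from_one(self):
        """Activation drives R/R0 below 1; the peak is the farthest point."""
        t = np.arange(0, 6) * 0.5
        vals = np.array([1.0, 0.99, 0.95, 0.96, 0.97, 0.98])
        out = fk.peak_response(trace(vals, t, kind="R_over_R0"), (0, 2.5))
        assert out["peak"] == pytest.approx(0.95)
        assert out["percent_change"] == pytest.approx(-5.0)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            fk.peak_response(trace([1.0, 2.0], t=[0.0, 0.5]), (3.0, 4.0))


class TestIntegrateResponse:
    def test_zero_trace(self):
        t = np.arange(0, 24) * 0.5
        assert fk.integrate_response(trace(np.zeros(t.size), t, "negdR")) == 0.0

    def test_constant_value_closed_form(self):
        t = np.arange(0, 24) * 0.5
        c = 0.004
        got = fk.integrate_response(trace(np.full(t.size, c), t, "negdR"), (5, 10))
        assert got == pytest.approx(5 * c, abs=1e-15)

    def test_linear_ramp_closed_form(self):
        """Ramp 0 -> 0.01 across 5-10 min integrates to 0.025."""
        t = np.arange(0, 24) * 0.5
        v = np.interp(t, [5.0, 10.0], [0.0, 0.01])
        got = fk.integrate_response(trace(v, t, "negdR"), (5, 10))
        assert got == pytest.approx(0.025, abs=1e-12)

    def test_coverage_gap_rejected(self):
        t = np.arange(0, 10) * 0.5  # ends at 4.5 min
        with pytest.raises(ValueError, match="cover"):
            fk.integrate_response(trace(np.zeros(t.size), t, "negdR"), (5, 10))


def students_t_oracle(a, b):
    """Textbook pooled-variance two-sample t-test."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    va = np.sum((a - np.mean(a)) ** 2)
    vb = np.sum((b - np.mean(b)) ** 2)
    sp2 = (va + vb) / (na + nb - 2)
    tstat = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(tstat), na + nb - 2)
    return tstat, p


class TestCompareGroups:
    def test_identical_samples(self):
        res = fk.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_stat == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_zero_variance_equal_means_convention(self):
        res = fk.compare_groups([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    def test_matches_textbook_oracle(self):
        a = np.array([0.9, 1.1, 1.0, 1.2])
        b = np.array([2.0, 2.2, 1.9, 2.1])
        res = fk.compare_groups(a, b, test="student")
        t_ref, p_ref = students_t_oracle(a, b)
        assert res.t_stat == pytest.approx(t_ref, rel=1e-12)
        assert res.p_value == pytest.approx(p_ref, rel=1e-12)
        assert res.n_a == 4 and res.n_b == 4

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=12),
           st.lists(st.floats(-10, 10), min_size=3, max_size=12))
    def test_oracle_property(self, a, b):
        a, b = np.asarray(a), np.asarray(b)
        if np.var(a) == 0 and np.var(b) == 0:
            return
        res = fk.compare_groups(a, b, test="student")
        t_ref, p_ref = students_t_oracle(a, b)
        assert res.t_stat == pytest.approx(t_ref, rel=1e-9, abs=1e-9)
        assert res.p_value == pytest.approx(p_ref, rel=1e-9, abs=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            fk.compare_groups([1.0], [1.0, 2.0])


class TestNormalizeDoseResponse:
    def test_already_normalized_unchanged(self):
        doses = np.array([1.0, 2.0, 4.0])
        resp = np.array([0.0, 50.0, 100.0])
        out, _ = fk.normalize_dose_response(doses, resp)
        assert np.allclose(out, resp)

    def test_hand_computed_group_means(self):
        doses = np.array([1.0, 2.0, 4.0])
        resp = np.array([0.001, 0.003, 0.005])
        out, anchors = fk.normalize_dose_response(doses, resp)
        assert np.allclose(out, [0.0, 50.0, 100.0])
        assert anchors == (0.001, 0.005)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        doses = np.repeat([1.0, 3.0, 9.0], 4)
        resp = rng.normal(doses, 0.1)
        out1, _ = fk.normalize_dose_response(doses, resp)
        out2, _ = fk.normalize_dose_response(doses, 7.0 * resp - 3.0)
        assert np.allclose(out1, out2)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fk.normalize_dose_response([1.0, 2.0, 4.0], [5.0, 5.0, 5.0])

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError):
            fk.normalize_dose_response([1.0, 2.0], [0.0, 1.0])


class TestFitHill:
    def test_noise_free_recovery(self):
        """Noise-free data from EC50=3, h=1: recovery within 1e-6, r2 = 1."""
        doses = np.array([0.75, 1.5, 3.0, 6.0, 9.0, 12.0])
        y = 100.0 * doses / (3.0 + doses)
        # normalize to the 0-100 convention before fitting, as the pipeline does
        norm, _ = fk.normalize_dose_response(doses, y)
        fit = fk.fit_hill(doses, y)
        assert fit.ec50 == pytest.approx(3.0, abs=1e-6)
        assert fit.hill_slope == pytest.approx(1.0, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_midpoint_identity(self):
        doses = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        h = 1.7
        y = 100.0 * doses ** h / (2.0 ** h + doses ** h)
        fit = fk.fit_hill(doses, y)
        assert fit.fitted_curve()(fit.ec50) == pytest.approx(50.0, abs=1e-6)

    def test_steep_slope_recovery(self):
        doses = np.array([0.75, 1.5, 3.0, 6.0, 12.0, 24.0])
        y = 100.0 * doses ** 2.5 / (4.0 ** 2.5 + doses ** 2.5)
        fit = fk.fit_hill(doses, y)
        assert fit.ec50 == pytest.approx(4.0, rel=1e-5)
        assert fit.hill_slope == pytest.approx(2.5, rel=1e-5)

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            fk.fit_hill([0.0, 1.0, 2.0], [0.0, 50.0, 100.0])


class TestEndToEndPower:
    def test_treated_vs_vehicle_power_and_false_positives(self):
        """Simulated design: treated n=12 cells (dr = -0.01, tau = 2 min) vs
        vehicle n=10, per-frame trace noise sd 0.002, summary = mean -dR over
        2-10 min, Student t-test.  Detection at p < 0.01 in >= 90% of 100
        replicates; vehicle-vs-vehicle false positives <= 7% at alpha 0.05
        over 200 replicates."""
        kin_treated = fk.KineticsSpec(delta_r_max=-0.01, tau=2.0, ec50=3.0)
        kin_vehicle = fk.KineticsSpec(delta_r_max=-0.01, tau=2.0, ec50=3.0)

        def summaries(kin, n, dose, seed):
            traces = fk.simulate_roi_traces(kin, n, dose, 0.002, seed=seed)
            out = []
            for tr in traces:
                sm = fk.smooth_trace(tr, 3)
                d = fk.delta_over_baseline(sm)
                out.append(fk.summarize_mean_response(d, (2.0, 10.0)))
            return np.array(out)

        hits = 0
        for rep in range(100):
            a = summaries(kin_treated, 12, dose=1e6, seed=10_000 + rep)
            b = summaries(kin_vehicle, 10, dose=0.0, seed=20_000 + rep)
            if fk.compare_groups(a, b).p_value < 0.01:
                hits += 1
        assert hits >= 90

        false_pos = 0
        for rep in range(200):
            a = summaries(kin_vehicle, 12, dose=0.0, seed=30_000 + rep)
            b = summaries(kin_vehicle, 10, dose=0.0, seed=40_000 + rep)
            if fk.compare_groups(a, b).p_value < 0.05:
                false_pos += 1
        assert false_pos <= 0.07 * 200
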