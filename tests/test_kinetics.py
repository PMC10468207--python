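"""Two-component model evaluation, global fitting and half-times."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ihp import kinetics, synth


class TestEvalModel:
    def test_zero_at_time_zero(self):
        assert kinetics.eval_model(0.0, 0.3, 0.5, 0.01, 10.0) == 0.0

    def test_single_exponential_half_life(self):
        assert kinetics.eval_model(1.0, 1.0, math.log(2), 0.0, 0.0) == pytest.approx(0.5)

    def test_two_component_value(self):
        # 1 - 0.5 e^{-0.4} - 0.5 e^{-0.1}, frozen from independent evaluation
        assert kinetics.eval_model(2.0, 0.5, 0.2, 0.005, 10.0) == pytest.approx(
            0.21242126796420058, abs=1e-12
        )

    def test_out_of_range_a1_rejected(self):
        with pytest.raises(ValueError):
            kinetics.eval_model(1.0, 1.2, 0.1, 0.01, 10.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        a1=st.floats(0.0, 1.0),
        r1=st.floats(0.01, 2.0),
        k2=st.floats(1e-4, 0.05),
        c=st.floats(0.1, 100.0),
    )
    def test_nondecreasing_and_bounded(self, a1, r1, k2, c):
        t = np.linspace(0.0, 200.0, 100)
        f = kinetics.eval_model(t, a1, r1, k2, c)
        assert np.all(np.diff(f) >= -1e-12)
        assert np.all((f >= 0.0) & (f <= 1.0))  # sup is 1, reached only in float rounding


class TestNormalize:
    def test_ratio_equal_to_max_gives_one(self):
        table = pd.DataFrame(
            {"conc_nM": 10.0, "time_min": [1, 2, 3], "replicate": 1,
             "phospho": [0.8, 0.8, 0.8], "total": 1.0}
        )
        out = kinetics.normalize_curve(table, fit_max=0.8)
        assert np.allclose(out["normalized"], 1.0)

    def test_double_max_gives_half(self):
        table = pd.DataFrame(
            {"conc_nM": 10.0, "time_min": [1, 2], "replicate": 1,
             "phospho": [0.4, 0.4], "total": 1.0}
        )
        out = kinetics.normalize_curve(table, fit_max=0.8)
        assert np.allclose(out["normalized"], 0.5)

    def test_zero_total_excluded_and_counted(self):
        table = pd.DataFrame(
            {"conc_nM": 10.0, "time_min": [1, 2, 3], "replicate": 1,
             "phospho": [0.1, 0.2, 0.3], "total": [1.0, 0.0, 1.0]}
        )
        out = kinetics.normalize_curve(table, fit_max=1.0)
        assert len(out) == 2
        assert out.attrs["n_excluded"] == 1

    def test_end_to_end_plateau_near_one(self):
        truth = synth.KineticTruth(noise_sd=0.02, seed=5)
        raw = synth.gen_timecourse(truth).drop(columns="normalized")
        sub = raw[raw["conc_nM"] == 10.0]
        fit_max = kinetics.estimate_fit_max(sub)
        out = kinetics.normalize_curve(sub, fit_max)
        plateau = out[out["time_min"] >= 30.0]["normalized"].mean()
        assert plateau == pytest.approx(1.0, abs=0.05)


class TestGlobalFit:
    def test_noiseless_recovery(self):
        truth = synth.KineticTruth(
            a1=0.6, r1=0.3, k2=0.004, concentrations=(0.5, 2.0, 10.0), noise_sd=0.0, seed=0
        )
        fit = kinetics.fit_global(synth.gen_timecourse(truth))
        assert fit.a1 == pytest.approx(0.6, rel=1e-4)
        assert fit.r1 == pytest.approx(0.3, rel=1e-4)
        assert fit.k2 == pytest.approx(0.004, rel=1e-4)

    def test_noisy_recovery_within_20pct(self):
        truth = synth.KineticTruth(noise_sd=0.05, seed=0)
        fit = kinetics.fit_global(synth.gen_timecourse(truth))
        assert fit.a1 == pytest.approx(0.6, rel=0.2)
        assert fit.r1 == pytest.approx(0.3, rel=0.2)
        assert fit.k2 == pytest.approx(0.004, rel=0.2)

    def test_saturating_concentration_reduces_to_single_exponential(self):
        # data generated with A1=0 at every curve; fit flags one as saturating
        t = np.array([1.0, 2.0, 5.0, 10.0, 20.0, 40.0, 80.0])
        rows = []
        for c in (10.0, 100.0):
            y = 1.0 - np.exp(-c * 0.004 * t)
            for rep in (1, 2):
                for ti, yi in zip(t, y):
                    rows.append((c, ti, rep, yi, 1.0, yi))
        table = pd.DataFrame(
            rows, columns=["conc_nM", "time_min", "replicate", "phospho", "total",
                           "normalized"]
        )
        fit = kinetics.fit_global(table, saturating={10.0, 100.0})
        assert fit.k2 == pytest.approx(0.004, abs=1e-6)
        assert fit.half_times[100.0] == pytest.approx(math.log(2) / 0.4, rel=1e-6)

    def test_row_order_invariance(self, noiseless_timecourse):
        shuffled = noiseless_timecourse.sample(frac=1.0, random_state=1)
        a = kinetics.fit_global(noiseless_timecourse)
        b = kinetics.fit_global(shuffled)
        assert (a.a1, a.r1, a.k2) == pytest.approx((b.a1, b.r1, b.k2), rel=1e-9)

    def test_too_few_concentrations_rejected(self, noiseless_timecourse):
        single = noiseless_timecourse[noiseless_timecourse["conc_nM"] == 10.0]
        with pytest.raises(kinetics.FitError):
            kinetics.fit_global(single)


class TestLangmuir:
    def test_exact_data_recovered(self):
        t = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        table = pd.DataFrame(
            {"conc_nM": 10.0, "time_min": t, "replicate": 1,
             "phospho": 2.0 * t / (4.0 + t), "total": 1.0}
        )
        fit = kinetics.fit_langmuir(table)
        assert fit.ymax == pytest.approx(2.0, abs=1e-8)
        assert fit.t_half == pytest.approx(4.0, abs=1e-8)
        assert not fit.degenerate

    def test_step_like_data_flagged_degenerate(self):
        t = np.array([0.01, 1.0, 2.0, 5.0, 10.0, 30.0])
        table = pd.DataFrame(
            {"conc_nM": 10.0, "time_min": t, "replicate": 1,
             "phospho": np.ones_like(t), "total": 1.0}
        )
        fit = kinetics.fit_langmuir(table)
        assert fit.degenerate

    def test_noisy_recovery(self, rng):
        t = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 60.0])
        y = 1.0 * t / (4.0 + t) + rng.normal(0, 0.03, len(t))
        table = pd.DataFrame(
            {"conc_nM": 10.0, "time_min": t, "replicate": 1, "phospho": y, "total": 1.0}
        )
        fit = kinetics.fit_langmuir(table)
        assert fit.t_half == pytest.approx(4.0, rel=0.15)


class TestHalfTime:
    @pytest.mark.parametrize(
        "r1,expected", [(0.693147, 1.0000002), (1.386294, 0.5000002)]
    )
    def test_closed_form_single_component(self, r1, expected):
        assert kinetics.half_time((1.0, r1, 0.0), c=0.0) == pytest.approx(expected, rel=1e-5)

    def test_agrees_with_grid_scan(self):
        params = (0.5, 0.2, 0.005)
        c = 10.0
        ht = kinetics.half_time(params, c=c)
        t_grid = np.arange(0.0, 60.0, 1e-4)
        f = kinetics.eval_model(t_grid, *params, c)
        oracle = t_grid[np.argmax(f >= 0.5)]
        assert ht == pytest.approx(oracle, abs=1e-3)

    def test_decreasing_in_r1(self):
        hts = [kinetics.half_time((1.0, r1, 0.0), c=0.0) for r1 in (0.1, 0.5, 1.0, 2.0)]
        assert all(a > b for a, b in zip(hts, hts[1:]))

    def test_nonincreasing_in_concentration(self):
        hts = [kinetics.half_time((0.4, 0.2, 0.004), c=c) for c in (0.5, 2.0, 10.0, 100.0)]
        assert all(a >= b - 1e-9 for a, b in zip(hts, hts[1:]))

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError):
            kinetics.half_time((0.0, 0.3, 0.0), c=10.0)
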