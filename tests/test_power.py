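"""Monte-Carlo power engine: Pearson testing, power, inflation, grids."""

import math

import numpy as np
import pytest

from prescreenpower import (
    LatentSpec,
    SamplingPlan,
    analytic_power,
    estimate_power,
    pearson_test,
    prescreen_factor_sweep,
    run_grid,
)

REPS = 4000
MC3SE = 3 * math.sqrt(0.5 * 0.5 / REPS)  # worst-case 3 binomial SEs


class TestPearsonTest:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = pearson_test(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_matches_scipy(self, rng):
        from scipy import stats

        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        r, p = pearson_test(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_constructed_effect_p_value(self, rng):
        # sample with exactly r = 0.4 at n = 30; p frozen against a
        # 10^5-draw permutation oracle (0.0291), t-based value 0.0285
        x = rng.standard_normal(30)
        y0 = rng.standard_normal(30)
        xc = (x - x.mean()) / x.std()
        resid = y0 - (y0 @ xc / (xc @ xc)) * xc
        resid -= resid.mean()
        resid /= np.sqrt(resid @ resid / 30)
        y = 0.4 * xc + math.sqrt(1 - 0.16) * resid
        r, p = pearson_test(x, y)
        assert r == pytest.approx(0.4, abs=1e-10)
        assert p == pytest.approx(0.0285, abs=0.005)

    def test_null_calibration(self, rng):
        x = rng.standard_normal((5000, 20))
        y = rng.standard_normal((5000, 20))
        from prescreenpower.power import _pearson_batch

        _, p = _pearson_batch(x, y)
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.01)
        # p-values uniform on (0, 1) under the null
        assert p.mean() == pytest.approx(0.5, abs=0.02)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_test(np.ones(10), np.arange(10.0))

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_test(np.arange(3.0), np.arange(3.0))


class TestEstimatePower:
    def test_random_sampling_needs_about_100(self, pop03):
        res = estimate_power(pop03, SamplingPlan(scheme="random", n=100),
                             n_reps=REPS, seed=1)
        assert res.power >= 0.85 - MC3SE

    def test_prescreening_reaches_same_power_at_30(self, pop03):
        res = estimate_power(
            pop03, SamplingPlan(scheme="extreme", n=30, prescreen_factor=6),
            n_reps=REPS, seed=2,
        )
        assert res.power >= 0.85 - MC3SE

    def test_null_false_positive_rate_preserved(self, pop00):
        res = estimate_power(
            pop00, SamplingPlan(scheme="extreme", n=30, prescreen_factor=6),
            n_reps=REPS, seed=3,
        )
        assert res.power == pytest.approx(0.05, abs=0.015)
        # signed mean significant effect stays zero at the null
        assert res.mean_sig_r == pytest.approx(0.0, abs=0.15)

    def test_counts_consistent(self, pop03):
        res = estimate_power(pop03, SamplingPlan(scheme="random", n=30),
                             n_reps=REPS, seed=4)
        assert res.n_sig == round(res.power * res.n_reps)
        assert 0 <= res.power <= 1

    def test_deterministic_given_seed(self, pop03):
        plan = SamplingPlan(scheme="extreme", n=30, prescreen_factor=6)
        a = estimate_power(pop03, plan, n_reps=500, seed=5)
        b = estimate_power(pop03, plan, n_reps=500, seed=5)
        assert a == b

    def test_accepts_float_and_latent_spec(self):
        plan = SamplingPlan(scheme="random", n=50)
        res = estimate_power(0.3, plan, n_reps=500, seed=6, pop_size=100_000)
        assert res.r_o == 0.3
        spec = LatentSpec(r_h=0.43, rel_brain=0.7, rel_behav=0.7)
        res2 = estimate_power(spec, plan, n_reps=500, seed=6, pop_size=100_000)
        assert res2.r_o == pytest.approx(0.301, abs=1e-9)

    def test_effect_size_inflation_ordering(self, pop03):
        # significance filtering inflates; extreme sampling inflates more
        rand = estimate_power(pop03, SamplingPlan(scheme="random", n=20),
                              n_reps=REPS, seed=7)
        extr = estimate_power(
            pop03, SamplingPlan(scheme="extreme", n=20, prescreen_factor=6),
            n_reps=REPS, seed=7,
        )
        assert extr.mean_sig_r >= rand.mean_sig_r >= 0.3

    def test_matches_analytic_power_random_sampling(self, pop03):
        for n in (30, 60, 100):
            res = estimate_power(pop03, SamplingPlan(scheme="random", n=n),
                                 n_reps=REPS, seed=8)
            assert res.power == pytest.approx(
                analytic_power(pop03.r_empirical, n), abs=0.03
            )

    def test_latent_direct_equivalence(self):
        # power depends only on r_o, not its (r_h, reliability) decomposition
        plan = SamplingPlan(scheme="extreme", n=30, prescreen_factor=6)
        direct = estimate_power(0.3, plan, n_reps=REPS, seed=9, pop_size=500_000)
        spec = LatentSpec(r_h=0.43, rel_brain=0.7, rel_behav=0.7)
        latent = estimate_power(spec, plan, n_reps=REPS, seed=9, pop_size=500_000)
        assert latent.power == pytest.approx(direct.power, abs=0.025)

    def test_dropout_cost_is_small_and_boost_preserved(self, pop03):
        # oracle (200k paired reps, two populations): scanning a random 15
        # of the 18 invited per tail costs ~0.028 power at this design,
        # while the boost over random sampling at the same n (~0.39) remains
        base = SamplingPlan(scheme="extreme", n=30, prescreen_factor=6)
        drop = SamplingPlan(scheme="extreme", n=30, prescreen_factor=6,
                            invited_per_tail=18)
        a = estimate_power(pop03, base, n_reps=10_000, seed=10)
        b = estimate_power(pop03, drop, n_reps=10_000, seed=10)
        rand = estimate_power(pop03, SamplingPlan(scheme="random", n=30),
                              n_reps=10_000, seed=10)
        assert a.power - b.power == pytest.approx(0.028, abs=0.015)
        assert b.power - rand.power > 0.3

    def test_too_few_reps_rejected(self, pop03):
        with pytest.raises(ValueError):
            estimate_power(pop03, SamplingPlan(scheme="random", n=30), n_reps=50)


class TestGrids:
    def test_single_cell_grid_matches_direct_estimate(self):
        df = run_grid(r_o_values=[0.3], n_values=[40], n_reps=1000,
                      seed=11, pop_size=100_000)
        assert len(df) == 1
        row = df.iloc[0]
        assert row["scheme"] == "random"
        assert 0 <= row["power"] <= 1
        # rerun reproduces exactly (per-cell substreams)
        df2 = run_grid(r_o_values=[0.3], n_values=[40], n_reps=1000,
                       seed=11, pop_size=100_000)
        assert row["power"] == df2.iloc[0]["power"]

    def test_power_monotone_in_n_and_r(self):
        df = run_grid(
            r_o_values=[0.2, 0.4], n_values=[30, 60, 100],
            n_reps=2000, seed=12, pop_size=200_000,
        )
        for r_o, sub in df.groupby("r_o"):
            p = sub.sort_values("n")["power"].to_numpy()
            assert np.all(np.diff(p) >= -0.02)
        for n, sub in df.groupby("n"):
            p = sub.sort_values("r_o")["power"].to_numpy()
            assert np.all(np.diff(p) >= -0.02)

    def test_factor_sweep_tradeoff(self):
        # the worked design: factor 6 at n=30 and factor 4 at n=40 both work
        df = prescreen_factor_sweep(
            0.3, n_values=[30, 40], factors=[1, 4, 6],
            n_reps=REPS, seed=13, pop_size=300_000,
        )
        get = lambda n, f: df[(df.n == n) & (df.factor == f)]["power"].iloc[0]
        assert get(30, 6) >= 0.85 - MC3SE
        assert get(40, 4) >= 0.85 - MC3SE
        # power nondecreasing in the prescreening factor
        for n in (30, 40):
            p = [get(n, f) for f in (1, 4, 6)]
            assert np.all(np.diff(p) >= -0.02)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            run_grid(r_o_values=[], n_values=[30], n_reps=1000)
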