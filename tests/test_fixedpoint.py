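"""Fixed-point machinery: KDE, crossing extraction, Bayes test."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from risky_defaults.fixedpoint import (
    DensityEstimate,
    crossing_point,
    crossing_set,
    estimate_density,
    fixed_point_bayes_test,
    make_grid,
    pooled_bandwidth,
)


def _mixture_density(grid, p, loc1=300.0, loc2=700.0, scale=50.0):
    return p * stats.norm.pdf(grid, loc1, scale) + (1 - p) * stats.norm.pdf(
        grid, loc2, scale
    )


class TestPooledBandwidth:
    def test_two_point_sample(self):
        assert pooled_bandwidth([100.0, 300.0]) == pytest.approx(
            np.std([100.0, 300.0], ddof=1)
        )

    def test_matches_two_pass_variance_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(6.5, 0.5, 500)
        mean = sum(x) / len(x)
        var = sum((v - mean) ** 2 for v in x) / (len(x) - 1)
        assert pooled_bandwidth(x) == pytest.approx(math.sqrt(var))

    def test_scale_equivariance(self):
        x = np.array([200.0, 350.0, 900.0, 410.0])
        assert pooled_bandwidth(3.7 * x) == pytest.approx(3.7 * pooled_bandwidth(x))

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pooled_bandwidth([500.0, 500.0, 500.0])


class TestEstimateDensity:
    def test_normalizes_and_matches_kernel_sum_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(6.5, 0.4, 200)
        bw = pooled_bandwidth(x)
        grid = make_grid(x, bw)
        d = estimate_density(x, bw, grid)
        assert np.all(d.density >= 0)
        assert np.trapezoid(d.density, grid) == pytest.approx(1.0, abs=0.01)
        # naive kernel-sum oracle at a few grid points
        for i in (0, 100, 300, 511):
            ref = sum(
                math.exp(-0.5 * ((grid[i] - xi) / bw) ** 2)
                for xi in x
            ) / (len(x) * bw * math.sqrt(2 * math.pi))
            assert d.density[i] == pytest.approx(ref, rel=1e-9)

    def test_near_identical_values_stay_finite(self):
        x = np.array([500.0, 500.1, 500.05, 499.9, 500.2])
        d = estimate_density(x, 50.0, np.linspace(0, 1000, 128))
        assert np.all(np.isfinite(d.density))

    def test_too_few_rts_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            estimate_density([1.0, 2.0], 1.0, np.linspace(0, 3, 10))

    def test_kde_converges_to_true_density(self):
        rng = np.random.default_rng(4)
        grid = np.linspace(100, 3000, 512)
        errs = []
        for n in (200, 1000, 5000):
            x = rng.lognormal(6.5, 0.4, n)
            bw = 1.06 * x.std(ddof=1) * n ** (-1 / 5)  # consistency-rate bandwidth
            d = estimate_density(x, bw, grid)
            truth = stats.lognorm.pdf(grid, 0.4, scale=np.exp(6.5))
            errs.append(np.max(np.abs(d.density - truth)))
        assert errs[2] < errs[0]


class TestCrossingPoint:
    def test_equal_variance_gaussian_mixtures_cross_at_midpoint(self):
        grid = np.linspace(0, 1000, 2048)
        d1 = DensityEstimate(grid, _mixture_density(grid, 0.25), 50.0, 1000)
        d2 = DensityEstimate(grid, _mixture_density(grid, 0.75), 50.0, 1000)
        x = crossing_point(d1, d2)
        assert x == pytest.approx(500.0, abs=0.5)

    def test_three_mixture_proportions_share_one_crossing(self):
        grid = np.linspace(0, 1000, 2048)
        dens = [
            DensityEstimate(grid, _mixture_density(grid, p), 50.0, 1000)
            for p in (0.2, 0.5, 0.8)
        ]
        xs = [
            crossing_point(dens[i], dens[j])
            for i, j in ((0, 1), (0, 2), (1, 2))
        ]
        assert np.ptp(xs) < 1.0
        assert xs[0] == pytest.approx(500.0, abs=0.5)

    def test_kde_recovers_the_fixed_point_from_samples(self):
        rng = np.random.default_rng(5)

        def sample(p, n=1000):
            comp = rng.random(n) < p
            return np.where(comp, rng.normal(300, 50, n), rng.normal(700, 50, n))

        xs = {p: sample(p) for p in (0.2, 0.5, 0.8)}
        pooled = np.concatenate(list(xs.values()))
        bw = 30.0
        grid = make_grid(pooled, bw, 1024)
        dens = {p: estimate_density(x, bw, grid) for p, x in xs.items()}
        crossings = [
            crossing_point(dens[a], dens[b],
                           lo=float(np.median(xs[a])), hi=float(np.median(xs[b])))
            for a, b in ((0.2, 0.5), (0.2, 0.8), (0.5, 0.8))
        ]
        assert all(c is not None for c in crossings)
        assert np.allclose(crossings, 500.0, atol=40.0)

    def test_pure_shift_family_gives_distinct_midpoint_crossings(self):
        grid = np.linspace(-200, 1400, 4096)
        locs = (400.0, 600.0, 900.0)
        dens = [
            DensityEstimate(grid, stats.norm.pdf(grid, m, 80.0), 80.0, 1000)
            for m in locs
        ]
        xs = [
            crossing_point(dens[i], dens[j])
            for i, j in ((0, 1), (0, 2), (1, 2))
        ]
        mids = [(locs[i] + locs[j]) / 2 for i, j in ((0, 1), (0, 2), (1, 2))]
        assert xs == pytest.approx(mids, abs=1.0)
        assert len({round(x) for x in xs}) == 3

    def test_non_crossing_densities_return_missing(self):
        grid = np.linspace(0, 100, 256)
        d1 = DensityEstimate(grid, np.full(256, 0.02), 1.0, 10)
        d2 = DensityEstimate(grid, np.full(256, 0.01), 1.0, 10)
        assert crossing_point(d1, d2) is None


class TestFixedPointBayesTest:
    def _frame(self, values):
        rows = []
        for subj, triple in enumerate(values):
            for pair, v in zip(("a|b", "a|c", "b|c"), triple):
                rows.append((subj, pair, v, ""))
        return pd.DataFrame(rows, columns=["subject", "pair", "crossing", "reason"])

    def test_identical_crossings_strongly_favor_the_null(self):
        rng = np.random.default_rng(6)
        base = rng.normal(500, 30, 12)
        cs = self._frame([[b + rng.normal(0, 5) for _ in range(3)] for b in base])
        res = fixed_point_bayes_test(cs)
        assert res.bf01 > 1
        assert res.n_participants == 12

    def test_large_pair_effect_rejects_the_null(self):
        rng = np.random.default_rng(7)
        cs = self._frame(
            [[400 + rng.normal(0, 10), 500 + rng.normal(0, 10), 600 + rng.normal(0, 10)]
             for _ in range(12)]
        )
        res = fixed_point_bayes_test(cs)
        assert res.bf01 < 1

    def test_bic_identity_against_direct_likelihood_computation(self):
        rng = np.random.default_rng(8)
        cs = self._frame(rng.normal(500, 40, (8, 3)).tolist())
        res = fixed_point_bayes_test(cs)
        # recompute from maximized OLS likelihoods directly
        y = cs["crossing"].to_numpy()
        S = pd.get_dummies(cs["subject"]).to_numpy(float)
        P = pd.get_dummies(cs["pair"], drop_first=True).to_numpy(float)

        def ols_ll(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = np.sum((y - X @ beta) ** 2)
            n = len(y)
            return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1), np.linalg.matrix_rank(X) + 1

        ll0, k0 = ols_ll(S)
        ll1, k1 = ols_ll(np.column_stack([S, P]))
        n = len(y)
        bf01 = np.exp(((-2 * ll1 + k1 * np.log(n)) - (-2 * ll0 + k0 * np.log(n))) / 2)
        assert res.bf01 == pytest.approx(bf01, rel=1e-9)

    def test_incomplete_participants_are_excluded_with_report(self):
        cs = self._frame(np.random.default_rng(9).normal(500, 40, (4, 3)).tolist())
        cs.loc[(cs.subject == 0) & (cs.pair == "a|b"), "crossing"] = np.nan
        res = fixed_point_bayes_test(cs)
        assert res.excluded == [0]
        assert res.n_participants == 3
        with pytest.raises(ValueError, match="fewer than 2"):
            fixed_point_bayes_test(cs[cs.subject <= 1])


class TestCrossingSet:
    def test_three_crossings_per_included_participant(self, learned_trials):
        cs = crossing_set(learned_trials, "tot_code")
        ok = cs[np.isfinite(cs["crossing"])]
        n_subj = learned_trials["subject"].nunique()
        per = ok.groupby("subject").size()
        assert (per <= 3).all()
        assert (per == 3).sum() >= 0.8 * n_subj

    def test_sparse_participants_are_excluded_with_reason(self, learned_trials):
        # strip one subject's high-TP trials below the inclusion minimum
        t = learned_trials.copy()
        mask = (t.subject == 0) & (t.tp_code == 1) & (t.session == "experimental")
        t = t.drop(t[mask].index[4:])
        cs = crossing_set(t, "tp_code")
        sub0 = cs[cs.subject == 0]
        assert sub0["crossing"].isna().all()
        assert sub0["reason"].str.contains("fewer than").all()
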