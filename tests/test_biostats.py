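import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fibroquant as fb
from fibroquant.biostats import PairedRatings
from fibroquant.errors import (
    ParameterError,
    PreconditionError,
    UndefinedStatisticError,
)


def anova_oneway_oracle(values: np.ndarray):
    """From-first-principles one-way ANOVA ICC(1,1): explicit double loops,
    no shared code with the implementation."""
    n, k = values.shape
    grand = sum(values[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(values[i]) / k for i in range(n)]
    ssb = k * sum((m - grand) ** 2 for m in row_means)
    ssw = sum(
        (values[i][j] - row_means[i]) ** 2
        for i in range(n)
        for j in range(k)
    )
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw), msb / msw


def wilcoxon_exact_oracle(diff: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign vectors."""
    d = diff[diff != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        if min(w_plus, n * (n + 1) / 2 - w_plus) <= w_obs:
            count += 1
    return count / 2**n


class TestIccOneway:
    def test_identical_columns_give_one(self):
        ratings = PairedRatings(
            ["a", "b", "c", "d"], np.array([[1.0, 1], [2, 2], [5, 5], [9, 9]])
        )
        res = fb.icc_oneway(ratings)
        assert res.estimate == 1.0
        assert res.ci_lower == res.ci_upper == 1.0

    def test_constant_rater_offset_lowers_icc_but_cell_shift_does_not(self):
        rng = np.random.default_rng(1)
        base = rng.normal(10, 3, size=(20, 1))
        shifted = np.hstack([base, base + 2.0])
        res = fb.icc_oneway(PairedRatings([f"s{i}" for i in range(20)], shifted))
        assert res.estimate < 1.0
        # adding the same constant to every cell leaves the ICC unchanged
        res2 = fb.icc_oneway(
            PairedRatings([f"s{i}" for i in range(20)], shifted + 7.5)
        )
        assert res2.estimate == pytest.approx(res.estimate, abs=1e-12)
        assert res2.ci_lower == pytest.approx(res.ci_lower, abs=1e-12)

    def test_zero_total_variance_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            fb.icc_oneway(PairedRatings(["a", "b", "c"], np.full((3, 2), 4.0)))

    def test_matches_brute_force_anova_on_random_instances(self):
        """Oracle equivalence at 1e-10 over 200 random small tables."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(3, 13))
            k = int(rng.integers(2, 4))
            values = rng.normal(0, 1, size=(n, k)) + rng.normal(
                0, 1, size=(n, 1)
            )
            res = fb.icc_oneway(
                PairedRatings([f"s{i}" for i in range(n)], values)
            )
            est, f = anova_oneway_oracle(values)
            assert res.estimate == pytest.approx(est, abs=1e-10)
            assert res.f_stat == pytest.approx(f, rel=1e-10)

    def test_matches_pingouin_icc1(self):
        """Independent library cross-check on a simulated ratings table."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        ratings = fb.simulate_paired_ratings(0.7, n=40, k=2, seed=3)
        res = fb.icc_oneway(ratings)
        long = pd.DataFrame(
            {
                "subject": np.repeat(ratings.subject_ids, ratings.k),
                "rater": np.tile(np.arange(ratings.k), ratings.n),
                "score": ratings.values.ravel(),
            }
        )
        icc1 = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type").loc["ICC(1,1)"]
        assert res.estimate == pytest.approx(icc1["ICC"], abs=1e-6)
        assert res.f_stat == pytest.approx(icc1["F"], rel=1e-6)
        lo, hi = icc1["CI95"]  # pingouin rounds its bounds to 2 decimals
        assert round(res.ci_lower, 2) == pytest.approx(lo, abs=0.011)
        assert round(res.ci_upper, 2) == pytest.approx(hi, abs=0.011)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        shift=st.floats(-50, 50), scale=st.floats(0.1, 10),
        seed=st.integers(0, 100),
    )
    def test_invariance_under_affine_rescaling(self, shift, scale, seed):
        ratings = fb.simulate_paired_ratings(0.6, n=15, k=2, seed=seed)
        base = fb.icc_oneway(ratings)
        transformed = PairedRatings(
            ratings.subject_ids, ratings.values * scale + shift
        )
        res = fb.icc_oneway(transformed)
        assert res.estimate == pytest.approx(base.estimate, abs=1e-9)
        assert res.ci_lower == pytest.approx(base.ci_lower, abs=1e-9)
        assert res.ci_upper == pytest.approx(base.ci_upper, abs=1e-9)

    def test_simulation_recovery_of_true_icc(self):
        """Monte-Carlo consistency: mean estimate near the population ICC."""
        estimates = [
            fb.icc_oneway(fb.simulate_paired_ratings(0.5, 50, 2, seed=s)).estimate
            for s in range(400)
        ]
        assert abs(np.mean(estimates) - 0.5) < 0.03


class TestIccCiFromEstimate:
    def test_null_estimate_interval_contains_zero(self):
        lo, hi = fb.icc_ci_from_estimate(0.0, 30, 2)
        assert lo < 0.0 < hi

    def test_perfect_agreement_collapses(self):
        assert fb.icc_ci_from_estimate(1.0, 30, 2) == (1.0, 1.0)

    def test_agrees_exactly_with_icc_oneway_interval(self):
        """Same F pivot, so reconstruction from the estimate is exact."""
        ratings = fb.simulate_paired_ratings(0.75, 60, 2, seed=9)
        res = fb.icc_oneway(ratings)
        lo, hi = fb.icc_ci_from_estimate(res.estimate, res.n, res.k)
        assert lo == pytest.approx(res.ci_lower, abs=1e-12)
        assert hi == pytest.approx(res.ci_upper, abs=1e-12)


class TestPearson:
    def test_perfect_line_gives_r_one(self):
        x = np.arange(10.0)
        res = fb.pearson_ci(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            fb.pearson_ci(np.ones(10), np.arange(10.0))

    def test_from_estimate_symmetric_about_zero(self):
        lo, hi = fb.pearson_ci_from_estimate(0.0, 100)
        assert lo == pytest.approx(-hi)

    def test_fisher_interval_monotone_in_r_and_shrinks_with_n(self):
        los = [fb.pearson_ci_from_estimate(r, 50)[0] for r in (0.1, 0.3, 0.5, 0.7)]
        assert los == sorted(los)
        widths = [
            np.diff(fb.pearson_ci_from_estimate(0.5, n))[0]
            for n in (10, 30, 100, 300)
        ]
        assert widths == sorted(widths, reverse=True)

    def test_from_estimate_agrees_with_percentile_bootstrap(self):
        """Bootstrap oracle: Fisher-z bounds within 0.02 of the percentile
        bootstrap on matched bivariate-normal data."""
        rho, n = 0.62, 151
        rng = np.random.default_rng(12)
        cov = [[1, rho], [rho, 1]]
        # find a sample whose empirical r matches rho closely
        for _ in range(200):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            r = np.corrcoef(xy[:, 0], xy[:, 1])[0, 1]
            if abs(r - rho) < 0.005:
                break
        assert abs(r - rho) < 0.005
        boots = np.empty(10000)
        for b in range(10000):
            idx = rng.integers(0, n, size=n)
            boots[b] = np.corrcoef(xy[idx, 0], xy[idx, 1])[0, 1]
        lo_b, hi_b = np.percentile(boots, [2.5, 97.5])
        lo, hi = fb.pearson_ci_from_estimate(r, n)
        assert lo == pytest.approx(lo_b, abs=0.02)
        assert hi == pytest.approx(hi_b, abs=0.02)

    def test_coverage_of_fisher_interval(self):
        """Empirical 95% CI coverage at rho=0.5, n=60 over 2000 draws."""
        rho, n = 0.5, 60
        rng = np.random.default_rng(5)
        cov = [[1, rho], [rho, 1]]
        hits = 0
        reps = 2000
        for _ in range(reps):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            res = fb.pearson_ci(xy[:, 0], xy[:, 1])
            hits += res.ci_lower <= rho <= res.ci_upper
        assert abs(hits / reps - 0.95) <= 0.015


class TestSimulators:
    def test_simulate_paired_ratings_reproducible_and_unbiased(self):
        a = fb.simulate_paired_ratings(0.9, 200, 2, seed=4)
        b = fb.simulate_paired_ratings(0.9, 200, 2, seed=4)
        assert (a.values == b.values).all()
        est = [
            fb.icc_oneway(fb.simulate_paired_ratings(0.9, 200, 2, seed=s)).estimate
            for s in range(300)
        ]
        assert abs(np.mean(est) - 0.9) < 0.02

    def test_zero_icc_columns_independent(self):
        est = [
            fb.icc_oneway(fb.simulate_paired_ratings(0.0, 50, 2, seed=s)).estimate
            for s in range(300)
        ]
        assert abs(np.mean(est)) < 0.05

    def test_invalid_true_icc_rejected(self):
        with pytest.raises(ParameterError):
            fb.simulate_paired_ratings(1.0, 10, 2, seed=0)

    def test_simulate_grouped_degenerate_group(self):
        values, labels = fb.simulate_grouped(
            [fb.GroupSpec(label=2, n=5, mean=3.0, sd=0.0)], seed=0
        )
        assert (values == 3.0).all() and (labels == 2).all()

    def test_printed_group_specs_total_151(self):
        specs = [
            fb.GroupSpec(0, 40, 8.3, 2.4),
            fb.GroupSpec(1, 82, 10.7, 3.6),
            fb.GroupSpec(2, 18, 17.1, 6.4),
            fb.GroupSpec(3, 11, 20.1, 8.0),
        ]
        values, labels = fb.simulate_grouped(specs, seed=1)
        assert len(values) == sum(g.n for g in specs) == 151


class TestPairedLocationTest:
    def test_identical_sequences_degenerate(self):
        res = fb.paired_location_test([1.0, 2, 3, 4, 5], [1.0, 2, 3, 4, 5])
        assert res.degenerate and res.p_wilcoxon == 1.0 and res.p_paired_t == 1.0

    def test_all_positive_n6_exact_p(self):
        """Exact two-sided signed-rank p for 6 uniformly positive
        differences is 2/64 (only the all-plus and all-minus assignments
        are as extreme)."""
        before = np.zeros(6)
        after = np.array([1.0, 2, 3, 4, 5, 6])
        res = fb.paired_location_test(before, after)
        assert res.p_wilcoxon == pytest.approx(2 / 64)

    def test_matches_enumeration_oracle_small_n(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(6, 11))
            before = rng.normal(0, 1, n)
            after = before + rng.normal(0.4, 1, n)
            res = fb.paired_location_test(before, after)
            assert res.p_wilcoxon == pytest.approx(
                wilcoxon_exact_oracle(after - before), abs=1e-12
            )

    def test_power_at_one_sd_shift(self):
        """A 1-SD paired shift at n=30 is detected >90% of the time."""
        rng = np.random.default_rng(8)
        rejections = 0
        reps = 500
        for _ in range(reps):
            before = rng.normal(0, 1, 30)
            after = before + rng.normal(1.0, 1.0, 30)
            res = fb.paired_location_test(before, after)
            rejections += res.p_wilcoxon < 0.05
        assert rejections / reps > 0.90


class TestOlsSimple:
    def test_exact_line(self):
        x = np.arange(12.0)
        res = fb.ols_simple(x, 3 * x - 2)
        assert res.slope == pytest.approx(3.0)
        assert res.intercept == pytest.approx(-2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_x_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            fb.ols_simple(np.ones(5), np.arange(5.0))

    def test_matches_normal_equations(self):
        """Closed-form oracle to 1e-10 relative on random data."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            x = rng.normal(0, 3, n)
            y = rng.normal(1, 2, n) + 0.5 * x
            res = fb.ols_simple(x, y)
            xbar, ybar = x.mean(), y.mean()
            slope = ((x - xbar) @ (y - ybar)) / ((x - xbar) @ (x - xbar))
            intercept = ybar - slope * xbar
            ss_res = ((y - intercept - slope * x) ** 2).sum()
            ss_tot = ((y - ybar) ** 2).sum()
            assert res.slope == pytest.approx(slope, rel=1e-10)
            assert res.intercept == pytest.approx(intercept, rel=1e-10, abs=1e-10)
            assert res.r_squared == pytest.approx(1 - ss_res / ss_tot, rel=1e-10)

    def test_r_squared_equals_squared_pearson(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = 0.7 * x + rng.normal(size=30)
        res = fb.ols_simple(x, y)
        assert res.r_squared == pytest.approx(
            np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12
        )


class TestGroupSummary:
    def test_small_example(self):
        specs = fb.group_summary([1.0, 1, 3, 3], [0, 0, 1, 1])
        assert [(g.label, g.n, g.mean, g.sd) for g in specs] == [
            (0, 2, 1.0, 0.0), (1, 2, 3.0, 0.0),
        ]
        assert all(g.degenerate for g in specs)

    def test_single_observation_group_flagged(self):
        (spec,) = fb.group_summary([5.0], [1])
        assert spec.degenerate and spec.sd == 0.0

    def test_round_trip_with_simulator(self):
        specs = [
            fb.GroupSpec(0, 200, 8.3, 2.4),
            fb.GroupSpec(1, 200, 17.1, 6.4),
        ]
        values, labels = fb.simulate_grouped(specs, seed=6)
        recovered = fb.group_summary(values, labels)
        for want, got in zip(specs, recovered):
            assert got.n == want.n
            assert abs(got.mean - want.mean) <= 3 * want.sd / np.sqrt(want.n)
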