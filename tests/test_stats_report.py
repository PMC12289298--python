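"""Outcome statistical battery: robust screening, tests, effect sizes, FDR."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from dyadmind.stats_report import (
    MeasurePlan,
    PairedSample,
    anderson_darling_normal,
    bh_fdr,
    cohens_d_paired,
    mean_diff_ci,
    outcome_table,
    paired_t_one_sided,
    rank_sum,
    remove_outliers_mad,
    signed_rank_one_sided,
    spearman_corr,
)


class TestRemoveOutliersMad:
    def test_single_extreme_value_removed(self):
        x = list(range(1, 11)) + [100]
        kept, removed = remove_outliers_mad(x)
        assert removed.tolist() == [10]
        assert kept.tolist() == list(map(float, range(1, 11)))

    def test_constant_vector_unchanged(self):
        kept, removed = remove_outliers_mad([5.0] * 6)
        assert removed.size == 0

    def test_inliers_unchanged(self):
        kept, removed = remove_outliers_mad([1.0, 2.0, 3.0, 4.0])
        assert removed.size == 0

    def test_zero_mad_fallback_keeps_median_matches(self):
        with pytest.warns(UserWarning, match="MAD is zero"):
            kept, removed = remove_outliers_mad([2.0, 2.0, 2.0, 2.0, 7.0])
        assert kept.tolist() == [2.0] * 4
        assert removed.tolist() == [4]


class TestAndersonDarling:
    def test_normal_samples_pass(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(500)
            hits += anderson_darling_normal(x)["normal"]
        assert hits >= 90

    def test_exponential_samples_fail(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(size=500)
            hits += not anderson_darling_normal(x)["normal"]
        assert hits >= 95

    def test_degenerate_routed_to_rank_tests(self):
        out = anderson_darling_normal(np.ones(20))
        assert out["degenerate"] and not out["normal"]
        out = anderson_darling_normal(np.arange(5.0))
        assert out["degenerate"] and not out["normal"]


def _exact_signed_rank_p(diffs, direction):
    """Enumerate all sign patterns of the rank magnitudes (exact null)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(ranks)
    ws = [np.sum([r for r, s in zip(ranks, signs) if s]) for signs in
          itertools.product([0, 1], repeat=n)]
    ws = np.array(ws)
    if direction == "increase":
        return np.mean(ws >= w_obs)
    return np.mean(ws <= w_obs)


class TestSignedRank:
    def test_uniform_decrease_is_detected(self):
        pre = np.arange(20, dtype=float) + 10
        post = pre - 2.0
        assert signed_rank_one_sided(pre, post, "decrease")["p"] < 0.001

    def test_matches_exact_enumeration(self, rng):
        for _ in range(10):
            pre = rng.standard_normal(8)
            post = pre + rng.standard_normal(8)
            for direction in ("decrease", "increase"):
                approx = signed_rank_one_sided(pre, post, direction)["p"]
                exact = _exact_signed_rank_p(post - pre, direction)
                assert approx == pytest.approx(exact, abs=0.03)

    def test_direction_reversal_consistency(self, rng):
        """One-sided p values in the two directions cover the whole null
        distribution, overlapping only in P(T = t_obs)."""
        pre = rng.standard_normal(8)
        post = pre + rng.standard_normal(8)
        d = post - pre
        p_dec = _exact_signed_rank_p(d, "decrease")
        p_inc = _exact_signed_rank_p(d, "increase")
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = np.array([np.sum([r for r, s in zip(ranks, signs) if s])
                       for signs in itertools.product([0, 1], repeat=8)])
        p_eq = np.mean(ws == w_obs)
        assert p_dec + p_inc == pytest.approx(1.0 + p_eq, abs=1e-12)

    def test_all_zero_differences_degenerate(self):
        x = np.arange(6, dtype=float)
        out = signed_rank_one_sided(x, x, "decrease")
        assert out["degenerate"] and out["p"] == 1.0


class TestRankSum:
    def test_identical_groups(self):
        a = np.arange(10, dtype=float)
        out = rank_sum(a, a.copy())
        assert out["z"] == pytest.approx(0.0)
        assert out["p"] > 0.9

    def test_fully_separated_groups(self):
        out = rank_sum(np.arange(10.0), np.arange(10.0) + 100)
        assert out["p"] < 0.001

    def test_matches_exact_enumeration(self, rng):
        from itertools import combinations
        for _ in range(5):
            a, b = rng.standard_normal(5), rng.standard_normal(5)
            pooled = np.concatenate([a, b])
            ranks = sps.rankdata(pooled)
            w_obs = ranks[:5].sum()
            ws = np.array([ranks[list(idx)].sum() for idx in combinations(range(10), 5)])
            exact = np.mean(np.abs(ws - ws.mean()) >= abs(w_obs - ws.mean()) - 1e-9)
            assert rank_sum(a, b)["p"] == pytest.approx(exact, abs=0.03)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum([1.0, 2.0], [1.0, 2.0, 3.0])


class TestPairedT:
    def test_constant_differences_flagged(self):
        pre = np.arange(6, dtype=float)
        out = paired_t_one_sided(pre, pre + 2.0, "increase")
        assert out["degenerate"]

    def test_power_at_medium_effect(self):
        """One-sided t at d=0.5, n=24 has ~76% power."""
        rng = np.random.default_rng(3)
        hits = 0
        n_sims = 1000
        for _ in range(n_sims):
            pre = rng.standard_normal(24)
            post = pre + 0.5 + rng.standard_normal(24)
            hits += paired_t_one_sided(pre, post, "increase")["p"] < 0.05
        assert hits / n_sims == pytest.approx(0.76, abs=0.05)

    def test_type1_error_calibrated(self):
        rng = np.random.default_rng(4)
        hits = 0
        n_sims = 2000
        for _ in range(n_sims):
            pre = rng.standard_normal(12)
            post = pre + rng.standard_normal(12)
            hits += paired_t_one_sided(pre, post, "decrease")["p"] < 0.05
        assert hits / n_sims == pytest.approx(0.05, abs=0.015)


class TestEffectSizes:
    def test_hand_computed_d(self):
        pre = np.zeros(3)
        post = np.array([1.0, 2.0, 3.0])
        assert cohens_d_paired(pre, post) == pytest.approx(2.0)

    def test_zero_sd_rejected(self):
        x = np.arange(5, dtype=float)
        with pytest.raises(ValueError):
            cohens_d_paired(x, x)

    def test_ci_degenerate_and_symmetric(self):
        assert mean_diff_ci(np.zeros(5)) == (0.0, 0.0, 0.0)
        mean, lo, hi = mean_diff_ci(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]))
        assert mean == 0.0 and lo == pytest.approx(-hi)

    def test_ci_coverage(self):
        rng = np.random.default_rng(5)
        n_sims, covered = 1000, 0
        for _ in range(n_sims):
            d = 1.0 + rng.standard_normal(200)
            _, lo, hi = mean_diff_ci(d)
            covered += lo <= 1.0 <= hi
        assert covered / n_sims == pytest.approx(0.95, abs=0.02)


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman_corr(x, x**3) == pytest.approx(1.0)
        assert spearman_corr(x, -x) == pytest.approx(-1.0)

    def test_tied_ranks_match_hand_ranking(self):
        x = [1.0, 1.0, 2.0, 3.0]
        y = [2.0, 3.0, 1.0, 4.0]
        rx = sps.rankdata(x)  # [1.5, 1.5, 3, 4]
        ry = sps.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_corr(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr([1.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])


class TestBhFdr:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.04], [0.04]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.01, 0.5, 0.9], [0.03, 0.75, 0.9]),
        ],
    )
    def test_hand_computed(self, p, expected):
        np.testing.assert_allclose(bh_fdr(p), expected)

    def test_monotone_and_order_preserving(self, rng):
        p = rng.random(10)
        adj = bh_fdr(p)
        # adjusted values are a nondecreasing function of the raw values
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        # permutation equivariance: sorting p sorts adj identically
        np.testing.assert_allclose(np.sort(adj), bh_fdr(np.sort(p)))
        assert (adj >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestOutcomeTable:
    def _samples(self, rng, n=24, shift=0.0):
        samples, plans = [], []
        for i in range(4):
            pre = rng.standard_normal(n) * 3 + 10
            post = pre + shift + rng.standard_normal(n)
            samples.append(PairedSample(measure=f"m{i}", pre=tuple(pre), after=tuple(post)))
            plans.append(MeasurePlan(measure=f"m{i}", direction="decrease", family="fam"))
        return samples, plans

    def test_row_order_invariance(self, rng):
        samples, plans = self._samples(rng)
        t1 = outcome_table(samples, plans)
        t2 = outcome_table(samples[::-1], plans[::-1])
        import pandas as pd
        pd.testing.assert_frame_equal(t1, t2)

    def test_fdr_within_family_and_adjusted_not_below_raw(self, rng):
        samples, plans = self._samples(rng, shift=-1.0)
        table = outcome_table(samples, plans)
        assert (table["p_fdr"] >= table["p_raw"] - 1e-12).all()
        np.testing.assert_allclose(
            table["p_fdr"].to_numpy(), bh_fdr(table["p_raw"].to_numpy())
        )

    def test_listwise_missing_reduces_n(self, rng):
        samples, plans = self._samples(rng)
        s = samples[0]
        pre = list(s.pre)
        pre[0] = float("nan")
        samples[0] = PairedSample(measure=s.measure, pre=tuple(pre), after=s.after)
        # huge mad_k disables outlier screening so only the NaN pair drops
        table = outcome_table(samples, plans, mad_k=1e9).set_index("measure")
        assert table.loc["m0", "n"] == table.loc["m1", "n"] - 1

    def test_rank_tests_invariant_to_monotone_transform(self, rng):
        """Signed-rank p depends only on the ordering of |differences| and
        their signs, so a strictly monotone transform of the differences
        preserving both leaves it unchanged."""
        pre = rng.standard_normal(16)
        diffs = rng.standard_normal(16)
        p1 = signed_rank_one_sided(pre, pre + diffs, "decrease")["p"]
        # cube: strictly monotone, odd, order- and sign-preserving on diffs
        p2 = signed_rank_one_sided(pre, pre + diffs**3, "decrease")["p"]
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_global_null_rarely_significant(self):
        """Under a global null, at most 1 of 8 measures reaches fdr
        significance in the vast majority of replicates."""
        rng = np.random.default_rng(6)
        ok = 0
        n_reps = 200
        for _ in range(n_reps):
            samples, plans = [], []
            for i in range(8):
                pre = rng.standard_normal(24)
                post = pre + rng.standard_normal(24)
                samples.append(PairedSample(measure=f"m{i}", pre=tuple(pre), after=tuple(post)))
                plans.append(MeasurePlan(measure=f"m{i}", direction="decrease", family="fam"))
            table = outcome_table(samples, plans)
            ok += (table["p_fdr"] < 0.05).sum() <= 1
        assert ok / n_reps >= 0.8
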