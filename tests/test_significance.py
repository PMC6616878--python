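"""Exact sign-test rules, median confidence intervals and data-set assembly."""

import math

import numpy as np
import pytest
from scipy import stats

from dyadrank.dyads import DyadKey, DyadSummary
from dyadrank.interaction_io import AnimalId, PenRoster
from dyadrank.significance import (
    build_datasets,
    critical_value,
    critical_value_table,
    dataset_summary,
    dyad_limit_test,
    median_ci,
    pen_limit,
    pen_limit_test,
    sign_test_p,
)
from .conftest import make_record


def dyad(pen, a, b, wins_a, wins_b):
    return DyadSummary(DyadKey.of(AnimalId(pen, a), AnimalId(pen, b)), wins_a, wins_b)


# ---------------------------------------------------------------------------
# exact sign test
# ---------------------------------------------------------------------------

class TestSignTest:
    @pytest.mark.parametrize(
        "x, n, expected",
        [(0, 5, 0.03125), (1, 8, 9 / 256), (7, 7, 1.0), (3, 6, 42 / 64)],
    )
    def test_hand_computed_values(self, x, n, expected):
        assert sign_test_p(x, n) == pytest.approx(expected, abs=1e-12)

    def test_matches_binomial_cdf_oracle(self):
        for n in range(1, 30):
            for x in range(n + 1):
                assert sign_test_p(x, n) == pytest.approx(
                    stats.binom.cdf(x, n, 0.5), abs=1e-12
                )

    def test_full_tail_is_one(self):
        assert sign_test_p(12, 12) == 1.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            sign_test_p(3, 2)
        with pytest.raises(ValueError):
            sign_test_p(0, 0)


class TestCriticalValue:
    def test_agrees_with_smallest_x_oracle(self):
        for n in range(1, 41):
            cum = 0.0
            oracle = None
            for x in range(n + 1):
                cum += math.comb(n, x) / 2.0**n
                if cum >= 0.05:
                    oracle = x
                    break
            assert critical_value(n, 0.05) == oracle

    def test_no_significance_below_five_fights(self):
        assert all(critical_value(n, 0.05) == 0 for n in range(1, 5))

    def test_non_decreasing_in_n(self):
        values = [critical_value(n) for n in range(1, 60)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_table_object_extends_beyond_tabulated_range(self):
        table = critical_value_table(0.05, n_max=10)
        assert table[7] == 1
        assert table[25] == 8  # computed on demand


class TestDyadLimit:
    @pytest.mark.parametrize(
        "wins, expected",
        [((5, 0), True), ((4, 0), False), ((8, 1), True), ((8, 2), False), ((0, 0), False)],
    )
    def test_examples(self, wins, expected):
        res = dyad_limit_test(dyad("p", "a", "b", *wins))
        assert res.significant is expected
        assert res.method == "dyad_limit"

    def test_monotone_in_asymmetry(self):
        # at fixed n_fights, a more lopsided outcome never loses significance
        for n in range(1, 26):
            flags = [dyad_limit_test(dyad("p", "a", "b", n - lo, lo)).significant
                     for lo in range(n // 2 + 1)]
            # flags run from most asymmetric (lo=0) to least
            assert all(a or not b for a, b in zip(flags, flags[1:]))

    def test_alpha_monotonicity(self):
        d = dyad("p", "a", "b", 4, 0)
        assert not dyad_limit_test(d, alpha=0.05).significant
        assert dyad_limit_test(d, alpha=0.10).significant


# ---------------------------------------------------------------------------
# order-statistic median CI
# ---------------------------------------------------------------------------

def coverage_two_sided(ci_fn, n, conf, rng, n_sim=2000, median=0.0):
    hits = 0
    for _ in range(n_sim):
        sample = rng.standard_normal(n) + median
        lo, hi = ci_fn(sample, conf)
        hits += lo <= median <= hi
    return hits / n_sim


class TestMedianCI:
    def test_degenerate_sample(self):
        assert median_ci([3, 3, 3, 3]) == (3.0, 3.0)
        assert median_ci([5.0]) == (5.0, 5.0)

    def test_small_sample_clamps_to_range(self):
        # n = 5: even (X_(1), X_(5)) covers only 1 - 2/32 = 0.9375 < 0.95
        assert median_ci([1, 1, 2, 3, 5], conf=0.95) == (1.0, 5.0)

    def test_interpolated_interval_matches_order_statistic_oracle(self):
        # oracle: brute-force achievable coverages + linear interpolation,
        # built directly from the binomial distribution
        sample = [0, 0, 0, 0, 1, 1, 1, 2, 4]
        n = len(sample)
        x = np.sort(np.asarray(sample, float))
        cov = {d: 1 - 2 * stats.binom.cdf(d - 1, n, 0.5) for d in range(1, n // 2 + 1)}
        d_out = max(d for d in cov if cov[d] >= 0.95)
        d_in = d_out + 1
        w = (0.95 - cov[d_in]) / (cov[d_out] - cov[d_in])
        upper = (1 - w) * x[n - d_in] + w * x[n - d_out]
        lower = (1 - w) * x[d_in - 1] + w * x[d_out - 1]
        got = median_ci(sample, conf=0.95)
        assert got == pytest.approx((lower, upper))
        assert got[1] == pytest.approx(1.9222222222)

    def test_equivariance_under_scaling(self):
        sample = [0, 1, 1, 2, 3, 5, 8, 13, 21, 34]
        lo, hi = median_ci(sample)
        lo3, hi3 = median_ci([3 * v for v in sample])
        assert (lo3, hi3) == pytest.approx((3 * lo, 3 * hi))

    def test_two_sided_coverage(self):
        rng = np.random.default_rng(7)
        cov = coverage_two_sided(lambda s, c: median_ci(s, conf=c), n=15,
                                 conf=0.95, rng=rng)
        mc_se = math.sqrt(0.95 * 0.05 / 2000)
        assert cov >= 0.95 - 3 * mc_se

    def test_one_sided_lower_coverage(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(2000):
            sample = rng.standard_normal(20)
            lo, hi = median_ci(sample, conf=0.95, mode="one_sided_lower")
            assert hi == math.inf
            hits += lo <= 0.0
        mc_se = math.sqrt(0.95 * 0.05 / 2000)
        assert hits / 2000 >= 0.95 - 3 * mc_se

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            median_ci([])


# ---------------------------------------------------------------------------
# pen-individual limits
# ---------------------------------------------------------------------------

class TestPenLimit:
    def test_uniform_diffs_give_their_own_value(self):
        dyads = [dyad("p", "a", f"x{i}", 2, 1) for i in range(8)]  # all diff 1
        lim = pen_limit(dyads)
        assert lim.limit == pytest.approx(1.0)
        assert not any(pen_limit_test(d, lim).significant for d in dyads)

    def test_mixed_diffs_only_extreme_dyad_significant(self):
        wins = [(1, 1), (2, 2), (3, 3), (1, 1), (2, 1), (3, 2), (2, 1), (3, 1), (4, 0)]
        dyads = [dyad("p", "a", f"x{i}", *w) for i, w in enumerate(wins)]
        # diffs: 0,0,0,0,1,1,1,2,4 -> interpolated upper limit ~1.92,
        # exceeded by the diff-2 and diff-4 dyads only
        lim = pen_limit(dyads)
        assert lim.limit == pytest.approx(1.9222222222)
        flags = [pen_limit_test(d, lim).significant for d in dyads]
        assert flags == [False] * 7 + [True, True]

    def test_single_dyad_is_never_self_significant(self):
        d = dyad("p", "a", "b", 3, 0)
        lim = pen_limit([d])
        assert lim.limit == pytest.approx(3.0)
        assert not pen_limit_test(d, lim).significant  # strict inequality

    def test_unknown_dyads_excluded_by_default(self):
        interacting = [dyad("p", "a", f"x{i}", 3, 1) for i in range(5)]
        unknown = [dyad("p", "b", f"y{i}", 0, 0) for i in range(20)]
        lim = pen_limit(interacting + unknown)
        assert lim.n_dyads_used == 5
        lim_all = pen_limit(interacting + unknown, include_zero_diff_dyads=True)
        assert lim_all.n_dyads_used == 25
        assert lim_all.limit <= lim.limit

    def test_scaling_equivariance(self):
        wins = [(2, 1), (4, 1), (5, 2), (6, 0), (3, 3), (2, 0), (7, 3)]
        dyads1 = [dyad("p", "a", f"x{i}", *w) for i, w in enumerate(wins)]
        # same diffs scaled by 3, keeping every dyad interacting
        dyads3 = [dyad("p", "a", f"x{i}", 3 * (w[0] - w[1]) + 1, 1) for i, w in enumerate(wins)]
        lim1 = pen_limit(dyads1)
        lim3 = pen_limit(dyads3)
        assert lim3.limit == pytest.approx(3 * lim1.limit)

    def test_no_interacting_dyads_means_no_limit(self):
        unknown = [dyad("p", "a", f"x{i}", 0, 0) for i in range(6)]
        assert pen_limit(unknown) is None
        res = pen_limit_test(unknown[0], None)
        assert not res.significant and res.threshold == math.inf


# ---------------------------------------------------------------------------
# data sets ALL / PEN / DYAD
# ---------------------------------------------------------------------------

def small_roster(pen="p1", n=4):
    return PenRoster(pen, "weaned_piglet",
                     frozenset(AnimalId(pen, f"t{i}") for i in range(n)))


class TestBuildDatasets:
    def test_dyad_rule_keeps_exactly_the_significant_fights(self, piglet_schedule):
        roster = small_roster()
        rosters = {"p1": roster}
        records = [make_record(piglet_schedule, "p1", "t0", "t1", hour=0.2 + 0.1 * k)
                   for k in range(5)]                       # 5-0: significant
        records += [make_record(piglet_schedule, "p1", "t2", "t3", hour=2.0)]  # 1-0: not
        analysis = build_datasets(records, rosters)
        assert analysis.datasets["ALL"].n_interactions == 6
        assert analysis.datasets["DYAD"].n_interactions == 5
        assert {r.loser.tag for r in analysis.datasets["DYAD"].records} == {"t1"}

    def test_subset_structure(self, piglet_schedule):
        rng = np.random.default_rng(3)
        roster = small_roster(n=6)
        rosters = {"p1": roster}
        tags = [f"t{i}" for i in range(6)]
        records = []
        for _ in range(60):
            i, j = rng.choice(6, size=2, replace=False)
            records.append(make_record(piglet_schedule, "p1", tags[i], tags[j],
                                       hour=float(rng.uniform(0, 27.9))))
        analysis = build_datasets(records, rosters)
        all_set = set(map(id, analysis.datasets["ALL"].records))
        for label in ("PEN", "DYAD"):
            assert all(id(r) in all_set for r in analysis.datasets[label].records)

    def test_no_significant_dyads_anywhere(self, piglet_schedule):
        roster = small_roster()
        rosters = {"p1": roster}
        records = [make_record(piglet_schedule, "p1", "t0", "t1", hour=0.5)]
        analysis = build_datasets(records, rosters)
        for label in ("PEN", "DYAD"):
            ds = analysis.datasets[label]
            assert ds.n_interactions == 0 and ds.pens == [] and ds.animals == set()

    def test_summary_counts_only_retained_pens(self, piglet_schedule):
        roster = small_roster()
        rosters = {"p1": roster}
        records = [make_record(piglet_schedule, "p1", "t0", "t1", hour=0.2 + 0.1 * k)
                   for k in range(5)]
        analysis = build_datasets(records, rosters)
        table = dataset_summary(analysis).set_index("dataset")
        assert table.loc["ALL", "n_pens"] == 1
        assert table.loc["DYAD", "n_pens"] == 1
        assert table.loc["DYAD", "n_animals"] == 4  # whole roster of the retained pen
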