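"""Nonparametric statistics against independent oracles.

Oracles: brute-force pair counting for Cliff's delta, full rank-split
enumeration for the exact Mann-Whitney p, closed-form checks for the
Fisher-z interval, and hand-computable small cases for Spearman.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from cytomorph import stats as st
from cytomorph.errors import ValidationError


def brute_force_delta(x, y):
    gt = sum(1 for a in x for b in y if a > b)
    lt = sum(1 for a in x for b in y if a < b)
    return (gt - lt) / (len(x) * len(y))


def enumerate_mw_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating every assignment of
    the pooled ranks to the first sample (valid without ties)."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    n1, n2 = len(x), len(y)
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    m = n1 * n2
    us = []
    for combo in itertools.combinations(range(1, n1 + n2 + 1), n1):
        us.append(sum(combo) - n1 * (n1 + 1) / 2)
    us = np.array(us)
    lo, hi = min(u_obs, m - u_obs), max(u_obs, m - u_obs)
    return min(1.0, ((us <= lo).sum() + (us >= hi).sum()) / us.size)


class TestMedianIqr:
    def test_study_age_summaries(self, study_cohort):
        ages_e = [r.age for r in study_cohort.exposed]
        ages_n = [r.age for r in study_cohort.non_exposed]
        assert st.median_iqr(ages_e)[:2] == (1.50, 4.00)
        assert st.median_iqr(ages_n)[:2] == (4.50, 2.50)

    def test_study_cigarette_summary(self, study_cohort):
        cigs = [r.cigarettes_per_day for r in study_cohort.exposed]
        assert st.median_iqr(cigs)[:2] == (8.50, 4.00)

    def test_singleton(self):
        med, iqr, q1, q3 = st.median_iqr([5])
        assert (med, iqr, q1, q3) == (5, 0, 5, 5)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            st.median_iqr([])


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        u, p = st.mann_whitney_u([4, 5, 6], [1, 2, 3])
        assert u == 9
        assert p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        _, p = st.mann_whitney_u([1, 2], [1, 2])
        assert p == pytest.approx(1.0)

    def test_study_cigarettes_highly_significant(self, study_cohort):
        x = [r.cigarettes_per_day for r in study_cohort.exposed]
        y = [r.cigarettes_per_day for r in study_cohort.non_exposed]
        _, p = st.mann_whitney_u(x, y)
        assert p < 0.001

    def test_study_age_not_significant(self, study_cohort):
        x = [r.age for r in study_cohort.exposed]
        y = [r.age for r in study_cohort.non_exposed]
        _, p = st.mann_whitney_u(x, y)
        assert p >= 0.05

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(hst.data())
    def test_exact_mode_matches_enumeration(self, data):
        n1 = data.draw(hst.integers(2, 5))
        n2 = data.draw(hst.integers(2, 5))
        vals = data.draw(hst.lists(
            hst.integers(0, 1000), min_size=n1 + n2, max_size=n1 + n2,
            unique=True))
        x, y = vals[:n1], vals[n1:]
        _, p = st.mann_whitney_u(x, y)
        assert p == pytest.approx(enumerate_mw_p(x, y))


class TestCliffsDelta:
    def test_study_age_delta(self, study_cohort):
        x = [r.age for r in study_cohort.exposed]
        y = [r.age for r in study_cohort.non_exposed]
        assert st.cliffs_delta(x, y) == pytest.approx(-0.25)

    def test_study_cigarettes_delta_is_one(self, study_cohort):
        x = [r.cigarettes_per_day for r in study_cohort.exposed]
        y = [r.cigarettes_per_day for r in study_cohort.non_exposed]
        assert st.cliffs_delta(x, y) == 1.0

    def test_all_ties_zero(self):
        assert st.cliffs_delta([3, 3, 3], [3, 3, 3]) == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(hst.lists(hst.integers(-5, 5), min_size=1, max_size=8),
           hst.lists(hst.integers(-5, 5), min_size=1, max_size=8))
    def test_antisymmetry_and_brute_force(self, x, y):
        d = st.cliffs_delta(x, y)
        assert d == pytest.approx(brute_force_delta(x, y))
        assert d == pytest.approx(-st.cliffs_delta(y, x))
        assert -1 <= d <= 1


class TestBootstrapDeltaCI:
    def test_disjoint_supports_degenerate_ci(self, study_cohort):
        x = [r.cigarettes_per_day for r in study_cohort.exposed]
        y = [r.cigarettes_per_day for r in study_cohort.non_exposed]
        assert st.bootstrap_delta_ci(x, y, reps=2000, rng_seed=0) == (1.0, 1.0)

    def test_single_observations_collapse(self):
        lo, hi = st.bootstrap_delta_ci([2], [1], reps=100, rng_seed=0)
        assert lo == hi == 1.0

    def test_study_age_ci_stable_across_seeds(self, study_cohort):
        x = [r.age for r in study_cohort.exposed]
        y = [r.age for r in study_cohort.non_exposed]
        for seed in (0, 1):
            lo, hi = st.bootstrap_delta_ci(x, y, reps=10_000, rng_seed=seed)
            assert lo == pytest.approx(-0.61, abs=0.08)
            assert hi == pytest.approx(0.14, abs=0.08)

    def test_ci_brackets_point_estimate(self, study_cohort):
        x = [r.age for r in study_cohort.exposed]
        y = [r.age for r in study_cohort.non_exposed]
        d = st.cliffs_delta(x, y)
        lo, hi = st.bootstrap_delta_ci(x, y, reps=5000, rng_seed=3)
        assert lo <= d <= hi


class TestFisherExact:
    def test_study_sex_or_female_orientation(self):
        res = st.fisher_exact_2x2([[7, 13], [6, 4]])
        assert res.odds_ratio == pytest.approx(0.359, abs=5e-4)
        assert res.p_value >= 0.05

    def test_study_sex_or_male_orientation(self):
        res = st.fisher_exact_2x2([[13, 7], [4, 6]])
        assert res.odds_ratio == pytest.approx(2.79, abs=5e-3)

    def test_logit_ci(self):
        res = st.fisher_exact_2x2([[7, 13], [6, 4]], ci_method="logit")
        assert res.or_ci[0] == pytest.approx(0.08, abs=0.005)
        assert res.or_ci[1] == pytest.approx(1.71, abs=0.01)

    def test_exact_ci_contains_point(self):
        res = st.fisher_exact_2x2([[7, 13], [6, 4]])
        assert res.or_ci[0] < res.odds_ratio < res.or_ci[1]

    def test_null_table(self):
        res = st.fisher_exact_2x2([[1, 1], [1, 1]])
        assert res.odds_ratio == 1.0
        assert res.p_value == 1.0

    def test_or_reciprocity_on_column_swap(self):
        a = st.fisher_exact_2x2([[7, 13], [6, 4]])
        b = st.fisher_exact_2x2([[13, 7], [4, 6]])
        assert a.odds_ratio * b.odds_ratio == pytest.approx(1.0)
        assert a.p_value == pytest.approx(b.p_value)

    def test_zero_cell_flagged(self):
        res = st.fisher_exact_2x2([[5, 0], [2, 3]])
        assert res.degenerate
        assert math.isinf(res.odds_ratio)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            st.fisher_exact_2x2([[0, 0], [2, 3]])


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        x = [1.0, 2.5, 4.0, 9.0]
        assert st.spearman(x, [math.exp(v) for v in x])[0] == 1.0

    def test_reversal_is_minus_one(self):
        x = [1.0, 2.0, 3.0, 5.0]
        assert st.spearman(x, [-v for v in x])[0] == -1.0

    def test_hand_computed_small_case(self):
        rho, _ = st.spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_missing_pairs_dropped(self):
        rho, _ = st.spearman([1, 2, 3, 4, np.nan], [1, 3, 2, 4, 100])
        assert rho == pytest.approx(0.8)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            st.spearman([1, 2], [2, 1])

    def test_exact_p_matches_permutation_enumeration(self):
        # oracle: enumerate all pairings, scoring each with scipy's rho
        from scipy import stats as sps
        x = [3, 1, 4, 1.5, 9, 2.6]
        y = [2, 7, 1, 8, 2.8, 1.7]
        _, p = st.spearman(x, y)
        rho_obs = abs(sps.spearmanr(x, y).statistic)
        hits = total = 0
        for perm in itertools.permutations(y):
            total += 1
            hits += abs(sps.spearmanr(x, perm).statistic) >= rho_obs - 1e-12
        assert p == pytest.approx(hits / total)


class TestFisherZCI:
    def test_published_scale_interval(self):
        lo, hi = st.fisher_z_ci(0.85, 13)
        assert round(lo, 2) == 0.56
        assert round(hi, 2) == 0.95

    def test_symmetric_about_zero(self):
        lo, hi = st.fisher_z_ci(0.0, 7)
        assert lo == pytest.approx(-hi)

    def test_width_shrinks_with_n(self):
        w = [st.fisher_z_ci(0.5, n)[1] - st.fisher_z_ci(0.5, n)[0]
             for n in (10, 100, 10_000)]
        assert w[0] > w[1] > w[2]
        assert w[2] < 0.04

    def test_degenerate_rho(self):
        assert st.fisher_z_ci(1.0, 10) == (1.0, 1.0)

    def test_always_contains_rho(self):
        for rho in np.linspace(-0.95, 0.95, 9):
            lo, hi = st.fisher_z_ci(float(rho), 20)
            assert lo <= rho <= hi


class TestCorrelationMatrix:
    def test_symmetric_unit_diagonal(self):
        import pandas as pd
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("abc"))
        rho, p = st.correlation_matrix(df)
        assert np.allclose(rho.values, rho.values.T)
        assert np.allclose(np.diag(rho.values), 1.0)
        assert np.allclose(p.values, p.values.T)

    def test_insufficient_complete_cases_named(self):
        import pandas as pd
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [np.nan] * 4})
        with pytest.raises(ValidationError, match="b"):
            st.correlation_matrix(df)
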