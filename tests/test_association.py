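"""Odds ratios, count reconstruction, rank tests, Bonferroni."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytoclass.association import (
    AmbiguousCountError,
    NoSolutionError,
    RankTestResult,
    TwoByTwo,
    bonferroni,
    class_outcome_table,
    cytokine_outcome_ranks,
    mann_whitney,
    odds_ratio,
    reconstruct_counts,
)
from cytoclass.published import COUNT_CONSISTENT_ORS, published_two_by_two


class TestReconstructCounts:
    @pytest.mark.parametrize(
        "n,pct,expected",
        [(883, 9.9, 87), (197, 35.0, 69), (197, 87.8, 173), (890, 22.4, 199), (76, 57.9, 44)],
    )
    def test_unique_inversion(self, n, pct, expected):
        assert reconstruct_counts(n, pct) == expected

    def test_no_solution(self):
        with pytest.raises(NoSolutionError):
            reconstruct_counts(192, 28.5)

    def test_ambiguous(self):
        # with n=2000 neighbouring counts print identically at 1 decimal
        with pytest.raises(AmbiguousCountError):
            reconstruct_counts(2000, 10.0)

    def test_exhaustive_consistency(self):
        """Every successful inversion round-trips through the printing rule."""
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(10, 1000))
            x = int(rng.integers(0, n + 1))
            pct = math.floor(100.0 * x / n * 10 + 0.5) / 10.0
            try:
                got = reconstruct_counts(n, pct)
            except AmbiguousCountError:
                continue
            assert math.floor(100.0 * got / n * 10 + 0.5) / 10.0 == pct


class TestOddsRatio:
    def test_unit_table(self):
        assert odds_ratio(TwoByTwo(1, 1, 1, 1)).oddsratio == 1.0

    def test_zero_cell_haldane(self):
        res = odds_ratio(TwoByTwo(0, 10, 5, 5))
        assert res.continuity_corrected
        assert res.oddsratio == (0.5 * 5.5) / (10.5 * 5.5)

    def test_published_worked_examples(self):
        for (cls, outcome), (orv, lo, hi) in COUNT_CONSISTENT_ORS.items():
            res = odds_ratio(published_two_by_two(cls, outcome))
            assert res.oddsratio == pytest.approx(orv, abs=0.011)
            assert res.ci_low == pytest.approx(lo, abs=0.02)
            assert res.ci_high == pytest.approx(hi, abs=0.02)

    def test_matches_logistic_regression(self):
        """Closed-form OR equals the one-dummy logistic-regression MLE."""
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 200, size=4)
            t = TwoByTwo(int(a), int(b), int(c), int(d))
            res = odds_ratio(t)
            y = np.array([1, 0, 1, 0])
            x = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 0.0], [1.0, 0.0]])
            fit = sm.GLM(
                y, x, family=sm.families.Binomial(), freq_weights=np.array([a, b, c, d])
            ).fit()
            assert res.oddsratio == pytest.approx(math.exp(fit.params[1]), abs=1e-8)


class TestMannWhitney:
    def test_separated_groups_exact(self):
        res = mann_whitney([1, 2, 3, 4, 5, 6], [False, False, False, True, True, True])
        assert res.mean_rank_neg == 2.0
        assert res.mean_rank_pos == 5.0
        assert res.u_statistic == 9.0  # equivalently U=0 for the other group
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)

    def test_rank_conservation(self):
        """Weighted mean of group mean ranks is (n+1)/2 exactly."""
        rng = np.random.default_rng(1)
        v = rng.normal(size=2000)
        g = rng.random(2000) < 0.5
        res = mann_whitney(v, g)
        n = len(v)
        pooled = (res.n_neg * res.mean_rank_neg + res.n_pos * res.mean_rank_pos) / n
        assert pooled == pytest.approx((n + 1) / 2, abs=1e-9)

    def test_shift_increases_mean_rank(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=40)
        g = np.arange(40) < 20
        base = mann_whitney(v, g).mean_rank_pos
        v2 = v.copy()
        v2[g] += 10.0
        assert mann_whitney(v2, g).mean_rank_pos > base

    def test_ties_use_midranks(self):
        res = mann_whitney([1, 1, 2, 2], [False, True, False, True])
        assert res.mean_rank_neg == res.mean_rank_pos == 2.5

    def test_degenerate_all_identical(self):
        res = mann_whitney([3.0, 3.0, 3.0, 3.0], [False, False, True, True])
        assert res.p_value == 1.0
        assert res.degenerate

    def test_exact_close_to_normal_approximation(self):
        """For moderate group sizes the enumeration p and the tie-corrected
        normal approximation agree within the usual small-sample error."""
        rng = np.random.default_rng(3)
        from scipy import stats

        for _ in range(10):
            v = rng.normal(size=14)
            g = np.arange(14) < 7
            exact = mann_whitney(v, g)
            assert exact.method == "exact"
            approx = stats.mannwhitneyu(v[g], v[~g], alternative="two-sided", method="asymptotic")
            assert exact.p_value == pytest.approx(float(approx.pvalue), abs=0.05)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([1.0, 2.0], [True, True])


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.25], m=4)[0] == 1.0
        assert bonferroni([0.01], m=20)[0] == pytest.approx(0.20)
        assert bonferroni([0.0], m=1000)[0] == 0.0

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
        st.integers(min_value=1, max_value=100),
    )
    @settings(deadline=None, max_examples=50)
    def test_bounds(self, ps, m):
        adj = bonferroni(ps, m=m)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni([0.5], m=0)
        with pytest.raises(ValueError):
            bonferroni([1.5])


def _toy_labelled_cohort(rng, n=600, k=3, prevalence_by_class=None):
    labels = rng.integers(0, k + 1, size=n)
    if prevalence_by_class is None:
        prevalence_by_class = {c: 0.3 for c in range(k + 1)}
    p = np.array([prevalence_by_class[c] for c in labels])
    wheeze = rng.random(n) < p
    asthma = wheeze & (rng.random(n) < 0.5)
    spt = np.where(rng.random(n) < p, 4.0, 1.0)
    ige = np.where(rng.random(n) < p, 2.0, 0.1)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "hard_label": labels,
            "wheeze": wheeze,
            "asthma": asthma,
            "spt_mm": spt,
            "ige_kul": ige,
        }
    )


class TestClassOutcomeTable:
    def test_row_count_and_columns(self):
        df = _toy_labelled_cohort(np.random.default_rng(0))
        table = class_outcome_table(df)
        assert len(table) == 3 * 4  # (k classes) x (4 outcomes)
        assert {"class_id", "outcome", "n", "pct_positive", "or_value", "ci_low",
                "ci_high", "p_raw", "p_adjusted"} <= set(table.columns)
        assert (table["p_adjusted"] >= table["p_raw"] - 1e-15).all()
        assert (table["ci_low"] <= table["or_value"] + 1e-12).all()
        assert (table["or_value"] <= table["ci_high"] + 1e-12).all()

    def test_equal_prevalence_gives_null_ors(self):
        df = _toy_labelled_cohort(np.random.default_rng(1), n=4000)
        table = class_outcome_table(df)
        assert table["or_value"].between(0.6, 1.7).all()
        assert (table["p_adjusted"] > 0.2).all()

    def test_enriched_class_detected(self):
        df = _toy_labelled_cohort(
            np.random.default_rng(2), n=4000, prevalence_by_class={0: 0.1, 1: 0.1, 2: 0.1, 3: 0.7}
        )
        table = class_outcome_table(df)
        top = table[(table["class_id"] == 3) & (table["outcome"] == "wheeze")].iloc[0]
        assert top["or_value"] > 5
        assert top["p_adjusted"] < 1e-6

    def test_empty_reference_rejected(self):
        df = _toy_labelled_cohort(np.random.default_rng(3))
        with pytest.raises(ValueError):
            class_outcome_table(df[df["hard_label"] != 0])


def test_cytokine_outcome_ranks_shape(responders):
    table = cytokine_outcome_ranks(responders)
    assert len(table) == 16
    assert set(table["cytokine"]) == {"il5", "il13", "il10", "ifng"}
    # Th2 cytokines rank higher among sensitized children in the
    # calibrated cohort
    row = table[(table["cytokine"] == "il13") & (table["outcome"] == "ige")].iloc[0]
    assert row["mean_rank_pos"] > row["mean_rank_neg"]
    assert row["p_adjusted"] < 0.001
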