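"""Class-vs-outcome and cytokine-vs-outcome statistics.

Reproduces the reporting shape of the cohort analysis: Mann–Whitney mean
ranks of net cytokine levels by clinical outcome, odds ratios (with 95%
Wald confidence intervals) of each cytokine class against the
nonresponder reference class, and Bonferroni adjustment of the p-values.

Odds ratios are computed in closed form from 2×2 tables — for a single
binary contrast this is exactly the univariate logistic-regression MLE
(cross-checked against an iteratively fitted logistic model in the test
suite). :func:`reconstruct_counts` inverts printed "n (% positive)" table
cells back to integer counts so published tables can be consumed as
inputs.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cytoclass.simulate import CYTOKINES

#: outcome name -> column + binarization rule applied to a cohort table
OUTCOME_RULES = {
    "wheeze": lambda df: df["wheeze"].astype("boolean"),
    "asthma": lambda df: df["asthma"].astype("boolean"),
    "spt": lambda df: (df["spt_mm"] >= 3.0).mask(df["spt_mm"].isna()),
    "ige": lambda df: (df["ige_kul"] > 0.35).mask(df["ige_kul"].isna()),
}


class NoSolutionError(ValueError):
    """No integer count rounds to the printed percentage."""


class AmbiguousCountError(ValueError):
    """More than one integer count rounds to the printed percentage."""


def _round_half_up_1dp(x: float) -> float:
    return math.floor(x * 10.0 + 0.5) / 10.0


def reconstruct_counts(n: int, pct: float) -> int:
    """Invert a printed "n (% positive)" cell to its integer count.

    Finds the unique x in 0..n with round(100*x/n, 1) == pct (half-up
    rounding at one decimal). Raises :class:`NoSolutionError` /
    :class:`AmbiguousCountError` otherwise, with n and pct in the message.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= pct <= 100.0:
        raise ValueError("pct must lie in [0, 100]")
    target = round(pct * 10.0)
    matches = [x for x in range(n + 1) if round(_round_half_up_1dp(100.0 * x / n) * 10) == target]
    if not matches:
        raise NoSolutionError(f"no count x with round(100*x/{n}, 1) == {pct}")
    if len(matches) > 1:
        raise AmbiguousCountError(f"counts {matches} all print as {pct}% of {n}")
    return matches[0]


@dataclasses.dataclass
class TwoByTwo:
    """2×2 table: (a, b) = exposed positive/negative, (c, d) = reference
    positive/negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @classmethod
    def from_groups(cls, exposed: Sequence[bool], reference: Sequence[bool]) -> "TwoByTwo":
        e = np.asarray(exposed, dtype=bool)
        r = np.asarray(reference, dtype=bool)
        return cls(a=int(e.sum()), b=int((~e).sum()), c=int(r.sum()), d=int((~r).sum()))


@dataclasses.dataclass
class OddsRatioResult:
    oddsratio: float
    ci_low: float
    ci_high: float
    p_value: float
    continuity_corrected: bool


def odds_ratio(t: TwoByTwo, alpha: float = 0.05) -> OddsRatioResult:
    """OR = ad/bc with a Wald CI and two-sided Wald p.

    A zero cell triggers the Haldane–Anscombe correction (+0.5 to all
    four cells), flagged in the result.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orv = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    log_or = math.log(orv)
    ci_low = math.exp(log_or - z * se)
    ci_high = math.exp(log_or + z * se)
    p = 2 * stats.norm.sf(abs(log_or) / se)
    return OddsRatioResult(orv, ci_low, ci_high, float(p), corrected)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m*p) elementwise.

    ``m`` defaults to the number of p-values; m larger than the family is
    allowed (a deliberately conservative correction), smaller than 1 is
    not.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)


def class_outcome_table(
    cohort_with_labels: pd.DataFrame,
    reference_class: int = 0,
    m_tests: int | None = None,
    alpha: float = 0.05,
    outcomes: Sequence[str] = ("wheeze", "asthma", "spt", "ige"),
) -> pd.DataFrame:
    """Class-by-outcome association table against the reference class.

    ``cohort_with_labels`` must carry ``hard_label`` plus the outcome
    columns (``wheeze``, ``asthma``, ``spt_mm``, ``ige_kul``; the SPT
    ≥3 mm and IgE >0.35 kU/L rules are applied here). One row per
    (non-reference class × outcome) with the class's n (non-missing for
    that outcome), % positive, OR vs the reference, 95% CI, raw and
    Bonferroni-adjusted p. ``m_tests`` defaults to the number of rows.
    """
    df = cohort_with_labels
    labels = sorted(df["hard_label"].unique())
    if reference_class not in labels:
        raise ValueError(f"reference class {reference_class} not present")
    if (df["hard_label"] == reference_class).sum() == 0:
        raise ValueError("reference class is empty")

    rows = []
    for cls in labels:
        if cls == reference_class:
            continue
        for outcome in outcomes:
            vals = OUTCOME_RULES[outcome](df)
            in_cls = (df["hard_label"] == cls) & vals.notna()
            in_ref = (df["hard_label"] == reference_class) & vals.notna()
            exposed = vals[in_cls].astype(bool).to_numpy()
            reference = vals[in_ref].astype(bool).to_numpy()
            t = TwoByTwo.from_groups(exposed, reference)
            res = odds_ratio(t, alpha=alpha)
            n = t.a + t.b
            rows.append(
                {
                    "class_id": cls,
                    "outcome": outcome,
                    "n": n,
                    "pct_positive": 100.0 * t.a / n if n else float("nan"),
                    "or_value": res.oddsratio,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p_raw": res.p_value,
                    "continuity_corrected": res.continuity_corrected,
                    "method": "wald_2x2",
                }
            )
    table = pd.DataFrame(rows)
    m = m_tests if m_tests is not None else len(table)
    table["p_adjusted"] = bonferroni(table["p_raw"].to_numpy(), m)
    return table


# ---------------------------------------------------------------------------
# Mann–Whitney rank tests (cytokine level by outcome)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RankTestResult:
    n_neg: int
    n_pos: int
    mean_rank_neg: float
    mean_rank_pos: float
    u_statistic: float
    p_value: float
    method: str          # "exact" or "asymptotic"
    degenerate: bool = False


def _exact_mw_p(ranks: np.ndarray, n_pos: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating all assignments of the observed
    (mid)ranks to the positive group; handles ties naturally."""
    n = len(ranks)
    n_neg = n - n_pos
    center = n_pos * n_neg / 2.0
    dev = abs(u_obs - center)
    count = 0
    total = 0
    offset = n_pos * (n_pos + 1) / 2.0
    for combo in itertools.combinations(range(n), n_pos):
        u = ranks[list(combo)].sum() - offset
        if abs(u - center) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total


def mann_whitney(values: Sequence[float], group: Sequence[bool]) -> RankTestResult:
    """Mann–Whitney U test of ``values`` between group=False and True.

    Midranks are used for ties and both group mean ranks are reported.
    The p-value is an exact enumeration over rank assignments when both
    groups have ≤ 8 members, and the tie-corrected normal approximation
    (with continuity correction) otherwise. All-identical values give
    p = 1 with the ``degenerate`` flag set.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(group, dtype=bool)
    if v.shape != g.shape or v.ndim != 1:
        raise ValueError("values and group must be 1-d and of equal length")
    n_pos = int(g.sum())
    n_neg = int((~g).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both groups must be non-empty")

    ranks = stats.rankdata(v)  # midranks
    mean_rank_pos = float(ranks[g].mean())
    mean_rank_neg = float(ranks[~g].mean())
    u = float(ranks[g].sum() - n_pos * (n_pos + 1) / 2.0)

    if np.all(v == v[0]):
        return RankTestResult(
            n_neg, n_pos, mean_rank_neg, mean_rank_pos, u, 1.0, "degenerate", True
        )
    if n_pos <= 8 and n_neg <= 8:
        p = _exact_mw_p(ranks, n_pos, u)
        method = "exact"
    else:
        res = stats.mannwhitneyu(v[g], v[~g], alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "asymptotic"
    return RankTestResult(n_neg, n_pos, mean_rank_neg, mean_rank_pos, u, p, method)


def cytokine_outcome_ranks(
    responders_with_outcomes: pd.DataFrame,
    m_tests: int | None = None,
    outcomes: Sequence[str] = ("asthma", "wheeze", "spt", "ige"),
) -> pd.DataFrame:
    """Rank-test table: net cytokine level by each clinical outcome.

    One row per (cytokine × outcome) with the two group mean ranks, U,
    raw and Bonferroni-adjusted p. Input is the net-response table joined
    with outcome columns (missing outcomes dropped row-wise).
    """
    rows = []
    for cyt in CYTOKINES:
        for outcome in outcomes:
            vals = OUTCOME_RULES[outcome](responders_with_outcomes)
            ok = vals.notna() & responders_with_outcomes[f"net_{cyt}"].notna()
            res = mann_whitney(
                responders_with_outcomes.loc[ok, f"net_{cyt}"].to_numpy(dtype=float),
                vals[ok].astype(bool).to_numpy(),
            )
            rows.append(
                {
                    "cytokine": cyt,
                    "outcome": outcome,
                    "n_neg": res.n_neg,
                    "n_pos": res.n_pos,
                    "mean_rank_neg": res.mean_rank_neg,
                    "mean_rank_pos": res.mean_rank_pos,
                    "u_statistic": res.u_statistic,
                    "p_raw": res.p_value,
                    "method": res.method,
                }
            )
    table = pd.DataFrame(rows)
    m = m_tests if m_tests is not None else len(table)
    table["p_adjusted"] = bonferroni(table["p_raw"].to_numpy(), m)
    return table
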