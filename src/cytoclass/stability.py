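"""Bootstrap stability of the cytokine-class solution.

Robustness of the clustering is quantified two ways, following common
practice for model-based clustering of biomarker panels:

* **overall structure** — B bootstrap resamples of the subjects are drawn;
  the clustering pipeline is refitted on each resample; every *original*
  subject is then assigned under the bootstrap model, and the agreement of
  that partition with the reference partition is measured by the adjusted
  Rand index (ARI). The distribution of the B ARI values (median, IQR)
  summarizes stability. The a-priori nonresponder class participates as an
  immovable class of its own.
* **single-cluster support** — a reference cluster counts as reproduced in
  a bootstrap run iff some bootstrap cluster has exactly the same member
  set (a deliberately hard criterion); its support is the fraction of runs
  in which it is reproduced. A relaxed criterion (maximum Jaccard overlap
  ≥ τ) is reported alongside.

The same machinery drives the choice of discretization scheme: each
candidate scheme is clustered and bootstrapped, and the scheme with the
highest median ARI wins (ties toward fewer levels).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cytoclass.discretize import (
    SCHEME_LEVELS,
    apply_discretizer,
    codes_matrix,
    fit_discretizer,
)
from cytoclass.mixture import assign, em_fit, select_k_cv


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Hubert–Arabie adjusted Rand index between two labelings.

    Computed from the pair-count contingency table:
    ``(sum_ij C(n_ij,2) - E) / (0.5*(sum_i C(a_i,2) + sum_j C(b_j,2)) - E)``
    with ``E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2)``. Equals 1 for
    identical partitions (up to relabeling) and is ~0 for chance
    agreement. The degenerate case where both partitions are a single
    cluster, or both are all singletons, returns 1.0.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be 1-d and of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two items")

    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)

    def comb2(x):
        x = np.asarray(x, dtype=np.float64)
        return x * (x - 1.0) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both trivial partitions
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


@dataclasses.dataclass
class ClusteringConfig:
    """Knobs for the discretize → EM → assign stage.

    ``k=None`` selects k by cross-validation; during bootstrap the
    reference model's k is held fixed by default (``reselect_k_bootstrap``
    re-runs the CV search inside every resample).
    """

    k: int | None = None
    k_max: int = 8
    folds: int = 10
    n_restarts: int = 10
    cv_restarts: int = 3
    tol: float = 1e-6
    max_iter: int = 500
    sd_floor: float = 1e-6
    refit_discretizer: bool = False
    reselect_k_bootstrap: bool = False

    def em_kwargs(self) -> dict:
        return dict(
            tol=self.tol,
            max_iter=self.max_iter,
            n_restarts=self.n_restarts,
            sd_floor=self.sd_floor,
        )

    def cv_kwargs(self) -> dict:
        kw = self.em_kwargs()
        kw["n_restarts"] = self.cv_restarts
        return kw


@dataclasses.dataclass
class ClusteredScheme:
    """A fitted reference solution for one discretization scheme."""

    scheme: object                # DiscretizationScheme
    codes: pd.DataFrame
    class0_ids: list
    model: object                 # MixtureModel
    assignment: pd.DataFrame      # subject_id, p_class*, hard_label
    cv_table: pd.DataFrame | None

    @property
    def labels(self) -> pd.Series:
        return self.assignment.set_index("subject_id")["hard_label"]


def cluster_scheme(
    responders: pd.DataFrame,
    scheme_name: str,
    config: ClusteringConfig | None = None,
    seed: int = 0,
) -> ClusteredScheme:
    """Discretize under ``scheme_name`` and fit the reference mixture."""
    config = config or ClusteringConfig()
    scheme = fit_discretizer(responders, scheme_name)
    codes, class0_ids = apply_discretizer(scheme, responders)
    X = codes_matrix(codes)
    cv_table = None
    k = config.k
    if k is None:
        k, cv_table = select_k_cv(
            X, k_max=config.k_max, folds=config.folds, seed=seed, **config.cv_kwargs()
        )
    model = em_fit(X, k, seed=seed, **config.em_kwargs())
    assignment = assign(model, codes, class0_ids)
    return ClusteredScheme(scheme, codes, class0_ids, model, assignment, cv_table)


@dataclasses.dataclass
class StabilityReport:
    """Bootstrap ARI distribution and per-cluster supports for one scheme."""

    scheme: str
    seed: int
    B: int
    reference_k: int
    ari_values: np.ndarray
    cluster_support: dict          # cluster id -> exact-set support fraction
    cluster_support_jaccard: dict  # cluster id -> Jaccard>=tau support
    jaccard_tau: float

    @property
    def ari_median(self) -> float:
        return float(np.median(self.ari_values))

    @property
    def ari_iqr(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.ari_values, [25, 75])
        return float(lo), float(hi)

    def to_dict(self) -> dict:
        lo, hi = self.ari_iqr
        return {
            "scheme": self.scheme,
            "seed": self.seed,
            "B": self.B,
            "reference_k": self.reference_k,
            "ari_values": np.asarray(self.ari_values).tolist(),
            "ari_median": self.ari_median,
            "ari_iqr": [lo, hi],
            "cluster_support": {str(k): v for k, v in self.cluster_support.items()},
            "cluster_support_jaccard": {str(k): v for k, v in self.cluster_support_jaccard.items()},
            "jaccard_tau": self.jaccard_tau,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def cluster_support(
    reference_labels: pd.Series,
    bootstrap_labels: Iterable[pd.Series],
    jaccard_tau: float = 0.8,
) -> tuple[dict, dict]:
    """Per-cluster reproduction frequency across bootstrap partitions.

    Exact-set criterion: cluster c is reproduced in a run iff some cluster
    of that run contains exactly the same subjects. Relaxed criterion:
    some cluster overlaps with Jaccard index ≥ ``jaccard_tau``. The
    relaxed support always dominates the exact one.
    """
    ref_sets = {
        c: frozenset(reference_labels.index[reference_labels == c])
        for c in sorted(reference_labels.unique())
    }
    runs = list(bootstrap_labels)
    hard = {c: 0 for c in ref_sets}
    soft = {c: 0 for c in ref_sets}
    for labels in runs:
        if set(labels.index) != set(reference_labels.index):
            raise ValueError("bootstrap assignment covers a different subject universe")
        boot_sets = [frozenset(labels.index[labels == c]) for c in labels.unique()]
        for c, members in ref_sets.items():
            if any(bs == members for bs in boot_sets):
                hard[c] += 1
            best_j = max(
                (len(bs & members) / len(bs | members)) if (bs or members) else 1.0
                for bs in boot_sets
            )
            if best_j >= jaccard_tau:
                soft[c] += 1
    B = max(1, len(runs))
    return (
        {c: hard[c] / B for c in ref_sets},
        {c: soft[c] / B for c in ref_sets},
    )


def bootstrap_stability(
    responders: pd.DataFrame,
    scheme_name: str,
    config: ClusteringConfig | None = None,
    B: int = 100,
    seed: int = 0,
    jaccard_tau: float = 0.8,
    reference: ClusteredScheme | None = None,
    include_class0: bool = True,
) -> StabilityReport:
    """Bootstrap the full pipeline for one scheme and score stability.

    For each of B runs: resample subjects with replacement, refit the
    mixture (discretizer cutpoints reused from the reference unless
    ``config.refit_discretizer``; k fixed at the reference k unless
    ``config.reselect_k_bootstrap``), assign *all* original subjects by
    max posterior, and compute the ARI against the reference partition,
    with the nonresponder class included as a fixed class
    (``include_class0=False`` scores the responder partition only, since
    the immovable Class 0 mechanically inflates agreement).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    config = config or ClusteringConfig()
    if reference is None:
        reference = cluster_scheme(responders, scheme_name, config, seed=seed)
    ref_labels = reference.labels
    if include_class0:
        order = list(ref_labels.index)
    else:
        order = [s for s in ref_labels.index if ref_labels[s] != 0]
    ref_arr = ref_labels.loc[order].to_numpy()

    rng = np.random.default_rng(seed + 1)
    n = len(responders)
    ari_values = np.empty(B)
    boot_label_runs = []
    k_ref = reference.model.k
    fixed_orig = None
    if not config.refit_discretizer:
        fixed_orig = (reference.codes, reference.class0_ids)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        resample = responders.iloc[idx]
        if config.refit_discretizer:
            scheme = fit_discretizer(resample, scheme_name)
            # original-subject features under this run's scheme
            orig_codes, orig_class0 = apply_discretizer(scheme, responders)
        else:
            scheme = reference.scheme
            orig_codes, orig_class0 = fixed_orig
        boot_codes, _ = apply_discretizer(scheme, resample)
        Xb = codes_matrix(boot_codes)
        k = k_ref
        if config.reselect_k_bootstrap:
            k, _ = select_k_cv(
                Xb, k_max=config.k_max, folds=config.folds,
                seed=seed + 7919 * (b + 1), **config.cv_kwargs(),
            )
        model = em_fit(Xb, min(k, len(Xb)), seed=seed + 7919 * (b + 1), **config.em_kwargs())
        assignment = assign(model, orig_codes, orig_class0)
        labels = assignment.set_index("subject_id")["hard_label"]
        boot_label_runs.append(labels)
        ari_values[b] = adjusted_rand_index(ref_arr, labels.loc[order].to_numpy())

    hard, soft = cluster_support(ref_labels, boot_label_runs, jaccard_tau=jaccard_tau)
    return StabilityReport(
        scheme=scheme_name,
        seed=seed,
        B=B,
        reference_k=k_ref,
        ari_values=ari_values,
        cluster_support=hard,
        cluster_support_jaccard=soft,
        jaccard_tau=jaccard_tau,
    )


def select_discretization(
    responders: pd.DataFrame,
    schemes: Sequence[str] = ("binary", "tertile", "quartile"),
    config: ClusteringConfig | None = None,
    B: int = 100,
    seed: int = 0,
    jaccard_tau: float = 0.8,
) -> tuple[str, pd.DataFrame, dict]:
    """Pick the discretization scheme with the most stable clustering.

    Runs the full cluster + bootstrap pipeline per candidate scheme and
    selects the one with the highest median bootstrap ARI; ties are broken
    toward fewer levels. Returns ``(chosen, comparison_table, reports)``
    where the comparison table has one row per scheme (levels, selected k,
    median/IQR ARI, per-cluster supports).
    """
    if len(schemes) < 1:
        raise ValueError("need at least one candidate scheme")
    config = config or ClusteringConfig()
    reports: dict[str, StabilityReport] = {}
    references: dict[str, ClusteredScheme] = {}
    rows = []
    for name in schemes:
        ref = cluster_scheme(responders, name, config, seed=seed)
        rep = bootstrap_stability(
            responders, name, config, B=B, seed=seed, jaccard_tau=jaccard_tau, reference=ref
        )
        reports[name] = rep
        references[name] = ref
        lo, hi = rep.ari_iqr
        rows.append(
            {
                "scheme": name,
                "levels": SCHEME_LEVELS[name],
                "k": rep.reference_k,
                "ari_median": rep.ari_median,
                "ari_q25": lo,
                "ari_q75": hi,
                "cluster_support": json.dumps(
                    {str(c): round(v, 4) for c, v in rep.cluster_support.items()}
                ),
                "cluster_support_jaccard": json.dumps(
                    {str(c): round(v, 4) for c, v in rep.cluster_support_jaccard.items()}
                ),
            }
        )
    table = pd.DataFrame(rows)
    # highest median ARI; ties toward fewer levels
    ranked = table.sort_values(["ari_median", "levels"], ascending=[False, True], kind="mergesort")
    chosen = str(ranked.iloc[0]["scheme"])
    return chosen, table, {"reports": reports, "references": references}
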