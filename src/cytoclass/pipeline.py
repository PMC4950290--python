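"""One reproducible end-to-end run.

Orchestrates simulate → qc → discretize → cluster → stability → associate
with a single master seed, writing every stage artifact (CSV/JSON) into
an output directory. All randomness is drawn from named substreams of the
master seed, so adding a stage never perturbs the streams of earlier
stages, and two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from pathlib import Path

import pandas as pd
import yaml

from cytoclass import association, qc, simulate
from cytoclass.discretize import apply_discretizer, fit_discretizer
from cytoclass.stability import ClusteringConfig, cluster_scheme, select_discretization

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2^31)."""
    return (master_seed * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``input_csv`` points at an existing cohort table, or
    ``cohorts`` lists per-cohort simulation settings (dicts of
    :func:`cytoclass.simulate.default_config` overrides; at minimum
    ``n_subjects`` and ``cohort``). The analysis itself always runs on the
    merged table; a per-cohort class-proportion table is emitted so
    cohort-specific structure remains visible.
    """

    outdir: str = "results/run"
    seed: int = 0
    input_csv: str | None = None
    cohorts: list = dataclasses.field(
        default_factory=lambda: [
            {"n_subjects": 268, "cohort": "COHORT_A"},
            {"n_subjects": 1374, "cohort": "COHORT_B"},
        ]
    )
    schemes: tuple = ("binary", "tertile", "quartile")
    bootstrap_B: int = 100
    k: int | None = None
    k_max: int = 8
    folds: int = 10
    n_restarts: int = 10
    tol: float = 1e-6
    max_iter: int = 500
    lod_threshold: float = 10.0
    jaccard_tau: float = 0.8
    m_tests: int | None = None

    def clustering_config(self) -> ClusteringConfig:
        return ClusteringConfig(
            k=self.k,
            k_max=self.k_max,
            folds=self.folds,
            n_restarts=self.n_restarts,
            tol=self.tol,
            max_iter=self.max_iter,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schemes"] = list(self.schemes)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "schemes" in d:
            d["schemes"] = tuple(d["schemes"])
        return cls(**d)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output location is not
        part of the scientific configuration)."""
        d = self.to_dict()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclasses.dataclass
class RunReport:
    outdir: Path
    artifacts: dict
    summary: dict


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage in order; see module docstring.

    Artifacts: ``cohort.csv``, ``exclusions.csv``, ``responders.csv``,
    ``scheme_comparison.csv``, ``stability_<scheme>.json``, ``codes.csv``,
    ``scheme.json``, ``model.json``, ``cv_table.csv``,
    ``assignments.csv``, ``class_sizes.csv``, ``class_by_cohort.csv``,
    ``table1.csv``, ``table2.csv``, ``summary.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    summary: dict = {"seed": config.seed, "config_hash": config.config_hash()}

    # -- stage 1: cohort ----------------------------------------------------
    if config.input_csv:
        cohort = pd.read_csv(config.input_csv)
        logger.info("loaded cohort from %s: %d subjects", config.input_csv, len(cohort))
    else:
        parts = []
        for i, spec in enumerate(config.cohorts):
            cfg = simulate.default_config(
                seed=stage_seed(config.seed, f"simulate:{spec.get('cohort', i)}"), **spec
            )
            parts.append(simulate.generate_cohort(cfg))
        cohort = pd.concat(parts, ignore_index=True)
        logger.info("simulated %d subjects across %d cohorts", len(cohort), len(parts))
    _write_csv(cohort, outdir / "cohort.csv")
    artifacts["cohort"] = outdir / "cohort.csv"
    summary["n_subjects"] = int(len(cohort))

    # -- stage 2: QC + net responses ----------------------------------------
    qc_result = qc.qc_filter(cohort)
    _write_csv(qc_result.excluded, outdir / "exclusions.csv")
    artifacts["exclusions"] = outdir / "exclusions.csv"
    responders = qc.net_responses(
        cohort, threshold=config.lod_threshold, subject_ids=qc_result.included
    )
    _write_csv(responders, outdir / "responders.csv")
    artifacts["responders"] = outdir / "responders.csv"
    summary["n_included"] = int(len(responders))
    summary["n_excluded"] = int(qc_result.n_excluded)
    summary["exclusion_reasons"] = (
        qc_result.excluded["reason"].value_counts().to_dict() if qc_result.n_excluded else {}
    )
    logger.info("QC: %d included / %d excluded", summary["n_included"], summary["n_excluded"])

    # -- stage 3: scheme selection by bootstrap stability ---------------------
    ccfg = config.clustering_config()
    chosen, comparison, extras = select_discretization(
        responders,
        schemes=config.schemes,
        config=ccfg,
        B=config.bootstrap_B,
        seed=stage_seed(config.seed, "stability"),
        jaccard_tau=config.jaccard_tau,
    )
    _write_csv(comparison, outdir / "scheme_comparison.csv")
    artifacts["scheme_comparison"] = outdir / "scheme_comparison.csv"
    for name, report in extras["reports"].items():
        p = outdir / f"stability_{name}.json"
        report.to_json(p)
        artifacts[f"stability_{name}"] = p
    summary["chosen_scheme"] = chosen
    summary["ari_median_by_scheme"] = {
        name: rep.ari_median for name, rep in extras["reports"].items()
    }
    logger.info("scheme selected by stability: %s", chosen)

    # -- stage 4: final clustering under the chosen scheme --------------------
    # refit at a dedicated seed so the final model does not depend on which
    # other schemes were screened
    ref = cluster_scheme(responders, chosen, ccfg, seed=stage_seed(config.seed, "cluster"))
    _write_csv(ref.codes, outdir / "codes.csv")
    artifacts["codes"] = outdir / "codes.csv"
    with open(outdir / "scheme.json", "w") as fh:
        json.dump(ref.scheme.to_dict(), fh, indent=2, sort_keys=True)
    artifacts["scheme"] = outdir / "scheme.json"
    ref.model.to_json(outdir / "model.json")
    artifacts["model"] = outdir / "model.json"
    if ref.cv_table is not None:
        _write_csv(ref.cv_table, outdir / "cv_table.csv")
        artifacts["cv_table"] = outdir / "cv_table.csv"
    _write_csv(ref.assignment, outdir / "assignments.csv")
    artifacts["assignments"] = outdir / "assignments.csv"
    summary["k_responder_classes"] = int(ref.model.k)
    summary["n_class0"] = int(len(ref.class0_ids))

    labelled = cohort.merge(
        ref.assignment[["subject_id", "hard_label"]], on="subject_id", how="inner"
    )
    sizes = (
        labelled["hard_label"].value_counts().sort_index().rename_axis("class_id").reset_index(name="n")
    )
    sizes["pct"] = 100.0 * sizes["n"] / sizes["n"].sum()
    _write_csv(sizes, outdir / "class_sizes.csv")
    artifacts["class_sizes"] = outdir / "class_sizes.csv"
    summary["class_sizes"] = dict(zip(sizes["class_id"].astype(int), sizes["n"].astype(int)))

    by_cohort = (
        pd.crosstab(labelled["hard_label"], labelled["cohort"], normalize="columns") * 100.0
    )
    by_cohort = by_cohort.rename_axis("class_id").reset_index()
    _write_csv(by_cohort, outdir / "class_by_cohort.csv")
    artifacts["class_by_cohort"] = outdir / "class_by_cohort.csv"

    # -- stage 5: association tables -----------------------------------------
    responders_out = responders.merge(
        ref.assignment[["subject_id", "hard_label"]], on="subject_id", how="inner"
    )
    table1 = association.cytokine_outcome_ranks(responders_out)
    _write_csv(table1, outdir / "table1.csv")
    artifacts["table1"] = outdir / "table1.csv"
    table2 = association.class_outcome_table(
        labelled, reference_class=0, m_tests=config.m_tests
    )
    _write_csv(table2, outdir / "table2.csv")
    artifacts["table2"] = outdir / "table2.csv"

    summary["stage_counts"] = {
        "simulated_or_loaded": summary["n_subjects"],
        "qc_included": summary["n_included"],
        "responders_clustered": int(len(ref.codes)),
        "class0": summary["n_class0"],
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    artifacts["summary"] = outdir / "summary.json"
    return RunReport(outdir=outdir, artifacts=artifacts, summary=summary)
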