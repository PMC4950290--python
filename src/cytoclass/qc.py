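"""Exclusion rules and net HDM responses.

Two rules mirror the cohort studies' participant flow: subjects whose
PBMCs show no positive net response to the PHA mitogen control are
quality-control failures, and subjects flagged for inadequate viable cell
numbers or with missing cytokine values cannot be analysed. The remaining
subjects are reduced to net (medium-subtracted) HDM responses with a
per-cytokine positivity call at the assay detection limit.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from cytoclass.simulate import CYTOKINES

logger = logging.getLogger(__name__)

#: default positivity threshold: the 10 pg/ml assay limit of detection
LOD_THRESHOLD = 10.0

REASONS = ("pha_negative", "inadequate_cells", "missing_data")

_REQUIRED = [f"{cond}_{cyt}" for cond in ("medium", "pha", "hdm") for cyt in CYTOKINES]


@dataclasses.dataclass
class QCResult:
    """Partition of the input subjects into included and excluded.

    ``excluded`` is a DataFrame with columns ``subject_id`` and ``reason``
    (one of :data:`REASONS`). Included and excluded ids are disjoint and
    jointly cover the input.
    """

    included: list
    excluded: pd.DataFrame

    @property
    def n_included(self) -> int:
        return len(self.included)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def qc_filter(cohort: pd.DataFrame) -> QCResult:
    """Apply the exclusion rules to a raw cohort table.

    Precedence: missing data, then the ``inadequate_cells`` flag (if the
    column is present), then PHA negativity — a subject is PHA-negative
    when the net PHA response (PHA − medium) is ≤ 0 for *all* four
    cytokines, i.e. the positive control elicited nothing.
    """
    if cohort.empty:
        logger.warning("qc_filter received an empty cohort")
        return QCResult(included=[], excluded=pd.DataFrame(columns=["subject_id", "reason"]))

    ids = cohort["subject_id"].to_numpy()
    missing = cohort[_REQUIRED].isna().any(axis=1).to_numpy()
    if "inadequate_cells" in cohort.columns:
        inadequate = cohort["inadequate_cells"].fillna(False).astype(bool).to_numpy()
    else:
        inadequate = np.zeros(len(cohort), dtype=bool)

    pha = cohort[[f"pha_{c}" for c in CYTOKINES]].to_numpy(dtype=float)
    medium = cohort[[f"medium_{c}" for c in CYTOKINES]].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        pha_negative = np.all((pha - medium) <= 0, axis=1)
    pha_negative &= ~missing  # cannot call PHA status on incomplete rows

    reason = np.full(len(cohort), "", dtype=object)
    reason[pha_negative] = "pha_negative"
    reason[inadequate] = "inadequate_cells"
    reason[missing] = "missing_data"

    excluded_mask = reason != ""
    excluded = pd.DataFrame(
        {"subject_id": ids[excluded_mask], "reason": reason[excluded_mask]}
    ).reset_index(drop=True)
    included = list(ids[~excluded_mask])
    logger.info(
        "QC: %d subjects in, %d included, %d excluded (%s)",
        len(cohort),
        len(included),
        len(excluded),
        excluded["reason"].value_counts().to_dict() if len(excluded) else {},
    )
    return QCResult(included=included, excluded=excluded)


def net_responses(
    cohort: pd.DataFrame,
    threshold: float = LOD_THRESHOLD,
    subject_ids: Sequence | None = None,
) -> pd.DataFrame:
    """Net HDM responses and positivity calls for (a subset of) a cohort.

    Returns one row per subject with columns ``net_<cyt>`` (HDM − medium,
    signed), ``positive_<cyt>`` (net strictly greater than ``threshold``)
    and ``any_positive``. Rows with missing HDM or medium values are
    dropped (they belong in the QC exclusion ledger, not here).
    """
    df = cohort
    if subject_ids is not None:
        df = df[df["subject_id"].isin(set(subject_ids))]
    needed = [f"{cond}_{cyt}" for cond in ("medium", "hdm") for cyt in CYTOKINES]
    df = df.dropna(subset=needed)

    out = pd.DataFrame({"subject_id": df["subject_id"].to_numpy()})
    if "cohort" in df.columns:
        out["cohort"] = df["cohort"].to_numpy()
    pos_cols = []
    for cyt in CYTOKINES:
        net = df[f"hdm_{cyt}"].to_numpy(dtype=float) - df[f"medium_{cyt}"].to_numpy(dtype=float)
        out[f"net_{cyt}"] = net
        out[f"positive_{cyt}"] = net > threshold
        pos_cols.append(f"positive_{cyt}")
    out["any_positive"] = out[pos_cols].any(axis=1)
    # carry outcome / truth columns through when present
    for col in ("wheeze", "asthma", "spt_mm", "ige_kul", "true_class"):
        if col in df.columns:
            out[col] = df[col].to_numpy()
    return out.reset_index(drop=True)
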