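"""Ordinal coding of skewed net cytokine responses.

The net responses are heavily right-skewed, so before clustering they are
discretized. Three schemes are supported, named by their total number of
levels including the "negative responder" code 0:

* ``binary`` — 0 = negative, 1 = positive (2 levels, no cutpoints);
* ``tertile`` — 0 = negative, 1 = low, 2 = high (the positive responders
  are split at their per-cytokine median);
* ``quartile`` — 0 = negative, 1 = low, 2 = medium, 3 = high (positives
  split at their per-cytokine tertiles).

Code 0 is reserved for non-positive responses; positive values are binned
into equal-frequency groups using quantiles computed over positive
responders only, per cytokine. (The alternative reading — quantiles over
the full value distribution — is available via ``positives_only=False``.)
Subjects negative for every cytokine never enter the clustering feature
set: they are routed to Class 0 a priori.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from cytoclass.simulate import CYTOKINES

SCHEME_LEVELS = {"binary": 2, "tertile": 3, "quartile": 4}

CODE_COLUMNS = [f"{cyt}_code" for cyt in CYTOKINES]


@dataclasses.dataclass
class DiscretizationScheme:
    """Fitted cutpoints for one scheme.

    ``cutpoints[cyt]`` holds the strictly increasing boundaries between
    the positive bins for that cytokine (empty for ``binary``). A value v
    receives code ``1 + #{cut < v}`` if positive, else 0, so ties at a
    cutpoint fall into the lower bin and values outside the fitted range
    land in the boundary bins.
    """

    name: str
    levels: int
    cutpoints: dict[str, np.ndarray]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "levels": self.levels,
            "cutpoints": {c: np.asarray(v).tolist() for c, v in self.cutpoints.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscretizationScheme":
        return cls(
            name=d["name"],
            levels=int(d["levels"]),
            cutpoints={c: np.asarray(v, dtype=float) for c, v in d["cutpoints"].items()},
        )


def fit_discretizer(
    responders: pd.DataFrame,
    scheme: str = "tertile",
    positives_only: bool = True,
) -> DiscretizationScheme:
    """Fit per-cytokine equal-frequency cutpoints for ``scheme``.

    ``responders`` is the output of :func:`cytoclass.qc.net_responses`.
    Requires at least ``levels - 1`` positive values per cytokine.
    Duplicate quantile boundaries (heavy ties) are collapsed with a
    warning, merging the affected bins.
    """
    if scheme not in SCHEME_LEVELS:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {sorted(SCHEME_LEVELS)}")
    levels = SCHEME_LEVELS[scheme]
    n_pos_bins = levels - 1
    cutpoints: dict[str, np.ndarray] = {}
    for cyt in CYTOKINES:
        net = responders[f"net_{cyt}"].to_numpy(dtype=float)
        if positives_only:
            vals = net[responders[f"positive_{cyt}"].to_numpy(dtype=bool)]
        else:
            vals = net
        if len(vals) < n_pos_bins:
            raise ValueError(
                f"too few positive values for {cyt!r}: {len(vals)} < {n_pos_bins} "
                f"required for scheme {scheme!r}"
            )
        if n_pos_bins == 1:
            cuts = np.empty(0)
        else:
            qs = np.arange(1, n_pos_bins) / n_pos_bins
            cuts = np.quantile(vals, qs)
            uniq = np.unique(cuts)
            if len(uniq) < len(cuts):
                warnings.warn(
                    f"duplicate cutpoints for {cyt!r} collapsed "
                    f"({len(cuts)} -> {len(uniq)}); bins merged",
                    stacklevel=2,
                )
                cuts = uniq
        cutpoints[cyt] = cuts
    return DiscretizationScheme(name=scheme, levels=levels, cutpoints=cutpoints)


def apply_discretizer(
    scheme: DiscretizationScheme,
    responders: pd.DataFrame,
) -> tuple[pd.DataFrame, list]:
    """Code every responder and route all-negative subjects to Class 0.

    Returns ``(codes, class0_ids)``: ``codes`` has one row per subject
    with at least one positive cytokine (columns ``subject_id``,
    ``il5_code`` … ``ifng_code``, ``scheme``); ``class0_ids`` lists the
    subjects with no positive response, excluded from clustering.
    """
    any_pos = responders["any_positive"].to_numpy(dtype=bool)
    class0_ids = list(responders.loc[~any_pos, "subject_id"])
    pos_df = responders[any_pos]
    out = pd.DataFrame({"subject_id": pos_df["subject_id"].to_numpy()})
    for cyt in CYTOKINES:
        net = pos_df[f"net_{cyt}"].to_numpy(dtype=float)
        positive = pos_df[f"positive_{cyt}"].to_numpy(dtype=bool)
        cuts = scheme.cutpoints[cyt]
        # code = 1 + number of cutpoints strictly below the value, so a tie
        # at a cutpoint falls into the lower bin
        codes = np.where(positive, 1 + (net[:, None] > cuts[None, :]).sum(axis=1), 0)
        out[f"{cyt}_code"] = codes.astype(int)
    out["scheme"] = scheme.name
    return out.reset_index(drop=True), class0_ids


def codes_matrix(codes: pd.DataFrame) -> np.ndarray:
    """(n, 4) float matrix of the ordinal codes in canonical cytokine order."""
    return codes[CODE_COLUMNS].to_numpy(dtype=float)
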