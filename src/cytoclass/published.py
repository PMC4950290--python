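"""Published class-by-outcome cells from the merged MAAS/Raine analysis.

The original two-cohort study reported, for each cytokine class, the
number of children with a non-missing outcome and the percentage positive
("n (% positive)" cells), alongside odds-ratio columns against the
nonresponder Class 0. These printed cells are the only public record of
the class-level results (the underlying cohort data are not deposited),
so they serve as inputs for the count-exact worked examples: the integer
counts are reconstructed from each cell with
:func:`cytoclass.association.reconstruct_counts` and the odds ratios are
recomputed from the resulting 2×2 tables.

Recomputing the table reveals an internal inconsistency of the published
version: the printed OR columns are rotated relative to the count
columns. The OR printed under *asthma* matches the wheeze counts, the OR
printed under *SPT* matches the IgE counts, and the OR printed under
*IgE* matches the SPT counts; several asthma cells admit no integer
count at the printed rounding at all. This module therefore exposes the
count-consistent pairings — the reproducible quantities — via
:data:`COUNT_CONSISTENT_ORS`.
"""

from __future__ import annotations

from cytoclass.association import TwoByTwo, reconstruct_counts

#: class id -> outcome -> (n with non-missing outcome, % positive), as printed
CELLS = {
    0: {"wheeze": (883, 9.9), "asthma": (857, 6.8), "spt": (875, 16.2), "ige": (890, 22.4)},
    1: {"wheeze": (48, 16.7), "asthma": (47, 10.6), "spt": (49, 14.3), "ige": (49, 20.4)},
    2: {"wheeze": (53, 9.4), "asthma": (52, 9.6), "spt": (52, 21.2), "ige": (56, 26.8)},
    3: {"wheeze": (344, 15.1), "asthma": (336, 11.2), "spt": (340, 32.4), "ige": (343, 45.8)},
    4: {"wheeze": (74, 21.6), "asthma": (69, 22.1), "spt": (72, 48.6), "ige": (76, 57.9)},
    5: {"wheeze": (197, 35.0), "asthma": (192, 28.5), "spt": (199, 76.4), "ige": (197, 87.8)},
}

#: published class sizes (class id -> n), 1642 children in total
CLASS_SIZES = {0: 905, 1: 49, 2: 56, 3: 351, 4: 77, 5: 204}

#: (class id, outcome) -> printed OR and CI that the reconstructed counts
#: reproduce (note the column rotation documented in the module docstring)
COUNT_CONSISTENT_ORS = {
    (5, "wheeze"): (4.93, 3.41, 7.11),
    (5, "ige"): (25.02, 15.87, 39.45),
    (3, "ige"): (2.93, 2.24, 3.81),
    (4, "ige"): (4.77, 2.94, 7.73),
    (4, "spt"): (4.88, 2.97, 8.01),
}


def published_two_by_two(class_id: int, outcome: str, reference_class: int = 0) -> TwoByTwo:
    """2×2 table of a published cell against the reference class, with
    integer counts reconstructed from the printed "n (%)" values."""
    n_e, pct_e = CELLS[class_id][outcome]
    n_r, pct_r = CELLS[reference_class][outcome]
    a = reconstruct_counts(n_e, pct_e)
    c = reconstruct_counts(n_r, pct_r)
    return TwoByTwo(a=a, b=n_e - a, c=c, d=n_r - c)
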