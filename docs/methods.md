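# Methods

`cytoclass` reimplements, as a tested pipeline, a latent-class analysis of
PBMC cytokine responses to house-dust-mite (HDM) allergen: per-subject
supernatant concentrations of IL-5, IL-13, IL-10 and IFN-γ measured under
a medium control, a PHA positive control and HDM stimulation are reduced
to net responses, discretized, clustered with a Gaussian mixture, checked
for bootstrap stability, and related to clinical outcomes (current
wheeze, current asthma, HDM sensitization by skin-prick test and by
specific IgE). Because the underlying birth-cohort data (MAAS, Raine) are
not publicly deposited, a synthetic-cohort generator is a first-class
component: it defines the study conditions under which every stage is
tested.

## Pipeline model and assumptions

**QC and net responses.** A subject is excluded when any cytokine value
is missing, when flagged for inadequate viable cells, or when the net PHA
response (PHA − medium) is ≤ 0 for all four cytokines ("PHA-negative":
the positive control elicited nothing, so a null HDM response is
uninterpretable). Net HDM response is HDM − medium per cytokine, kept
signed; a response is *positive* when the net value strictly exceeds the
10 pg/ml assay limit of detection (LOD). Whether the LOD should apply
before or after medium subtraction is not determinable from the source
material; we apply it to the net value and expose the threshold as a
parameter.

**Class 0.** Subjects with no positive net response for any cytokine are
assigned a priori to a nonresponder class (Class 0) and never enter the
mixture fit. A k-component responder model therefore yields k+1 analysis
classes.

**Discretization.** Net responses are heavily right-skewed, so
clustering operates on ordinal codes. Scheme names count total levels
including the negative code 0: binary (0/1), tertile (0/low/high),
quartile (0/low/medium/high). Positive values are split into
equal-frequency bins by quantiles computed over positive responders
only, per cytokine (the alternative — quantiles over all values — exists
behind `positives_only=False`). This "levels" reading (tertile = 2
positive bins) follows the schemes' own level naming rather than
statistical tertiles of the full distribution. Ties at a cutpoint fall
into the lower bin; duplicate cutpoints are collapsed with a warning;
values outside the fitted range go to the boundary bin. Cutpoints are
fitted on the merged responder pool when cohorts are merged.

**Mixture model.** Codes are treated as numeric and modelled as a
k-component Gaussian mixture with diagonal covariance, fitted by EM.
Defaults: 10 random restarts (k-means++-style seeding — distance-weighted
choice of k data points, jittered, with a diffuse global-sd start),
absolute log-likelihood tolerance 1e-6, at most 500 iterations, and a
standard-deviation floor of 1e-6 code units. The floor keeps point-mass
components (all members sharing one code vector) finite; because the
floored M-step is still the constrained maximizer, EM monotonicity holds
and is asserted (with a scale-aware 1e-8 tolerance) on every fit. The
best restart by final training log-likelihood wins. Components are
renumbered in ascending (mean IL-13, mean IL-5) order so the last class
is reproducibly the high-Th2 class.

**Number of classes.** Forward search with 10-fold cross-validation: k
grows from 1 while the mean held-out log-likelihood per observation
improves by more than 1e-6, and stops at the first non-improving k
(capped at 8 by default). Fold fits use 3 restarts (the score averages
over folds); the table of per-k CV scores is reported even when the
search stops early. On discretized data the sd floor interacts with this
search: a collapsed component inflates the held-out likelihood of its
own cell but occasionally devastates a fold (a held-out subject one code
away receives log-density ~ −10^11), and this brake — not a smooth
information criterion — is what ends the search. This mirrors the
behaviour of EM/CV clustering tools with a minimum-sd safeguard on
ordinal data; the selected k is therefore noticeably seed-dependent on
discrete codes (see Limitations).

**Assignment.** Subjects take the class with the highest posterior
probability; exact ties break toward the lowest class index. Class 0
subjects carry a degenerate posterior.

**Stability.** For each of B=100 bootstrap resamples of the subjects,
the mixture is refitted (cutpoints reused from the reference fit and k
held at the reference k by default; both refittable per config), *all*
original subjects are reassigned under the bootstrap model, and the
agreement with the reference partition is scored by the Hubert–Arabie
adjusted Rand index, with Class 0 included as an immovable class
(excludable via `include_class0=False`; inclusion mechanically raises
ARI because 55% of subjects can never move). Per-cluster *support* is
the fraction of runs in which some bootstrap cluster has exactly the
reference cluster's member set — deliberately stringent — with a relaxed
maximum-Jaccard ≥ 0.8 criterion reported alongside. Scheme selection
runs this per candidate scheme and takes the highest median ARI, ties
toward fewer levels.

**Associations.** Mann–Whitney U tests (midranks for ties; exact
enumeration over rank assignments when both groups have ≤ 8 members,
tie-corrected normal approximation otherwise) compare net cytokine
levels between outcome groups, reporting group mean ranks. Class-level
risk is an odds ratio of each class against Class 0 from the 2×2 table,
OR = ad/bc, with Wald 95% CI exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)) and a
two-sided Wald p; a zero cell triggers the Haldane–Anscombe +0.5
correction. For a single binary contrast this closed form equals the
univariate logistic-regression MLE (property-tested against an
iteratively fitted GLM). Bonferroni adjustment is min(1, m·p) with m
defaulting to the number of rows in the emitted table; the family size
used in the original report is not recoverable from its adjusted values.
Outcome denominators vary by row (missing outcomes are dropped row-wise).
The SPT ≥ 3 mm and IgE > 0.35 kU/L sensitization rules are applied at
table-building time from the continuous wheal/titre values.

**Printed-table inversion.** `reconstruct_counts(n, pct)` recovers the
unique integer x with round(100·x/n, 1) = pct (half-up rounding),
raising explicit errors when no or several solutions exist. Recomputing
the published class-by-outcome table this way shows its printed OR
columns are rotated relative to its count columns: the OR printed under
asthma matches the wheeze counts (69/197 vs 87/883 → 4.93), the OR under
SPT matches the IgE counts (173/197 vs 199/890 → 25.03, printed 25.02),
and the OR under IgE matches the SPT counts (→ 16.69); several asthma
cells admit no integer count at the printed rounding. The package
reports count-consistent values.

## Synthetic-cohort generator

The generator draws, per subject: a latent class from the six-class
weight vector (905/49/56/351/77/204 normalized — a 55% nonresponder
class); per-cytokine positive net responses by class-conditional
probability; log-normal magnitudes given positive; censoring of values
≤ 10 pg/ml to 0 (so the stored HDM concentration equals the medium
control there — no sentinel needed); a small log-normal medium control
(median 2 pg/ml); a strongly positive PHA column except for a
`pha_fail_rate` (default 1%) of subjects whose PHA equals medium; and
class-conditional clinical outcomes.

Key calibration choices (none of the magnitude parameters are published;
these are this package's own realistic choices, fixed once):

* **Response probabilities** follow the published per-class co-expression
  counts where stated (e.g. IL-13 in 20/49 of the IL-10 class, 37/56 of
  the IFN-γ class; IFN-γ/IL-10 in ~45% of the high-Th2 class), with
  "few" rendered as 4–5%.
* **Magnitudes**: positive responses are log-normal (the simplest
  censored-skew model). The IL-13-medium class holds the *lowest*
  positive IL-13 levels (log-mean 3.4 ≈ 30 pg/ml) — it spans roughly the
  bottom half of IL-13 positives, matching its share (351 of ~668) — so
  the tertile cut falls at its boundary; the high-Th2 class is highest
  (log-mean 6.0 ≈ 400 pg/ml); log-sd 0.6 throughout.
* **IL-5/IL-13 coupling**: one shared standard-normal factor per subject
  (loading √ρ, default ρ = 0.8) drives both the probit positivity calls
  and the log-magnitudes of IL-5 and IL-13, so log-scale Pearson R²
  among double responders equals ρ and exceeds the 0.35 floor reported
  for the real cohorts whenever ρ ≥ 0.75. Other cytokines are
  independent given class.
* **Outcomes**: class-conditional prevalences follow the published
  percentages. Asthma is drawn only among wheezers with conditional
  probability min(1, p_asthma/p_wheeze) — for the IFN-γ class the
  published asthma prevalence (9.6%) slightly exceeds its wheeze
  prevalence (9.4%, different denominators), so that class's simulated
  asthma marginal is capped at its wheeze prevalence. SPT wheal and IgE
  titre are continuous (wheal: uniform < 3 mm or 3 mm + gamma;
  titre: 0.35 + log-normal if sensitized, a log-normal squashed into
  (0, 0.35) otherwise) so the threshold rules are genuinely exercised.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: age effects and cohort batch effects; assay
noise and inter-plate variation; within-class heterogeneity beyond
class-conditional independence (real co-expression scatter is messier
than a latent-cell model); and any feature of the real joint
distribution not derivable from the published class descriptions.

## Numerical choices

Log-densities are computed via a two-GEMM expansion of the diagonal
Gaussian quadratic form, falling back to the exact centered form
whenever any sd is below 1e-3 (the expansion cancels catastrophically
near the sd floor). Posteriors use log-sum-exp. Empty components keep
their previous parameters with weight → 0. Degenerate Mann–Whitney
inputs (all values identical) return p = 1 with a flag. Quantile
cutpoint ties collapse with a warning, merging bins. All pipeline
randomness derives from one master seed through named per-stage
substreams (CRC-based), so adding a stage never perturbs earlier
streams and two runs with one config are byte-identical.

## Problem sizes

The shipped analysis and test configurations use a merged synthetic
cohort of 1642 subjects (268 + 1374), B = 100 bootstrap refits for the
headline stability comparison (smaller B in unit tests), 10-fold CV with
k ≤ 8, and 20-seed replication (n = 700) for the mixture-recovery study.
These sizes reproduce the scale of the original analysis while keeping
a full run in the minutes range on one CPU.

## Known limitations and negative findings

* **Chance-level stability is not zero.** Bootstrap partitions of
  structureless data still share the quantile-code lattice, which alone
  sustains ARI ≈ 0.2 (instead of ~0 for unconstrained labelings). Tests
  assert noise stability < 0.35 versus ≥ 0.95 for separated structure.
* **Binary coding of the synthetic cohort is stable.** Under this
  generator the published class patterns are largely separable from
  positivity patterns alone (the IL-13-only and IL-5+IL-13 classes
  occupy distinct binary cells), so the reported instability of the
  binary solution on real data does not emerge at any probed setting
  (fixed or re-selected k, Class 0 in or out, n = 119–1642). The
  stability-based preference for tertile coding is demonstrated instead
  on a constructed cohort whose classes differ only through response
  levels; on real-world data with messier co-expression the published
  ordering may well hold, but it is not implied by the published class
  structure.
* **k selection on ordinal codes is fragile.** The CV forward search's
  stopping point depends on the collapse brake described above; selected
  k varies across seeds (typically 3–8 on the calibrated cohort).
* ORs are unadjusted single contrasts (as in the source analysis); no
  confidence intervals are attached to ARI summaries.
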