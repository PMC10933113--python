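# Methods

`skinsens` implements the computational chain used to identify skin
sensitizers from a quantitative high-throughput screen (qHTS): plate
normalization and Hill-curve activity calling, per-assay decision rules
from the OECD test guidelines, three defined approaches (2o3, ITSv2,
STS) for hazard and GHS potency, chemotype-based prioritization, and a
fingerprint QSAR modeling grid. This note records the models, the
parameters that matter, and the design choices made where the design
was genuinely open.

## Concentration-response model

Raw well signals are normalized per plate run to percent activity,

    % activity = (V_compound − V_DMSO) / V_DMSO × 100,

where `V_DMSO` is the median of that run's DMSO vehicle wells. Each
compound × run titration is fitted by least squares to the
four-parameter Hill equation

    y(x) = S0 + (Sinf − S0) / (1 + (AC50 / x)^h),

parameterized in log10(AC50) with bounds AC50 ∈ [min conc/10,
max conc×10] and h ∈ [0.3, 8], from three AC50 starting points spread
across the tested range (the best of the three by SSE is kept).
Signed efficacy is Sinf − S0; its sign distinguishes activation from
inhibition.

**Curve classes and ranks.** The exact sub-thresholds of the original
curve-class scheme are not public in full, so the package fixes a
documented stand-in that preserves the scheme's testable properties
(ranks in [−9, 9], 0 = inactive, |rank| > 3 ⇔ reproducible
high-quality activity):

* class 4 (rank 0): no usable fit or |efficacy| < 30 %;
* class 1 (both asymptotes inside the tested range, i.e. the fitted
  response at each range end is within 10 % of |efficacy| of its
  asymptote): 1.1 if r² ≥ 0.9 and |efficacy| ≥ 80 %, else 1.2;
* class 3: the half-maximal concentration lies beyond the top tested
  concentration (response only at the highest dose);
* class 2 otherwise: 2.1/2.2 split as for class 1.

|rank| is 9/8 for class 1.1, 7/6 for 1.2, 5/4 for 2.1, 3/2 for 2.2
(high tier when |efficacy| ≥ 80 %), 1 for class 3 and 0 for class 4,
signed by direction. Within a class, larger |efficacy| never lowers
|rank|, and mirroring a curve about baseline negates its rank.

**Tri-run outcome.** A run is active when |rank| > 3. A compound is
active with ≥ 2 same-direction active runs, inactive with ≥ 2 class-4
runs and no active run, and inconclusive otherwise.

**KeratinoSens summaries.** On the normalized scale 100 % equals a
two-fold induction, so the 1.5-fold threshold is y = 50 %. EC1.5 is
solved on the fitted curve and clamped to the tested range; it is
absent when the curve never crosses. Imax reports the maximal observed
activity (the fitted maximum is emitted alongside, since either
convention is defensible). Reporter points measured at concentrations
where paired viability falls below 70 % of control can be masked
before fitting (`mask_cytotoxic_points`; threshold configurable).
Plate pattern correction beyond DMSO-median normalization is out of
scope.

## Assay call rules

| Assay | Guideline rule (positive iff) | Curve-rank rule |
|---|---|---|
| DPRA | cysteine depletion > 13.89 %, or mean(cys, lys) > 6.38 % | rank < −3 (depletion is inhibition mode) |
| KeratinoSens | fold induction crosses 1.5 (EC1.5 exists) at a non-cytotoxic dose | rank > 3 |
| hCLAT | CD86 RFI > 1.5 or CD54 RFI > 2.0 | — (single concentration) |
| IL-8 | fold ≥ 1.4 and 95 % CI lower bound > 1.0 | rank > 3 |

All inequalities follow the quoted wording strictly (boundary values
are negative). Negative depletions are clipped to 0 before comparison,
standard practice for DPRA measurement noise. The IL-8 confidence
interval is a two-sided t-interval on the mean fold across replicates
(the construction is not specified upstream; a t-interval is the
conventional choice for 2–3 replicates). Missing sources propagate as
`absent`, never coerced to negative. The two call criteria (guideline
vs curve rank) are computed independently; their concordance is an
output.

## Defined approaches

**2o3** calls a sensitizer on ≥ 2 positives among DPRA, KS, hCLAT and
a non-sensitizer on ≥ 2 negatives. With one source missing, the call
is made only when the two present sources agree (the upstream handling
is unstated; requiring agreement is the conservative completion).

**ITSv2** scores DPRA 0–3, hCLAT 0–3, and the in silico hazard
prediction 0–1, summed over available sources. The depletion bins
(mean: 6.38 / 22.62 / 42.47 %; cysteine-only: 13.89 / 23.09 / 98.24 %)
and MIT bins (≤ 10 / ≤ 150 / ≤ 5000 µg/mL) follow the score-based
defined-approach convention, anchored at the guideline thresholds
6.38/13.89 and the strong-depletion threshold 23.09 %. Totals map to
GHS: with 3 sources 6–7 → 1A, 2–5 → 1B, 0–1 → NC; with 2 sources
6 → 1A, 2–5 → 1B, 1 → inconclusive, 0 → NC; with fewer,
inconclusive. Out-of-domain in silico predictions count as absent. A
positive hCLAT without any concentration information cannot be scored
and is treated as an absent ITS source. Borderline ranges around the
thresholds are intentionally not implemented.

**STS**: hCLAT positive → 1A if MIT ≤ 10 µg/mL else 1B; when the
screen design provides no MIT (single concentration), a positive
hCLAT maps to 1B. hCLAT negative → 1B if DPRA positive, NC otherwise.

**Concordance analytics.** `da_venn` counts compounds positive in ≥ 1,
≥ 2, and all 3 DAs (ITS/STS positive = class 1A or 1B).
`potency_contingency` cross-tabulates ITS × STS GHS categories;
`percent_agreement` divides the diagonal by either the table total or
an explicit denominator. The distinction matters: at study scale, a
contingency table whose resolved cells sum to 255 yields the quoted
82 % agreement only against the full 288-compound denominator
(235/288 = 81.6 → 82; against 255 it would be 92 %). Both are
available; the full-set denominator is what the package reports in its
acceptance summary.

## Chemotype prioritization

Each compound carries ≥ 1 chemotype; the representative chemotype is
chosen by size band — 10–20 members first, then < 10, then > 20 —
with ties broken by larger cluster, then lexicographic id (the
upstream tie-break is unstated; determinism is required for testing).
The band *labels* quoted upstream ("large … < 10", "small … > 20")
contradict their sizes; the implementation follows the stated
preference order. Selection ranks candidates within clusters by AC50
ascending then |efficacy| descending; clusters of ≤ 2 members
contribute only compounds with AC50 < 10 µM and efficacy > 50 %;
quotas start at one per contributing cluster and grow proportionally
to cluster size (largest-remainder apportionment, capped by candidate
counts) until the requested total — 288 by default — is met. The
exact quota function used upstream is unstated; only the
proportionality principle is reproduced. The chemotype × assay
activity matrix is the arithmetic mean curve rank over members, with
sign cancellation reported rather than masked.

## QSAR modeling grid

Fingerprints are binary compound × feature matrices (729 features by
convention). The grid: stratified 70/30 split (exact sizes
round(n×0.7); 6,520 → 4,564/1,956); feature selection on the training
side only — two-sided Fisher exact test (p ≤ 0.01…0.05), per-feature
AUC (closed form (TPR + TNR)/2 for a binary feature, direction-folded
to max(AUC, 1−AUC) so depletion-type features survive; cutoffs
0.52…0.60), or top-10…50 by random-forest Gini or gradient-boosting
gain importance; rebalancing by down/up-sampling, SMOTE (k = 5
nearest-neighbor interpolation, fractional coordinates kept — tree and
kernel models tolerate them), or ROSE (per-class smoothed bootstrap
with Silverman bandwidths, balanced at the original sample size);
five classifier families — Bernoulli naive Bayes with Laplace
smoothing, a one-hidden-layer perceptron (√p hidden units, 500
iterations), random forest (100 trees), RBF SVM, and gradient-boosted
trees fixed at learning rate 0.01, max depth 3, column subsample 0.5.
SMOTE and ROSE are implemented in this package following their
published algorithms. A two-sided Fisher test is used (a one-sided
enrichment test would also be defensible); the per-feature AUC is
direction-folded by default — both are switchable. Repeated
stratified 3-fold cross-validation (default 20 repeats) reports
mean ± sd of AUC-ROC, balanced accuracy, and MCC per grid cell;
binary calls threshold the model score at 0.5 (or 0 for margin
scores). If a fold's selection is empty, the single best-ranked
feature is kept so every cell remains defined. External validation
runs the frozen model and feature set on the untouched holdout.

## Synthetic data: what it emulates and what it does not

The generators provide ground-truthed inputs at the study's stated
conditions: 15-point log dilutions over 0.0028–92 µM, three runs, 16
DMSO wells per run, an active fraction of 676/6520 ≈ 10.4 %, and
729-feature fingerprints.

* **Plates.** Actives follow Hill curves with S0 = 0, |efficacy| in
  40–150 % (activation with probability 0.7), slope in 0.8–3, and AC50
  log-uniform with a 20-fold margin from both range ends so the full
  transition is observable — making noise-free activity outcomes
  exactly recoverable. Noise is i.i.d. Gaussian on the % activity
  scale (default sd 5 %); the real screen's noise process (spatial
  plate patterns, heteroscedasticity, dispense artifacts) is unknown
  and not claimed.
* **Panels.** Generation works backwards from the ITS score table: a
  compound's class fixes the set of valid (DPRA, hCLAT, in silico)
  score decompositions — constrained so STS agrees (1A requires
  MIT ≤ 10; 1B excludes hCLAT score 3 and all-negative sources; NC is
  negative everywhere) — one is drawn uniformly, and quantitative
  values are sampled inside the corresponding bins. This guarantees
  exact noise-free recovery by both ITS and STS, which is what makes
  the DA engine testable; it does not reproduce the correlation
  structure of real assay batteries. `flip_noise` perturbs each source
  independently; `missingness` blanks the in silico (to out-of-domain)
  and hCLAT sources, the two limited in practice.
* **Fingerprints.** Enriched features multiply the Bernoulli odds by a
  stated odds ratio among actives; all other features are class-
  independent. Real chemotype bits are sparse, correlated, and
  hierarchical; passing tests demonstrate the statistics and the
  leakage-free pipeline, not real-data performance. In particular the
  published external AUC (≈ 0.8 on the real screen) is not a target of
  the synthetic world.
* **Chemotypes.** Cluster sizes are realized exactly from a requested
  histogram; multiplicity > 1 adds Poisson-distributed secondary
  memberships (which inflate realized sizes of receiving clusters).

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the
smallest sizes at which the checked properties are statistically
stable: 500-compound panels for DA recovery, 200 noisy titrations for
Hill recovery, 1,000 random 2×2 tables for the Fisher oracle, and a
600-compound / 100-feature fingerprint world with 20 label shuffles
for the null calibration (each shuffle re-randomizes labels so
dataset-level spurious correlations average out). Fisher p-values are
computed via `scipy.stats.fisher_exact` and verified against an
independent `math.comb` hypergeometric enumeration. Hill fits flag
`converged=False` on optimizer failure; flat series fit with
near-zero efficacy and classify inactive. Degenerate contingency or
empty call overlaps raise `MissingDataError` rather than returning
NaN.

## Known limitations

* The curve-class sub-thresholds and rank mapping are a documented
  stand-in, not a reproduction of the original supplement.
* The study-scale concordance counts (Venn 82/157/172, Tables of
  per-assay agreement, the 86 %/90 % criteria-concordance balanced
  accuracies, the 0.81 external AUC) depend on the real per-compound
  screening data and are not reproducible from synthetic inputs; the
  package instead verifies the properties those numbers rest on.
* hCLAT is modeled in single-concentration mode by default; MIT-aware
  scoring requires a concentration series (`hclat_mit`).
* RF uses 100 trees (library default) rather than the R default of
  500; at the tested scales the ranking of grid cells is insensitive
  to this, and runtime is not.
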