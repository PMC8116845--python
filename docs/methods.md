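# Methods

## Scope and data model

`decompscore` operates downstream of untargeted LC-HRMS processing: its
input is an aligned feature table (rows = compounds with neutral
monoisotopic mass in Da and retention time in minutes; columns =
samples; cells = peak areas in arbitrary units, gap-filled so absent
signals are zeros) plus a sensory table assigning each sample a 1–100
expert decomposition score and its design coordinates (product, quality
increment, extraction day). Raw-signal processing (alignment, grouping,
gap filling), MS² acquisition, and spectral-database searching are out
of scope.

## Differential selection

Samples are segregated at the regulatory boundary: score > 50 →
decomposed, score < 50 → nondecomposed. The rule is undefined at
exactly 50, so segregation raises an error there rather than guessing;
the synthetic generator likewise resamples any score that lands on 50.

Per compound, the volcano statistics are

* log₂FC = log₂[(mean(areas, decomposed) + ε) / (mean(areas,
  nondecomposed) + ε)], ε = `pseudo_area` (default 1 area unit), and
* a two-sided Welch (unequal-variance) *t*-test on log₂(area + ε),
  with the Welch–Satterthwaite degrees of freedom.

The selection keeps the `n_top` (default 100) lowest p-values among
compounds with |log₂FC| > 1. Both directions pass the filter because a
minority of real markers are *higher* in fresh samples. Design choices
worth stating:

* The upstream vendor software's volcano test is unspecified; Welch on
  log areas is the standard differential-abundance choice and is robust
  to unequal group variances. Tests cross-check it against an
  independent first-principles t/Welch–Satterthwaite computation.
* Zero variance in both groups with equal means gives p = 1 (no
  evidence), with different means p = 0 (the infinite-t limit).
* Ties in p at the selection boundary break by larger |log₂FC|, then
  lexicographic compound id, so selection is deterministic.
* By default selection runs on training samples only, preventing the
  held-out samples from influencing feature choice; a study-faithful
  all-samples mode is available (`selection_scope="all"`). Tests verify
  that perturbing test-sample areas never changes the panel.

## Train/test split

One third of the samples form the test set. The default rounds n/3 to
the nearest integer (half-up; 73 → 24, 56 → 19, 83 → 28, 70 → 23),
computed in exact rational arithmetic; a ceiling option exists. The
partition is a seeded permutation of the sorted sample ids, so it is
reproducible and independent of input order.

## Random Forest modeling

Both stages use a regression Random Forest (scikit-learn
`RandomForestRegressor`), default 2000 trees, seeded. Stage one fits on
all selected compounds; compounds are then ranked by permutation
importance (mean importance over 5 permutation repeats on the training
set, seeded; ties break by compound id). Permutation importance is
preferred to impurity importance because it is less biased for
correlated features.

Panel-size optimization refits a forest on the top-k ranked compounds
for each k in the grid (default exhaustive 1..100) and records
r_k = Pearson(training scores, out-of-bag predictions). OOB predictions
are used because the optimization metric's evaluation set is otherwise
ambiguous, and OOB tunes k without touching the test set. The chosen
k* is the smallest k attaining the maximal r_k; the final model is a
fresh forest on that panel. Predictions are tree-mean aggregates and
therefore always lie within the training-score range. OOB statistics
require every training sample to be out of bag at least once, which is
essentially guaranteed for ≥ 50 trees (the library warns below that).

Model bundles serialize to JSON: panel, optimization trace, split,
seeds, forest configuration, and the training matrix. The forest itself
is not pickled — loading a bundle refits it, which is exact because a
seeded forest is a deterministic function of (data, seed,
configuration). This keeps bundles portable, text-only and
version-tolerant at the cost of a refit on load.

## Evaluation

Modeled scores are classified with the same 50-point rule. A modeled
score of exactly 50 is called nondecomposed: both error definitions use
strict inequalities and leave 50 unassigned, and the conservative
choice is the regulatory-negative one. False positive = sensory < 50
with modeled > 50; false negative = the reverse. Rates are reported as
half-up-rounded percentages (1 decimal for rates, 0 for the
triplicate-range proportions, 3 for correlations — the print precisions
used in this application area). Correlation is Pearson's product-moment
r; it errors on constant vectors rather than returning NaN.

Triplicate reproducibility: portions with a third-day extraction are
identified by the generator's id convention (`…-d<day>` suffix), with a
fallback for other id schemes that groups rows by (product, increment,
shared sensory score) — valid because replicate extractions reuse the
portion's single pre-storage sensory assessment. Each group must have
exactly 3 rows; the statistic is range = max − min of the three modeled
scores, and the summary is the percentage of ranges ≤ 5, 10, 15 points,
overall and by low/middle/high state.

## Annotation

Matching is inclusive-window: |ppm| ≤ 5 with
ppm = 10⁶·(observed − reference)/reference, and |ΔRT| ≤ 0.2 min,
in neutral-mass space (the packaged 112-entry reference library prints
neutral monoisotopic masses; no adduct arithmetic is performed, so
callers must supply neutral masses). A compound inside several
reference windows yields all matches, unresolved, because isomeric and
closely related compounds can share a window; unmatched compounds are
reported with status `unknown`. The library records each entry's
confirmation level (reference-standard, spectral-database, unknown) and
direction (16 of 112 entries are higher in fresh samples).

## Synthetic-data generator

The generator emulates the study design so every downstream stage is
testable without instrument data, and emits ground truth for recovery
tests.

Design (defaults): 7 quality increments spanning fresh to advanced
decomposition, 5 portions per increment, duplicate extraction days, and
a third-day replicate of one portion from each of the low, borderline
and high increments ({1, ⌈n/2⌉, n}) → 73 sample records; an
8-increment product gives 83. Counts are configuration, not hard-coded
per product.

Sensory scores: increment means run linearly from 15 to 85 (straddling
the boundary, with the middle increment at the borderline, as the
controlled-spoilage protocol intends); portion scores are Gaussian
around the mean with sd 3 (analyst noise), clipped to [1, 100], exact
50s resampled. A portion's score is assessed once and shared by all its
extraction rows, because sensory evaluation precedes frozen storage and
extraction — replicate rows differ only analytically.

Feature table: `n_markers` = 100 responsive and `n_background` = 1900
non-responsive compounds (the magnitude of a real aligned table after
vendor processing). Marker expected area is
baseline · 2^(b·d(s)) with decomposition driver d(s) = (score − 50)/50 —
score-linked, not increment-linked, because the models are fit to
scores. Slopes b are signed (15% of markers decrease with
decomposition) with magnitudes drawn around the configured effect and
calibrated by bisection against the noiseless design trajectory so that
the *realized* decomposed-vs-nondecomposed mean |log₂FC| equals
`effect_log2fc` (default 3.0, a strong spoilage-marker contrast; an
uncalibrated slope would undershoot because borderline samples dilute
the group contrast). All compounds receive mean-one lognormal noise
(CV 0.2, typical peak-area repeatability) and a per-compound, per-day
lognormal batch factor (sd 0.1 on the log scale). Baselines are
log-uniform over 10⁵–10⁷ area units; synthetic masses/RTs are uniform
over 100–900 Da and 0.5–33 min.

What the generator does **not** emulate: correlated marker families
(real spoilage markers co-vary through shared metabolic pathways),
missingness beyond gap-filled zeros, RT drift, ionization suppression,
heteroscedastic low-abundance noise, and product-specific chemistry.
Passing recovery tests therefore demonstrates that the pipeline's
statistics behave correctly under the design's noise model — not that
any particular accuracy will be achieved on real instrument data.

A master seed fans out to per-product, per-stage seeds through
`numpy.random.SeedSequence` spawn keys (all derived seeds < 2³¹), so
one integer reproduces a whole multi-product run; the run manifest
records every derived seed and decision toggle, and excludes the output
path so reruns are byte-identical.

## Problem sizes used in the test suite

The suite exercises the generator at the full default scale (2000
compounds × 73 samples) for selection and recovery checks, but fits
forests at 100–300 trees with coarse k-grids; tree count only affects
the Monte-Carlo smoothness of ensemble estimates, not the planted
signal, and the package defaults (2000 trees, exhaustive k = 1..100)
remain those a production analysis would use. Recovery properties
(≥ 80% of planted markers in the top-100 selection, test-set r ≥ 0.95,
FP/FN each ≤ 5%) are checked over 5 seeds.

## Known limitations

* The per-product accuracy of the original application (r between
  0.971 and 0.999, 548/550 concordant test samples) depends on
  instrument data that is not publicly deposited; this package mirrors
  those behaviors on synthetic data only.
* Welch-on-log-areas is a documented substitute for the unspecified
  vendor volcano test, not a reconstruction of it.
* Annotation ignores MS² evidence entirely; a mass+RT window match is
  putative by construction.
* Forest refit-on-load makes bundle loading O(fit); for 2000 trees on
  ~50 training samples this is a few seconds.
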