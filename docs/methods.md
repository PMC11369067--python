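# Methods

This note documents the models, conventions and design choices behind
engraftkit, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Engraftment model

Engraftment is quantified over a per-recipient *donor-derived species set*:
the assigned donor's core species (detected at ≥ τ in at least
`min_core_samples` of the donor's longitudinal samples; default 6) that are
absent from **every** pre-FMT sample of the recipient. Using the union of
all pre-FMT samples (weeks 0 and 3 in the default layout) is the
conservative exclusion: one detection anywhere before FMT disqualifies a
species from being called engrafted. The absolute count 6 is the default
prevalence rule even though donors contribute unequal sample numbers (13 vs
14); a fractional rule is available (`min_prevalence`), with the absolute
count taking precedence.

Three metrics are computed per subject and window, then combined:

* **SEI** — median over window samples of the summed relative abundance of
  detected donor-derived species. Medians over an even number of values are
  the mean of the two central order statistics (numpy convention),
  everywhere in the package.
* **SEF** — fraction of the donor-derived set detected in at least one
  window sample. Detection is window-level on purpose: a species seen only
  at week 5 counts for the acute and overall windows, not the durable one.
  Subjects with an empty donor-derived set have undefined SEF; they keep
  their SEI and similarity values and are excluded from SEF-based medians.
* **Donor similarity** — per window sample, the median Aitchison distance to
  the donor's samples; per window, the median of those per-timepoint values
  (a pooled all-pairs median is available behind the `pooled` flag); the
  similarity is `baseline_distance / window_distance`, the reciprocal of the
  baseline-normalized distance, where the baseline is the recipient's
  latest pre-FMT sample (week 3, after pretreatment and bowel lavage). The
  reciprocal-of-normalized form realizes "inverse distance, high = more
  engraftment" in a single monotone quantity; an alternative order of
  operations would differ only by a per-subject positive constant and would
  not change any rank-based comparison.

**Total score.** Within each window, the cohort median SEF is the reference;
SEI and similarity are multiplied by `reference / own_median` so all three
medians coincide exactly (the normalization invariant is checked to 1e-9 in
the tests), then summed. The scales are returned (`ScoreNormalization`) and
written as a sidecar by the CLI so scores are reproducible and auditable. A
metric whose cohort median is zero cannot be rescaled; its contribution is
dropped with a warning rather than producing an infinite scale.

## Compositional machinery

The Aitchison distance is the Euclidean distance between centred log-ratio
(CLR) transforms. Zero handling: the composition is closed to sum 1,
zeros are replaced multiplicatively by a pseudocount, and the vector is
re-closed. The default pseudocount is τ/2 — a zero after thresholding means
"below the detection limit τ", and half the limit is the natural midpoint
imputation; a fixed pseudocount is configurable. Closing before replacement
makes the transform invariant to a positive rescaling of the input, which
the property suite verifies along with the metric axioms.

For a pairwise recipient–donor distance the species universe is the union
of species detected in the two samples, zero-filled (zeros then receive the
pseudocount). For a whole-table distance matrix (ordination, PERMANOVA) the
universe is instead the union over all samples in the table, so the matrix
is a true metric on a common space.

## Thresholding

The detection limit τ = 0.001 (0.1% relative abundance) is applied after
closing rows to sum 1. Sub-threshold mass is **discarded, not
redistributed**: row sums of the thresholded table report the retained
cumulative abundance per sample, which is itself a quantity of interest. A
`renormalize` flag re-closes rows for sensitivity analyses. Thresholding is
idempotent and presence everywhere in the package means "≥ τ after
thresholding".

## Clinical classification

The partial Mayo score sums stool frequency, rectal bleeding and physician
global assessment (each 0–3). The endoscopic subscore uses the 5-level
ordered scale 0 < 1a < 1b < 2 < 3; 1a and 1b both contribute 1 numerically
to the full Mayo but are distinct steps, so a 1b→1a change counts as an
endoscopic decrease for partial remission. The remission rule's "no
individual subscore above 2" is implemented literally even though a partial
Mayo ≤ 2 makes it nearly redundant; the cutoff is a parameter
(`max_subscore`) for users who prefer the stricter conventional reading.
Dropout for progressive disease forces "no response" at both assessment
weeks. The classifier is deterministic and total; an exhaustive truth-table
test checks it against an independent restatement of the rules over all
valid input combinations.

## Statistics

* **Fisher's exact test** is authored in-package with exact integer
  arithmetic (`math.comb`): the two-sided p sums hypergeometric
  probabilities of all tables with the observed margins whose point
  probability does not exceed the observed one. With integer weights the
  comparison is exact, so no floating tolerance is needed. The
  tail-doubling convention is available behind a flag. scipy's
  implementation serves as an independent oracle in the tests, never as the
  implementation.
* **Wilcoxon rank-sum**: exact null distribution when both groups have ≤ 12
  observations and the pooled data are tie-free; otherwise mid-ranks with
  the tie-corrected normal approximation. The method used is recorded in
  the result. Backed by `scipy.stats.mannwhitneyu`; a full-enumeration
  oracle verifies the exact branch.
* **Two-way ANOVA**: additive model with Type II sums of squares
  (statsmodels), matching the reporting of one factor's effect "controlling
  for" the other in an unbalanced two-arm, two-donor design. A
  zero-variance response short-circuits to F = 0, p = 1.
* **PERMANOVA**: scikit-bio's implementation (pseudo-F, p = (1 + #{F* ≥ F})
  / (1 + n_perm)) with an explicit seed for bit-reproducible permutation
  streams; default 999 permutations and Aitchison distances.
* **Diversity**: richness = species at ≥ τ; Shannon H = −Σ p ln p in natural
  log units over the detected sub-composition re-closed to 1.
* **Donor profiling**: complete-linkage hierarchical clustering on Euclidean
  distances between donors' mean family-level abundance profiles
  (scipy.cluster.hierarchy), checked against a brute-force agglomeration
  oracle.

## Synthetic cohort generator

The generator emulates the trial layout: 2 donors with 13 and 14 samples,
24 recipients sampled at weeks 0, 3 (pre-FMT) and 4, 5, 6, 7, 8, 10, 14
(post-FMT), donors alternating across recipients, a deterministic 12/12 arm
allocation, and a species pool of 500.

* **Base compositions** are log-normal (σ = 1.5) over each entity's species
  subset, clipped below at 3τ (0.003) and re-closed. The clip encodes that
  the generator models the *detectable* community: a species whose expected
  abundance sits below the detection limit is unobservable with the study's
  own threshold and is not a meaningful community member. Without it,
  shared species with sub-τ means flicker across the threshold and
  dominate the false-engraftment floor.
* **Per-sample noise** is Dirichlet resampling with concentration
  `dispersion` (default 1000, i.e. stable longitudinal communities) plus
  independent per-species dropout (default 0.15), which makes prevalence
  vary and exercises the 6-of-13 core rule. Under these defaults the
  false-engraftment floor (mean SEF at λ = 0) is dropout-dominated and
  small; the acceptance suite computes it.
* **Engraftment forward model**: the post-FMT sample at week w is a noisy
  resample of the re-closed convex mixture (1−λ_w)·baseline + λ_w·donor
  base. By default λ is constant over weeks and evenly spaced across
  recipients in [0.05, 0.8]; an explicit per-recipient, per-week schedule
  can be supplied. Ground truth records λ and the detectably transferred
  species (donor species outside the baseline with λ_max·abundance ≥ τ).
* **Donor richness**: subset sizes span `donor_species_range` (150–250) from
  richest to poorest, so the first donor is the higher-diversity one, as in
  the trial's donor pair.
* **Clinical generator** is constructive: it works backward from requested
  week-10/week-14 calls (and dropout flags) to Mayo assessments that the
  classifier maps to exactly those calls, so classifier round-trip tests
  are exact rather than probabilistic. The default outcome allocation
  reproduces the trial's printed margins: week 10 — 10 remission, 2
  partial, 12 none, 8 of 12 responders on budesonide; week 14 — 9
  remission, 1 partial, 14 none, responders split 2 vs 8 across donors and
  6 vs 4 across arms; two never-responders drop out.

What the generator does **not** model: phylogenetic correlation among
species, strain-level dynamics within species, time-varying community
drift unrelated to FMT, compositional interactions (the mixture is linear
on the simplex), or any dependence of clinical outcome on engraftment.
Consequently, passing tests demonstrate that the pipeline recovers the
generative signal under a plausible noise model — not that the metrics are
clinically valid on real cohorts.

## Problem sizes and numerics

Default analyses run on 243 samples × 500 species and complete in seconds;
the permutation and simulation batteries in the test suite use 99–999
permutations and a few hundred replicates, sizes chosen so the whole suite
stays comfortably interactive. Degenerate inputs are handled explicitly:
all-zero samples are rejected with the sample named; a recipient identical
to its donor at baseline (distance 0) is an error rather than an infinite
similarity; zero-margin contingency tables yield p = 1 with a warning
(Fisher) or an error (chi-square); dropouts simply skip windows with no
samples, with no imputation.

## Known limitations

* Species identity is exact string match; profiles must come from one
  classifier's namespace. No taxonomic harmonization is attempted.
* Engraftment is species-level presence/abundance; strain-level transfer
  (SNV or marker-based tracking) is out of scope, though it is the sharper
  instrument when donor and recipient share a species.
* The exact Wilcoxon branch does not enumerate under ties; tied data fall
  back to the normal approximation regardless of sample size.
* The donor core's cumulative abundance in donor samples is reported as a
  descriptive statistic, never enforced as a filter.
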