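# Methods

## Problem and model

Transcription factors within a family often recognize the same short DNA
motif yet bind distinct genomic loci. The working hypothesis behind this
package is that locus selection is collaborative: which sites a factor binds
is shaped by the ensemble of other motifs present at each locus. The model
therefore treats binding-site prediction as a sparse regression over an
entire motif library rather than a single-motif enrichment problem.

Given binding sites (peaks) and an equal number of GC-matched background
loci, the feature for locus *k* and motif *n* is the best-match log-odds
score: the maximum over all ungapped windows on both strands of
Σ_i ln(p_i(base)/bg(base)), with negative maxima set to zero. Natural
logarithms are used throughout; the zero-floor and the sign of every score
are base-invariant, and standardization removes the remaining scale, so
the choice has no effect on fitted models. Scores are standardized per
motif — mean 0, variance 1 with the population (divisor *m*) standard
deviation — over the combined binding + background set. Labels (1 = bound,
0 = background) are fit with L1-penalized logistic regression; the L1
penalty drives uninformative motif weights to exactly zero, which is what
makes the model readable.

Assumptions worth stating: windows are scored independently (no
position-interdependence within a motif, no motif-spacing or orientation
grammar between motifs); background loci are exchangeable with binding sites
apart from sequence content; and one best match per motif per locus carries
the signal (multiple weaker matches are not accumulated).

## Library merging

Public motif libraries are redundant, and redundant columns make regression
weights unstable. Similarity of two position probability matrices (PPMs) is
the Pearson correlation of their entries after centering each position on
its row mean (0.25 for a proper probability row), computed on the optimal
gapless alignment: every offset of one matrix against the other is tried, in
both orientations, with overhangs padded by background frequencies, and the
best-correlating placement wins. Ties prefer smaller |offset|, then the
forward orientation. Motif sets with aligned correlation ≥ 0.9 are merged by
aligning every member to the cluster seed — the longest member,
lexicographically first name on ties — and averaging nucleotide frequencies
per position (padding with background), then renormalizing rows.

Two genuinely open design points, and the choices made:

* **Cluster rule.** Clusters are single-linkage connected components of the
  ≥-threshold graph: simple, deterministic, and faithful to the idea of
  "sets" of mutually similar motifs. Average linkage (cutting a hierarchy at
  the same correlation level) is exposed via `linkage="average"` for users
  who want tighter clusters.
* **Orientation.** Reverse complements are considered during alignment by
  default (`both_orientations=True`), because a PPM and its reverse
  complement describe the same biochemical object; a flag disables it.

Uniform (zero-variance) PPMs have undefined correlation; it is defined as 0
so uninformative matrices never seed clusters. When count matrices are read,
a pseudocount of 0.001 per cell precedes row normalization so no probability
is exactly zero (a zero would make log-odds scores −∞ downstream).

## GC-matched background

Background loci are sampled by binned rejection: foreground GC content is
histogrammed into 20 equal-width bins (configurable), and for each
foreground locus a random locus of the same length is drawn
(length-weighted across contigs, uniform within) until it lands in the same
GC bin, contains no N, and overlaps no foreground locus. This yields exact
per-bin histogram equality and an exact count match by construction. The
rejection loop is bounded (20 000 attempts per locus) and raises, naming
the offending bin, when the genome cannot satisfy it. Mappability is
reduced to N-exclusion; genuine mappability tracks are out of scope.

## Training, significance, and diagnostics

Cross-validation uses stratified 5-fold splits (seeded); each fold trains on
80% and evaluates auROC and precision on the held-out 20%. Reported weights
and intercept are fold means. The solver is scikit-learn's liblinear with
tolerance 1e-6 and up to 5000 iterations; the default inverse-regularization
C = 1.0 is deliberately unexciting — the stable outputs of the method are
the ranked significances, not raw weight magnitudes, and C is exposed for
sensitivity analysis. liblinear penalizes the intercept as well; with
standardized features and C of order 1 this bias is negligible.

Per-motif significance is an in-silico deletion: the full and the
one-motif-removed model are trained under identical fold assignments (same
seed, same stratification — required for a fair likelihood comparison), the
Bernoulli log-likelihood of the observed labels is evaluated under each
model's fold-averaged weights over *all* loci (train and test pooled), and
2·ΔLL is referred to chi-squared with 1 df. Negative statistics (the
perturbed model fitting better by chance) are clipped to 0, p = 1. When
models are trained on replicate experiments, the per-motif "mean p-value" is
the arithmetic mean across replicates; ranking ties are broken by |weight|
descending.

Collinearity is quantified per motif as VIF = 1/(1−R²) from OLS of its
(standardized) scores on all other motifs; R² within 1e-12 of 1 is reported
capped at 1e12. VIF > 10 is the conventional trouble threshold, and the
merge step exists precisely to bring the library under it.

## Condition deltas and the two-strain model

With models trained on two conditions over the same motif set, the predicted
change in binding at locus *k* is (W_a − W_b)·S_k — exactly linear in the
standardized scores, so predictions add and negate as dot products do.

The two-strain model targets loci whose sequence differs between two
genomes. Loci with identical sequences are dropped (they carry no variant
signal). Per motif, D = score_A − score_B (each score floored at zero, both
orientations; unequal sequence lengths from indels are scored natively —
coordinate liftover between genomes is the caller's problem). D is
standardized per column over the retained loci, and the log2 binding ratio
log2((reads_A + 1)/(reads_B + 1)) — pseudocount 1 stabilizes zero counts —
is regressed on Z by OLS under the same 5-fold protocol, weights reported
as fold means. Per-motif significance is a partial (drop-one-column) F-test
on the full-data fit; the partial form is used because it is the only
F-test that yields a significance per motif. Binding strengths are taken as
given (assumed pre-normalized). Predictions accept either the two-strain
weights (with intercept) or single-strain logistic weights applied to Z
(no intercept); both are supported read-outs.

## Synthetic data: what it emulates and what it does not

The generators produce the statistical structure the model assumes, with
known truth: i.i.d. background sequence at 41% GC (a mammalian-like
default), 200-bp loci (the conventional fixed peak size), causal motif
instances sampled from their PPMs and planted at uniform positions
(replacing background, one instance per event, probability 0.5 per
locus/motif), and labels drawn from logistic(b + Z·W_true). Default library:
20 motifs of length 8–12 with one dominant base per position; default causal
weights (1, −1, 2, −2, 3). Duplicate motifs for merge tests are jittered
copies constructed to have aligned correlation ≥ 0.9. Strain B mutates
strain A at 2% per-base SNP rate and 0.2% indel rate (lengths 1–3,
insertion/deletion equiprobable); read counts are constructed so the log2
ratio equals Z·W_true plus Gaussian noise (sd 0.5 by default), with the
exponent split across the two strains so neither count underflows.

Passing tests on these data show the estimation machinery is correct under
the model's own assumptions. They do not show that real binding follows
those assumptions: real peaks have positional motif structure, correlated
background composition, mappability artifacts, and binding strengths with
measurement noise far from logistic/Gaussian ideals. Real-data conclusions
still require the usual replicate-consistency checks.

## Numerical choices and problem sizes

Windows containing N score −∞ (excluded by the max); all-N or too-short
sequences score 0. Constant feature columns are flagged and set to zero
rather than dropped, keeping column indices stable. Probability rows are
validated to sum to 1 within 1e-6; correlation denominators of exactly zero
are flagged as undefined. Fold assignment, liblinear's internal shuffling,
and every generator draw from a single seed, so all outputs are
reproducible bit-for-bit.

The bundled verification (`scripts/acceptance.py` and the test suite) runs
at desk scale, chosen to make the statistical checks decisive while keeping
a full run in minutes on one CPU: 100 random pairs for the scoring oracle,
2000 loci for merge/VIF and delta checks, 5000 loci × 10 seeds for weight
recovery, 200 replicates of 400 loci for null calibration of the
likelihood-ratio test, 20 replicates of 2000 loci for its power, and
1000–2000 mutated-pair loci for the two-strain checks.

## Known limitations

* No motif discovery, no gapped PPM alignment, no position-dependence within
  motifs, no motif-spacing grammar.
* Merging averages member PPMs; a merged matrix can be blurrier than any
  member when members differ in length or register.
* The L1 path makes individual weights depend on the penalty; compare ranked
  significances, not weights, across settings.
* The deletion test refits the perturbed model, so its null distribution is
  approximate; the calibration check (type-I rate within [0.01, 0.10] at
  nominal 0.05) bounds the slack empirically.
* Read-count normalization, peak calling, alignment and genome liftover are
  all upstream of this package.
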