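# Methods

This note documents the statistical models, the synthetic-data generator,
and the numerical and design choices behind `embryomics`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Proteome model

Protein abundance is quantified as the log2 light/heavy (L/H) SILAC ratio of
each protein against a labeled internal-standard lysate; missing entries
mean the protein was not detected in that run.

**Detection filter.** `filter_detected(matrix, design, min_reps, min_stages)`
keeps proteins observed in at least `min_reps` replicates of at least
`min_stages` stages. Two conventions coexist in this field — "two replicates
of one or more stages" for the working quantified set, and the stricter
"two stages in two replicates" for normalization and testing — so both are
parameters; the pipeline uses (2, 1) for the working set and (2, all stages)
for the clustering input.

**Quantile normalization.** Complete-case samples are mapped to the
rank-wise mean (all columns share the identical sorted vector). With missing
values, each sample's observed values are interpolated through its own
empirical quantile function onto the pooled reference distribution (the
mean of the per-sample quantile functions on a [0, 1] grid). This reduces
exactly to the classical algorithm on complete data and is idempotent
there; ties receive the average-rank position.

**Batch correction.** Replicates were processed as batches, so the model
log2 L/H = μ + X_rep + ε is fitted per protein with the replicate id as a
fixed categorical effect; the corrected value is the residual plus the
protein's global observed mean, i.e. x − mean(replicate group) + mean(all
observed). This leaves all within-replicate stage contrasts exactly
unchanged and makes per-replicate means coincide on balanced complete data.
Proteins observed in fewer than two replicate groups pass through unchanged
with a logged warning. Note that with the dropped blastocyst replicate the
design is unbalanced, so the third replicate's correction absorbs a small
stage-composition component; this is a property of the one-way model itself.

**Stage test and fold changes.** One-way ANOVA of log2 L/H across stages on
observed values; proteins observed in fewer than two stages or with fewer
than two residual degrees of freedom get NA, and an all-identical profile
gets p = 1 (conservative degenerate convention; zero within-variance with
real between-variance gives p = 0). No multiple-testing correction is
applied to protein ANOVA p-values by default (raw P ≤ 0.05), matching
common practice for this design; `bh_adjust` can be applied by the caller.
Stage means are arithmetic means of log2 ratios (geometric means of ratios),
and fold-change profiles are stage means minus the oocyte mean, NA when
either side is unobserved. Differential proteins satisfy P ≤ 0.05 and
|log2 FC| ≥ 1 between any two stages, or between consecutive stages for the
per-transition sets.

## Transcriptome model

Counts are normalized by median-of-ratios size factors (genes containing
any zero are excluded from the geometric-mean reference). Note the
reference fixes only factor *ratios*; scaling one sample's counts by c
multiplies its factor by c relative to the others.

**NB Wald test.** For stage vs oocyte (two samples per group), per-gene
log2 fold change is lfc = log2((m₁+ε)/(m₀+ε)) on normalized group means
with ε = 0.5/mean(size factor) to avoid infinities at zero counts. The
variance model is Var(c/f) = μ/f + αμ². Dispersion α is estimated by the
method of moments from the pooled within-group variance and stabilized
across genes by a 25-bin mean–dispersion trend on the log-mean axis fitted
to the *raw* (unclipped) per-gene estimates — bin means, not medians,
because at two residual degrees of freedom the per-gene estimates are so
right-skewed that their median sits far below the mean dispersion and the
test becomes anticonservative. By default the test uses the trend value
directly: with n = 2 per group a per-gene estimate carries almost no
information, and mixing it in (the `shrinkage` argument, log-space weight)
only destabilizes the standard error. The Wald z is lfc over a delta-method
standard error of the log mean (including the second-order trigamma term),
with a two-sided normal p-value. Calibration is verified in the acceptance
suite by pooling null p-values across independent simulated datasets:
pooling is used because a single dataset's 5,000 p-values share the size
factors and the dispersion trend, which inflates the variance of a
Kolmogorov–Smirnov statistic without reflecting any miscalibration.

FDR control is Benjamini–Hochberg per stage; direction calls use
FDR ≤ 10⁻⁵ and |log2 FC| ≥ 1, yielding disjoint up/down sets.

## Concordance statistic

For transcript stage S_i and protein stage S_j, proteins cognate to
transcripts up- (resp. down-) regulated at S_i and detected at both S_j and
the oocyte form two disjoint groups of protein log2 fold changes at S_j.
The signed score is

  score = (1/R) ∫ [F_down(x) − F_up(x)] dx

integrated over the union support of the two samples, where F are the
empirical (right-continuous step) CDFs and R is the normalization range.
Integrating over the union support makes the identity
∫(F_down − F_up) = mean(up) − mean(down) exact, which the test suite asserts
to 10⁻¹⁰ together with antisymmetry and the translation identity
(score increases by exactly δ/R when every up-value shifts by δ). The score
is kept signed — positive means protein changes follow transcript direction;
an absolute-value view is a reporting option. R is global (max − min of all
protein fold changes entering the grid) so cells are comparable; per-cell
normalization is available. Cells where either group holds fewer than 25
proteins are left undefined with a reason code; the ≥ 25 rule is applied per
group, the strictest reading of the skip rule. Change-level relationships
are additionally summarized by Spearman correlations of
(transcript FC at S_i, protein FC at S_j) over complete gene pairs.

## Clustering and cluster comparison

Fold-change profiles are z-scored per feature (zero-variance profiles map to
zeros, logged). Fuzzy c-means uses Euclidean distance with fuzzifier
m = 1.25 — the common choice for expression profiles, soft enough to expose
gradual membership but close to k-means — with k-means++-style seeding,
several restarts (best objective kept), and convergence when the objective
changes by < 10⁻⁹. Membership rows sum to 1 to 10⁻⁹ at every iterate; hard
assignments take the maximal membership with ties to the lowest cluster
index (a configurable membership floor is available).

k is chosen from the minimum pairwise centroid distance D_min(k): while
k does not exceed the number of genuine archetypes D_min stays of the order
of the archetype separation, and collapses once a real cluster is split; the
selected k is the largest k before D_min first drops below `drop_frac`
(default 0.4) of its k = 2 value. The default was chosen from the geometry
of the planted archetype library (minimal pairwise z-scored separation 1.73
versus a k = 2 separation of ≈ 4), not from any particular dataset.

Cluster pairs across layers are compared by (i) Pearson correlation of
per-stage *median* fold-change profiles of hard members, aligned through the
protein→transcript stage map (the 2-cell protein stage contributes one
aligned pair for each of the two 2-cell transcript stages); (ii) membership
overlap over the universe of genes clustered in both layers, with one-sided
(enrichment) Fisher exact tests; and (iii) a meta 2×2 test classifying every
cluster pair by (r ≥ 0.5) × (overlap p ≤ 0.05), reported with the
conditional-MLE odds ratio (the convention of standard Fisher-test tooling,
sample odds ratio alongside) and a one-sided Fisher p.

## Marker discovery

Samples are labeled early (oocyte, 1-cell, 2-cell) or late (4-cell to
blastocyst). With features ≫ samples the pooled within-class covariance is
singular, so LDA uses S_reg = (1−λ)S + λ·diag(S) with λ = 0.5 by default;
the weight vector solves S_reg w = μ_late − μ_early through the Woodbury
identity (O(p n²)), and the intercept places the boundary at the projected
class-mean midpoint. Evaluation is leave-one-out cross-validation with a
midrank Mann–Whitney AUC. Markers are ranked by |w_g|·SD_g (standardized
discriminant weight, invariant to positive rescaling of a feature), ties by
feature id. By default LDA runs on proteins observed in all samples;
mean-imputation is an explicit caller choice. Marker-set enrichment against
annotation gene sets is a Fisher exact test (enrichment-sided by default)
over a declared universe.

## Completeness

For each protein complex, coverage is the fraction of members detected;
since all members are required for function, shortfalls measure detection
limits rather than biology. Complexes are first restricted to the measured
universe (so coverage is not confounded with annotation mismatch) and
dropped below 2 members; per-stage fractions use detection in ≥ 1 replicate
of the stage and the overall fraction uses the union over stages. Medians
over complexes summarize each variant.

## Validation

External measurement sets (enzymatic or quantified immunofluorescence
profiles, arbitrary monotone scales) are compared to mean corrected-L/H
stage profiles by Spearman correlation over shared stages (≥ 3 required).
The empirical p-value counts the sets with ρ ≥ 0.6, re-draws the
set→profile matching uniformly at random n_perm = 10,000 times (without
replacement by default; with replacement available), and reports the
relative frequency of permutation statistics at least as large — no add-one
correction, and deterministic given the seed. Because the statistic is a
small count, calibration is checked through the randomized probability
integral transform of the discrete p-value, which is uniform for a valid
permutation test.

## Ordination

PCA centers features and decomposes the samples × features matrix by SVD
over the complete-case feature subset (the transcript layer uses all genes
after log2 normalization). Percent variance per component comes from the
squared singular values; signs are fixed by making each component's
largest-magnitude loading positive. Replicate QC reports min/max pairwise
Spearman correlation between replicate columns within each stage.

## Synthetic-data generator

The generator emulates the *processed* outputs of the study design: 2,000
genes by default; 7 proteome stages × 3 replicates with the third
blastocyst replicate dropped (20 samples); 8 transcriptome stages × 2
replicates. All draws are deterministic given the seed (independent named
streams per component).

**Profiles.** Fold-change profiles relative to the oocyte are built from
archetype libraries scaled by per-gene lognormal amplitudes. Transcript
archetypes cover gradual maternal decay and genome activation (early/late
variants), a transient 2-cell wave and an 8-cell peak with their mirror
images, and a blastocyst surge; the transient shapes receive higher draw
probabilities, as transcript dynamics around EGA are dominated by transient
programs. Protein archetypes form three antipodal pairs — steady
increase/decrease, early-mid peak/dip, and a mild drift ending in a sharp
morula→blastocyst crash/surge — chosen mutually separated after z-scoring
so profile clusters are well defined. Uncoupled genes blend their archetype
with idiosyncratic per-stage shape noise (per-gene purity U(0, 0.6)); the
idiosyncratic component is AR(1) along the stage axis with stronger
persistence on the transcript side (φ = 0.55) than the protein side
(φ = 0.10), reflecting gradually drifting transcriptional programs versus
turnover-buffered protein levels. Transcript amplitudes (median 2.5 log2
units) exceed protein amplitudes (median 1.4): maternal stores and steady
basal translation damp the proteome.

**Coupling.** 7% of genes are planted as correlated and 3% as
anticorrelated: their protein profile is the sign times the delay-weighted
transcript profile evaluated one transcript stage earlier
(`coupling_delay = 1`), with weights ramping from 0.70 (1-cell) to 1.00
(blastocyst) — the free-ribosome mechanism — plus small independent noise.
Strongly coupled genes draw from the sustained (smooth) transcript
archetypes, whose stage ranks survive the delay. All remaining genes carry
weak background coupling (per-gene strength U(0, 0.35) blended into the
protein profile), reproducing the weak-but-nonzero global concordance that
motivates the analysis; without it the concordance grid would sit at the
sampling-noise floor under the 10% strong-coupling fraction.

**Measurement layers.** log2 L/H = baseline + FC + batch + N(0, 0.25), with
per-replicate batch offsets N(0, 0.3); a value is censored with probability
1 − logistic(x − (−3.5)), the abundance-dependent MS detection limit, and
each protein is detected study-wide with probability 0.8 (proteome depth).
Counts are NB with mean sf·baseline·2^FC, dispersion α = 0.02 and
log-uniform size factors in [2/3, 1.5]; baselines are lognormal with median
300. Forty marker genes get a ramped early/late shift (±3.5 log2 units;
0 through the 2-cell stage, 0.7 at the 4-cell stage, 1 afterwards) and
abundant baselines (N(3.0, 0.4)) — markers are, by construction, proteins
robust enough to assay. Annotations comprise 233 complexes (sizes 2–20) and
20 pathways, one of which contains 20 planted markers. 37 external
measurement sets (14 high-fidelity) are true profiles plus noise pushed
through a random increasing transform.

**What passing tests do and do not show.** The generator plants the
qualitative structure the analysis is designed to detect (delayed, ramped
coupling; archetypal profile clusters; an early/late proteome switch) with
independent Gaussian/NB noise. Real data add peptide-level quantification
structure, correlated missingness across runs, isoform ambiguity and
annotation error, none of which are modeled; recovery results on synthetic
data demonstrate correctness of the statistical machinery, not performance
guarantees on real measurements.

## Problem sizes and numerical choices

Recovery checks run at n_genes = 2,000 (concordance, markers, coupling
fractions), 1,200 (clustering), and 5,000 (test calibration), each over ten
seeds where seed variability matters; these sizes give the planted effects
comfortable signal-to-noise while keeping the full suite fast. Monotonicity
of the concordance ramp is asserted up to a sampling-noise allowance (10%
of the column maximum), per-cell counting noise being irreducible at fixed
gene count. Degenerate cases are fixed conventions, not errors: zero-variance
ANOVA → p = 1, zero-variance profiles → zero z-scores, empty CDF groups and
sub-threshold grid cells → explicit NA with reason, Fisher tables with empty
margins → conditional-MLE odds ratio NaN/∞ as appropriate.

## Known limitations

* The NB Wald test with trend-only dispersion assumes dispersion varies
  smoothly with expression; a gene with truly outlying dispersion can be
  mis-calibrated at n = 2 (no per-gene information exists at this depth).
* The one-way batch model cannot separate batch from stage composition in
  the unbalanced (dropped-replicate) design; a small stage-dependent
  component remains in the corrected third replicate.
* Quantile normalization with heavy missingness equalizes only observed
  quantiles; detection-biased missingness can still shift sample means.
* LDA margins at p ≫ n are dominated by overfit directions; the ranking and
  LOOCV AUC are reliable, but margin *magnitudes* are not interpretable as
  confidence.
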