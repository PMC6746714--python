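# embryomics

Integrated proteome–transcriptome analysis of mouse preimplantation
development, implemented as a tested, reusable Python pipeline over
synthetic data with known ground truth.

## The scientific problem

Early mouse embryos store their ribosomes in cytoplasmic lattices and are
poorly competent for translation, so transcriptome changes — which happen
early, around embryonic genome activation at the 2-cell stage — are expected
to reach the proteome only later, once free ribosomes appear at the morula
stage. Testing this requires analyzing a SILAC LC-MS/MS proteome (log2 L/H
ratios over 7 developmental stages × 3 replicates, with one blastocyst
replicate dropped for quality control) side by side with an RNA-seq
transcriptome (8 stages × 2 replicates, the 2-cell stage split into early
and late).

The package implements the full statistical workflow for users who want to
run, extend or stress-test this kind of two-layer developmental analysis:

* **Proteome processing** — detection filtering, quantile normalization of
  log2 L/H ratios, replicate batch correction via the residuals of
  log2 L/H = μ + X_rep + ε, stage-wise one-way ANOVA
  (log2 L/H = μ + T_stage + ε, P ≤ 0.05) and fold-change profiles relative
  to the oocyte (FC ≥ 2 or ≤ 0.5).
* **Transcriptome processing** — median-of-ratios size factors, a
  negative-binomial Wald test of each stage against the oocyte with a
  cross-gene mean–dispersion trend, Benjamini–Hochberg FDR, and up/down
  calls at FDR ≤ 10⁻⁵ and |log2 FC| ≥ 1.
* **Concordance** — the core statistic: for transcript stage S_i and protein
  stage S_j, proteins are split into two disjoint groups by the direction of
  their cognate transcript's change at S_i, and the signed area between the
  two empirical CDFs of protein log2 fold changes at S_j (normalized by the
  global protein fold-change range) quantifies how much transcript changes
  are reflected in protein changes. The raw area equals
  mean(up) − mean(down) exactly. Cells with fewer than 25 proteins per group
  are left undefined. Change-level Spearman correlations accompany the grid.
* **Clustering** — fuzzy c-means (m = 1.25) of z-scored fold-change profiles
  for each layer, k selection from the minimum centroid-distance curve, and
  the cluster comparison: Pearson correlation of per-stage median profiles,
  one-sided Fisher overlap tests, and a meta 2×2 Fisher test asking whether
  profile-similar cluster pairs share more members.
* **Markers** — shrinkage LDA (S_reg = (1−λ)S + λ·diag S) separating early
  (oocyte–2-cell) from late (4-cell–blastocyst) samples, leave-one-out ROC
  AUC, marker ranking by standardized discriminant weight |w|·SD, and Fisher
  enrichment of the top-20 list against pathway annotations.
* **Completeness** — per-complex detected-member fractions over a catalog of
  233 protein complexes, with per-stage and overall medians.
* **Validation** — Spearman correlation of external (enzymatic /
  immunofluorescence-style) stage profiles against mean L/H profiles, and an
  empirical p-value from 10,000 random re-assignments of the 37 measurement
  sets (statistic: number of sets with ρ ≥ 0.6).
* **Ordination** — PCA of both layers and replicate-correlation QC.

The synthetic-data generator (`embryomics.simulate`) is a first-class,
tested component: it plants per-gene transcript→protein coupling (7%
correlated, 3% anticorrelated, weak background coupling elsewhere) with a
one-stage developmental delay and coupling weights that ramp toward the
blastocyst, profile archetypes, batch offsets, abundance-dependent
missingness, NB counts, complexes, pathways and external measurements — so
every downstream claim can be checked against known truth.

## Worked example

```python
import embryomics as em
from embryomics.pipeline import run_pipeline

result = run_pipeline(em.SimulationConfig(n_genes=2000, seed=1))
s = result.summarize()
print(f"proteins detected: {s['n_proteins_detected']}")
print(f"stage-dependent (ANOVA P<=0.05): {s['n_de_anova']}")
print(f"max concordance score: {s['concordance_max']:.3f}")
print(f"strong +/- profile correlations: {s['pct_correlated']:.1f}% / "
      f"{s['pct_anticorrelated']:.1f}%")
print(f"early/late LOOCV AUC: {s['marker_auc']:.2f}")
print(f"complex coverage median: {s['complex_coverage_median']:.2f}")
```

prints

```
proteins detected: 1613
stage-dependent (ANOVA P<=0.05): 1465
max concordance score: 0.059
strong +/- profile correlations: 7.5% / 3.7%
early/late LOOCV AUC: 1.00
complex coverage median: 0.82
```

Of 2,000 simulated genes, 1,613 proteins are detected (study-wide
detectability 0.8 plus abundance-dependent missingness). The concordance
grid peaks at the (morula → blastocyst) cell — transcript changes at the
morula best predict protein changes at the blastocyst, the planted one-stage
delay. The strong positive/negative profile-correlation tails recover the
planted 7%/3% coupling classes, the LDA separates early from late stages
perfectly (AUC 1.00) with planted markers filling the top of the ranking,
and the median complex coverage matches the planted per-member detection
probability.

The same analysis is available from the shell:

```bash
embryomics simulate --out data/ --seed 1        # write the dataset as TSV/GMT
embryomics all --out results/ --seed 1          # run the full pipeline
```

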