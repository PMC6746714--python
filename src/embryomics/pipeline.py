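"""End-to-end pipeline: simulate -> proteome -> transcriptome -> concordance ->
clustering -> markers -> completeness -> validation -> ordination.

``run_pipeline`` executes the whole analysis on a synthetic dataset (or one
loaded from disk) and returns a result bundle whose ``summarize()`` method
collects the headline quantities: detection tiers, differential-expression
counts, PCA variance fractions, the concordance grid, cluster counts and the
meta overlap test, correlated/anticorrelated gene fractions, marker AUC and
enrichment, complex-coverage medians, and the validation permutation p-value.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    ClusterComparison,
    FuzzyClustering,
    MetaOverlapResult,
    compare_clusterings,
    fuzzy_cmeans,
    meta_overlap_test,
    select_k,
    zscore_profiles,
)
from .completeness import CoverageResult, complex_coverage
from .concordance import ConcordanceGrid, change_correlation, concordance_grid
from .datatypes import DEFAULT_STAGE_MAP, CognateMap
from .markers import MarkerResult, discover_markers, enrichment_test
from .ordination import PCAResult, pca_embed, replicate_correlation
from .proteome import (
    DEResult,
    batch_correct,
    call_de_proteins,
    filter_detected,
    fold_changes,
    protein_de,
    quantile_normalize,
    stage_means,
)
from .simulate import SimulationConfig, SyntheticDataset, simulate_dataset
from .transcriptome import (
    TranscriptDEResult,
    call_de_transcripts,
    transcript_de,
)
from .validation import PermutationResult, empirical_pvalue, profile_correlation
from . import io as eio

logger = logging.getLogger(__name__)

EARLY_STAGES = ("oocyte", "1cell", "2cell")
LATE_STAGES = ("4cell", "8cell", "morula", "blastocyst")


@dataclass(frozen=True)
class AnalysisThresholds:
    """All statistical thresholds used along the pipeline."""

    p_max: float = 0.05  # protein ANOVA
    min_fc: float = 2.0  # protein fold-change (linear)
    fdr_max: float = 1e-5  # transcript FDR
    min_abs_lfc: float = 1.0  # transcript |log2 FC|
    min_n: int = 25  # concordance cell size
    r_min: float = 0.5  # cluster-pair profile correlation
    top_n: int = 20  # marker list size
    rho_min: float = 0.6  # validation correlation
    n_perm: int = 10_000  # validation permutations
    lda_shrinkage: float = 0.5
    fuzzifier: float = 1.25
    k_range: tuple[int, ...] = tuple(range(2, 10))


@dataclass
class PipelineResult:
    """Everything one pipeline run produces."""

    dataset: SyntheticDataset
    thresholds: AnalysisThresholds
    # proteome
    protein_corrected: pd.DataFrame
    protein_de: DEResult
    protein_fc: pd.DataFrame
    de_any_pair: pd.Index
    de_consecutive: pd.Index
    de_transitions: dict[str, pd.Index]
    # transcriptome
    transcript_result: TranscriptDEResult
    transcript_calls: dict
    # concordance
    grid: ConcordanceGrid
    change_rho: pd.Series
    # clustering
    protein_clust: FuzzyClustering
    transcript_clust: FuzzyClustering
    comparison: ClusterComparison
    meta: MetaOverlapResult
    profile_rho: pd.Series  # per-gene protein/transcript profile Spearman
    # markers
    markers: MarkerResult
    marker_enrichment: tuple[float, float]
    marker_pathway: str
    # completeness
    coverage: CoverageResult
    # validation
    measurement_rho: pd.Series
    permutation: PermutationResult
    # ordination
    protein_pca: PCAResult
    transcript_pca: PCAResult
    replicate_rho: pd.DataFrame

    def summarize(self) -> dict[str, float | int]:
        cons = self.protein_de.consecutive_log2fc.columns
        last_transition = cons[-1] if len(cons) else None
        defined = self.grid.scores.stack().dropna()
        summary: dict[str, float | int] = {
            "n_proteins_detected": int(self.dataset.protein_matrix.notna().any(axis=1).sum()),
            "n_proteins_min2rep": int(len(self.protein_corrected)),
            "n_proteins_complete": int(self.protein_corrected.dropna().shape[0]),
            "n_transcripts": int(len(self.dataset.count_matrix)),
            "n_de_anova": int((self.protein_de.pvalues <= self.thresholds.p_max).sum()),
            "n_de_any_pair": int(len(self.de_any_pair)),
            "n_de_consecutive": int(len(self.de_consecutive)),
            "n_de_last_transition": int(
                len(self.de_transitions.get(last_transition, []))
            ),
            "protein_pc1_pct": float(self.protein_pca.variance_fraction[0]),
            "protein_pc2_pct": float(self.protein_pca.variance_fraction[1]),
            "change_rho_min": float(self.change_rho.min()),
            "change_rho_max": float(self.change_rho.max()),
            "concordance_max": float(defined.max()) if len(defined) else float("nan"),
            "n_protein_clusters": int(self.protein_clust.k),
            "n_transcript_clusters": int(self.transcript_clust.k),
            "meta_odds_ratio": float(self.meta.odds_ratio),
            "meta_pvalue": float(self.meta.pvalue),
            "pct_correlated": float(100.0 * (self.profile_rho >= 0.8).mean()),
            "pct_anticorrelated": float(100.0 * (self.profile_rho <= -0.8).mean()),
            "median_profile_rho": float(self.profile_rho.median()),
            "marker_auc": float(self.markers.auc),
            "marker_enrichment_or": float(self.marker_enrichment[0]),
            "marker_enrichment_p": float(self.marker_enrichment[1]),
            "complex_coverage_median": float(self.coverage.overall_median),
            "validation_n_strong": int(self.permutation.observed),
            "validation_empirical_p": float(self.permutation.pvalue),
        }
        return summary


def run_pipeline(
    config: SimulationConfig | None = None,
    thresholds: AnalysisThresholds | None = None,
    dataset: SyntheticDataset | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the complete analysis; simulates a dataset unless one is given."""
    thresholds = thresholds or AnalysisThresholds()
    if dataset is None:
        config = config or SimulationConfig()
        dataset = simulate_dataset(config)
    config = dataset.config
    t = thresholds

    # --- proteome: filter, normalize, batch-correct, test ------------------
    pmat, pdes = dataset.protein_matrix, dataset.protein_design
    working = filter_detected(pmat, pdes, min_reps=2, min_stages=1)
    normalized = quantile_normalize(working)
    corrected = batch_correct(normalized, pdes)
    de = protein_de(corrected, pdes)
    pfc = fold_changes(corrected, pdes)
    de_any, _ = call_de_proteins(de, p_max=t.p_max, min_fc=t.min_fc, scope="any_pair")
    de_cons, transitions = call_de_proteins(
        de, p_max=t.p_max, min_fc=t.min_fc, scope="consecutive"
    )

    # --- transcriptome ------------------------------------------------------
    cmat, tdes = dataset.count_matrix, dataset.transcript_design
    tres = transcript_de(cmat, tdes)
    tcalls = call_de_transcripts(tres, fdr_max=t.fdr_max, min_abs_lfc=t.min_abs_lfc)

    # --- concordance --------------------------------------------------------
    grid = concordance_grid(tcalls, pfc, dataset.cognate_map, min_n=t.min_n)
    pairs = [(ts, ps) for ts in tres.lfc.columns for ps in pfc.columns]
    change_rho = change_correlation(pfc, tres.lfc, pairs, dataset.cognate_map).dropna()

    # --- clustering ---------------------------------------------------------
    # cluster the strictly-detected, differentially expressed proteins
    strict = filter_detected(pmat, pdes, min_reps=2, min_stages=len(pdes.stages))
    clusterable = corrected.loc[corrected.index.intersection(strict.index)]
    clust_de = protein_de(clusterable, pdes)
    clust_sel, _ = call_de_proteins(
        clust_de, p_max=t.p_max, min_fc=t.min_fc, scope="any_pair"
    )
    pz = zscore_profiles(fold_changes(clusterable.loc[clust_sel], pdes).dropna())
    k_p = select_k(pz, k_range=t.k_range, m=t.fuzzifier, seed=config.seed)
    protein_clust = fuzzy_cmeans(pz, k_p.k, m=t.fuzzifier, seed=config.seed)

    p2t = dataset.cognate_map.protein_to_transcript()
    cognate_transcripts = [p2t[p] for p in pz.index if p in p2t]
    tfc = tres.lfc.loc[tres.lfc.index.intersection(cognate_transcripts)]
    tz = zscore_profiles(tfc.dropna())
    k_t = select_k(tz, k_range=t.k_range, m=t.fuzzifier, seed=config.seed)
    transcript_clust = fuzzy_cmeans(tz, k_t.k, m=t.fuzzifier, seed=config.seed)

    comparison = compare_clusterings(
        protein_clust,
        transcript_clust,
        dataset.cognate_map,
        fold_changes(clusterable.loc[clust_sel], pdes),
        tfc,
    )
    meta = meta_overlap_test(comparison, r_min=t.r_min, p_max=t.p_max)

    # per-gene profile correlation over mapped stage pairs (clustered genes)
    mapped_pairs = [
        (ts, ps)
        for ps in pfc.columns
        for ts in DEFAULT_STAGE_MAP.get(ps, ())
        if ts in tres.lfc.columns
    ]
    profile_rho = _per_gene_profile_rho(
        pfc.loc[pz.index], tres.lfc, mapped_pairs, dataset.cognate_map
    )

    # --- markers ------------------------------------------------------------
    complete = corrected.dropna()
    early = [s for s in EARLY_STAGES if s in pdes.stages]
    late = [s for s in LATE_STAGES if s in pdes.stages]
    markers = discover_markers(
        complete, pdes, early, late, shrinkage=t.lda_shrinkage, top_n=t.top_n
    )
    pathway_name, (enr_or, enr_p) = _best_marker_pathway(
        markers.top, dataset.pathways, universe=list(complete.index)
    )

    # --- completeness -------------------------------------------------------
    detected_by_stage = {
        s: set(pmat.index[pmat[pdes.samples_of_stage(s)].notna().any(axis=1)])
        for s in pdes.stages
    }
    coverage = complex_coverage(
        detected_by_stage, dataset.complexes, universe=list(dataset.truth.genes)
    )

    # --- validation ---------------------------------------------------------
    profiles = stage_means(corrected, pdes)
    meas_rho = profile_correlation(dataset.measurements, profiles)
    permutation = empirical_pvalue(
        dataset.measurements,
        profiles,
        rho_min=t.rho_min,
        n_perm=t.n_perm,
        seed=config.seed,
    )

    # --- ordination ---------------------------------------------------------
    protein_pca = pca_embed(corrected, n_components=2)
    tnorm = _transcript_log_expression(cmat)
    transcript_pca = pca_embed(tnorm, n_components=2)
    replicate_rho = replicate_correlation(corrected, pdes)

    result = PipelineResult(
        dataset=dataset,
        thresholds=t,
        protein_corrected=corrected,
        protein_de=de,
        protein_fc=pfc,
        de_any_pair=de_any,
        de_consecutive=de_cons,
        de_transitions=transitions,
        transcript_result=tres,
        transcript_calls=tcalls,
        grid=grid,
        change_rho=change_rho,
        protein_clust=protein_clust,
        transcript_clust=transcript_clust,
        comparison=comparison,
        meta=meta,
        profile_rho=profile_rho,
        markers=markers,
        marker_enrichment=(enr_or, enr_p),
        marker_pathway=pathway_name,
        coverage=coverage,
        measurement_rho=meas_rho,
        permutation=permutation,
        protein_pca=protein_pca,
        transcript_pca=transcript_pca,
        replicate_rho=replicate_rho,
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def _transcript_log_expression(counts: pd.DataFrame) -> pd.DataFrame:
    from .transcriptome import normalize_log, size_factors

    return normalize_log(counts, size_factors(counts))


def _per_gene_profile_rho(
    protein_fc: pd.DataFrame,
    transcript_fc: pd.DataFrame,
    mapped_pairs,
    cognate_map: CognateMap,
) -> pd.Series:
    from scipy import stats

    p2t = cognate_map.protein_to_transcript()
    out = {}
    for p in protein_fc.index:
        tid = p2t.get(p)
        if tid is None or tid not in transcript_fc.index:
            continue
        x = np.array([protein_fc.loc[p, ps] for _, ps in mapped_pairs], dtype=float)
        y = np.array([transcript_fc.loc[tid, ts] for ts, _ in mapped_pairs], dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3:
            continue
        out[p] = float(stats.spearmanr(x[ok], y[ok]).statistic)
    return pd.Series(out, name="profile_rho")


def _best_marker_pathway(top_markers, pathways, universe):
    """Most-enriched pathway for the marker list (one-sided Fisher)."""
    best = (None, (float("nan"), 1.0))
    markers_in = [m for m in top_markers if m in set(universe)]
    for name, members in pathways.items():
        genes_in = [g for g in members if g in set(universe)]
        if not genes_in:
            continue
        res = enrichment_test(markers_in, genes_in, universe)
        if best[0] is None or res[1] < best[1][1]:
            best = (name, res)
    return best


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write TSV outputs plus a run log of versions, seeds and thresholds."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    eio.write_matrix(outdir / "protein_corrected.tsv", result.protein_corrected, "protein_id")
    eio.write_matrix(outdir / "protein_fold_changes.tsv", result.protein_fc, "protein_id")
    de_table = pd.DataFrame(
        {
            "anova_p": result.protein_de.pvalues,
            "max_abs_log2fc": result.protein_de.max_abs_log2fc,
        }
    )
    eio.write_matrix(outdir / "protein_de.tsv", de_table, "protein_id")
    eio.write_matrix(outdir / "transcript_lfc.tsv", result.transcript_result.lfc, "gene")
    eio.write_matrix(outdir / "transcript_fdr.tsv", result.transcript_result.fdr, "gene")
    eio.write_grid(outdir / "concordance_grid.tsv", result.grid.scores, result.grid.skip_reason)
    eio.write_matrix(outdir / "protein_cluster_membership.tsv", result.protein_clust.membership, "protein_id")
    eio.write_matrix(outdir / "cluster_r.tsv", result.comparison.r, "protein_cluster")
    eio.write_matrix(outdir / "pca_protein_scores.tsv", result.protein_pca.scores, "sample")
    markers_table = pd.DataFrame(
        {"relevance": result.markers.relevance, "rank": result.markers.rank}
    ).sort_values("rank")
    eio.write_matrix(outdir / "marker_ranking.tsv", markers_table, "protein_id")
    eio.write_matrix(
        outdir / "complex_coverage.tsv",
        result.coverage.fractions.assign(overall=result.coverage.overall_fractions),
        "complex",
    )
    summary = result.summarize()
    with (outdir / "summary.tsv").open("w") as fh:
        for k, v in summary.items():
            fh.write(f"{k}\t{v:.6f}\n" if isinstance(v, float) else f"{k}\t{v}\n")
    with (outdir / "run_log.txt").open("w") as fh:
        fh.write(f"embryomics version: {__version__}\n")
        fh.write(f"seed: {result.dataset.config.seed}\n")
        fh.write("thresholds:\n")
        for f_ in dataclasses.fields(result.thresholds):
            fh.write(f"  {f_.name}: {getattr(result.thresholds, f_.name)}\n")
        fh.write("simulation config:\n")
        for f_ in dataclasses.fields(result.dataset.config):
            fh.write(f"  {f_.name}: {getattr(result.dataset.config, f_.name)}\n")
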