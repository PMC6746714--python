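"""Transcript count normalization and stage-vs-oocyte differential expression.

Counts are normalized with median-of-ratios size factors and tested with a
negative-binomial Wald test: per-gene dispersions are estimated by the method
of moments, stabilized by shrinking toward a mean-dispersion trend fitted
across genes, and the log2 fold change is tested against zero with a
delta-method standard error.  Benjamini-Hochberg FDR control and the
fold-change + FDR direction calls match the thresholds used throughout the
analysis (FDR <= 1e-5, |log2 FC| >= 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import DesignError, StageDesign, check_matrix

_MIN_DISP = 1e-8


class CountError(ValueError):
    """Raised for invalid count matrices."""


def _check_counts(counts: pd.DataFrame) -> np.ndarray:
    arr = counts.to_numpy()
    if np.isnan(arr.astype(float)).any():
        raise CountError("count matrix contains missing values")
    if (arr < 0).any():
        raise CountError("counts must be nonnegative")
    if not np.allclose(arr, np.round(arr)):
        raise CountError("counts must be integral")
    return arr.astype(float)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    factor_j = median over all-positive genes g of count_gj / geomean_g.
    Genes containing any zero are excluded from the reference set.
    """
    arr = _check_counts(counts)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise CountError("no gene with all-positive counts; cannot form the reference")
    ref = arr[positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_log(
    counts: pd.DataFrame, factors: pd.Series | None = None, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount) expression values."""
    if factors is None:
        factors = size_factors(counts)
    if (factors <= 0).any():
        raise CountError("size factors must be positive")
    norm = counts.div(factors, axis=1)
    return np.log2(norm + pseudocount)


def _dispersion_trend(mean_all: np.ndarray, alpha_mom: np.ndarray, n_bins: int = 25) -> np.ndarray:
    """Mean-dispersion trend over log-mean bins, interpolated per gene.

    Bin averages (not medians) of the method-of-moments estimates are used:
    with very few residual degrees of freedom the per-gene estimates are
    strongly right-skewed, and their median sits well below the mean
    dispersion, which would make the Wald test anticonservative.
    """
    log_mean = np.log(np.maximum(mean_all, 1e-8))
    order = np.argsort(log_mean)
    edges = np.linspace(0, len(order), n_bins + 1).astype(int)
    centers, levels = [], []
    for b in range(n_bins):
        idx = order[edges[b] : edges[b + 1]]
        if len(idx) == 0:
            continue
        centers.append(log_mean[idx].mean())
        levels.append(alpha_mom[idx].mean())
    if not centers:
        return np.full_like(alpha_mom, float(np.mean(alpha_mom)))
    return np.interp(log_mean, np.array(centers), np.array(levels))


def nb_wald_test(
    counts: pd.DataFrame,
    design: StageDesign,
    stage: str,
    reference: str | None = None,
    factors: pd.Series | None = None,
    shrinkage: float = 0.0,
) -> pd.DataFrame:
    """Negative-binomial Wald test of ``stage`` vs ``reference`` (per gene).

    Returns a DataFrame with columns ``lfc`` (log2 fold change with
    pseudo-offset eps = 0.5 / mean(size factor)), ``se`` and ``pvalue``
    (two-sided normal).  Dispersion comes from the cross-gene mean-dispersion
    trend; ``shrinkage`` > 0 mixes in that weight of the per-gene
    method-of-moments estimate (in log space).  With two samples per group a
    per-gene estimate carries almost no information and only destabilizes the
    test, so the default is fully trend-based.
    """
    check_matrix(counts, design)
    reference = design.reference if reference is None else reference
    g1 = [s for s in design.samples_of_stage(stage) if s in counts.columns]
    g0 = [s for s in design.samples_of_stage(reference) if s in counts.columns]
    if len(g1) < 2 or len(g0) < 2:
        raise DesignError("each group needs >= 2 samples for the NB Wald test")
    if factors is None:
        factors = size_factors(counts)
    used = g1 + g0
    norm = counts[used].div(factors[used], axis=1).to_numpy(dtype=float)
    n1, n0 = len(g1), len(g0)
    x1, x0 = norm[:, :n1], norm[:, n1:]
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    eps = 0.5 / float(factors[used].mean())
    lfc = np.log2((m1 + eps) / (m0 + eps))

    # method-of-moments dispersion from the pooled within-group variance;
    # the Poisson part of Var(c/f) = mu/f + alpha*mu^2 is subtracted using
    # the group's mean inverse size factor.
    v1 = x1.var(axis=1, ddof=1)
    v0 = x0.var(axis=1, ddof=1)
    v_pooled = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
    inv_f1 = float((1.0 / factors[g1]).mean())
    inv_f0 = float((1.0 / factors[g0]).mean())
    mean_all = (n1 * m1 + n0 * m0) / (n1 + n0)
    inv_f_all = (n1 * inv_f1 + n0 * inv_f0) / (n1 + n0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = (v_pooled - mean_all * inv_f_all) / np.maximum(mean_all, 1e-8) ** 2
    # the trend is fitted on the raw (possibly negative) estimates so that
    # clipping does not bias it upward where the true dispersion is small
    trend = np.maximum(_dispersion_trend(mean_all, alpha_raw), _MIN_DISP)
    if shrinkage > 0:
        alpha_mom = np.maximum(alpha_raw, _MIN_DISP)
        # re-center the skewed per-gene log estimates around the trend
        log_bias = np.median(np.log(alpha_mom) - np.log(trend))
        alpha = np.exp(
            shrinkage * (np.log(alpha_mom) - log_bias)
            + (1.0 - shrinkage) * np.log(trend)
        )
    else:
        alpha = trend

    # delta-method variance of ln(mean + eps), with the second-order
    # (gamma trigamma) term for the skew of the group mean
    c1 = (m1 * inv_f1 + alpha * m1**2) / n1 / (m1 + eps) ** 2
    c0 = (m0 * inv_f0 + alpha * m0**2) / n0 / (m0 + eps) ** 2
    se = np.sqrt(c1 * (1 + c1 / 2) + c0 * (1 + c0 / 2)) / np.log(2.0)
    se = np.maximum(se, 1e-12)
    z = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(lfc == 0.0, 1.0, p)
    return pd.DataFrame({"lfc": lfc, "se": se, "pvalue": p}, index=counts.index)


def bh_adjust(pvals: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up FDR values (NaNs passed through)."""
    arr = np.asarray(pvals, dtype=float)
    ok = ~np.isnan(arr)
    if ((arr[ok] < 0) | (arr[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(arr, np.nan)
    if ok.sum() > 0:
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    if isinstance(pvals, pd.Series):
        return pd.Series(out, index=pvals.index, name="fdr")
    return out


@dataclass
class TranscriptDEResult:
    """Per-gene, per-stage differential expression vs the oocyte."""

    lfc: pd.DataFrame  # genes x non-reference stages
    se: pd.DataFrame
    pvalue: pd.DataFrame
    fdr: pd.DataFrame
    reference: str

    def direction(self, fdr_max: float = 1e-5, min_abs_lfc: float = 1.0) -> pd.DataFrame:
        """'up' | 'down' | 'none' per gene and stage at the given thresholds."""
        up = (self.fdr <= fdr_max) & (self.lfc >= min_abs_lfc)
        down = (self.fdr <= fdr_max) & (self.lfc <= -min_abs_lfc)
        out = pd.DataFrame("none", index=self.lfc.index, columns=self.lfc.columns)
        out = out.mask(up, "up").mask(down, "down")
        return out


def transcript_de(
    counts: pd.DataFrame,
    design: StageDesign,
    reference: str | None = None,
    shrinkage: float = 0.0,
) -> TranscriptDEResult:
    """NB Wald test of every non-reference stage against the oocyte, with BH FDR."""
    reference = design.reference if reference is None else reference
    factors = size_factors(counts)
    lfc, se, pv, fdr = {}, {}, {}, {}
    for stage in design.stages:
        if stage == reference:
            continue
        res = nb_wald_test(counts, design, stage, reference, factors=factors, shrinkage=shrinkage)
        lfc[stage] = res["lfc"]
        se[stage] = res["se"]
        pv[stage] = res["pvalue"]
        fdr[stage] = bh_adjust(res["pvalue"])
    return TranscriptDEResult(
        lfc=pd.DataFrame(lfc),
        se=pd.DataFrame(se),
        pvalue=pd.DataFrame(pv),
        fdr=pd.DataFrame(fdr),
        reference=reference,
    )


@dataclass(frozen=True)
class DirectionSets:
    up: frozenset[str]
    down: frozenset[str]


def call_de_transcripts(
    result: TranscriptDEResult, fdr_max: float = 1e-5, min_abs_lfc: float = 1.0
) -> dict[str, DirectionSets]:
    """Per-stage up/down gene sets (disjoint by construction)."""
    if not 0 < fdr_max <= 1 or min_abs_lfc < 0:
        raise ValueError("invalid thresholds")
    direction = result.direction(fdr_max=fdr_max, min_abs_lfc=min_abs_lfc)
    out = {}
    for stage in direction.columns:
        col = direction[stage]
        out[stage] = DirectionSets(
            up=frozenset(col.index[col == "up"]),
            down=frozenset(col.index[col == "down"]),
        )
    return out
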