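"""Proteome processing: detection filter, quantile normalization, replicate
batch correction, stage ANOVA and fold-change profiles.

All functions operate on a proteins x samples DataFrame of log2 L/H ratios
(``NaN`` = not detected) plus a :class:`~embryomics.datatypes.StageDesign`.

The batch model treats the replicate id as a fixed categorical effect:
``log2 L/H = mu + X_rep + eps``; corrected values are the residuals of the
per-protein one-way fit with the protein's global mean added back.  The
stage test is the one-way ANOVA F-test of ``log2 L/H = mu + T_stage + eps``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DesignError, StageDesign, check_matrix

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    """Raised when a matrix cannot be normalized."""


def filter_detected(
    matrix: pd.DataFrame,
    design: StageDesign,
    min_reps: int = 2,
    min_stages: int = 1,
) -> pd.DataFrame:
    """Keep proteins observed in >= ``min_reps`` replicates of >= ``min_stages`` stages.

    ``(2, 1)`` reproduces the working set of quantified proteins ("at least
    two replicates of one or more developmental stages"); ``(2, 2)`` is the
    stricter variant used for normalization and the stage test.  Values are
    never modified, only rows dropped.
    """
    if min_reps < 1 or min_stages < 1:
        raise ValueError("min_reps and min_stages must be >= 1")
    check_matrix(matrix, design)
    observed = matrix.notna()
    stage_counts = pd.DataFrame(
        {
            stage: observed[design.samples_of_stage(stage)].sum(axis=1)
            for stage in design.stages
            if design.samples_of_stage(stage)
        }
    )
    n_ok = (stage_counts >= min_reps).sum(axis=1)
    return matrix.loc[n_ok >= min_stages]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize samples; missing entries stay missing.

    Complete-case columns end up sharing the identical sorted value vector
    (the rank-wise mean).  Columns with missing values are handled by
    mapping each sample's observed values, through linear interpolation of
    its own empirical quantiles, onto the pooled reference distribution
    (the mean of the per-sample quantile functions).
    """
    if matrix.shape[1] < 2:
        raise NormalizationError("quantile normalization needs >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    n_obs = (~np.isnan(values)).sum(axis=0)
    for j, n in enumerate(n_obs):
        if n < 2:
            raise NormalizationError(
                f"sample {matrix.columns[j]!r} has {int(n)} observed values (need >= 2)"
            )
    sorted_cols = [np.sort(values[~np.isnan(values[:, j]), j]) for j in range(values.shape[1])]
    grids = [np.linspace(0.0, 1.0, len(c)) for c in sorted_cols]

    def reference(p: np.ndarray) -> np.ndarray:
        return np.mean([np.interp(p, g, c) for g, c in zip(grids, sorted_cols)], axis=0)

    out = np.full_like(values, np.nan)
    for j in range(values.shape[1]):
        col = values[:, j]
        obs = ~np.isnan(col)
        ranks = stats.rankdata(col[obs], method="average")  # ties -> average rank
        p = (ranks - 1.0) / (n_obs[j] - 1.0)
        out[obs, j] = reference(p)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def batch_correct(matrix: pd.DataFrame, design: StageDesign) -> pd.DataFrame:
    """Remove per-replicate offsets: residuals of ``x = mu + X_rep`` plus ``mu``.

    For each protein the fitted value of the one-way fixed-effects model on
    the replicate id is the replicate mean, so the corrected value is
    ``x - mean(replicate) + mean(all observed)``.  Proteins observed in
    fewer than two replicate groups are passed through unchanged (logged).
    """
    check_matrix(matrix, design)
    reps = design.replicate_series(list(matrix.columns))
    if reps.isna().any():
        raise DesignError("design lacks replicate ids for some samples")
    values = matrix.to_numpy(dtype=float)
    obs = ~np.isnan(values)
    rep_labels = reps.to_numpy()
    uniq = list(dict.fromkeys(rep_labels))
    # per-protein per-replicate means
    rep_means = np.full((values.shape[0], len(uniq)), np.nan)
    rep_counts = np.zeros((values.shape[0], len(uniq)), dtype=int)
    for k, r in enumerate(uniq):
        cols = rep_labels == r
        block = values[:, cols]
        cnt = (~np.isnan(block)).sum(axis=1)
        with np.errstate(invalid="ignore"):
            rep_means[:, k] = np.where(cnt > 0, np.nansum(block, axis=1) / np.maximum(cnt, 1), np.nan)
        rep_counts[:, k] = cnt
    n_groups = (rep_counts > 0).sum(axis=1)
    n_tot = obs.sum(axis=1)
    with np.errstate(invalid="ignore"):
        grand = np.where(n_tot > 0, np.nansum(values, axis=1) / np.maximum(n_tot, 1), np.nan)

    fitted = np.full_like(values, np.nan)
    for k, r in enumerate(uniq):
        cols = rep_labels == r
        fitted[:, cols] = rep_means[:, [k]]
    corrected = values - fitted + grand[:, None]

    passthrough = n_groups < 2
    if passthrough.any():
        logger.warning(
            "%d proteins observed in <2 replicate groups passed through uncorrected",
            int(passthrough.sum()),
        )
        corrected[passthrough] = values[passthrough]
    corrected[~obs] = np.nan
    return pd.DataFrame(corrected, index=matrix.index, columns=matrix.columns)


def estimated_batch_offsets(matrix: pd.DataFrame, design: StageDesign) -> pd.Series:
    """Pre-correction replicate means relative to the grand mean (diagnostic)."""
    reps = design.replicate_series(list(matrix.columns))
    grand = np.nanmean(matrix.to_numpy(dtype=float))
    out = {}
    for r in dict.fromkeys(reps):
        cols = reps.index[reps == r]
        out[r] = float(np.nanmean(matrix[cols].to_numpy(dtype=float)) - grand)
    return pd.Series(out, name="batch_offset")


def anova_stage_test(matrix: pd.DataFrame, design: StageDesign) -> pd.Series:
    """Per-protein one-way ANOVA F-test across developmental stages.

    Proteins observed in fewer than 2 stages, or with fewer than 2 residual
    degrees of freedom, get ``NaN``.  A protein whose observed values are all
    identical gets p = 1 (degenerate zero-variance convention).
    """
    check_matrix(matrix, design)
    values = matrix.to_numpy(dtype=float)
    stages = design.stage_series(list(matrix.columns)).to_numpy()
    uniq = list(dict.fromkeys(stages))
    n_feat = values.shape[0]

    group_sum = np.zeros((n_feat, len(uniq)))
    group_n = np.zeros((n_feat, len(uniq)))
    for k, stage in enumerate(uniq):
        block = values[:, stages == stage]
        group_sum[:, k] = np.nansum(block, axis=1)
        group_n[:, k] = (~np.isnan(block)).sum(axis=1)
    total_n = group_n.sum(axis=1)
    total_sum = group_sum.sum(axis=1)
    total_sq = np.nansum(values**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        group_mean_sq = np.where(group_n > 0, group_sum**2 / np.maximum(group_n, 1), 0.0)
        ss_within = total_sq - group_mean_sq.sum(axis=1)
        grand_term = total_sum**2 / np.maximum(total_n, 1)
        ss_between = group_mean_sq.sum(axis=1) - grand_term
    k_obs = (group_n > 0).sum(axis=1)
    df_b = k_obs - 1.0
    df_w = total_n - k_obs

    p = np.full(n_feat, np.nan)
    valid = (k_obs >= 2) & (df_w >= 2)
    ss_within = np.maximum(ss_within, 0.0)
    ss_between = np.maximum(ss_between, 0.0)
    degenerate = valid & (ss_between + ss_within <= 1e-12)
    p[degenerate] = 1.0
    compute = valid & ~degenerate
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between[compute] / df_b[compute]) / (ss_within[compute] / df_w[compute])
    p[compute] = stats.f.sf(F, df_b[compute], df_w[compute])
    # zero within-variance but real between-variance: F = inf -> p = 0
    p[compute] = np.where(np.isnan(F) | np.isinf(F), 0.0, p[compute])
    return pd.Series(p, index=matrix.index, name="anova_p")


def stage_means(matrix: pd.DataFrame, design: StageDesign) -> pd.DataFrame:
    """Per-protein mean log2 L/H per stage over observed replicates (NaN if none)."""
    check_matrix(matrix, design)
    out = {}
    for stage in design.stages:
        cols = design.samples_of_stage(stage)
        cols = [c for c in cols if c in matrix.columns]
        if not cols:
            continue
        block = matrix[cols].to_numpy(dtype=float)
        cnt = (~np.isnan(block)).sum(axis=1)
        with np.errstate(invalid="ignore"):
            out[stage] = np.where(cnt > 0, np.nansum(block, axis=1) / np.maximum(cnt, 1), np.nan)
    return pd.DataFrame(out, index=matrix.index)


def fold_changes(
    matrix: pd.DataFrame, design: StageDesign, reference: str | None = None
) -> pd.DataFrame:
    """Log2 fold-change profile vs the reference stage (the oocyte).

    FC(stage) = mean(log2 L/H at stage) - mean(log2 L/H at reference);
    ``NaN`` wherever either side has no observations.
    """
    reference = design.reference if reference is None else reference
    if reference not in design.stages:
        raise DesignError(f"reference stage {reference!r} not in design")
    means = stage_means(matrix, design)
    if reference not in means.columns:
        raise DesignError(f"no samples for reference stage {reference!r}")
    fc = means.sub(means[reference], axis=0)
    return fc.drop(columns=[reference])


@dataclass
class DEResult:
    """Stage-wise differential-expression summary for the proteome."""

    pvalues: pd.Series  # ANOVA p per protein (NaN where untestable)
    stage_means: pd.DataFrame  # proteins x stages
    max_abs_log2fc: pd.Series  # max |difference| between any two stage means
    consecutive_log2fc: pd.DataFrame  # proteins x "stageA->stageB" transitions

    @property
    def transitions(self) -> list[str]:
        return list(self.consecutive_log2fc.columns)


def protein_de(matrix: pd.DataFrame, design: StageDesign) -> DEResult:
    """ANOVA p-values plus pairwise/consecutive stage fold changes."""
    p = anova_stage_test(matrix, design)
    means = stage_means(matrix, design)
    arr = means.to_numpy(dtype=float)
    all_nan = np.isnan(arr).all(axis=1)
    safe = np.where(all_nan[:, None], 0.0, arr)
    max_fc = np.nanmax(safe, axis=1) - np.nanmin(safe, axis=1)
    max_fc[all_nan] = np.nan
    ordered = [s for s in design.stages if s in means.columns]
    cons = {
        f"{a}->{b}": means[b] - means[a] for a, b in zip(ordered[:-1], ordered[1:])
    }
    return DEResult(
        pvalues=p,
        stage_means=means,
        max_abs_log2fc=pd.Series(max_fc, index=means.index, name="max_abs_log2fc"),
        consecutive_log2fc=pd.DataFrame(cons),
    )


def call_de_proteins(
    de: DEResult,
    p_max: float = 0.05,
    min_fc: float = 2.0,
    scope: str = "any_pair",
) -> tuple[pd.Index, dict[str, pd.Index]]:
    """Differentially expressed proteins at ``p <= p_max`` and fold change >= ``min_fc``.

    ``scope='any_pair'`` requires |log2 FC| >= log2(min_fc) between some pair
    of stages; ``scope='consecutive'`` between at least one consecutive pair,
    and additionally returns the per-transition protein sets.
    """
    if not 0 < p_max <= 1:
        raise ValueError("p_max must be in (0, 1]")
    if min_fc < 1:
        raise ValueError("min_fc must be >= 1")
    if scope not in ("any_pair", "consecutive"):
        raise ValueError(f"invalid scope {scope!r}")
    thr = np.log2(min_fc)
    sig = de.pvalues <= p_max
    if scope == "any_pair":
        hit = sig & (de.max_abs_log2fc >= thr)
        return de.pvalues.index[hit.fillna(False)], {}
    per_transition = {
        t: de.pvalues.index[(sig & (de.consecutive_log2fc[t].abs() >= thr)).fillna(False)]
        for t in de.transitions
    }
    any_hit = sig & (de.consecutive_log2fc.abs() >= thr).any(axis=1)
    return de.pvalues.index[any_hit.fillna(False)], per_transition
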