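"""PCA embeddings and replicate-correlation quality control."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import StageDesign, check_matrix


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    variance_fraction: np.ndarray  # percent of total variance per component
    loadings: pd.DataFrame  # features x components


def pca_embed(matrix: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """PCA of samples over the complete-case feature subset.

    Features (rows) are centered; the SVD of the samples x features matrix
    yields scores and percent variance explained.  Component signs are fixed
    by making each component's largest-magnitude loading positive.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples")
    complete = matrix.dropna(axis=0)
    if complete.shape[0] < n_components:
        raise ValueError(
            f"only {complete.shape[0]} complete features for {n_components} components"
        )
    X = complete.to_numpy(dtype=float).T  # samples x features
    X = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((s**2).sum())
    var_frac = 100.0 * s**2 / total if total > 0 else np.zeros_like(s)
    n_components = min(n_components, len(s))
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T
    # sign convention: largest-|loading| entry positive
    for c in range(n_components):
        peak = np.argmax(np.abs(loadings[:, c]))
        if loadings[peak, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=cols),
        variance_fraction=var_frac[:n_components],
        loadings=pd.DataFrame(loadings, index=complete.index, columns=cols),
    )


def replicate_correlation(matrix: pd.DataFrame, design: StageDesign) -> pd.DataFrame:
    """Min/max pairwise Spearman correlation between replicates, per stage.

    Correlations use complete-case features per column pair; stages with a
    single replicate get NaN.
    """
    check_matrix(matrix, design)
    rows = {}
    for stage in design.stages:
        cols = [c for c in design.samples_of_stage(stage) if c in matrix.columns]
        if len(cols) < 2:
            rows[stage] = {"min_rho": np.nan, "max_rho": np.nan}
            continue
        rhos = []
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                a = matrix[cols[i]].to_numpy(dtype=float)
                b = matrix[cols[j]].to_numpy(dtype=float)
                ok = ~(np.isnan(a) | np.isnan(b))
                if ok.sum() < 3:
                    continue
                rhos.append(float(stats.spearmanr(a[ok], b[ok]).statistic))
        if rhos:
            rows[stage] = {"min_rho": min(rhos), "max_rho": max(rhos)}
        else:
            rows[stage] = {"min_rho": np.nan, "max_rho": np.nan}
    return pd.DataFrame(rows).T
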