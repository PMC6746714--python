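"""Early/late stage classification and marker discovery from protein abundances.

A two-class linear discriminant (LDA) separates early (oocyte through 2-cell)
from late (4-cell through blastocyst) samples.  Because the number of proteins
far exceeds the 20 samples, the pooled within-class covariance is regularized
toward its diagonal: S_reg = (1 - lambda) S + lambda diag(S).  Proteins are
ranked as markers by their standardized discriminant weight |w_g| * SD_g, and
marker sets are tested for annotation enrichment with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import fisher_enrichment
from .datatypes import DesignError, StageDesign


def label_stages(
    design: StageDesign,
    early_stages: Sequence[str],
    late_stages: Sequence[str],
) -> pd.Series:
    """Map samples to 'early'/'late'; the two stage sets must partition the design."""
    early, late = set(early_stages), set(late_stages)
    if early & late:
        raise DesignError(f"stages in both sets: {sorted(early & late)}")
    if early | late != set(design.stages):
        missing = set(design.stages) - (early | late)
        extra = (early | late) - set(design.stages)
        raise DesignError(f"early/late sets must partition the stages (missing {sorted(missing)}, unknown {sorted(extra)})")
    return pd.Series(
        {s: ("early" if design.stage_of[s] in early else "late") for s in design.samples},
        name="label",
    )


@dataclass
class LDAModel:
    """Two-class shrinkage LDA: positive margin = 'late'."""

    weights: pd.Series  # per-feature discriminant weight
    intercept: float
    shrinkage: float
    classes: tuple[str, str] = ("early", "late")

    def decision_function(self, matrix: pd.DataFrame) -> pd.Series:
        """Signed margin per sample (columns of a features x samples matrix)."""
        X = matrix.loc[self.weights.index].to_numpy(dtype=float).T
        return pd.Series(X @ self.weights.to_numpy() + self.intercept, index=matrix.columns)

    def predict(self, matrix: pd.DataFrame) -> pd.Series:
        margin = self.decision_function(matrix)
        return margin.map(lambda v: self.classes[1] if v > 0 else self.classes[0])


def _solve_shrunk(S_diag: np.ndarray, Xc: np.ndarray, lam: float, delta: np.ndarray,
                  n_dof: int) -> np.ndarray:
    """Solve [(1-lam) Xc'Xc/n_dof + lam diag] w = delta via Woodbury when p >> n."""
    d = lam * S_diag
    d = np.maximum(d, 1e-12 * max(S_diag.mean(), 1e-30))  # guard constant features
    if lam >= 1.0 or Xc.shape[0] == 0:
        return delta / d
    U = np.sqrt((1.0 - lam) / n_dof) * Xc.T  # p x n
    Dinv_delta = delta / d
    Dinv_U = U / d[:, None]
    core = np.eye(U.shape[1]) + U.T @ Dinv_U
    rhs = U.T @ Dinv_delta
    return Dinv_delta - Dinv_U @ np.linalg.solve(core, rhs)


def fit_lda(
    matrix: pd.DataFrame,
    labels: pd.Series,
    shrinkage: float = 0.5,
) -> LDAModel:
    """Fit the shrinkage LDA on complete features (features x samples matrix).

    Both classes need >= 2 samples; the intercept places the boundary at the
    midpoint of the projected class means (equal priors).
    """
    if matrix.isna().any().any():
        raise ValueError("LDA requires complete features; filter or impute first")
    if not 0 <= shrinkage <= 1:
        raise ValueError("shrinkage must be in [0, 1]")
    labels = labels.loc[matrix.columns]
    classes = ("early", "late")
    idx0 = labels.index[labels == classes[0]]
    idx1 = labels.index[labels == classes[1]]
    if len(idx0) < 2 or len(idx1) < 2:
        raise ValueError("each class needs >= 2 samples")
    X0 = matrix[idx0].to_numpy(dtype=float).T  # n0 x p
    X1 = matrix[idx1].to_numpy(dtype=float).T
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    Xc = np.vstack([X0 - mu0, X1 - mu1])
    n_dof = len(idx0) + len(idx1) - 2
    S_diag = (Xc**2).sum(axis=0) / n_dof
    delta = mu1 - mu0
    w = _solve_shrunk(S_diag, Xc, shrinkage, delta, n_dof)
    intercept = -float(w @ (mu0 + mu1) / 2.0)
    return LDAModel(
        weights=pd.Series(w, index=matrix.index, name="weight"),
        intercept=intercept,
        shrinkage=shrinkage,
        classes=classes,
    )


def rank_auc(scores: pd.Series, labels: pd.Series) -> float:
    """Mann-Whitney AUC (midrank ties) of 'late' scores over 'early' scores."""
    s = scores.to_numpy(dtype=float)
    y = (labels.loc[scores.index] == "late").to_numpy()
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    order = pd.Series(s).rank(method="average").to_numpy()
    return float((order[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def loocv_auc(
    matrix: pd.DataFrame,
    labels: pd.Series,
    shrinkage: float = 0.5,
) -> tuple[float, pd.Series]:
    """Leave-one-out cross-validated AUC with per-sample held-out scores."""
    scores = {}
    for sample in matrix.columns:
        rest = [c for c in matrix.columns if c != sample]
        model = fit_lda(matrix[rest], labels.loc[rest], shrinkage=shrinkage)
        scores[sample] = float(model.decision_function(matrix[[sample]]).iloc[0])
    score_series = pd.Series(scores, name="loocv_score")
    return rank_auc(score_series, labels), score_series


@dataclass
class MarkerResult:
    """Standardized discriminant weights, ranking and classifier diagnostics."""

    relevance: pd.Series  # |w_g| * SD_g, descending order retained in `rank`
    rank: pd.Series  # 1-based rank (permutation of features)
    top: list[str]  # top-N marker ids
    weights: pd.Series
    auc: float | None = None
    loocv_scores: pd.Series | None = None
    margins: pd.Series | None = None


def rank_markers(
    model: LDAModel, matrix: pd.DataFrame, top_n: int = 20
) -> MarkerResult:
    """Rank proteins by |weight| * feature SD; ties broken by feature id."""
    if top_n > len(model.weights):
        raise ValueError("top_n exceeds the number of features")
    sd = matrix.loc[model.weights.index].std(axis=1, ddof=1)
    relevance = (model.weights.abs() * sd).rename("relevance")
    order = sorted(relevance.index, key=lambda g: (-relevance[g], g))
    rank = pd.Series({g: i + 1 for i, g in enumerate(order)}, name="rank")
    return MarkerResult(
        relevance=relevance,
        rank=rank,
        top=order[:top_n],
        weights=model.weights,
    )


def discover_markers(
    matrix: pd.DataFrame,
    design: StageDesign,
    early_stages: Sequence[str],
    late_stages: Sequence[str],
    shrinkage: float = 0.5,
    top_n: int = 20,
) -> MarkerResult:
    """Complete workflow: label, fit, LOOCV AUC, rank.

    ``matrix`` must be complete (restrict to features observed in all
    samples, or impute, beforehand).
    """
    labels = label_stages(design, early_stages, late_stages)
    labels = labels.loc[matrix.columns]
    model = fit_lda(matrix, labels, shrinkage=shrinkage)
    auc, scores = loocv_auc(matrix, labels, shrinkage=shrinkage)
    result = rank_markers(model, matrix, top_n=top_n)
    result.auc = auc
    result.loocv_scores = scores
    result.margins = model.decision_function(matrix)
    return result


def enrichment_test(
    marker_set: Sequence[str],
    gene_set: Sequence[str],
    universe: Sequence[str],
    alternative: str = "greater",
) -> tuple[float, float]:
    """Fisher exact test of gene-set membership vs markership over the universe.

    Returns (conditional-MLE odds ratio, p-value); the default alternative is
    enrichment (one-sided).
    """
    univ = set(universe)
    if not univ:
        raise ValueError("empty universe")
    markers = set(marker_set) & univ
    genes = set(gene_set) & univ
    if set(marker_set) - univ or set(gene_set) - univ:
        raise ValueError("marker_set and gene_set must be subsets of the universe")
    overlap = len(markers & genes)
    if alternative == "greater":
        return fisher_enrichment(overlap, len(markers), len(genes), len(univ))
    from scipy import stats
    from scipy.stats.contingency import odds_ratio as _or

    table = np.array(
        [
            [overlap, len(markers) - overlap],
            [len(genes) - overlap, len(univ) - len(markers) - len(genes) + overlap],
        ]
    )
    res = stats.fisher_exact(table, alternative=alternative)
    try:
        or_cmle = float(_or(table, kind="conditional").statistic)
    except ValueError:
        or_cmle = np.nan
    return or_cmle, float(res.pvalue)
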