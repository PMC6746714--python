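"""Fuzzy c-means clustering of z-scored fold-change profiles and the
protein-vs-transcript cluster comparison.

The clustering is the standard fuzzy c-means of Bezdek (Euclidean distance,
fuzzifier ``m``), run from several random restarts and kept deterministic by
seed.  Cluster similarity across omic layers is measured as the Pearson
correlation between per-stage *median* fold-change profiles of cluster
members (aligned through the protein->transcript stage map), membership
overlap with one-sided Fisher exact tests, and a meta 2x2 Fisher test that
asks whether profile-similar cluster pairs also share more members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .datatypes import DEFAULT_STAGE_MAP, CognateMap

logger = logging.getLogger(__name__)


def zscore_profiles(fc_profile: pd.DataFrame) -> pd.DataFrame:
    """Standardize each profile to mean 0, sample SD 1 across stages.

    All-NaN profiles are dropped; zero-variance profiles map to all zeros
    (logged).  Profiles must have >= 2 defined stage values.
    """
    mat = fc_profile.dropna(how="all")
    n_def = mat.notna().sum(axis=1)
    if (n_def < 2).any():
        raise ValueError("profiles need >= 2 defined stage values to be z-scored")
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.warning("%d zero-variance profiles mapped to all-zeros", int(flat.sum()))
    z = mat.sub(mean, axis=0).div(sd.where(~flat, 1.0), axis=0)
    z[flat] = 0.0
    return z


@dataclass
class FuzzyClustering:
    """Result of one fuzzy c-means run (best restart)."""

    centroids: pd.DataFrame  # k x stages
    membership: pd.DataFrame  # features x k, rows sum to 1
    hard: pd.Series  # argmax membership (ties -> lowest cluster index)
    m: float
    objective: float
    seed: int

    @property
    def k(self) -> int:
        return len(self.centroids)

    def members(self, cluster: int) -> pd.Index:
        return self.hard.index[self.hard == cluster]


def _plusplus_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread the initial centroids over the data."""
    n = X.shape[0]
    centroids = [X[rng.integers(n)]]
    d2 = ((X - centroids[0]) ** 2).sum(axis=1)
    for _ in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids.append(X[rng.integers(n)])
            continue
        centroids.append(X[rng.choice(n, p=d2 / total)])
        d2 = np.minimum(d2, ((X - centroids[-1]) ** 2).sum(axis=1))
    return np.array(centroids)


def _fcm_once(
    X: np.ndarray, k: int, m: float, rng: np.random.Generator, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float]:
    centroids = _plusplus_init(X, k, rng)
    prev_obj = np.inf
    u = np.full((X.shape[0], k), 1.0 / k)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-300
        row_zero = zero.any(axis=1)
        # normalize by the row minimum before exponentiating to avoid overflow
        d2_safe = np.maximum(d2, 1e-300)
        ratio = d2_safe / d2_safe.min(axis=1, keepdims=True)
        u = ratio ** (-1.0 / (m - 1.0))
        u[row_zero] = zero[row_zero].astype(float)
        u /= u.sum(axis=1, keepdims=True)
        um = u**m
        centroids = (um.T @ X) / um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        obj = float((um * d2).sum())
        if abs(prev_obj - obj) < tol:
            prev_obj = obj
            break
        prev_obj = obj
    return centroids, u, prev_obj


def fuzzy_cmeans(
    matrix: pd.DataFrame,
    k: int,
    m: float = 1.25,
    seed: int = 0,
    n_restarts: int = 3,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> FuzzyClustering:
    """Fuzzy c-means with ``n_restarts`` random initializations (best objective).

    Centroid update: c_j = sum_i u_ij^m x_i / sum_i u_ij^m; membership
    update: u_ij = 1 / sum_l (d_ij / d_il)^(2/(m-1)); iterated until the
    objective changes by < ``tol`` or ``max_iter`` sweeps.
    """
    if matrix.isna().any().any():
        raise ValueError("clustering input must be complete (no NaN)")
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of features ({n})")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if k == 1:
        centroid = X.mean(axis=0, keepdims=True)
        u = np.ones((n, 1))
        obj = float(((X - centroid) ** 2).sum())
        best = (centroid, u, obj)
    else:
        seeds = np.random.SeedSequence(seed).spawn(n_restarts)
        best = None
        for ss in seeds:
            res = _fcm_once(X, k, m, np.random.default_rng(ss), tol, max_iter)
            if best is None or res[2] < best[2]:
                best = res
    centroids, u, obj = best
    hard = u.argmax(axis=1)  # argmax returns the lowest index on ties
    return FuzzyClustering(
        centroids=pd.DataFrame(centroids, columns=matrix.columns),
        membership=pd.DataFrame(u, index=matrix.index, columns=range(u.shape[1])),
        hard=pd.Series(hard, index=matrix.index, name="cluster"),
        m=m,
        objective=obj,
        seed=seed,
    )


def _min_centroid_distance(clustering: FuzzyClustering) -> float:
    c = clustering.centroids.to_numpy(dtype=float)
    d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(axis=2))
    iu = np.triu_indices(len(c), k=1)
    return float(d[iu].min())


@dataclass
class KSelection:
    k: int
    d_min: pd.Series  # D_min(k) curve
    threshold: float


def select_k(
    matrix: pd.DataFrame,
    k_range: Sequence[int] = range(2, 10),
    m: float = 1.25,
    seed: int = 0,
    drop_frac: float = 0.4,
    n_restarts: int = 6,
) -> KSelection:
    """Choose k from the minimum pairwise centroid distance curve.

    D_min(k) stays of the order of the true archetype separation while
    k <= k_true and collapses once a genuine cluster is split; the chosen k
    is the largest k before D_min first drops below ``drop_frac`` times its
    k=2 value.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    if len(ks) == 1:
        return KSelection(k=ks[0], d_min=pd.Series(dtype=float), threshold=np.nan)
    if ks[0] < 2:
        raise ValueError("k_range must start at >= 2")
    d_min = {}
    for k in ks:
        clust = fuzzy_cmeans(matrix, k, m=m, seed=seed, n_restarts=n_restarts)
        d_min[k] = _min_centroid_distance(clust)
    curve = pd.Series(d_min, name="d_min")
    threshold = drop_frac * curve.iloc[0]
    chosen = ks[0]
    for k in ks:
        if curve[k] < threshold:
            break
        chosen = k
    return KSelection(k=chosen, d_min=curve, threshold=threshold)


def fisher_enrichment(
    overlap: int, size_a: int, size_b: int, universe: int
) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test; returns (conditional-MLE OR, p)."""
    if universe <= 0:
        raise ValueError("empty universe")
    table = np.array(
        [
            [overlap, size_a - overlap],
            [size_b - overlap, universe - size_a - size_b + overlap],
        ]
    )
    if (table < 0).any():
        raise ValueError("inconsistent 2x2 table")
    res = stats.fisher_exact(table, alternative="greater")
    try:
        or_cmle = float(_odds_ratio(table, kind="conditional").statistic)
    except ValueError:
        or_cmle = np.nan
    return or_cmle, float(res.pvalue)


@dataclass
class ClusterComparison:
    """Pairwise protein-cluster vs transcript-cluster comparison."""

    r: pd.DataFrame  # Pearson r of median profiles (protein x transcript clusters)
    overlap: pd.DataFrame  # shared members (via cognate map)
    pvalues: pd.DataFrame  # one-sided Fisher enrichment p
    universe: int
    protein_members: dict[int, list[str]]
    transcript_members: dict[int, list[str]]


def _median_profiles(fc: pd.DataFrame, clustering: FuzzyClustering) -> pd.DataFrame:
    rows = {}
    for c in range(clustering.k):
        members = [g for g in clustering.members(c) if g in fc.index]
        rows[c] = fc.loc[members].median(axis=0)
    return pd.DataFrame(rows).T


def compare_clusterings(
    protein_clust: FuzzyClustering,
    transcript_clust: FuzzyClustering,
    cognate_map: CognateMap,
    protein_fc: pd.DataFrame,
    transcript_fc: pd.DataFrame,
    stage_map: Mapping[str, tuple[str, ...]] | None = None,
) -> ClusterComparison:
    """Median-profile correlations and membership-overlap Fisher tests.

    The Pearson correlation is computed between the per-stage median log2
    fold-change profile of each protein cluster and each transcript cluster,
    with profiles aligned through the stage map (a protein stage facing two
    transcript stages contributes one aligned pair per transcript stage).
    The overlap universe is the set of genes clustered in both layers.
    """
    stage_map = DEFAULT_STAGE_MAP if stage_map is None else stage_map
    p_prof = _median_profiles(protein_fc, protein_clust)
    t_prof = _median_profiles(transcript_fc, transcript_clust)
    pairs = [
        (ps, ts)
        for ps in p_prof.columns
        for ts in stage_map.get(ps, ())
        if ts in t_prof.columns
    ]
    if len(pairs) < 3:
        raise ValueError("stage map aligns fewer than 3 stage pairs")

    r = pd.DataFrame(np.nan, index=range(protein_clust.k), columns=range(transcript_clust.k))
    for a in range(protein_clust.k):
        for b in range(transcript_clust.k):
            x = np.array([p_prof.loc[a, ps] for ps, _ in pairs], dtype=float)
            y = np.array([t_prof.loc[b, ts] for _, ts in pairs], dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                continue
            r.loc[a, b] = float(stats.pearsonr(x[ok], y[ok]).statistic)

    p2t = cognate_map.protein_to_transcript()
    clustered_p = set(protein_clust.hard.index)
    clustered_t = set(transcript_clust.hard.index)
    universe = [p for p in clustered_p if p2t.get(p) in clustered_t]
    n_univ = len(universe)
    p_members = {
        c: sorted(set(protein_clust.members(c)) & set(universe))
        for c in range(protein_clust.k)
    }
    t_members_p = {
        c: sorted(
            {p for p in universe if transcript_clust.hard.get(p2t[p]) == c}
        )
        for c in range(transcript_clust.k)
    }
    overlap = pd.DataFrame(0, index=r.index, columns=r.columns)
    pvals = pd.DataFrame(np.nan, index=r.index, columns=r.columns)
    for a, am in p_members.items():
        for b, bm in t_members_p.items():
            o = len(set(am) & set(bm))
            overlap.loc[a, b] = o
            _, pvals.loc[a, b] = fisher_enrichment(o, len(am), len(bm), n_univ)
    return ClusterComparison(
        r=r,
        overlap=overlap,
        pvalues=pvals,
        universe=n_univ,
        protein_members=p_members,
        transcript_members={
            c: sorted(transcript_clust.members(c)) for c in range(transcript_clust.k)
        },
    )


@dataclass
class MetaOverlapResult:
    odds_ratio: float  # conditional MLE
    sample_odds_ratio: float
    pvalue: float  # one-sided Fisher
    table: np.ndarray  # [[high-r & sig, high-r & not], [low-r & sig, low-r & not]]


def meta_overlap_test(
    comparison: ClusterComparison, r_min: float = 0.5, p_max: float = 0.05
) -> MetaOverlapResult:
    """Do profile-similar cluster pairs share more members than chance?

    Every (protein cluster, transcript cluster) pair is classified by
    (r >= r_min) x (overlap p <= p_max); the resulting 2x2 table is tested
    with a one-sided Fisher exact test (enrichment of significant overlaps
    among high-correlation pairs).
    """
    r = comparison.r.to_numpy(dtype=float).ravel()
    p = comparison.pvalues.to_numpy(dtype=float).ravel()
    ok = ~(np.isnan(r) | np.isnan(p))
    if ok.sum() < 1:
        raise ValueError("no comparable cluster pairs")
    high = r[ok] >= r_min
    sig = p[ok] <= p_max
    table = np.array(
        [
            [int((high & sig).sum()), int((high & ~sig).sum())],
            [int((~high & sig).sum()), int((~high & ~sig).sum())],
        ]
    )
    res = stats.fisher_exact(table, alternative="greater")
    a, b = table[0]
    c, d = table[1]
    sample_or = np.inf if b * c == 0 and a * d > 0 else (
        np.nan if b * c == 0 else a * d / (b * c)
    )
    try:
        or_cmle = float(_odds_ratio(table, kind="conditional").statistic)
    except ValueError:
        or_cmle = np.nan
    return MetaOverlapResult(
        odds_ratio=or_cmle,
        sample_odds_ratio=float(sample_or),
        pvalue=float(res.pvalue),
        table=table,
    )
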