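"""Orthogonal validation: correlate external stage profiles with mean L/H
profiles and compute a permutation empirical p-value.

External measurements (enzymatic assays, quantified immunofluorescence) live
on arbitrary monotone scales, so agreement with the MS profile is assessed by
Spearman rank correlation per measurement set.  Significance of the number of
strongly correlated sets (rho >= 0.6) is judged against random re-assignments
of measurement sets to protein profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import MeasurementSet

logger = logging.getLogger(__name__)


def profile_correlation(
    measurement_sets: Sequence[MeasurementSet],
    mean_lh_profiles: pd.DataFrame,
) -> pd.Series:
    """Spearman rho per measurement set vs its protein's mean-L/H stage profile.

    ``mean_lh_profiles`` is proteins x stages.  Correlations use the stages
    shared by the measurement and a defined profile value; sets with < 3
    shared stages get NaN (logged).
    """
    out = {}
    for ms in measurement_sets:
        if ms.protein not in mean_lh_profiles.index:
            logger.warning("measurement set %s: protein %s has no profile", ms.name, ms.protein)
            out[ms.name] = np.nan
            continue
        profile = mean_lh_profiles.loc[ms.protein]
        shared = [s for s in ms.values.index if s in profile.index and not np.isnan(profile[s])]
        if len(shared) < 3:
            logger.warning("measurement set %s: only %d shared stages", ms.name, len(shared))
            out[ms.name] = np.nan
            continue
        rho = stats.spearmanr(ms.values[shared], profile[shared]).statistic
        out[ms.name] = float(rho)
    return pd.Series(out, name="spearman_rho")


@dataclass
class PermutationResult:
    """Empirical p-value for the count of strongly correlated measurement sets."""

    pvalue: float  # P(perm statistic >= observed), relative frequency
    observed: int
    n_perm: int
    rho_min: float
    null_statistics: np.ndarray  # statistic per permutation
    n_greater_equal: int
    n_greater: int


def empirical_pvalue(
    measurement_sets: Sequence[MeasurementSet],
    profiles: pd.DataFrame,
    rho_min: float = 0.6,
    n_perm: int = 10_000,
    seed: int = 0,
    with_replacement: bool = False,
) -> PermutationResult:
    """Permutation test: randomly re-associate measurements and profiles.

    The observed statistic is the number of sets with rho >= ``rho_min``.
    Each permutation re-pairs every measurement set with one of the proteins
    carrying a measurement (a full random matching without replacement by
    default) and recomputes the statistic; p is the relative frequency of
    permutation statistics >= observed (no add-one correction).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(measurement_sets) < 2:
        raise ValueError("need >= 2 measurement sets")
    proteins = [ms.protein for ms in measurement_sets]
    n = len(measurement_sets)
    # rho of set i against the profile of protein j, for all candidate pairings
    rho_matrix = np.full((n, n), np.nan)
    for j, prot in enumerate(proteins):
        if prot not in profiles.index:
            continue
        profile = profiles.loc[prot]
        for i, ms in enumerate(measurement_sets):
            shared = [
                s for s in ms.values.index if s in profile.index and not np.isnan(profile[s])
            ]
            if len(shared) < 3:
                continue
            rho_matrix[i, j] = stats.spearmanr(ms.values[shared], profile[shared]).statistic
    hits = rho_matrix >= rho_min  # NaN -> False
    observed = int(np.trace(hits))

    rng = np.random.default_rng(seed)
    stats_null = np.empty(n_perm, dtype=int)
    rows = np.arange(n)
    for b in range(n_perm):
        perm = rng.integers(0, n, size=n) if with_replacement else rng.permutation(n)
        stats_null[b] = int(hits[rows, perm].sum())
    n_ge = int((stats_null >= observed).sum())
    n_gt = int((stats_null > observed).sum())
    return PermutationResult(
        pvalue=n_ge / n_perm,
        observed=observed,
        n_perm=n_perm,
        rho_min=rho_min,
        null_statistics=stats_null,
        n_greater_equal=n_ge,
        n_greater=n_gt,
    )
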