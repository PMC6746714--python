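"""Transcript->protein concordance via the difference of empirical-CDF areas.

For a transcript stage S_i and protein stage S_j, proteins are split into two
disjoint groups by the direction of their cognate transcript's change at S_i
relative to the oocyte.  The signed concordance score is the integral of
F_down - F_up over the union support of the two groups' protein log2
fold-change distributions at S_j, normalized by the global protein
fold-change range; it is positive when the up-group CDF sits to the right of
the down-group CDF (protein changes follow transcript direction).  The raw
(unnormalized) area equals mean(up) - mean(down) exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CognateMap
from .transcriptome import DirectionSets

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StepCDF:
    """Right-continuous empirical CDF of a finite sample."""

    values: np.ndarray  # sorted
    probabilities: np.ndarray  # nondecreasing, ending at 1

    @classmethod
    def from_sample(cls, sample: Sequence[float]) -> "StepCDF":
        v = np.sort(np.asarray(sample, dtype=float))
        if v.size == 0:
            raise ValueError("empty sample")
        p = np.arange(1, v.size + 1) / v.size
        return cls(values=v, probabilities=p)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.values, x, side="right") / self.values.size


def cdf_area_difference(
    down_fcs: Sequence[float],
    up_fcs: Sequence[float],
    norm_range: float = 1.0,
) -> float:
    """Signed area between the two empirical CDFs over their union support.

    score = (1/norm_range) * integral of [F_down(x) - F_up(x)] dx; positive
    when the up-group values are shifted to the right of the down-group.
    """
    if norm_range <= 0:
        raise ValueError("norm_range must be positive")
    down = np.asarray(down_fcs, dtype=float)
    up = np.asarray(up_fcs, dtype=float)
    if down.size == 0 or up.size == 0:
        raise ValueError("both groups must be nonempty")
    f_down = StepCDF.from_sample(down)
    f_up = StepCDF.from_sample(up)
    grid = np.unique(np.concatenate([f_down.values, f_up.values]))
    widths = np.diff(grid)
    heights = f_down(grid[:-1]) - f_up(grid[:-1])
    return float(np.sum(heights * widths)) / norm_range


def split_by_direction(
    calls_at_stage: DirectionSets,
    cognate_map: CognateMap,
    protein_fcs_at_stage: pd.Series,
) -> tuple[pd.Series, pd.Series]:
    """Protein fold changes grouped by the cognate transcript's direction.

    Only proteins with a defined fold change (detected at both the target
    stage and the oocyte) are kept; unmapped transcripts are dropped and
    counted in the log.
    """
    t2p = cognate_map.transcript_to_protein()
    out = []
    for transcripts in (calls_at_stage.down, calls_at_stage.up):
        proteins = [t2p[t] for t in transcripts if t in t2p]
        n_unmapped = len(transcripts) - len(proteins)
        if n_unmapped:
            logger.info("dropped %d transcripts without a cognate protein", n_unmapped)
        vals = protein_fcs_at_stage.reindex(proteins).dropna()
        out.append(vals)
    down_vals, up_vals = out
    return down_vals, up_vals


@dataclass
class ConcordanceGrid:
    """Transcript-stage x protein-stage matrix of normalized CDF-area scores."""

    scores: pd.DataFrame  # NaN where skipped
    n_down: pd.DataFrame
    n_up: pd.DataFrame
    skip_reason: pd.DataFrame  # "" where computed
    norm_range: float
    min_n: int

    def max_cell(self) -> tuple[str, str]:
        """(transcript stage, protein stage) of the largest defined score."""
        arr = self.scores.to_numpy(dtype=float)
        if np.isnan(arr).all():
            raise ValueError("grid has no defined cells")
        i, j = np.unravel_index(np.nanargmax(arr), arr.shape)
        return str(self.scores.index[i]), str(self.scores.columns[j])


def concordance_grid(
    transcript_calls_by_stage: Mapping[str, DirectionSets],
    protein_fc_profile: pd.DataFrame,
    cognate_map: CognateMap,
    min_n: int = 25,
    norm: str = "global",
) -> ConcordanceGrid:
    """Fill the full stage x stage grid of concordance scores.

    Cells where either direction group holds fewer than ``min_n`` proteins are
    left undefined with a reason.  With ``norm='global'`` every cell is
    normalized by the max-min range of all protein fold changes entering the
    grid; ``norm='per_cell'`` uses each cell's own range.
    """
    if norm not in ("global", "per_cell"):
        raise ValueError(f"invalid norm {norm!r}")
    t_stages = list(transcript_calls_by_stage)
    p_stages = list(protein_fc_profile.columns)
    groups: dict[tuple[str, str], tuple[pd.Series, pd.Series]] = {}
    pooled: list[np.ndarray] = []
    for ts in t_stages:
        for ps in p_stages:
            down, up = split_by_direction(
                transcript_calls_by_stage[ts], cognate_map, protein_fc_profile[ps]
            )
            groups[(ts, ps)] = (down, up)
            if len(down) >= min_n and len(up) >= min_n:
                pooled.extend([down.to_numpy(), up.to_numpy()])
    if pooled:
        allv = np.concatenate(pooled)
        global_range = float(allv.max() - allv.min()) if allv.size else np.nan
    else:
        global_range = np.nan

    scores = pd.DataFrame(np.nan, index=t_stages, columns=p_stages)
    n_down = pd.DataFrame(0, index=t_stages, columns=p_stages)
    n_up = pd.DataFrame(0, index=t_stages, columns=p_stages)
    reason = pd.DataFrame("", index=t_stages, columns=p_stages)
    for (ts, ps), (down, up) in groups.items():
        n_down.loc[ts, ps] = len(down)
        n_up.loc[ts, ps] = len(up)
        if len(down) < min_n or len(up) < min_n:
            reason.loc[ts, ps] = "insufficient"
            continue
        if norm == "global":
            rng = global_range
        else:
            cell = np.concatenate([down.to_numpy(), up.to_numpy()])
            rng = float(cell.max() - cell.min())
        if not np.isfinite(rng) or rng <= 0:
            reason.loc[ts, ps] = "degenerate_range"
            continue
        scores.loc[ts, ps] = cdf_area_difference(down, up, norm_range=rng)
    return ConcordanceGrid(
        scores=scores,
        n_down=n_down,
        n_up=n_up,
        skip_reason=reason,
        norm_range=global_range,
        min_n=min_n,
    )


def change_correlation(
    protein_fc_profile: pd.DataFrame,
    transcript_fc_profile: pd.DataFrame,
    stage_pairs: Sequence[tuple[str, str]],
    cognate_map: CognateMap | None = None,
) -> pd.Series:
    """Spearman correlation of (transcript FC at S_i, protein FC at S_j) over genes.

    ``stage_pairs`` is a sequence of (transcript stage, protein stage); rows
    are matched via the cognate map (identity if omitted); pairs with fewer
    than 3 complete gene pairs get NaN.
    """
    if cognate_map is not None:
        p2t = cognate_map.protein_to_transcript()
        proteins = [p for p in protein_fc_profile.index if p in p2t]
        transcripts = [p2t[p] for p in proteins]
    else:
        proteins = [p for p in protein_fc_profile.index if p in transcript_fc_profile.index]
        transcripts = proteins
    out = {}
    for ts, ps in stage_pairs:
        t_vals = transcript_fc_profile.loc[transcripts, ts].to_numpy(dtype=float)
        p_vals = protein_fc_profile.loc[proteins, ps].to_numpy(dtype=float)
        ok = ~(np.isnan(t_vals) | np.isnan(p_vals))
        if ok.sum() < 3:
            out[(ts, ps)] = np.nan
            continue
        rho = stats.spearmanr(t_vals[ok], p_vals[ok]).statistic
        out[(ts, ps)] = float(rho)
    return pd.Series(out, name="spearman_rho")
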