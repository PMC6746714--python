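"""Proteome completeness from protein-complex member coverage.

Because every member of an annotated complex is required for its function,
undetected members indicate a detection limit rather than biological absence;
the distribution of per-complex detected-member fractions therefore estimates
how complete the measured proteome is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd


@dataclass
class CoverageResult:
    """Per-complex, per-stage detected-member fractions and their medians."""

    fractions: pd.DataFrame  # complexes x stages, values in [0, 1]
    stage_medians: pd.Series
    overall_fractions: pd.Series  # detection in >= 1 replicate of >= 1 stage
    overall_median: float
    n_complexes: int


def complex_coverage(
    detected_by_stage: Mapping[str, Iterable[str]],
    catalog: Mapping[str, Iterable[str]],
    min_size: int = 2,
    universe: Iterable[str] | None = None,
) -> CoverageResult:
    """Fraction of each complex's members detected, per stage and overall.

    ``detected_by_stage`` maps a stage to the proteins detected in at least
    one replicate of that stage; the overall fraction uses the union over
    stages.  If ``universe`` is given, complex members outside it are removed
    first (so coverage measures detection, not annotation mismatch), and
    complexes that fall below ``min_size`` members are dropped.
    """
    members = {c: set(m) for c, m in catalog.items()}
    if universe is not None:
        uni = set(universe)
        members = {c: m & uni for c, m in members.items()}
    members = {c: m for c, m in members.items() if len(m) >= min_size}
    if not members:
        raise ValueError("no complexes left after filtering")

    stage_sets = {s: set(d) for s, d in detected_by_stage.items()}
    union = set().union(*stage_sets.values()) if stage_sets else set()

    names = sorted(members)
    fractions = pd.DataFrame(
        {
            s: [len(members[c] & det) / len(members[c]) for c in names]
            for s, det in stage_sets.items()
        },
        index=names,
    )
    overall = pd.Series(
        [len(members[c] & union) / len(members[c]) for c in names],
        index=names,
        name="overall",
    )
    return CoverageResult(
        fractions=fractions,
        stage_medians=fractions.median(axis=0),
        overall_fractions=overall,
        overall_median=float(overall.median()),
        n_complexes=len(names),
    )
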