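"""Shared containers for the proteome/transcriptome analysis.

Expression data are kept in plain :class:`pandas.DataFrame` objects
(features in rows, samples in columns, ``NaN`` marking values that were
not detected).  The classes here carry the experimental design metadata
that the matrices themselves cannot: which sample belongs to which
developmental stage and replicate, how the proteome stage axis maps onto
the transcriptome stage axis, and the protein<->transcript cognate
relation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd


class DesignError(ValueError):
    """Raised when a sample/stage design is inconsistent."""


#: Canonical proteome stage order: mature oocyte through blastocyst.
PROTEIN_STAGES = ("oocyte", "1cell", "2cell", "4cell", "8cell", "morula", "blastocyst")

#: Transcriptome stages split the 2-cell stage into early and late to
#: resolve embryonic genome activation.
TRANSCRIPT_STAGES = (
    "oocyte",
    "1cell",
    "2cell_early",
    "2cell_late",
    "4cell",
    "8cell",
    "morula",
    "blastocyst",
)

#: Protein stage -> transcript stage(s).  The single 2-cell proteome stage
#: faces both 2-cell transcriptome stages.
DEFAULT_STAGE_MAP: dict[str, tuple[str, ...]] = {
    "oocyte": ("oocyte",),
    "1cell": ("1cell",),
    "2cell": ("2cell_early", "2cell_late"),
    "4cell": ("4cell",),
    "8cell": ("8cell",),
    "morula": ("morula",),
    "blastocyst": ("blastocyst",),
}

_SAMPLE_RE = re.compile(r"^(?P<stage>.+)_rep(?P<rep>\d+)$")


@dataclass(frozen=True)
class StageDesign:
    """Sample -> (stage, replicate) assignment with an ordered stage list.

    Parameters
    ----------
    stage_of :
        Mapping from sample id to stage label.
    replicate_of :
        Mapping from sample id to replicate id (the batch variable).
    stages :
        Ordered tuple of stage labels (developmental order).
    reference :
        Reference stage for fold changes (the mature oocyte).
    """

    stage_of: Mapping[str, str]
    replicate_of: Mapping[str, str]
    stages: tuple[str, ...]
    reference: str = "oocyte"

    def __post_init__(self) -> None:
        if len(self.stages) == 0:
            raise DesignError("stage list is empty")
        if len(set(self.stages)) != len(self.stages):
            raise DesignError("duplicate stage labels")
        if self.reference not in self.stages:
            raise DesignError(f"reference stage {self.reference!r} not in stage list")
        unknown = set(self.stage_of.values()) - set(self.stages)
        if unknown:
            raise DesignError(f"samples assigned to unknown stages: {sorted(unknown)}")
        if set(self.stage_of) != set(self.replicate_of):
            raise DesignError("stage and replicate assignments cover different samples")

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.stage_of)

    @property
    def replicates(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.replicate_of.values():
            seen.setdefault(r, None)
        return tuple(seen)

    def non_reference_stages(self) -> tuple[str, ...]:
        return tuple(s for s in self.stages if s != self.reference)

    def samples_of_stage(self, stage: str) -> list[str]:
        if stage not in self.stages:
            raise DesignError(f"unknown stage {stage!r}")
        return [s for s, st in self.stage_of.items() if st == stage]

    def samples_of_replicate(self, replicate: str) -> list[str]:
        return [s for s, r in self.replicate_of.items() if r == replicate]

    def stage_series(self, samples: Sequence[str] | None = None) -> pd.Series:
        samples = list(self.samples if samples is None else samples)
        missing = [s for s in samples if s not in self.stage_of]
        if missing:
            raise DesignError(f"samples not in design: {missing}")
        return pd.Series({s: self.stage_of[s] for s in samples}, name="stage")

    def replicate_series(self, samples: Sequence[str] | None = None) -> pd.Series:
        samples = list(self.samples if samples is None else samples)
        return pd.Series({s: self.replicate_of[s] for s in samples}, name="replicate")

    def subset(self, samples: Iterable[str]) -> "StageDesign":
        samples = list(samples)
        stages = tuple(s for s in self.stages if s in {self.stage_of[x] for x in samples})
        return StageDesign(
            stage_of={s: self.stage_of[s] for s in samples},
            replicate_of={s: self.replicate_of[s] for s in samples},
            stages=stages,
            reference=self.reference if self.reference in stages else stages[0],
        )

    @classmethod
    def from_sample_names(
        cls,
        samples: Sequence[str],
        stage_order: Sequence[str] | None = None,
        reference: str | None = None,
    ) -> "StageDesign":
        """Build a design from ``<stage>_rep<k>`` sample names."""
        stage_of: dict[str, str] = {}
        replicate_of: dict[str, str] = {}
        order: list[str] = []
        for name in samples:
            m = _SAMPLE_RE.match(name)
            if m is None:
                raise DesignError(f"malformed sample name {name!r} (expected <stage>_rep<k>)")
            stage = m.group("stage")
            stage_of[name] = stage
            replicate_of[name] = f"rep{int(m.group('rep'))}"
            if stage not in order:
                order.append(stage)
        if stage_order is not None:
            extra = set(order) - set(stage_order)
            if extra:
                raise DesignError(f"samples use stages outside the given order: {sorted(extra)}")
            order = [s for s in stage_order if s in set(order)]
        ref = reference if reference is not None else order[0]
        return cls(stage_of=stage_of, replicate_of=replicate_of, stages=tuple(order), reference=ref)


@dataclass(frozen=True)
class CognateMap:
    """Protein <-> transcript cognate relation (products of the same gene)."""

    table: pd.DataFrame  # columns: protein_id, transcript_id

    def __post_init__(self) -> None:
        cols = list(self.table.columns)
        if cols[:2] != ["protein_id", "transcript_id"]:
            raise ValueError("cognate map needs columns (protein_id, transcript_id)")

    @classmethod
    def identity(cls, ids: Iterable[str]) -> "CognateMap":
        ids = list(ids)
        return cls(pd.DataFrame({"protein_id": ids, "transcript_id": ids}))

    def protein_to_transcript(self) -> dict[str, str]:
        return dict(zip(self.table["protein_id"], self.table["transcript_id"]))

    def transcript_to_protein(self) -> dict[str, str]:
        return dict(zip(self.table["transcript_id"], self.table["protein_id"]))

    def __len__(self) -> int:
        return len(self.table)


def check_matrix(matrix: pd.DataFrame, design: StageDesign) -> None:
    """Validate that every matrix column is a sample known to the design."""
    unknown = [c for c in matrix.columns if c not in design.stage_of]
    if unknown:
        raise DesignError(f"matrix columns not in design: {unknown}")
    if matrix.columns.duplicated().any():
        raise DesignError("duplicate sample columns")
    if matrix.index.duplicated().any():
        raise DesignError("duplicate feature ids")


def map_protein_stage(
    protein_stage: str, stage_map: Mapping[str, tuple[str, ...]] | None = None
) -> tuple[str, ...]:
    stage_map = DEFAULT_STAGE_MAP if stage_map is None else stage_map
    try:
        return tuple(stage_map[protein_stage])
    except KeyError as exc:
        raise DesignError(f"protein stage {protein_stage!r} missing from stage map") from exc
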