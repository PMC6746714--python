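"""Readers and writers for the plain-text exchange formats.

Protein quantification tables are TSV with columns ``protein_id, gene,
<stage>_rep<k>...`` and empty cells for undetected values; an optional
``# scale: linear`` comment line declares linear L/H ratios which are
log2-transformed on load.  Count matrices are gene x sample TSV of integers.
Gene sets use the standard GMT dialect (name, description, tab-separated
members).  All floating-point output is written at fixed 6-decimal precision
for diffability.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .datatypes import CognateMap, StageDesign


class ParseError(ValueError):
    """Raised for malformed input files (message carries the line number)."""


FLOAT_FMT = "%.6f"


# ---------------------------------------------------------------------------
# protein quantification table
# ---------------------------------------------------------------------------

def read_protein_table(path: str | Path) -> tuple[pd.DataFrame, StageDesign]:
    """Read a protein quant TSV into a log2 L/H matrix plus its stage design."""
    path = Path(path)
    linear = False
    header: list[str] | None = None
    ids: list[str] = []
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "scale:" in line and "linear" in line:
                    linear = True
                continue
            fields = line.split("\t")
            if header is None:
                if len(fields) < 3 or fields[0] != "protein_id" or fields[1] != "gene":
                    raise ParseError(
                        f"{path}:{lineno}: header must start with 'protein_id\\tgene'"
                    )
                header = fields
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            pid = fields[0]
            if pid in ids:
                raise ParseError(f"{path}:{lineno}: duplicate protein id {pid!r}")
            vals = []
            for col, cell in zip(header[2:], fields[2:]):
                if cell.strip() == "":
                    vals.append(math.nan)
                    continue
                try:
                    v = float(cell)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad value {cell!r} in {col}") from exc
                if linear:
                    if v <= 0:
                        raise ParseError(
                            f"{path}:{lineno}: non-positive linear L/H ratio {v} in {col}"
                        )
                    v = math.log2(v)
                vals.append(v)
            ids.append(pid)
            rows.append(vals)
    if header is None:
        raise ParseError(f"{path}: empty file")
    samples = header[2:]
    design = StageDesign.from_sample_names(samples)
    matrix = pd.DataFrame(rows, index=pd.Index(ids, name="protein_id"), columns=samples)
    return matrix, design


def write_protein_table(
    path: str | Path, matrix: pd.DataFrame, gene_of: Mapping[str, str] | None = None
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# scale: log2\n")
        fh.write("protein_id\tgene\t" + "\t".join(matrix.columns) + "\n")
        for pid, row in matrix.iterrows():
            gene = gene_of.get(pid, pid) if gene_of else pid
            cells = ["" if np.isnan(v) else FLOAT_FMT % v for v in row.to_numpy(dtype=float)]
            fh.write(f"{pid}\t{gene}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> tuple[pd.DataFrame, StageDesign]:
    """Read a gene x sample TSV of integer counts."""
    path = Path(path)
    header: list[str] | None = None
    ids: list[str] = []
    rows: list[list[int]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            gid = fields[0]
            if gid in ids:
                raise ParseError(f"{path}:{lineno}: duplicate gene id {gid!r}")
            vals = []
            for col, cell in zip(header[1:], fields[1:]):
                try:
                    v = int(cell)
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-integer count {cell!r} in {col}"
                    ) from exc
                if v < 0:
                    raise ParseError(f"{path}:{lineno}: negative count in {col}")
                vals.append(v)
            ids.append(gid)
            rows.append(vals)
    if header is None:
        raise ParseError(f"{path}: empty file")
    samples = header[1:]
    design = StageDesign.from_sample_names(samples)
    matrix = pd.DataFrame(rows, index=pd.Index(ids, name="gene"), columns=samples)
    return matrix, design


def write_counts(path: str | Path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# cognate mapping and gene sets
# ---------------------------------------------------------------------------

def read_mapping(path: str | Path) -> CognateMap:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if list(table.columns[:2]) != ["protein_id", "transcript_id"]:
        raise ParseError(f"{path}: expected columns protein_id, transcript_id")
    return CognateMap(table)


def write_mapping(path: str | Path, mapping: CognateMap) -> None:
    mapping.table.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene sets: ``name<TAB>description<TAB>member...`` per line."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            members = [f for f in fields[2:] if f.strip()]  # trailing tabs tolerated
            if len(fields) < 3 or not members:
                raise ParseError(f"{path}:{lineno}: gene set with no members")
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
    return sets


def write_gmt(path: str | Path, sets: Mapping[str, list[str]], description: str = "") -> None:
    with Path(path).open("w") as fh:
        for name, members in sets.items():
            fh.write(name + "\t" + (description or name) + "\t" + "\t".join(members) + "\n")


# ---------------------------------------------------------------------------
# generic matrices / grids / config
# ---------------------------------------------------------------------------

def write_matrix(path: str | Path, matrix: pd.DataFrame, index_label: str = "id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FMT, na_rep="NA")


def write_grid(path: str | Path, scores: pd.DataFrame, reasons: pd.DataFrame) -> None:
    """Concordance grid TSV: scores with ``NA(reason)`` for skipped cells."""
    out = scores.copy().astype(object)
    for i in scores.index:
        for j in scores.columns:
            v = scores.loc[i, j]
            if isinstance(v, float) and np.isnan(v):
                out.loc[i, j] = f"NA({reasons.loc[i, j] or 'undefined'})"
            else:
                out.loc[i, j] = FLOAT_FMT % v
    out.to_csv(path, sep="\t", index_label="transcript_stage\\protein_stage")


def read_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg


def write_config(path: str | Path, config) -> None:
    if dataclasses.is_dataclass(config):
        config = dataclasses.asdict(config)
    config = {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in dict(config).items()
    }
    with Path(path).open("w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
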