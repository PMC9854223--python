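"""File formats and pipeline configuration.

One TSV dialect everywhere: tab-separated, UTF-8, header row, "." for
missing — so artifact files diff bit-exactly. Coordinates are 0-based
half-open in BED and in memory; genomes travel as FASTA (normalized to
uppercase on read).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("radiomethyl")

MISSING = "."


class SchemaError(ValueError):
    """A file did not match its documented schema."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA; mixed case is normalized to uppercase (logged)."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq)
        if not s.isupper():
            log.info("FASTA %s: normalized %s to uppercase", path, rec.id)
            s = s.upper()
        out[rec.id] = s
    return out


# ---------------------------------------------------------------------------
# BED (0-based, half-open; strand in column 6)
# ---------------------------------------------------------------------------


def write_bed(intervals, path: str | Path) -> None:
    """Write BED3 (contig, start, end) or BED6 tuples (+ name, score, strand)."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str | Path) -> list[tuple]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) not in (3, 6):
                raise SchemaError(f"{path}:{lineno}: expected 3 or 6 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start > end:
                raise SchemaError(f"{path}:{lineno}: start > end")
            if len(parts) == 3:
                rows.append((parts[0], start, end))
            else:
                rows.append((parts[0], start, end, parts[3], parts[4], parts[5]))
    return rows


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------


def write_tsv(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING, float_format=float_format)


def read_tsv(
    path: str | Path, required: list[str] | None = None
) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=True)
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: malformed TSV: {exc}") from exc
    for col in required or []:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    return df


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Every stage threshold in one auditable, serializable place."""

    # simulation scale
    contig_length: int = 60_000
    n_sites: int = 30
    n_islands: int = 6
    n_tss: int = 10
    n_repeats: int = 3
    samples_per_group: int = 8
    depth: int = 200
    error_rate: float = 0.0
    # differential filter
    diff_threshold: float = 5.0
    p_threshold: float = 0.1
    min_depth: int = 20
    test_kind: str = "t_on_fractions"
    # island + promoter criteria
    island_min_gc: float = 0.6
    island_min_oe: float = 0.6
    island_min_length: int = 200
    tss_window: int = 1000
    # marker positivity
    positivity_threshold: float = 5.0
    # model
    retention_p: float = 0.1
    train_fraction: float = 0.70
    folds: int = 5
    class_threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.folds < 2 or self.min_depth < 1 or self.island_min_length < 1:
            raise ValueError("folds/min_depth/island_min_length out of domain")
        if min(self.diff_threshold, self.p_threshold, self.positivity_threshold,
               self.retention_p) <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 <= self.class_threshold <= 1:
            raise ValueError("class_threshold must lie in [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg
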