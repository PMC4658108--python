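"""Readers and writers for the formats the pipeline touches.

FASTQ is Phred+33 by default (the offset is a config key for legacy data).
Reports are UTF-8 tab-separated files with a header row, written in input
order so every run is byte-reproducible.  Genomic intervals use a BED-like
six-column table (chrom, start, end, name, category, strand) with 0-based
half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator


class FastqParseError(ValueError):
    """Raised for a malformed FASTQ record, naming the 0-based record index."""


@dataclass(frozen=True)
class RawRead:
    """A sequencing read before trimming: id, sequence, per-base Phred scores."""

    id: str
    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.id!r}: sequence/quality length mismatch")


def read_fastq(path: str | Path, quality_offset: int = 33) -> Iterator[RawRead]:
    """Yield :class:`RawRead` records from a 4-line FASTQ file in file order."""
    with open(path, encoding="ascii") as fh:
        it = FastqGeneralIterator(fh)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:  # Biopython: length mismatch / truncation
                raise FastqParseError(f"malformed FASTQ record at index {index}: {exc}") from exc
            if len(seq) != len(qual):
                raise FastqParseError(f"malformed FASTQ record at index {index}: "
                                      "quality length differs from sequence length")
            yield RawRead(id=title.split()[0], seq=seq.upper(),
                          qual=tuple(ord(c) - quality_offset for c in qual))
            index += 1


def write_fastq(records: Iterable[RawRead], path: str | Path, quality_offset: int = 33) -> None:
    with open(path, "w", encoding="ascii") as fh:
        for r in records:
            qual = "".join(chr(q + quality_offset) for q in r.qual)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping (upper-cased)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    with open(path, "w", encoding="ascii") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_report(records: pd.DataFrame, path: str | Path) -> None:
    """Write a stage report as a header-carrying TSV in input row order."""
    records.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


BED_COLUMNS = ["chrom", "start", "end", "name", "category", "strand"]


def read_intervals(path: str | Path) -> pd.DataFrame:
    """Read a BED-like six-column interval table (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS, comment="#")
    if (df["end"] <= df["start"]).any():
        raise ValueError("interval table contains empty or inverted intervals")
    return df


def write_intervals(df: pd.DataFrame, path: str | Path) -> None:
    df[BED_COLUMNS].to_csv(path, sep="\t", index=False, header=False)
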