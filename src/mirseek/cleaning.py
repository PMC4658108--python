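"""Read cleaning: the four-step filter cascade and unique-tag collapsing.

Order of operations is fixed: (1) whole-read quality filter on the untrimmed
read, (2) adapter handling — reject 5'-contaminated reads and reads without
a locatable 3' adapter, trim the rest, (3) poly-nucleotide filter on the
insert, (4) minimum-length filter.  The surviving inserts are the clean
reads; collapsing them yields unique tags with per-sample counts (the
"total number / unique number" bookkeeping of a library summary table).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from mirseek.config import PipelineConfig
from mirseek.io import RawRead

REJECT_LOW_QUALITY = "low_quality"
REJECT_ADAPTER = "adapter"        # 5'-contaminant or missing 3' adapter
REJECT_POLYN = "polyN"
REJECT_SHORT = "short"


@dataclass(frozen=True)
class CleanRead:
    """An adapter-trimmed insert that passed all four filters."""

    id: str
    insert: str


@dataclass
class CleaningStats:
    """Ledger of the filter cascade; input == clean + sum(removed)."""

    input_reads: int = 0
    removed_low_quality: int = 0
    removed_adapter: int = 0
    removed_polyN: int = 0
    removed_short: int = 0
    clean_total: int = 0
    unique_count: int = 0

    def check(self) -> None:
        removed = (self.removed_low_quality + self.removed_adapter
                   + self.removed_polyN + self.removed_short)
        if self.input_reads != self.clean_total + removed:
            raise AssertionError("cleaning ledger does not balance")


def filter_low_quality(read: RawRead, quality_floor: int,
                       low_quality_fraction: float) -> bool:
    """True (keep) unless >= ``low_quality_fraction`` of bases fall below the floor."""
    if not read.seq:
        return False
    low = sum(1 for q in read.qual if q < quality_floor)
    return low / len(read.qual) < low_quality_fraction


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _find_adapter3(seq: str, adapter: str, max_mismatch: int, min_overlap: int) -> int | None:
    """Leftmost position of a 3'-adapter occurrence, or None.

    A full internal match anywhere, or a prefix of the adapter of length
    >= ``min_overlap`` flush with the read end, each within ``max_mismatch``
    substitutions.
    """
    n, m = len(seq), len(adapter)
    for start in range(0, n - m + 1):          # full internal matches, leftmost first
        if _mismatches(seq[start:start + m], adapter) <= max_mismatch:
            return start
    for overlap in range(min(m - 1, n), min_overlap - 1, -1):  # terminal prefix overlap
        start = n - overlap
        if _mismatches(seq[start:], adapter[:overlap]) <= max_mismatch:
            return start
    return None


def trim_adapters(read: RawRead, adapter3: str, adapter5: str,
                  max_mismatch: int = 1, min_overlap: int = 6) -> str | None:
    """Return the trimmed insert, or None if the read is adapter-rejected.

    Rejection reasons: the 5' adapter matches at the read start (a
    5'-primer contaminant), or no 3' adapter can be located.
    """
    overlap5 = min(len(adapter5), len(read.seq))
    if overlap5 >= min_overlap and _mismatches(
            read.seq[:overlap5], adapter5[:overlap5]) <= max_mismatch:
        return None
    pos = _find_adapter3(read.seq, adapter3, max_mismatch, min_overlap)
    if pos is None:
        return None
    return read.seq[:pos]


def filter_polyN(insert: str, polyN_fraction: float) -> bool:
    """True (keep) unless a single nucleotide reaches ``polyN_fraction`` of the insert."""
    if not insert:
        return False
    top = max(Counter(insert).values())
    return top / len(insert) < polyN_fraction


def filter_length(insert: str, min_length: int) -> bool:
    """True (keep) iff the insert is at least ``min_length`` nt."""
    return len(insert) >= min_length


def clean_read(read: RawRead, config: PipelineConfig) -> tuple[CleanRead | None, str | None]:
    """Run one read through the cascade; return (clean read, rejection reason)."""
    if not filter_low_quality(read, config.quality_floor, config.low_quality_fraction):
        return None, REJECT_LOW_QUALITY
    insert = trim_adapters(read, config.adapter3, config.adapter5,
                           config.adapter_max_mismatch, config.adapter_min_overlap)
    if insert is None:
        return None, REJECT_ADAPTER
    if not filter_polyN(insert, config.polyN_fraction):
        return None, REJECT_POLYN
    if not filter_length(insert, config.min_length):
        return None, REJECT_SHORT
    return CleanRead(id=read.id, insert=insert), None


def clean_library(reads: Iterable[RawRead],
                  config: PipelineConfig) -> tuple[list[CleanRead], CleaningStats]:
    """Apply the four filters in order and balance the stats ledger."""
    stats = CleaningStats()
    clean: list[CleanRead] = []
    for read in reads:
        stats.input_reads += 1
        cr, reason = clean_read(read, config)
        if cr is not None:
            clean.append(cr)
            stats.clean_total += 1
        elif reason == REJECT_LOW_QUALITY:
            stats.removed_low_quality += 1
        elif reason == REJECT_ADAPTER:
            stats.removed_adapter += 1
        elif reason == REJECT_POLYN:
            stats.removed_polyN += 1
        else:
            stats.removed_short += 1
    stats.unique_count = len({c.insert for c in clean})
    stats.check()
    return clean, stats


def collapse_unique(clean: Sequence[CleanRead]) -> pd.DataFrame:
    """Collapse clean reads to unique tags with counts (first-seen order)."""
    counts: Counter[str] = Counter(c.insert for c in clean)
    return pd.DataFrame({"insert": list(counts.keys()),
                         "count": list(counts.values())})


def length_histogram(clean: Sequence[CleanRead]) -> pd.DataFrame:
    """Read-count frequency by insert length (the length-distribution plot input)."""
    counts = Counter(len(c.insert) for c in clean)
    lengths = sorted(counts)
    total = sum(counts.values())
    return pd.DataFrame({
        "length": lengths,
        "reads": [counts[l] for l in lengths],
        "fraction": [counts[l] / total if total else 0.0 for l in lengths],
    })


def sharing_summary(tag_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Cross-sample tag sharing: per sample, the fraction of tags and reads
    whose insert is seen in every sample."""
    if not tag_tables:
        return pd.DataFrame(columns=["sample", "shared_tag_fraction", "shared_read_fraction"])
    sets = {s: set(df["insert"]) for s, df in tag_tables.items()}
    common = set.intersection(*sets.values())
    rows = []
    for sample, df in tag_tables.items():
        shared = df["insert"].isin(common)
        total_reads = int(df["count"].sum())
        rows.append({
            "sample": sample,
            "shared_tag_fraction": float(shared.mean()) if len(df) else 0.0,
            "shared_read_fraction": (float(df.loc[shared, "count"].sum()) / total_reads
                                     if total_reads else 0.0),
        })
    return pd.DataFrame(rows)
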