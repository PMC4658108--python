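"""Hierarchical annotation of unique tags against non-miRNA references.

A small RNA can hit several reference classes at once; to give every tag a
single label the classes are ranked
``rRNA > tRNA > scRNA > snRNA > snoRNA > repeat > exon > intron`` and the
highest-ranked match wins.  Tags matching nothing are passed forward as
miRNA candidates.

Matching is substring containment of the tag (or its reverse complement)
inside a reference entry, with an optional substitution budget — the small
RNA is expected to be a fragment of the longer non-coding RNA.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from mirseek.seq import revcomp

CATEGORY_PRIORITY = ["rRNA", "tRNA", "scRNA", "snRNA", "snoRNA", "repeat", "exon", "intron"]
CANDIDATE = "candidate"

_RANK = {c: i for i, c in enumerate(CATEGORY_PRIORITY)}


class AnnotationDB:
    """Category-labelled reference sequences.

    Built from ``(category, sequence)`` pairs; every entry carries exactly
    one category, which must come from the fixed priority list.
    """

    def __init__(self, entries: Iterable[tuple[str, str]]):
        self.by_category: dict[str, list[str]] = {}
        for category, seq in entries:
            if category not in _RANK:
                raise ValueError(f"unknown annotation category: {category!r}")
            self.by_category.setdefault(category, []).append(seq.upper())

    @classmethod
    def from_fasta_records(cls, records: Mapping[str, str]) -> "AnnotationDB":
        """Build from FASTA whose record ids start with ``<category>|``."""
        entries = []
        for name, seq in records.items():
            category = name.split("|")[0]
            entries.append((category, seq))
        return cls(entries)


def _matches(tag: str, ref: str, max_mismatch: int) -> bool:
    if max_mismatch == 0:
        return tag in ref
    n, m = len(ref), len(tag)
    for start in range(0, n - m + 1):
        mm = 0
        window = ref[start:start + m]
        for a, b in zip(tag, window):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return True
    return False


def assign_category(tag: str, db: AnnotationDB, max_mismatch: int = 0,
                    both_strands: bool = True) -> str:
    """Highest-priority category whose entries contain the tag, else "candidate"."""
    if not db.by_category:
        raise ValueError("annotation database is empty")
    queries = [tag] if not both_strands else [tag, revcomp(tag)]
    for category in CATEGORY_PRIORITY:
        for ref in db.by_category.get(category, ()):
            if any(_matches(q, ref, max_mismatch) for q in queries):
                return category
    return CANDIDATE


def annotate_tags(tags: pd.DataFrame, db: AnnotationDB, max_mismatch: int = 0,
                  both_strands: bool = True) -> pd.DataFrame:
    """Annotate a unique-tag table (columns ``insert``, ``count``)."""
    out = tags.copy()
    out["category"] = [assign_category(t, db, max_mismatch, both_strands)
                       for t in out["insert"]]
    return out


def summarize_categories(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-category proportions over unique tags and over total reads.

    Both denominators are reported because published category summaries are
    ambiguous about which one they use; each column sums to 1 including the
    "candidate" class.
    """
    total_tags = len(assignments)
    total_reads = int(assignments["count"].sum())
    rows = []
    for category in CATEGORY_PRIORITY + [CANDIDATE]:
        sub = assignments[assignments["category"] == category]
        rows.append({
            "category": category,
            "unique_tags": len(sub),
            "reads": int(sub["count"].sum()),
            "tag_proportion": len(sub) / total_tags if total_tags else 0.0,
            "read_proportion": int(sub["count"].sum()) / total_reads if total_reads else 0.0,
        })
    return pd.DataFrame(rows)
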