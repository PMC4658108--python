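"""Pipeline configuration: every threshold the stages consume, in one place.

The defaults encode the published constants of the protocol this package
implements: Phred floor 5 with a 50% low-quality fraction, 18 nt minimum
insert length, novel-miRNA reporting score 5, zero-count substitution 0.01,
normalized-expression exclusion boundary 1, and a 2-mismatch cap for
cross-species UTR transfer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

_ALPHABET = set("ACGTN")


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline.

    Proportions live in [0, 1]; count thresholds are non-negative; adapters
    are non-empty strings over {A, C, G, T, N}.
    """

    # read cleaning
    quality_floor: int = 5            # Phred score below which a base is "low quality"
    low_quality_fraction: float = 0.5  # reject read if >= this fraction of bases are low quality
    min_length: int = 18              # minimum insert length (nt) after trimming
    polyN_fraction: float = 0.8       # reject insert if one nucleotide reaches this fraction
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    adapter_max_mismatch: int = 1     # tolerance when locating adapters
    adapter_min_overlap: int = 6      # minimum 3'-adapter prefix overlap at the read end
    quality_offset: int = 33          # Phred ASCII offset (33 = modern Illumina)

    # annotation
    annot_max_mismatch: int = 0

    # discovery
    map_max_mismatch: int = 1         # genome mapping substitution budget
    conserved_tolerance: int = 2      # 5'-end tolerance (nt) against the catalog mature start
    excise_flank: int = 70            # genomic context excised on each side of a read stack
    report_score_min: float = 5.0     # candidate reported only above this signature score
    shuffle_count: int = 100          # dinucleotide shuffles for the structure p-value
    shuffle_alpha: float = 0.05       # structure p-value threshold for reporting
    min_window: int = 40              # shortest window worth folding

    # differential expression
    ne_floor_substitute: float = 0.01  # replaces NE == 0 before fold-change
    ne_exclusion: float = 1.0          # NE below this is "not considered"
    ne_exclusion_mode: str = "both"    # exclude when "both" or "either" NE < ne_exclusion
    de_p_threshold: float = 0.01
    de_lfc_threshold: float = 1.0

    # target prediction
    utr_max_mismatch: int = 2
    utr_min_coverage: float = 0.8
    utr_proximity: int = 1000         # max distance (nt) from an annotated gene 3' end
    target_score_min: float = 60.0
    trend_threshold: float = 0.2      # relative FPKM difference for a group trend call

    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("low_quality_fraction", "polyN_fraction", "utr_min_coverage",
                     "shuffle_alpha", "de_p_threshold", "trend_threshold"):
            v = getattr(self, name)
            if not 0.0 <= float(v) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ("quality_floor", "min_length", "adapter_max_mismatch",
                     "adapter_min_overlap", "annot_max_mismatch", "map_max_mismatch",
                     "conserved_tolerance", "excise_flank", "shuffle_count",
                     "utr_max_mismatch", "utr_proximity", "min_window"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        for name in ("adapter3", "adapter5"):
            a = getattr(self, name)
            if not a or set(a) - _ALPHABET:
                raise ValueError(f"{name} must be a non-empty string over ACGTN, got {a!r}")
        if self.ne_exclusion_mode not in ("both", "either"):
            raise ValueError("ne_exclusion_mode must be 'both' or 'either'")

    # -- flat key=value / YAML round-trip --------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, default_flow_style=False, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
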