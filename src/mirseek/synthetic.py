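"""Synthetic small-RNA experiment generator with full ground truth.

Builds a toy genome carrying planted hairpin precursors (a mature arm, a
loop, and a near-perfect reverse-complement star arm) plus labelled
non-miRNA loci, then simulates Dicer-like FASTQ libraries: mature-anchored
read stacks with small 5' jitter and 3' length variation, a trickle of star
and loop reads, category-labelled background reads, and the five
contaminant classes the cleaning cascade removes (low-quality reads,
3'-adapter-less reads, poly-nucleotide inserts, sub-18-nt inserts, and
5'-adapter contaminants).  Every read carries a truth label so downstream
stage outputs can be checked exactly.

The default design mirrors a four-library blood study: two "young" and two
"adult" samples, equal depths, and one miRNA planted at an 8-fold
between-group change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mirseek.annotation import CATEGORY_PRIORITY
from mirseek.cleaning import _find_adapter3, filter_polyN
from mirseek.config import PipelineConfig
from mirseek.io import RawRead
from mirseek.seq import revcomp

BASES = np.array(list("ACGT"))

CLASS_MIRNA = "mirna"
CLASS_STAR = "star"
CLASS_BACKGROUND = "background"
CLASS_LOW_QUALITY = "low_quality"
CLASS_NO_ADAPTER = "no_adapter3"
CLASS_POLYN = "polyN"
CLASS_SHORT = "short"
CLASS_ADAPTER5 = "adapter5"

CONTAMINANT_CLASSES = [CLASS_LOW_QUALITY, CLASS_NO_ADAPTER, CLASS_POLYN,
                       CLASS_SHORT, CLASS_ADAPTER5]


@dataclass(frozen=True)
class PlantedPrecursor:
    name: str
    start: int            # genomic, 0-based half-open
    end: int
    seq: str
    mature_start: int     # genomic
    mature_end: int
    star_start: int
    star_end: int
    strand: str = "+"


@dataclass
class SimConfig:
    """Study-design knobs of the generator (defaults = the tested conditions)."""

    genome_length: int = 12000
    n_precursors: int = 10
    mature_length: int = 22
    loop_range: tuple[int, int] = (8, 15)
    stem_mismatches: int = 0          # planted arm mismatches (<= 2 keeps a hairpin)
    loci_per_category: int = 1
    nonmirna_locus_length: int = 120
    margin: int = 90                  # spacing so excision windows never collide

    # read model
    length_weights: dict[int, float] = field(
        default_factory=lambda: {20: 0.10, 21: 0.25, 22: 0.45, 23: 0.20})
    jitter_prob: float = 0.2          # probability the 5' end shifts by +-1 nt
    star_fraction: float = 0.08       # star reads as a fraction of each miRNA's reads
    loop_read_fraction: float = 0.0

    # library composition (fractions of total depth; remainder = miRNA signal)
    background_fraction: float = 0.12
    contaminant_fractions: dict[str, float] = field(
        default_factory=lambda: {CLASS_LOW_QUALITY: 0.05, CLASS_NO_ADAPTER: 0.05,
                                 CLASS_POLYN: 0.03, CLASS_SHORT: 0.03,
                                 CLASS_ADAPTER5: 0.02})

    # study design
    samples: dict[str, str] = field(
        default_factory=lambda: {"young1": "young", "young2": "young",
                                 "adult1": "adult", "adult2": "adult"})
    fold_changes: dict[int, float] = field(default_factory=lambda: {0: 8.0})
    fold_up_group: str = "young"
    abundance_decay: float = 0.75     # geometric decay of per-miRNA base abundance

    high_quality: int = 35
    low_quality: int = 2

    def validate(self) -> None:
        total = self.background_fraction + sum(self.contaminant_fractions.values())
        if total >= 1.0:
            raise ValueError("background + contaminant fractions must leave room for signal")
        if not 0 <= self.jitter_prob <= 1:
            raise ValueError("jitter_prob must lie in [0, 1]")
        if self.n_precursors < 1:
            raise ValueError("need at least one planted precursor")


@dataclass
class SimTruth:
    """Everything the generator planted, for exact downstream checking."""

    genome: str
    precursors: list[PlantedPrecursor]
    nonmirna_loci: pd.DataFrame       # chrom, start, end, name, category, strand
    abundance: dict[str, dict[str, float]]   # sample -> miRNA name -> proportion
    fold_changes: dict[str, float]
    contaminant_fractions: dict[str, float]
    background_fraction: float
    config: SimConfig


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _place(rng: np.random.Generator, occupied: list[tuple[int, int]],
           length: int, genome_length: int, margin: int) -> int:
    """Find a non-overlapping start (margin nt of clearance); bounded retries."""
    for _ in range(2000):
        start = int(rng.integers(margin, genome_length - length - margin))
        if all(start + length + margin <= s or e + margin <= start
               for s, e in occupied):
            occupied.append((start, start + length))
            return start
    raise RuntimeError("could not place all features; genome too small")


def build_truth(config: SimConfig | None = None, seed: int = 0) -> SimTruth:
    """Plant precursors and non-miRNA loci in a fresh random genome."""
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    genome = list(_random_seq(rng, cfg.genome_length))
    occupied: list[tuple[int, int]] = []

    precursors: list[PlantedPrecursor] = []
    for i in range(cfg.n_precursors):
        mature = _random_seq(rng, cfg.mature_length)
        loop_len = int(rng.integers(cfg.loop_range[0], cfg.loop_range[1] + 1))
        loop = _random_seq(rng, loop_len)
        star = list(revcomp(mature))
        for pos in rng.choice(len(star), size=cfg.stem_mismatches, replace=False):
            choices = [b for b in "ACGT" if b != star[pos]]
            star[pos] = choices[rng.integers(3)]
        pre_seq = mature + loop + "".join(star)
        start = _place(rng, occupied, len(pre_seq), cfg.genome_length, cfg.margin)
        genome[start:start + len(pre_seq)] = pre_seq
        precursors.append(PlantedPrecursor(
            name=f"novel-mir-{i + 1}", start=start, end=start + len(pre_seq),
            seq=pre_seq,
            mature_start=start, mature_end=start + cfg.mature_length,
            star_start=start + cfg.mature_length + loop_len,
            star_end=start + len(pre_seq)))

    loci_rows = []
    for category in CATEGORY_PRIORITY:
        for j in range(cfg.loci_per_category):
            start = _place(rng, occupied, cfg.nonmirna_locus_length,
                           cfg.genome_length, cfg.margin)
            loci_rows.append({"chrom": "chr1", "start": start,
                              "end": start + cfg.nonmirna_locus_length,
                              "name": f"{category}-{j + 1}", "category": category,
                              "strand": "+"})
    loci = pd.DataFrame(loci_rows)

    # Per-sample miRNA proportions: geometric base abundance, group fold
    # changes applied on the absolute scale (one common normalization across
    # groups) so a planted k-fold change stays a k-fold change after
    # reads-per-million normalization; the per-sample background fraction
    # absorbs the difference in total signal.
    signal = 1.0 - cfg.background_fraction - sum(cfg.contaminant_fractions.values())
    base = np.array([cfg.abundance_decay ** i for i in range(cfg.n_precursors)])
    group_weights = {}
    for group in set(cfg.samples.values()):
        w = base.copy()
        if group == cfg.fold_up_group:
            for idx, fc in cfg.fold_changes.items():
                w[idx] *= fc
        group_weights[group] = w
    scale = signal / max(w.sum() for w in group_weights.values())
    abundance: dict[str, dict[str, float]] = {}
    for sample, group in cfg.samples.items():
        w = group_weights[group] * scale
        abundance[sample] = {p.name: float(w[i]) for i, p in enumerate(precursors)}

    return SimTruth(genome="".join(genome), precursors=precursors,
                    nonmirna_loci=loci, abundance=abundance,
                    fold_changes={precursors[i].name: fc
                                  for i, fc in cfg.fold_changes.items()},
                    contaminant_fractions=dict(cfg.contaminant_fractions),
                    background_fraction=cfg.background_fraction, config=cfg)


def _sample_lengths(rng: np.random.Generator, weights: dict[int, float], n: int) -> np.ndarray:
    lengths = np.array(sorted(weights))
    probs = np.array([weights[l] for l in lengths], dtype=float)
    probs /= probs.sum()
    return rng.choice(lengths, size=n, p=probs)


def _clean_random_insert(rng: np.random.Generator, length: int,
                         pconf: PipelineConfig) -> str:
    """Random insert guaranteed not to trip the polyN or adapter matchers."""
    for _ in range(100):
        ins = _random_seq(rng, length)
        if not filter_polyN(ins, pconf.polyN_fraction):
            continue
        if _find_adapter3(ins, pconf.adapter3, pconf.adapter_max_mismatch,
                          pconf.adapter_min_overlap) is not None:
            continue
        return ins
    raise RuntimeError("failed to draw an unambiguous random insert")


def simulate_library(truth: SimTruth, sample: str, depth: int, seed: int,
                     pipeline_config: PipelineConfig | None = None,
                     ) -> tuple[list[RawRead], pd.DataFrame]:
    """Simulate one FASTQ library; returns (reads, per-read truth labels).

    Truth labels carry the read class, the source locus/miRNA, and the exact
    insert, so cleaning and discovery outputs can be compared read by read.
    """
    cfg = truth.config
    pconf = pipeline_config or PipelineConfig()
    rng = np.random.default_rng(seed)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if sample not in truth.abundance:
        raise ValueError(f"unknown sample {sample!r}")

    mirnas = [p.name for p in truth.precursors]
    by_name = {p.name: p for p in truth.precursors}
    classes = (mirnas + [CLASS_BACKGROUND] + CONTAMINANT_CLASSES)
    signal = [truth.abundance[sample][m] for m in mirnas]
    contam = [truth.contaminant_fractions[c] for c in CONTAMINANT_CLASSES]
    # background takes whatever the sample's signal leaves unused, so miRNA
    # proportions stay absolute (comparable across samples)
    background = 1.0 - sum(signal) - sum(contam)
    if background < 0:
        raise ValueError("signal + contaminant fractions exceed 1")
    probs = np.array(signal + [background] + contam)
    counts = rng.multinomial(depth, probs)

    adapter3, adapter5 = pconf.adapter3, pconf.adapter5
    hi, lo = cfg.high_quality, cfg.low_quality
    genome = truth.genome
    loci = truth.nonmirna_loci

    reads: list[RawRead] = []
    labels: list[dict] = []
    ridx = 0

    def emit(seq: str, qual: tuple[int, ...], cls: str, source: str, insert: str) -> None:
        nonlocal ridx
        reads.append(RawRead(id=f"{sample}:{ridx}", seq=seq, qual=qual))
        labels.append({"read_id": f"{sample}:{ridx}", "class": cls,
                       "source": source, "insert": insert})
        ridx += 1

    for cls, n in zip(classes, counts):
        if n == 0:
            continue
        if cls in by_name:
            p = by_name[cls]
            n_star = rng.binomial(n, cfg.star_fraction)
            n_mat = n - n_star
            # mature reads: jittered 5' ends, 3' length variation off the genome
            jit = rng.choice([-1, 0, 1], size=n_mat,
                             p=[cfg.jitter_prob / 2, 1 - cfg.jitter_prob,
                                cfg.jitter_prob / 2])
            lens = _sample_lengths(rng, cfg.length_weights, n_mat)
            for d, L in zip(jit, lens):
                s = p.mature_start + int(d)
                ins = genome[s:s + int(L)]
                emit(ins + adapter3, (hi,) * (len(ins) + len(adapter3)),
                     CLASS_MIRNA, p.name, ins)
            lens = _sample_lengths(rng, cfg.length_weights, n_star)
            for L in lens:
                s = p.star_start
                ins = genome[s:s + int(L)]
                emit(ins + adapter3, (hi,) * (len(ins) + len(adapter3)),
                     CLASS_STAR, p.name, ins)
        elif cls == CLASS_BACKGROUND:
            locus_idx = rng.integers(0, len(loci), size=n)
            lens = _sample_lengths(rng, cfg.length_weights, n)
            for li, L in zip(locus_idx, lens):
                row = loci.iloc[int(li)]
                s = int(rng.integers(row["start"], row["end"] - int(L)))
                ins = genome[s:s + int(L)]
                if not filter_polyN(ins, pconf.polyN_fraction):  # keep labels unambiguous
                    ins = _clean_random_insert(rng, int(L), pconf)
                emit(ins + adapter3, (hi,) * (len(ins) + len(adapter3)),
                     CLASS_BACKGROUND, str(row["name"]), ins)
        elif cls == CLASS_LOW_QUALITY:
            for _ in range(n):
                ins = _clean_random_insert(rng, 22, pconf)
                seq = ins + adapter3
                n_low = math.ceil(0.6 * len(seq))
                qual = np.full(len(seq), hi)
                qual[rng.choice(len(seq), size=n_low, replace=False)] = lo
                emit(seq, tuple(int(q) for q in qual), cls, "", ins)
        elif cls == CLASS_NO_ADAPTER:
            for _ in range(n):
                seq = _clean_random_insert(rng, 30, pconf)
                emit(seq, (hi,) * len(seq), cls, "", seq)
        elif cls == CLASS_POLYN:
            for _ in range(n):
                base = "ACGT"[rng.integers(4)]
                ins = list(base * 22)
                for pos in rng.choice(22, size=2, replace=False):
                    ins[pos] = "ACGT"[rng.integers(4)]
                ins = "".join(ins)
                emit(ins + adapter3, (hi,) * (len(ins) + len(adapter3)), cls, "", ins)
        elif cls == CLASS_SHORT:
            for _ in range(n):
                ins = _clean_random_insert(rng, 12, pconf)
                emit(ins + adapter3, (hi,) * (len(ins) + len(adapter3)), cls, "", ins)
        elif cls == CLASS_ADAPTER5:
            for _ in range(n):
                ins = _clean_random_insert(rng, 22, pconf)
                seq = adapter5 + ins + adapter3
                emit(seq, (hi,) * len(seq), cls, "", ins)

    return reads, pd.DataFrame(labels)


def simulate_counts(truth: SimTruth, depth: int, seed: int) -> tuple[pd.DataFrame, dict[str, int]]:
    """Multinomial per-sample miRNA counts at the planted proportions.

    A fast path to an expression matrix for differential-expression studies;
    totals are the full library depths (signal + background + contaminants),
    matching what the clean-read totals converge to.
    """
    rng = np.random.default_rng(seed)
    mirnas = [p.name for p in truth.precursors]
    data = {}
    totals = {}
    for sample in truth.abundance:
        probs = np.array([truth.abundance[sample][m] for m in mirnas])
        rest = 1.0 - probs.sum()
        counts = rng.multinomial(depth, np.append(probs, rest))
        data[sample] = counts[:-1]
        totals[sample] = depth
    matrix = pd.DataFrame(data, index=mirnas)
    return matrix, totals


def nonmirna_reference(truth: SimTruth) -> dict[str, str]:
    """Category FASTA records (``<category>|<name>``) for the annotation stage."""
    out = {}
    for _, row in truth.nonmirna_loci.iterrows():
        out[f"{row['category']}|{row['name']}"] = truth.genome[row["start"]:row["end"]]
    return out


def catalog_fastas(truth: SimTruth, flank: int = 5) -> tuple[dict[str, str], dict[str, str]]:
    """miRBase-style (mature, precursor) records for the planted miRNAs.

    Precursor records carry a few nt of genomic flank, as catalog hairpins
    do, so 5'-jittered reads still align within them.
    """
    mature = {p.name: truth.genome[p.mature_start:p.mature_end] for p in truth.precursors}
    precursor = {p.name: truth.genome[max(0, p.start - flank):
                                      min(len(truth.genome), p.end + flank)]
                 for p in truth.precursors}
    return mature, precursor
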