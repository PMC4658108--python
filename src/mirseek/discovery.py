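"""Genome mapping, conserved-miRNA quantification and novel hairpin discovery.

Candidate tags are mapped to the genome on both strands within a small
substitution budget.  Tags landing inside catalog precursors with a 5' end
near the catalog mature start are counted as conserved miRNAs (tags of one
precursor aggregate into a single miRNA).  The remaining alignments are
clustered into read stacks; around each stack's dominant 5' position two
candidate windows are excised (the mature arm can sit on either side of the
loop), folded by weighted base-pair maximization, and scored with an
additive read-signature score:

    +4 x (share of stack reads whose 5' end is within +-1 nt of the
          dominant mature 5' end)
    +3   if >= 60% of mature bases are paired in the fold
    +2   if star-compatible reads exist (5' end within +-2 nt of the
         position implied by the mature arm's duplex partner)
    +1   if the loop length lies in [3, 25]
    -4 x (share of stack reads starting inside the loop)

A candidate is reported when its score exceeds the reporting threshold
(default 5) and its fold survives a dinucleotide-shuffle randomization test.
A genome-wide signal-to-noise ratio contrasts the number of reported
candidates on the real genome with the mean over dinucleotide-shuffled
genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mirseek.config import PipelineConfig
from mirseek.fold import fold_hairpin, pair_table, pairing_score
from mirseek.seq import dinucleotide_shuffle, revcomp

STACK_GAP = 20  # max nt between alignments merged into one stack


@dataclass(frozen=True)
class Alignment:
    tag: str
    chrom: str
    start: int
    strand: str
    mismatches: int


@dataclass
class ReadStack:
    """Overlapping tag alignments treated as one expressed locus."""

    chrom: str
    members: list[tuple[int, int, int]]  # (start, length, count)

    @property
    def start(self) -> int:
        return min(s for s, _, _ in self.members)

    @property
    def end(self) -> int:
        return max(s + l for s, l, _ in self.members)

    def dominant(self) -> tuple[int, int]:
        """(5' position, mature length) carrying the most reads."""
        by_start: dict[int, int] = {}
        for s, _, c in self.members:
            by_start[s] = by_start.get(s, 0) + c
        d = min(sorted(by_start), key=lambda s: (-by_start[s], s))
        by_len: dict[int, int] = {}
        for s, l, c in self.members:
            if s == d:
                by_len[l] = by_len.get(l, 0) + c
        length = min(sorted(by_len), key=lambda l: (-by_len[l], l))
        return d, length


@dataclass
class PrecursorCandidate:
    chrom: str
    window_start: int
    window_end: int
    window_seq: str
    structure: str
    pairing_score: int
    mature_start: int      # genomic
    mature_end: int
    signature_score: float
    structure_p: float = 1.0
    reported: bool = False
    stack: ReadStack | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# mapping

def _scan(genome_arr: np.ndarray, tag: str, max_mismatch: int) -> list[tuple[int, int]]:
    m = len(tag)
    if m > genome_arr.shape[0]:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(genome_arr, m)
    mm = (windows != np.frombuffer(tag.encode(), dtype=np.uint8)).sum(axis=1)
    hits = np.nonzero(mm <= max_mismatch)[0]
    return [(int(h), int(mm[h])) for h in hits]


def map_tags(tags: pd.DataFrame, genome: str, max_mismatch: int = 1,
             chrom: str = "chr1") -> list[Alignment]:
    """All alignments of each tag on either strand within the mismatch budget."""
    arr = np.frombuffer(genome.encode(), dtype=np.uint8)
    out: list[Alignment] = []
    for tag in tags["insert"]:
        for start, mm in _scan(arr, tag, max_mismatch):
            out.append(Alignment(tag, chrom, start, "+", mm))
        rc = revcomp(tag)
        if rc != tag:
            for start, mm in _scan(arr, rc, max_mismatch):
                out.append(Alignment(tag, chrom, start, "-", mm))
    return out


# ---------------------------------------------------------------------------
# conserved quantification

def quantify_conserved(tags: pd.DataFrame, mature: dict[str, str],
                       precursor: dict[str, str], tolerance: int = 2,
                       max_mismatch: int = 0) -> tuple[pd.DataFrame, set[str]]:
    """Count tags toward catalog miRNAs; returns (count table, used tag set).

    A tag counts toward a catalog entry when it aligns inside the precursor
    with its 5' end within ``tolerance`` nt of the mature 5' end; all tags
    of one precursor aggregate into one miRNA.  Both the precursor-level and
    the mature-level counts are reported (they differ when several matures
    share a precursor).
    """
    counts: dict[str, int] = {name: 0 for name in precursor}
    mature_counts: dict[str, int] = {name: 0 for name in mature}
    used: set[str] = set()
    mature_pos = {}
    for mname, mseq in mature.items():
        for pname, pseq in precursor.items():
            pos = pseq.find(mseq)
            if pos >= 0:
                mature_pos[mname] = (pname, pos)
                break
    tag_counts = dict(zip(tags["insert"], tags["count"]))
    for tag, n in tag_counts.items():
        for mname, (pname, mpos) in mature_pos.items():
            pseq = precursor[pname]
            hit = False
            for start in range(max(0, mpos - tolerance),
                               min(len(pseq) - len(tag), mpos + tolerance) + 1):
                window = pseq[start:start + len(tag)]
                if len(window) == len(tag) and sum(
                        a != b for a, b in zip(tag, window)) <= max_mismatch:
                    hit = True
                    break
            if hit:
                counts[pname] += int(n)
                mature_counts[mname] += int(n)
                used.add(tag)
                break
    table = pd.DataFrame({
        "miRNA": list(counts.keys()),
        "count": list(counts.values()),
        "mature_count": [sum(mature_counts[m] for m, (p, _) in mature_pos.items()
                             if p == name) for name in counts],
    })
    return table, used


# ---------------------------------------------------------------------------
# novel discovery

def build_stacks_counted(alignments: list[Alignment], tag_counts: dict[str, int],
                         gap: int = STACK_GAP) -> list[ReadStack]:
    """Cluster plus-strand alignments into stacks, weighted by tag counts.

    A new stack starts whenever the next alignment begins more than ``gap``
    nt past the current stack's end (the gap comfortably spans a hairpin
    loop, so mature and star alignments land in one stack)."""
    weighted: dict[tuple[str, int, int], int] = {}
    for a in alignments:
        if a.strand != "+":
            continue
        key = (a.chrom, a.start, len(a.tag))
        weighted[key] = weighted.get(key, 0) + int(tag_counts.get(a.tag, 1))
    items = sorted(weighted)
    stacks: list[ReadStack] = []
    for chrom, start, length in items:
        count = weighted[(chrom, start, length)]
        if stacks and stacks[-1].chrom == chrom and start <= stacks[-1].end + gap:
            stacks[-1].members.append((start, length, count))
        else:
            stacks.append(ReadStack(chrom=chrom, members=[(start, length, count)]))
    return stacks


def excise_candidates(stack: ReadStack, genome: str, flank: int = 70,
                      ) -> list[tuple[int, int, int, int]]:
    """Two candidate windows around the stack's dominant mature 5' position.

    Returns (window_start, window_end, mature_start, mature_end) tuples,
    clipped at genome ends: one window with upstream context (mature on the
    3' arm) and one with downstream context (mature on the 5' arm).
    """
    d, length = stack.dominant()
    n = len(genome)
    m_start, m_end = max(0, d), min(n, d + length)
    upstream = (max(0, m_start - flank), m_end, m_start, m_end)
    downstream = (m_start, min(n, m_end + flank), m_start, m_end)
    return [upstream, downstream]


def score_signature(stack: ReadStack, structure: str, window_start: int,
                    mature_start: int, mature_end: int) -> float:
    """Additive read-signature score in [-4, 10]; -inf if the mature arm is unpaired."""
    partner = pair_table(structure)
    n = len(structure)
    m_lo, m_hi = mature_start - window_start, mature_end - window_start
    m_lo, m_hi = max(0, m_lo), min(n, m_hi)
    if m_hi <= m_lo:
        return float("-inf")

    paired_positions = [i for i in range(m_lo, m_hi) if partner[i] >= 0]
    if not paired_positions:
        return float("-inf")
    paired_frac = len(paired_positions) / (m_hi - m_lo)

    # implied star 5': duplex partner of the 3'-most paired mature base
    # (+-2 nt acceptance absorbs the Dicer 2-nt 3' overhang)
    star5 = partner[max(paired_positions)]

    # loop = the unpaired span between the mature arm and its partner arm
    partners = [partner[i] for i in paired_positions]
    if min(partners) > m_hi - 1:          # mature on 5' arm
        loop_lo, loop_hi = m_hi, min(partners)
    else:                                  # mature on 3' arm
        loop_lo, loop_hi = max(partners) + 1, m_lo
    loop_len = max(0, loop_hi - loop_lo)

    total = sum(c for _, _, c in stack.members)
    d, _ = stack.dominant()

    def is_star(s: int) -> bool:
        return abs((s - window_start) - star5) <= 2

    def in_loop(s: int) -> bool:
        return loop_lo <= (s - window_start) < loop_hi

    star_exists = any(is_star(s) for s, _, _ in stack.members)
    share_loop = sum(c for s, _, c in stack.members if in_loop(s)) / total
    # 5'-homogeneity is judged over the mature-arm reads only: star and loop
    # reads are legitimate Dicer products and must not dilute the share
    core = [(s, c) for s, _, c in stack.members if not is_star(s) and not in_loop(s)]
    core_total = sum(c for _, c in core)
    share_dom = (sum(c for s, c in core if abs(s - d) <= 1) / core_total
                 if core_total else 0.0)

    return (4.0 * share_dom
            + (3.0 if paired_frac >= 0.6 else 0.0)
            + (2.0 if star_exists else 0.0)
            + (1.0 if 3 <= loop_len <= 25 else 0.0)
            - 4.0 * share_loop)


def shuffle_structure_test(window: str, observed_score: float, shuffle_count: int,
                           seed: int) -> float:
    """Empirical p-value of the pairing score under dinucleotide shuffling."""
    if shuffle_count < 20:
        raise ValueError("need at least 20 shuffles for a usable p-value")
    if len(window) < 10:
        return 1.0
    rng = np.random.default_rng(seed)
    hits = sum(1 for _ in range(shuffle_count)
               if pairing_score(dinucleotide_shuffle(window, rng)) >= observed_score)
    return (1 + hits) / (shuffle_count + 1)


def evaluate_stack(stack: ReadStack, genome: str, config: PipelineConfig,
                   seed: int) -> PrecursorCandidate | None:
    """Fold both excision windows, keep the better-scoring one, run the shuffle test."""
    best: PrecursorCandidate | None = None
    for w_start, w_end, m_start, m_end in excise_candidates(
            stack, genome, config.excise_flank):
        window = genome[w_start:w_end]
        if len(window) < config.min_window:
            continue
        structure, pscore = fold_hairpin(window)
        sig = score_signature(stack, structure, w_start, m_start, m_end)
        cand = PrecursorCandidate(
            chrom=stack.chrom, window_start=w_start, window_end=w_end,
            window_seq=window, structure=structure, pairing_score=pscore,
            mature_start=m_start, mature_end=m_end, signature_score=sig,
            stack=stack)
        if best is None or (cand.signature_score, cand.pairing_score,
                            -cand.window_start) > (best.signature_score,
                                                   best.pairing_score,
                                                   -best.window_start):
            best = cand
    if best is None or best.signature_score == float("-inf"):
        return None
    if best.signature_score > config.report_score_min:
        best.structure_p = shuffle_structure_test(
            best.window_seq, best.pairing_score, config.shuffle_count, seed)
        best.reported = (best.structure_p < config.shuffle_alpha)
    return best


def discover_novel(tags: pd.DataFrame, genome: str, config: PipelineConfig,
                   seed: int, exclude_tags: set[str] | None = None,
                   ) -> list[PrecursorCandidate]:
    """Full novel-miRNA discovery on a unique-tag table.

    Maps tags, clusters count-weighted plus-strand alignments into stacks,
    evaluates each stack, and merges overlapping reported windows (same
    precursor => same miRNA).
    """
    exclude = exclude_tags or set()
    work = tags[~tags["insert"].isin(exclude)]
    alignments = map_tags(work, genome, config.map_max_mismatch)
    tag_counts = dict(zip(work["insert"], work["count"]))
    stacks = build_stacks_counted(alignments, tag_counts)
    candidates: list[PrecursorCandidate] = []
    for i, stack in enumerate(stacks):
        cand = evaluate_stack(stack, genome, config, seed=seed + i)
        if cand is not None:
            candidates.append(cand)
    return merge_candidates(candidates)


def merge_candidates(candidates: list[PrecursorCandidate]) -> list[PrecursorCandidate]:
    """Collapse candidates with overlapping windows, keeping the best-scoring one."""
    candidates = sorted(candidates, key=lambda c: (c.chrom, c.window_start))
    merged: list[PrecursorCandidate] = []
    for cand in candidates:
        if (merged and merged[-1].chrom == cand.chrom
                and cand.window_start < merged[-1].window_end):
            if (cand.signature_score, cand.pairing_score) > (
                    merged[-1].signature_score, merged[-1].pairing_score):
                merged[-1] = cand
        else:
            merged.append(cand)
    return merged


def estimate_signal_to_noise(genome: str, tags: pd.DataFrame,
                             config: PipelineConfig, n_permutations: int = 3,
                             seed: int = 0) -> float:
    """Reported candidates on the real genome vs dinucleotide-shuffled genomes.

    ratio = real / (mean over shuffled genomes + 1); reported alongside the
    candidate list, never used as a per-candidate filter.
    """
    if n_permutations < 3:
        raise ValueError("need at least 3 genome permutations")
    real = sum(c.reported for c in discover_novel(tags, genome, config, seed))
    rng = np.random.default_rng(seed)
    noise = []
    for k in range(n_permutations):
        shuffled = dinucleotide_shuffle(genome, rng)
        noise.append(sum(c.reported for c in
                         discover_novel(tags, shuffled, config, seed + 1000 + k)))
    return real / (float(np.mean(noise)) + 1.0)


def candidate_table(candidates: list[PrecursorCandidate]) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(candidates):
        rows.append({"name": f"candidate-{i + 1}", "chrom": c.chrom,
                     "window_start": c.window_start, "window_end": c.window_end,
                     "mature_start": c.mature_start, "mature_end": c.mature_end,
                     "signature_score": c.signature_score,
                     "pairing_score": c.pairing_score,
                     "structure_p": c.structure_p, "reported": c.reported,
                     "structure": c.structure, "sequence": c.window_seq})
    return pd.DataFrame(rows)


def expression_matrix(sample_tags: dict[str, pd.DataFrame],
                      mature: dict[str, str], precursor: dict[str, str],
                      candidates: list[PrecursorCandidate],
                      genome: str, tolerance: int = 2) -> pd.DataFrame:
    """Counts per miRNA (conserved + reported novel) per sample."""
    rows: dict[str, dict[str, int]] = {}
    for sample, tags in sample_tags.items():
        conserved, _ = quantify_conserved(tags, mature, precursor, tolerance)
        for _, r in conserved.iterrows():
            rows.setdefault(r["miRNA"], {})[sample] = int(r["count"])
        tag_counts = dict(zip(tags["insert"], tags["count"]))
        for i, cand in enumerate(c for c in candidates if c.reported):
            name = f"novel-candidate-{i + 1}"
            total = 0
            for tag, n in tag_counts.items():
                pos = genome.find(tag, max(0, cand.window_start),
                                  cand.window_end + len(tag))
                if pos >= 0 and abs(pos - cand.mature_start) <= tolerance:
                    total += int(n)
            rows.setdefault(name, {})[sample] = total
    mat_df = pd.DataFrame(rows).T.fillna(0).astype(int)
    return mat_df[sorted(sample_tags)]
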