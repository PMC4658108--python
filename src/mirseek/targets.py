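"""Cross-species 3'UTR transfer, seed-based target prediction, pathway tallies.

The target genome usually lacks annotated 3'UTRs, so donor-species UTRs are
projected onto it: a donor UTR transfers when an ungapped alignment covers
at least 80% of its length with at most 2 substitutions and lands within a
proximity window of an annotated gene 3' end.  Unigene-derived UTRs join
the transferred set verbatim.  Prediction then scans each UTR for sites
whose bases are antiparallel-complementary to the miRNA seed (positions
2-8; one G:U wobble tolerated), extends an ungapped alignment over the full
mature (+5 per Watson-Crick pair, +1 per G:U, -4 per mismatch), and reports
sites whose total score clears a threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mirseek.config import PipelineConfig

WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
GU = {("G", "T"), ("T", "G")}  # miRNA base, mRNA base (T read as U)

SCORE_WC = 5.0
SCORE_GU = 1.0
SCORE_MISMATCH = -4.0


@dataclass(frozen=True)
class UTRRecord:
    """A usable 3'UTR: transferred from a donor species or taken from unigenes."""

    gene: str
    sequence: str
    source: str                  # "transferred" | "unigene"
    locus_start: int = -1        # genomic, transferred records only
    locus_end: int = -1
    distance_to_gene_end: int = -1


@dataclass(frozen=True)
class TargetSite:
    mirna: str
    gene: str
    position: int                # UTR offset of the site's 5'-most base
    seed_class: str              # "8mer" | "7mer" | "7mer-wobble"
    score: float
    paired_fraction: float


# ---------------------------------------------------------------------------
# UTR transfer

def _best_window(genome_arr: np.ndarray, utr: str, min_cov: float,
                 max_mismatch: int) -> tuple[int, int, int] | None:
    """Best (genome_start, length, mismatches) alignment window, or None.

    Ungapped: a contiguous stretch of the UTR of length >= min_cov * len(UTR)
    aligned with <= max_mismatch substitutions; ties broken toward longer
    windows, then fewer mismatches, then the 5'-most genome position.
    """
    L = len(utr)
    Lmin = math.ceil(min_cov * L)
    G = genome_arr.shape[0]
    if L > G:
        return None
    u = np.frombuffer(utr.encode(), dtype=np.uint8)
    # mismatch matrix over all full-length placements, prefix-summed per row
    placements = np.lib.stride_tricks.sliding_window_view(genome_arr, L) != u
    prefix = np.zeros((placements.shape[0], L + 1), dtype=np.int32)
    np.cumsum(placements, axis=1, out=prefix[:, 1:])
    for length in range(L, Lmin - 1, -1):     # longest acceptable window first
        best: tuple[int, int, int] | None = None
        for a in range(0, L - length + 1):    # UTR window start
            mm = prefix[:, a + length] - prefix[:, a]
            ok = np.nonzero(mm <= max_mismatch)[0]
            if ok.size:
                g0 = int(ok[np.argmin(mm[ok])])
                cand = (g0 + a, length, int(mm[g0]))
                if best is None or (cand[2], cand[0]) < (best[2], best[0]):
                    best = cand
        if best is not None:
            return best
    return None


def transfer_utrs(donor_utrs: dict[str, str], genome: str,
                  gene_ends: pd.DataFrame, config: PipelineConfig,
                  ) -> list[UTRRecord]:
    """Project donor 3'UTRs onto the genome near annotated gene 3' ends.

    ``gene_ends`` needs columns ``name`` and ``end`` (3'-end coordinate).
    Output is sorted by genomic locus, independent of donor input order.
    """
    arr = np.frombuffer(genome.encode(), dtype=np.uint8)
    ends = list(zip(gene_ends["name"], gene_ends["end"].astype(int)))
    records: list[UTRRecord] = []
    for donor_name in sorted(donor_utrs):
        utr = donor_utrs[donor_name].upper()
        hit = _best_window(arr, utr, config.utr_min_coverage, config.utr_max_mismatch)
        if hit is None:
            continue
        g, length, _mm = hit
        distances = [(abs(g - e), gene, e) for gene, e in ends]
        if not distances:
            continue
        dist, gene, _e = min(distances)
        if dist > config.utr_proximity:
            continue
        records.append(UTRRecord(gene=gene, sequence=genome[g:g + length],
                                 source="transferred", locus_start=g,
                                 locus_end=g + length, distance_to_gene_end=dist))
    records.sort(key=lambda r: (r.locus_start, r.gene))
    return records


def unigene_utrs(unigenes: dict[str, str]) -> list[UTRRecord]:
    """Accept unigene-derived UTR sequences verbatim as a second source."""
    return [UTRRecord(gene=name, sequence=seq.upper(), source="unigene")
            for name, seq in sorted(unigenes.items())]


# ---------------------------------------------------------------------------
# site prediction

def _pair_kind(mirna_base: str, mrna_base: str) -> str:
    if (mirna_base, mrna_base) in WC:
        return "wc"
    if (mirna_base, mrna_base) in GU:
        return "gu"
    return "mm"


def _classify_site(mature: str, window: str) -> tuple[str | None, float, float]:
    """(seed class or None, alignment score, paired fraction) for one offset.

    The mature aligns antiparallel: miRNA position k (1-based from its 5'
    end) faces window base ``window[L - k]``.
    """
    L = len(mature)
    kinds = [_pair_kind(mature[k - 1], window[L - k]) for k in range(1, L + 1)]
    seed = kinds[1:8]                      # positions 2-8
    n_wc = seed.count("wc")
    n_gu = seed.count("gu")
    if n_wc == 7:
        seed_class = "8mer" if kinds[0] == "wc" else "7mer"
    elif n_wc == 6 and n_gu == 1:
        seed_class = "7mer-wobble"
    else:
        return None, 0.0, 0.0
    score = sum(SCORE_WC if k == "wc" else SCORE_GU if k == "gu" else SCORE_MISMATCH
                for k in kinds)
    paired = sum(1 for k in kinds if k != "mm") / L
    return seed_class, score, paired


def predict_targets(mirna: str, mature: str, utr: UTRRecord,
                    config: PipelineConfig) -> list[TargetSite]:
    """All seed-anchored sites of ``mature`` in one UTR above the score threshold."""
    mature = mature.upper().replace("U", "T")
    if not 18 <= len(mature) <= 26:
        raise ValueError("mature length must lie in [18, 26] nt")
    seq = utr.sequence
    L = len(mature)
    sites: list[TargetSite] = []
    for j in range(0, len(seq) - L + 1):
        seed_class, score, paired = _classify_site(mature, seq[j:j + L])
        if seed_class is not None and score >= config.target_score_min:
            sites.append(TargetSite(mirna=mirna, gene=utr.gene, position=j,
                                    seed_class=seed_class, score=score,
                                    paired_fraction=paired))
    return sites


def predict_all(matures: dict[str, str], utrs: list[UTRRecord],
                config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for mirna in sorted(matures):
        for utr in utrs:
            for s in predict_targets(mirna, matures[mirna], utr, config):
                rows.append({"miRNA": s.mirna, "gene": s.gene, "position": s.position,
                             "seed_class": s.seed_class, "score": s.score,
                             "paired_fraction": s.paired_fraction,
                             "utr_source": utr.source})
    return pd.DataFrame(rows, columns=["miRNA", "gene", "position", "seed_class",
                                       "score", "paired_fraction", "utr_source"])


# ---------------------------------------------------------------------------
# pathway tallies and expression trends

def tally_pathways(sites: pd.DataFrame, gene_to_pathway: dict[str, str],
                   ) -> pd.DataFrame:
    """Unique target genes and contributing miRNAs per pathway.

    Genes missing from the map land in an "unmapped" row; a gene counts once
    per pathway however many miRNAs or sites hit it.
    """
    per_pathway_genes: dict[str, set[str]] = {}
    per_pathway_mirnas: dict[str, set[str]] = {}
    for _, row in sites.iterrows():
        pathway = gene_to_pathway.get(row["gene"], "unmapped")
        per_pathway_genes.setdefault(pathway, set()).add(row["gene"])
        per_pathway_mirnas.setdefault(pathway, set()).add(row["miRNA"])
    rows = [{"pathway": p, "target_genes": len(per_pathway_genes[p]),
             "mirnas": len(per_pathway_mirnas[p])}
            for p in sorted(per_pathway_genes)]
    return pd.DataFrame(rows, columns=["pathway", "target_genes", "mirnas"])


def target_counts(sites: pd.DataFrame) -> dict[str, int]:
    """Both target-counting conventions: unique genes overall, and summed
    per-miRNA gene counts (a gene hit by k miRNAs contributes k)."""
    if sites.empty:
        return {"unique_genes": 0, "gene_mirna_pairs": 0}
    return {"unique_genes": int(sites["gene"].nunique()),
            "gene_mirna_pairs": int(sites.drop_duplicates(["miRNA", "gene"]).shape[0])}


def compare_target_expression(fpkm: pd.DataFrame, target_genes: list[str],
                              groups: dict[str, str],
                              contrast: tuple[str, str],
                              threshold: float = 0.2) -> pd.DataFrame:
    """Per-gene group-mean FPKM and a trend label.

    A gene is ``higher_in_<group>`` when the relative difference of group
    means, |mA - mB| / mean(mA, mB), exceeds ``threshold``; otherwise
    ``tied``.  Genes absent from the table are flagged ``missing``.
    """
    ga, gb = contrast
    cols_a = [s for s in fpkm.columns if groups.get(s) == ga]
    cols_b = [s for s in fpkm.columns if groups.get(s) == gb]
    if not cols_a or not cols_b:
        raise ValueError("both contrast groups need at least one FPKM column")
    rows = []
    for gene in target_genes:
        if gene not in fpkm.index:
            rows.append({"gene": gene, "mean_A": float("nan"),
                         "mean_B": float("nan"), "trend": "missing"})
            continue
        ma = float(fpkm.loc[gene, cols_a].mean())
        mb = float(fpkm.loc[gene, cols_b].mean())
        center = (ma + mb) / 2
        if center == 0:
            trend = "tied"
        else:
            rel = (ma - mb) / center
            trend = (f"higher_in_{ga}" if rel > threshold
                     else f"higher_in_{gb}" if rel < -threshold else "tied")
        rows.append({"gene": gene, "mean_A": ma, "mean_B": mb, "trend": trend})
    return pd.DataFrame(rows)
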