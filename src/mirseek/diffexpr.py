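"""Exact two-library differential expression for tag counts.

Counts are first normalized to reads per million of clean reads
(NE = count / total * 1e6).  A zero NE is replaced by 0.01 so the
log2 fold change stays finite; miRNAs whose NE stays below 1 are excluded
from testing.  Significance comes from the Audic-Claverie exact statistic
for one tag observed x times in a library of depth N1 and y times in a
library of depth N2:

    p(y | x) = (N2/N1)^y * (x+y)! / (x! y!) / (1 + N2/N1)^(x+y+1)

which is the negative-binomial mass with size x+1 and success probability
N1/(N1+N2) evaluated at y.  The lower tail C sums p(y'|x) for y' <= y, the
upper tail D for y' >= y, and the two-sided p-value is 2*min(C, D) capped
at 1.  Everything is computed in log-gamma space so large counts are safe.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from mirseek.config import PipelineConfig

STATUS_TESTED = "tested"
STATUS_ZERO_SUBSTITUTED = "zero_substituted"
STATUS_EXCLUDED = "excluded_low_NE"


@dataclass(frozen=True)
class LibraryPair:
    """One miRNA's counts in two libraries with their clean-read totals."""

    x: int
    y: int
    N1: int
    N2: int

    def __post_init__(self) -> None:
        if min(self.x, self.y) < 0 or min(self.N1, self.N2) < 1:
            raise ValueError("counts must be >= 0 and totals >= 1")
        if self.x > self.N1 or self.y > self.N2:
            raise ValueError("count exceeds its library total")


def normalize(count: float, total: int) -> float:
    """Reads-per-million normalization: count / total * 1e6."""
    if total < 1:
        raise ValueError("library total must be >= 1")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    return count / total * 1e6


def preprocess_pair(ne1: float, ne2: float,
                    config: PipelineConfig) -> tuple[float, float, str]:
    """Zero substitution and low-expression exclusion, applied before testing.

    Exact zeros become ``ne_floor_substitute`` (default 0.01).  The pair is
    excluded when its adjusted NEs fall below ``ne_exclusion`` (strictly less
    than 1 by default) — in both libraries under mode "both", in at least one
    under mode "either".
    """
    if ne1 < 0 or ne2 < 0:
        raise ValueError("NE values must be non-negative")
    substituted = ne1 == 0 or ne2 == 0
    a1 = config.ne_floor_substitute if ne1 == 0 else ne1
    a2 = config.ne_floor_substitute if ne2 == 0 else ne2
    low1, low2 = a1 < config.ne_exclusion, a2 < config.ne_exclusion
    excluded = (low1 and low2) if config.ne_exclusion_mode == "both" else (low1 or low2)
    if excluded:
        return a1, a2, STATUS_EXCLUDED
    return a1, a2, STATUS_ZERO_SUBSTITUTED if substituted else STATUS_TESTED


def log2fc(ne_a: float, ne_b: float) -> float:
    """log2(NE_A / NE_B); both inputs must be positive (post-substitution)."""
    if ne_a <= 0 or ne_b <= 0:
        raise ValueError("fold change requires positive NE values")
    return math.log2(ne_a / ne_b)


def _log_pmf(y: np.ndarray, x: int, N1: int, N2: int) -> np.ndarray:
    log_r = math.log(N2) - math.log(N1)
    y = np.asarray(y, dtype=np.float64)
    return (y * log_r + gammaln(x + y + 1) - gammaln(x + 1) - gammaln(y + 1)
            - (x + y + 1) * np.log1p(math.exp(log_r)))


def ac_pmf(y: int, x: int, N1: int, N2: int) -> float:
    """Probability of observing y in library 2 given x in library 1."""
    if y < 0 or x < 0 or N1 < 1 or N2 < 1:
        raise ValueError("require y, x >= 0 and N1, N2 >= 1")
    return float(np.exp(_log_pmf(np.array([y]), x, N1, N2))[0])


def ac_tails(x: int, y_obs: int, N1: int, N2: int) -> tuple[float, float, float]:
    """(D, C, two-sided p) for observed counts (x, y_obs).

    C = sum_{y <= y_obs} p(y|x); D = 1 - sum_{y < y_obs} p(y|x) (the upper
    tail, by complement, so the infinite sum never has to converge);
    two-sided p = min(1, 2*min(C, D)).
    """
    if y_obs < 0 or x < 0 or N1 < 1 or N2 < 1:
        raise ValueError("require y_obs, x >= 0 and N1, N2 >= 1")
    log_p = _log_pmf(np.arange(y_obs + 1), x, N1, N2)
    c = float(np.exp(logsumexp(log_p)))
    below = float(np.exp(logsumexp(log_p[:-1]))) if y_obs > 0 else 0.0
    d = 1.0 - below
    c, d = min(c, 1.0), min(max(d, 0.0), 1.0)
    return d, c, min(1.0, 2.0 * min(c, d))


def analyze_pair(pair: LibraryPair, config: PipelineConfig) -> dict:
    """Full per-miRNA treatment of one library pair: NE, fold change, exact test."""
    ne1 = normalize(pair.x, pair.N1)
    ne2 = normalize(pair.y, pair.N2)
    a1, a2, status = preprocess_pair(ne1, ne2, config)
    lfc = log2fc(a1, a2)
    if status == STATUS_EXCLUDED:
        d = c = p2 = float("nan")
        significant = False
    else:
        d, c, p2 = ac_tails(pair.x, pair.y, pair.N1, pair.N2)
        significant = (p2 < config.de_p_threshold
                       and abs(lfc) >= config.de_lfc_threshold)
    return {"NE1": ne1, "NE2": ne2, "log2fc": lfc, "p_up": d, "p_down": c,
            "p_two_sided": p2, "status": status, "significant": significant}


def call_differential(matrix: pd.DataFrame, totals: dict[str, int],
                      groups: dict[str, str], config: PipelineConfig,
                      contrast: tuple[str, str] | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test every between-group sample pair and call consensus regulation.

    ``matrix`` holds read counts (rows = miRNAs, columns = samples);
    ``totals`` the per-sample clean-read totals; ``groups`` maps sample to
    group label.  Every (group A sample, group B sample) pair is tested with
    the exact statistic; a miRNA is consensus-up in group A when it is
    significant with positive log2fc in ALL pairs, consensus-down when
    negative in all pairs.  Returns (per-pair table, consensus table).
    """
    unknown = set(matrix.columns) - set(groups)
    if unknown:
        raise ValueError(f"samples without group assignment: {sorted(unknown)}")
    labels = sorted(set(groups.values()))
    if contrast is None:
        if len(labels) != 2:
            raise ValueError("contrast must be given when there are not exactly 2 groups")
        contrast = (labels[0], labels[1])
    ga, gb = contrast
    samples_a = [s for s in matrix.columns if groups[s] == ga]
    samples_b = [s for s in matrix.columns if groups[s] == gb]
    if not samples_a or not samples_b:
        raise ValueError("each contrast group needs at least one sample")

    rows = []
    for sa, sb in itertools.product(samples_a, samples_b):
        for mirna, counts in matrix[[sa, sb]].iterrows():
            pair = LibraryPair(int(counts[sa]), int(counts[sb]),
                               totals[sa], totals[sb])
            res = analyze_pair(pair, config)
            rows.append({"miRNA": mirna, "sample_A": sa, "sample_B": sb, **res})
    per_pair = pd.DataFrame(rows)

    consensus_rows = []
    for mirna, sub in per_pair.groupby("miRNA", sort=False):
        sig_up = bool((sub["significant"] & (sub["log2fc"] > 0)).all())
        sig_down = bool((sub["significant"] & (sub["log2fc"] < 0)).all())
        call = f"up_in_{ga}" if sig_up else (f"up_in_{gb}" if sig_down else "ns")
        consensus_rows.append({"miRNA": mirna, "contrast": f"{ga}_vs_{gb}",
                               "n_pairs": len(sub), "call": call,
                               "mean_log2fc": float(sub["log2fc"].mean())})
    return per_pair, pd.DataFrame(consensus_rows)
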