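"""Sequence primitives: complements and dinucleotide-preserving shuffles."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the DNA alphabet (N self-complementary)."""
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle ``seq`` preserving its exact dinucleotide counts.

    Altschul-Erickson construction: the sequence is an Eulerian walk on the
    multigraph whose vertices are the distinct letters and whose edges are
    the observed dinucleotides.  A uniformly random "last edge" per vertex is
    drawn until those edges form a tree rooted at the final letter; the
    remaining edges of each vertex are permuted freely and the walk is
    rebuilt from the first letter.  Sequences shorter than 3 letters, or with
    a single distinct letter, have a unique arrangement and are returned
    unchanged.
    """
    n = len(seq)
    if n < 3 or len(set(seq)) == 1:
        return seq

    # successor lists: edges[v] = list of letters following v in seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = [v for v in edges if v != last]

    # draw last-edge choices until they connect every non-terminal vertex
    # to the terminal letter (guarantees an Eulerian walk exists)
    for _ in range(10000):
        pick = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        ok = True
        for v in vertices:
            # follow last-edge pointers; must reach `last` without cycling
            seen = {v}
            cur = v
            while cur != last:
                cur = pick.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - bounded-retry safety net
        raise RuntimeError("dinucleotide shuffle failed to find a connected edge set")

    walk_edges: dict[str, list[str]] = {}
    for v, succ in edges.items():
        succ = list(succ)
        if v in pick:
            succ.remove(pick[v])
        order = rng.permutation(len(succ))
        shuffled = [succ[i] for i in order]
        if v in pick:
            shuffled.append(pick[v])
        walk_edges[v] = shuffled

    # rebuild the walk from the first letter
    out = [seq[0]]
    ptr = {v: 0 for v in walk_edges}
    cur = seq[0]
    for _ in range(n - 1):
        nxt = walk_edges[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def dinucleotide_counts(seq: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    return counts
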