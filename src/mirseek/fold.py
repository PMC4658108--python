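"""Secondary-structure scoring by weighted base-pair maximization.

A Nussinov-style dynamic program replaces thermodynamic folding: pairs are
worth GC=3, AU=2, GU=1 (T read as U), hairpin loops must span at least 3
unpaired bases, and the optimal score plus one optimal structure are
returned.  Tie-breaking is deterministic — pairing the outermost base is
preferred over leaving it unpaired, and among equal-scoring partners the
5'-most partner wins — so identical inputs always fold identically.
"""

from __future__ import annotations

import numpy as np

MIN_LOOP = 3

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}

# pair weights indexed by (code, code): GC=3, AU=2, GU=1
PAIR_WEIGHT = np.zeros((5, 5), dtype=np.int64)
PAIR_WEIGHT[2, 1] = PAIR_WEIGHT[1, 2] = 3
PAIR_WEIGHT[0, 3] = PAIR_WEIGHT[3, 0] = 2
PAIR_WEIGHT[2, 3] = PAIR_WEIGHT[3, 2] = 1


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in seq.upper()], dtype=np.int64)


def _fill_py(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    m = np.zeros((n, n), dtype=np.int64)
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = m[i + 1, j]                   # i unpaired
            for k in range(i + MIN_LOOP + 1, j + 1):  # i paired with k
                pw = w[x[i], x[k]]
                if pw == 0:
                    continue
                inner = m[i + 1, k - 1] if k - 1 > i + 1 else 0
                right = m[k + 1, j] if k + 1 <= j else 0
                cand = pw + inner + right
                if cand > best:
                    best = cand
            m[i, j] = best
    return m


try:  # the DP is O(n^3); JIT it when numba is present
    from numba import njit

    _fill = njit(cache=True)(_fill_py)
except Exception:  # pragma: no cover
    _fill = _fill_py


def pairing_score(seq: str) -> int:
    """Optimal weighted base-pair score of ``seq`` (no traceback)."""
    x = encode(seq)
    if x.shape[0] <= MIN_LOOP + 1:
        return 0
    return int(_fill(x, PAIR_WEIGHT)[0, x.shape[0] - 1])


def fold_hairpin(seq: str) -> tuple[str, int]:
    """Fold ``seq`` and return (dot-bracket structure, pairing score)."""
    x = encode(seq)
    n = x.shape[0]
    if n == 0:
        return "", 0
    if n <= MIN_LOOP + 1:
        return "." * n, 0
    m = _fill(x, PAIR_WEIGHT)
    struct = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        best = int(m[i, j])
        # prefer closing the outermost pair; among partners prefer the 5'-most
        chosen = None
        for k in range(i + MIN_LOOP + 1, j + 1):
            pw = int(PAIR_WEIGHT[x[i], x[k]])
            if pw == 0:
                continue
            inner = int(m[i + 1, k - 1]) if k - 1 > i + 1 else 0
            right = int(m[k + 1, j]) if k + 1 <= j else 0
            if pw + inner + right == best:
                chosen = k
                break
        if chosen is None:
            stack.append((i + 1, j))
        else:
            struct[i], struct[chosen] = "(", ")"
            if chosen - 1 > i + 1:
                stack.append((i + 1, chosen - 1))
            if chosen + 1 <= j:
                stack.append((chosen + 1, j))
    return "".join(struct), int(m[0, n - 1])


def pair_table(structure: str) -> list[int]:
    """Partner index per position from dot-bracket notation (-1 = unpaired)."""
    partner = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            partner[i], partner[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return partner
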