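"""Built-in nested-structure folding under a simple stacking-energy model.

This is deliberately not a full thermodynamic nearest-neighbour model: it is
a deterministic, dependency-free scoring scheme adequate for hairpin-shaped
molecules, and its energies are NOT comparable to Mfold/ViennaRNA values.
Any threshold trained on one folding backend must be applied with the same
backend; structures carry a backend tag for that reason.

Model
-----
A structure is a nested (pseudoknot-free) set of pairs drawn from
{A:U, G:C, G:U}, with at least ``MIN_LOOP`` unpaired bases inside every
hairpin loop. Its score is

    sum over pairs of pair_score(base pair)  +  STACK_BONUS per stacked pair

where a pair (i, j) is stacked when (i+1, j-1) is also paired. The reported
"MFE" is the negative of the maximal score, in kcal/mol-like arbitrary
units, so more stable structures are more negative, 0 means no pairs.

The optimum is found by an O(n^3) dynamic programme over three tables:

    W[i,j]  best score on [i..j]
    P[i,j]  best score on [i..j] with (i,j) paired
    N[i,j]  best score on [i..j] with (i,j) not paired to each other

with P[i,j] = e(i,j) + max(P[i+1,j-1] + STACK_BONUS, N[i+1,j-1]), which is
what lets the stacking term be scored exactly. Ties are broken
deterministically (pairing preferred, then leftmost decomposition), so
folding is reproducible.
"""

from __future__ import annotations

import numpy as np

MIN_LOOP = 3
STACK_BONUS = 1.0
PAIR_SCORES = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "T"): 2.0, ("T", "A"): 2.0,
    ("G", "T"): 1.0, ("T", "G"): 1.0,
}

NEG = -1e18


def pair_score(a: str, b: str) -> float | None:
    return PAIR_SCORES.get((a, b))


def _tables(seq: str):
    n = len(seq)
    e = np.full((n, n), NEG)
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            s = PAIR_SCORES.get((seq[i], seq[j]))
            if s is not None:
                e[i, j] = s
    # inclusive-index tables, extra row/col so that empty intervals read 0
    Wm = np.zeros((n + 2, n + 2))
    P = np.full((n + 2, n + 2), NEG)
    Nm = np.zeros((n + 2, n + 2))
    # iterate by span
    for span in range(1, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            # N[i,j]: i unpaired, or i paired to k<j
            best_n = Wm[i + 1, j] if span >= 2 else 0.0
            if span >= 2:
                ks = np.arange(i + MIN_LOOP + 1, j)
                if ks.size:
                    cand = P[i, ks] + Wm[ks + 1, j]
                    m = cand.max()
                    if m > best_n:
                        best_n = m
            Nm[i, j] = best_n
            # P[i,j]
            if span >= MIN_LOOP + 2 and e[i, j] > NEG / 2:
                inner_i, inner_j = i + 1, j - 1
                stacked = P[inner_i, inner_j] + STACK_BONUS if P[inner_i, inner_j] > NEG / 2 else NEG
                unstacked = Nm[inner_i, inner_j]
                P[i, j] = e[i, j] + max(stacked, unstacked)
            Wm[i, j] = max(Nm[i, j], P[i, j])
    return e, Wm, P, Nm


def fold_builtin(sequence: str) -> tuple[list[int | None], float]:
    """Fold a DNA/RNA string; returns (partner list, mfe).

    partner[i] is the 0-based partner of position i or None. mfe is the
    negated optimal score (<= 0).
    """
    seq = sequence.upper().replace("U", "T")
    n = len(seq)
    if n == 0:
        return [], 0.0
    e, Wm, P, Nm = _tables(seq)
    partner: list[int | None] = [None] * n

    def trace(i: int, j: int, must_pair: bool) -> None:
        if i >= j:
            return
        if must_pair or (P[i, j] > NEG / 2 and P[i, j] >= Nm[i, j]):
            # (i, j) paired
            partner[i], partner[j] = j, i
            ii, jj = i + 1, j - 1
            stacked = P[ii, jj] + STACK_BONUS if P[ii, jj] > NEG / 2 else NEG
            if stacked >= Nm[ii, jj] and stacked > NEG / 2:
                trace(ii, jj, True)
            else:
                trace_n(ii, jj)
        else:
            trace_n(i, j)

    def trace_n(i: int, j: int) -> None:
        if i >= j:
            return
        target = Nm[i, j]
        if target == Wm[i + 1, j]:
            trace(i + 1, j, False)
            return
        for k in range(i + MIN_LOOP + 1, j):
            if P[i, k] > NEG / 2 and abs(P[i, k] + Wm[k + 1, j] - target) < 1e-9:
                trace(i, k, True)
                trace(k + 1, j, False)
                return
        trace(i + 1, j, False)  # numerically safe fallback

    score = Wm[0, n - 1] if n >= 2 else 0.0
    # recursion depth can reach n for long helices; iterative safety margin
    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * n + 100))
    try:
        trace(0, n - 1, False)
    finally:
        sys.setrecursionlimit(old)
    return partner, (-float(score) if score else 0.0)


def structure_score(seq: str, pairs: list[tuple[int, int]]) -> float:
    """Score an explicit pair set under the same model (oracle helper)."""
    seq = seq.upper().replace("U", "T")
    pset = set(pairs)
    total = 0.0
    for i, j in pairs:
        s = PAIR_SCORES.get((seq[i], seq[j]))
        if s is None:
            raise ValueError(f"illegal pair {seq[i]}:{seq[j]} at ({i},{j})")
        total += s
        if (i + 1, j - 1) in pset:
            total += STACK_BONUS
    return total


def enumerate_structures(seq: str):
    """Yield every legal nested pair set (brute force; use only for n <= ~18).

    Independent of the DP: recursive enumeration by the fate of the first
    position. Serves as the exhaustive oracle for fold_builtin.
    """
    seq = seq.upper().replace("U", "T")
    n = len(seq)

    def gen(i: int, j: int):
        # all pair sets on inclusive [i..j]
        if i >= j:
            yield []
            return
        # i unpaired
        for rest in gen(i + 1, j):
            yield rest
        # i paired to k
        for k in range(i + MIN_LOOP + 1, j + 1):
            if PAIR_SCORES.get((seq[i], seq[k])) is None:
                continue
            for inner in gen(i + 1, k - 1):
                for outer in gen(k + 1, j):
                    yield [(i, k)] + inner + outer

    yield from gen(0, n - 1)
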