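"""Secondary-structure prediction for candidate precursor windows.

A hairpin is predicted by maximum-weight nested pairing (Nussinov-style
dynamic programming) with pair weights GC=3, AU=2, GU=1 and a minimum
hairpin-loop of 3 nt.  This is a combinatorial, not a thermodynamic, model:
it is fully deterministic, dependency-free and exactly checkable against
exhaustive enumeration, which is what the duplex-validation step downstream
needs.  An external thermodynamic folder can be substituted behind the same
``fold`` contract.

Traceback is deterministic: at every sub-interval the closing base ``j`` is
paired if pairing attains the optimum (preferring the smallest partner
``k``), otherwise left unpaired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from sporomir.sequences import encode

#: pair weights, indexed by encoded bases (A=0, C=1, G=2, T=3)
PAIR_WEIGHTS = np.zeros((4, 4), dtype=np.int32)
for _a, _b, _w in [("G", "C", 3), ("A", "T", 2), ("G", "T", 1)]:
    _i, _j = "ACGT".index(_a), "ACGT".index(_b)
    PAIR_WEIGHTS[_i, _j] = _w
    PAIR_WEIGHTS[_j, _i] = _w

MIN_LOOP = 3


@dataclass(frozen=True)
class Hairpin:
    """A folded window: dot-bracket structure plus a pair map.

    ``partner[i]`` is the paired position of ``i`` or -1; ``score`` is the
    total pair weight; ``loop_spans`` lists the (start, end) half-open
    intervals of hairpin loops (unpaired stretches closed by a pair).
    """

    sequence: str
    structure: str
    partner: np.ndarray
    score: int

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [(i, int(j)) for i, j in enumerate(self.partner) if 0 <= j and i < j]

    @property
    def loop_spans(self) -> list[tuple[int, int]]:
        spans = []
        for i, j in self.pairs:
            if all(self.partner[k] < 0 for k in range(i + 1, j)):
                spans.append((i + 1, j))
        return spans


@njit(cache=True)
def _fill(seq, wmat, min_loop):  # pragma: no cover - exercised via fold()
    n = seq.size
    W = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = W[i, j - 1]
            for k in range(i, j - min_loop):
                w = wmat[seq[k], seq[j]]
                if w > 0:
                    s = w + W[k + 1, j - 1]
                    if k > i:
                        s += W[i, k - 1]
                    if s > best:
                        best = s
            W[i, j] = best
    return W


@njit(cache=True)
def _traceback(W, seq, wmat, min_loop):  # pragma: no cover
    n = seq.size
    partner = np.full(n, -1, dtype=np.int32)
    stack = np.empty((2 * n + 2, 2), dtype=np.int32)
    top = 0
    stack[top, 0] = 0
    stack[top, 1] = n - 1
    top += 1
    while top > 0:
        top -= 1
        i, j = stack[top, 0], stack[top, 1]
        if j - i <= min_loop:
            continue
        target = W[i, j]
        chosen = -1
        for k in range(i, j - min_loop):
            w = wmat[seq[k], seq[j]]
            if w > 0:
                s = w + W[k + 1, j - 1]
                if k > i:
                    s += W[i, k - 1]
                if s == target:
                    chosen = k
                    break
        if chosen < 0:
            stack[top, 0] = i
            stack[top, 1] = j - 1
            top += 1
        else:
            partner[chosen] = j
            partner[j] = chosen
            if chosen > i:
                stack[top, 0] = i
                stack[top, 1] = chosen - 1
                top += 1
            stack[top, 0] = chosen + 1
            stack[top, 1] = j - 1
            top += 1
    return partner


def fold(window: str) -> Hairpin:
    """Fold a window into its maximum-weight nested structure.

    Parameters
    ----------
    window : str
        DNA/RNA sequence, typically 20-1000 nt.
    """
    if not window:
        raise ValueError("cannot fold an empty window")
    seq = encode(window.upper().replace("U", "T"))
    n = seq.size
    if n <= MIN_LOOP:
        partner = np.full(n, -1, dtype=np.int32)
        return Hairpin(window, "." * n, partner, 0)
    W = _fill(seq, PAIR_WEIGHTS, MIN_LOOP)
    partner = _traceback(W, seq, PAIR_WEIGHTS, MIN_LOOP)
    structure = "".join(
        "." if p < 0 else ("(" if p > i else ")") for i, p in enumerate(partner)
    )
    return Hairpin(window, structure, partner, int(W[0, n - 1]))
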