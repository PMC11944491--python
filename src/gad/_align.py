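"""Semi-global alignment kernel shared by the whole package.

Overlap (dovetail) alignment: gaps before the first and after the last
aligned column are free and excluded from scoring.  Interior columns score
match +1, mismatch -1, gap -1.  Among equal-score alignments the one with
the most matched columns is reported, which makes the derived identity a
symmetric, path-convention-free function of the two sequences.

The DP maximises (score, matches) lexicographically, packed into one
integer K = score*B + matches with B larger than any match count; the
interior column count then follows from columns = 2*matches - score, so no
traceback is needed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGTRYSWKMBDHVN"):
    _CODE[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-IUPAC characters")
    return arr


@njit(cache=True)
def _overlap_align(a, b):  # pragma: no cover - exercised via wrapper
    n, m = a.shape[0], b.shape[0]
    B = 2 * (n + m) + 2  # strictly above any match count
    prev = np.zeros(m + 1, dtype=np.int64)
    cur = np.zeros(m + 1, dtype=np.int64)
    best = np.int64(0)  # the empty (all-terminal-gap) alignment
    for i in range(n):
        ai = a[i]
        for j in range(m):
            kd = prev[j] + (B + 1 if ai == b[j] else -B)
            ku = prev[j + 1] - B
            if ku > kd:
                kd = ku
            kl = cur[j] - B
            if kl > kd:
                kd = kl
            cur[j + 1] = kd
        if cur[m] > best:  # ends in the last column: b suffix free
            best = cur[m]
        prev, cur = cur, prev
    for j in range(m + 1):  # ends in the last row: a suffix free
        if prev[j] > best:
            best = prev[j]
    matches = best % B
    score = (best - matches) // B
    return score, matches


def overlap_align(a: np.ndarray, b: np.ndarray):
    """Return (score, matches, scored_columns) for two encoded sequences."""
    s, m = _overlap_align(a, b)
    return int(s), int(m), int(2 * m - s)
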