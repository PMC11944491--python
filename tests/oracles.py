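"""Independent reference implementations used only by the tests.

Coded deliberately differently from the package: the alignment oracles work
top-down over suffixes (or enumerate complete alignment paths outright), and
the greedy-clustering oracle is a direct transliteration of the clustering
rule.  They exist so the production implementations can be checked against
an implementation that shares no code path with them.
"""

from functools import lru_cache
from typing import Dict, List, Sequence, Tuple

from gad.io_formats import SeqRecord
from gad.similarity import pairwise_identity

Pair = Tuple[int, int]  # (score, matches), compared lexicographically


def oracle_identity(a: str, b: str) -> float:
    """Best overlap-alignment identity via memoized suffix recursion.

    Terminal gaps are free: the alignment may start after skipping a prefix
    of one sequence and may stop as soon as either sequence is exhausted.
    Score ties resolve to the alignment with the most matches.
    """
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def rest(i: int, j: int) -> Pair:
        # best (score, matches) achievable from cell (i, j) onward
        if i == n or j == m:
            return (0, 0)  # stop; the remaining suffix is a free terminal gap
        eq = a[i] == b[j]
        ds, dm = rest(i + 1, j + 1)
        best = (ds + (1 if eq else -1), dm + (1 if eq else 0))
        us, um = rest(i + 1, j)
        if (us - 1, um) > best:
            best = (us - 1, um)
        ls, lm = rest(i, j + 1)
        if (ls - 1, lm) > best:
            best = (ls - 1, lm)
        return best

    starts = [(i, 0) for i in range(n + 1)] + [(0, j) for j in range(m + 1)]
    score, matches = max(rest(i, j) for i, j in starts)
    columns = 2 * matches - score
    return 100.0 * matches / columns if columns else 0.0


def enumerate_identity(a: str, b: str) -> float:
    """Full enumeration of every overlap alignment path (tiny strings only)."""
    n, m = len(a), len(b)
    best = (0, 0)

    def walk(i: int, j: int, score: int, matches: int) -> None:
        nonlocal best
        if i == n or j == m:
            # interior gaps from here on only lose score; stopping dominates
            if (score, matches) > best:
                best = (score, matches)
            return
        eq = a[i] == b[j]
        walk(i + 1, j + 1, score + (1 if eq else -1), matches + (1 if eq else 0))
        walk(i + 1, j, score - 1, matches)
        walk(i, j + 1, score - 1, matches)

    for i0 in range(n + 1):
        walk(i0, 0, 0, 0)
    for j0 in range(m + 1):
        walk(0, j0, 0, 0)
    score, matches = best
    columns = 2 * matches - score
    return 100.0 * matches / columns if columns else 0.0


def oracle_greedy(
    records: Sequence[SeqRecord], threshold_pct: float
) -> List[List[str]]:
    """Brute-force greedy clustering: size-ordered pass, first matching
    centroid wins.  Returns member-id lists in centroid creation order."""
    ordered = sorted(records, key=lambda r: (-r.abundance, -len(r.sequence), r.id))
    centroids: List[SeqRecord] = []
    clusters: List[List[str]] = []
    for rec in ordered:
        for idx, cen in enumerate(centroids):
            if pairwise_identity(rec.sequence, cen.sequence).identity_pct >= threshold_pct:
                clusters[idx].append(rec.id)
                break
        else:
            centroids.append(rec)
            clusters.append([rec.id])
    return clusters
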