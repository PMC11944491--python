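"""Rank-threshold calibration from a labeled reference set.

Intra-rank pairwise identity distributions (pairs sharing a rank label but
differing at every rank below it) characterise each taxonomic boundary; the
rounded median per rank is the recommended clustering threshold.  A mirror
check compares the distribution computed on full sequences with the one on
an extracted sub-region, and a fragmentation scan quantifies how many greedy
clusters a named taxon shatters into at a given threshold.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .clustering import greedy_cluster
from .io_formats import AlignedSeqRecord, SeqRecord
from .region_prep import RegionSpec, extract_region
from .similarity import ReferenceDB, pairwise_identity

logger = logging.getLogger("gad")

_RANK_BELOW = {"family": ("genus", "species"), "genus": ("species",), "species": ()}


@dataclass
class RankIdentityDistribution:
    rank: str  # family | genus | species
    identities: List[float]

    @property
    def median(self) -> float:
        if not self.identities:
            raise ValueError(f"empty identity distribution for rank {self.rank}")
        return float(statistics.median(self.identities))

    def percentile(self, q: float) -> float:
        if not self.identities:
            raise ValueError(f"empty identity distribution for rank {self.rank}")
        xs = sorted(self.identities)
        idx = min(len(xs) - 1, max(0, round(q / 100 * (len(xs) - 1))))
        return xs[idx]


def _rank_pairs(db: ReferenceDB, rank: str) -> List[Tuple[str, str]]:
    """Unordered id pairs sharing ``rank`` but differing at every lower rank."""
    below = _RANK_BELOW[rank]
    ids = [r.id for r in db.records]
    pairs = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ta, tb = db.taxonomy[ids[i]], db.taxonomy[ids[j]]
            if ta.rank(rank).startswith("UNK") or tb.rank(rank).startswith("UNK"):
                continue
            if ta.rank(rank) != tb.rank(rank):
                continue
            if any(
                not ta.rank(rb).startswith("UNK")
                and not tb.rank(rb).startswith("UNK")
                and ta.rank(rb) == tb.rank(rb)
                for rb in below
            ):
                continue
            pairs.append((ids[i], ids[j]))
    return pairs


def intra_taxon_identities(
    db: ReferenceDB,
    rank: str,
    region: Optional[RegionSpec] = None,
    aligned: Optional[Sequence[AlignedSeqRecord]] = None,
) -> RankIdentityDistribution:
    """Pairwise identities across one taxonomic boundary.

    With ``region`` given, identities are computed on the extracted sub-region
    of each sequence (aligned records required); otherwise on full sequences.
    """
    if rank not in _RANK_BELOW:
        raise ValueError(f"rank must be one of {sorted(_RANK_BELOW)}")
    seqs: Dict[str, str] = {r.id: r.sequence for r in db.records}
    if region is not None:
        if aligned is None:
            raise ValueError("region given but no aligned records")
        by_id = {a.id: a for a in aligned}
        missing = [i for i in seqs if i not in by_id]
        if missing:
            raise ValueError(f"aligned records missing for {missing[:5]}")
        seqs = {i: extract_region(by_id[i], region).sequence for i in seqs}
    pairs = _rank_pairs(db, rank)
    if not pairs:
        logger.warning("rank %s has <2 labeled members; empty distribution", rank)
    idents = [
        pairwise_identity(seqs[a], seqs[b]).identity_pct for a, b in pairs
    ]
    return RankIdentityDistribution(rank, idents)


def mirror_check(
    full: RankIdentityDistribution,
    region: RankIdentityDistribution,
    tolerance: float = 2.0,
) -> dict:
    """Does the sub-region reproduce the full-length identity structure?

    Passes when the rank medians differ by at most ``tolerance`` percentage
    points.
    """
    if full.rank != region.rank:
        raise ValueError("mirror_check requires distributions of the same rank")
    diff = abs(full.median - region.median)
    return {
        "rank": full.rank,
        "full_median": full.median,
        "region_median": region.median,
        "difference": diff,
        "tolerance": tolerance,
        "passed": diff <= tolerance,
    }


def recommend_thresholds(
    dists: Mapping[str, RankIdentityDistribution],
) -> Tuple[int, int, int]:
    """(species, genus, family) thresholds = rounded per-rank medians.

    Non-monotone medians (species < genus, or genus < family) signal
    mislabeled reference data and raise.
    """
    missing = {"species", "genus", "family"} - set(dists)
    if missing:
        raise ValueError(f"missing rank distributions: {sorted(missing)}")
    medians = {r: dists[r].median for r in ("species", "genus", "family")}
    if not (medians["species"] >= medians["genus"] >= medians["family"]):
        raise ValueError(
            f"non-monotone rank medians {medians}; check reference labels"
        )
    thresholds = tuple(round(medians[r]) for r in ("species", "genus", "family"))
    if not (thresholds[0] >= thresholds[1] >= thresholds[2]):
        raise ValueError(f"non-monotone rounded thresholds {thresholds}")
    return thresholds  # type: ignore[return-value]


def taxon_fragmentation(
    db: ReferenceDB, rank: str, threshold_pct: float
) -> Dict[str, int]:
    """Greedy cluster count per named taxon at ``rank``.

    A count above 1 means sequence-similarity clustering splits a taxonomy-
    defined group, i.e. cluster counts at that rank overestimate taxon counts.
    """
    groups: Dict[str, List[SeqRecord]] = {}
    for rec in db.records:
        name = db.taxonomy[rec.id].rank(rank)
        if name.startswith("UNK"):
            continue
        groups.setdefault(name, []).append(rec)
    return {
        name: len(greedy_cluster(members, threshold_pct, level=rank))
        for name, members in groups.items()
    }
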