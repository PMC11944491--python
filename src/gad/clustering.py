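"""Greedy centroid clustering and the tiered SOTU/GOTU/FOTU construction.

Records are processed in decreasing abundance order (UPARSE/VSEARCH size
ordering); each joins the first centroid it matches at the level threshold
or founds a new cluster.  Higher tiers cluster the lower tier's centroids,
each weighted by its cluster's total abundance, which guarantees strict
nesting of species into genus into family clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .io_formats import SeqRecord
from .similarity import DEFAULT_THRESHOLDS, pairwise_identity

OCCUPANCY_CLASSES = ("singleton", "doubleton", "tripleton", "moreton")


@dataclass
class Cluster:
    centroid_id: str
    member_ids: List[str]
    level: str  # species | genus | family
    total_abundance: int
    samples: frozenset

    def __post_init__(self):
        if self.centroid_id not in self.member_ids:
            raise ValueError("centroid must be a member of its cluster")

    @property
    def occupancy(self) -> str:
        n = len(self.samples)
        return OCCUPANCY_CLASSES[min(n, 4) - 1]


@dataclass
class TieredClusterSet:
    species_clusters: List[Cluster]
    genus_clusters: List[Cluster]
    family_clusters: List[Cluster]
    sotu_to_gotu: Dict[str, str]
    gotu_to_fotu: Dict[str, str]

    def counts(self) -> Dict[str, int]:
        return {
            "species": len(self.species_clusters),
            "genus": len(self.genus_clusters),
            "family": len(self.family_clusters),
        }

    def to_json(self) -> dict:
        def dump(clusters):
            return [
                {
                    "centroid_id": c.centroid_id,
                    "member_ids": list(c.member_ids),
                    "level": c.level,
                    "total_abundance": c.total_abundance,
                    "samples": sorted(c.samples),
                }
                for c in clusters
            ]

        return {
            "species_clusters": dump(self.species_clusters),
            "genus_clusters": dump(self.genus_clusters),
            "family_clusters": dump(self.family_clusters),
            "sotu_to_gotu": self.sotu_to_gotu,
            "gotu_to_fotu": self.gotu_to_fotu,
        }

    @classmethod
    def from_json(cls, data: dict) -> "TieredClusterSet":
        def load(items):
            return [
                Cluster(
                    d["centroid_id"],
                    list(d["member_ids"]),
                    d["level"],
                    d["total_abundance"],
                    frozenset(d["samples"]),
                )
                for d in items
            ]

        return cls(
            load(data["species_clusters"]),
            load(data["genus_clusters"]),
            load(data["family_clusters"]),
            dict(data["sotu_to_gotu"]),
            dict(data["gotu_to_fotu"]),
        )


def _ordered(records: Iterable[SeqRecord]) -> List[SeqRecord]:
    return sorted(records, key=lambda r: (-r.abundance, -len(r.sequence), r.id))


def greedy_cluster(
    records: Iterable[SeqRecord],
    threshold_pct: float,
    level: str = "species",
    match: str = "first",
) -> List[Cluster]:
    """Greedy centroid clustering at one identity threshold.

    ``match="first"`` joins the first centroid at >= threshold (the greedy
    convention of the cited tools); ``match="best"`` joins the highest-identity
    centroid above threshold.  The internal (abundance desc, length desc,
    id asc) sort makes the partition invariant to input order.
    """
    if match not in ("first", "best"):
        raise ValueError("match must be 'first' or 'best'")
    centroids: List[SeqRecord] = []
    members: List[List[SeqRecord]] = []
    for rec in _ordered(records):
        chosen: Optional[int] = None
        best_pct = -1.0
        for idx, cen in enumerate(centroids):
            pct = pairwise_identity(rec.sequence, cen.sequence).identity_pct
            if pct >= threshold_pct:
                if match == "first":
                    chosen = idx
                    break
                if pct > best_pct:
                    chosen, best_pct = idx, pct
        if chosen is None:
            centroids.append(rec)
            members.append([rec])
        else:
            members[chosen].append(rec)
    out = []
    for cen, mem in zip(centroids, members):
        samples = frozenset().union(*(m.samples for m in mem))
        out.append(
            Cluster(
                centroid_id=cen.id,
                member_ids=[m.id for m in mem],
                level=level,
                total_abundance=sum(m.abundance for m in mem),
                samples=samples,
            )
        )
    return out


def _centroid_records(
    clusters: Sequence[Cluster], by_id: Mapping[str, SeqRecord]
) -> List[SeqRecord]:
    """One pseudo-record per cluster: centroid sequence, aggregated provenance."""
    out = []
    for c in clusters:
        counts: Dict[str, int] = {}
        for mid in c.member_ids:
            for sample, n in by_id[mid].sample_counts.items():
                counts[sample] = counts.get(sample, 0) + n
        out.append(
            SeqRecord(
                c.centroid_id,
                by_id[c.centroid_id].sequence,
                counts,
                source=by_id[c.centroid_id].source,
            )
        )
    return out


def tiered_cluster(
    records: Sequence[SeqRecord],
    thresholds: Tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> TieredClusterSet:
    """Species clusters at the first threshold, genus clusters over species
    centroids at the second, family clusters over genus centroids at the third."""
    species_t, genus_t, family_t = thresholds
    by_id = {r.id: r for r in records}
    if len(by_id) != len(records):
        raise ValueError("duplicate record ids")

    species = greedy_cluster(records, species_t, "species")
    sotu_recs = _centroid_records(species, by_id)
    genus = greedy_cluster(sotu_recs, genus_t, "genus")
    gotu_recs = _centroid_records(genus, {r.id: r for r in sotu_recs})
    family = greedy_cluster(gotu_recs, family_t, "family")

    sotu_to_gotu = {
        sid: g.centroid_id for g in genus for sid in g.member_ids
    }
    gotu_to_fotu = {
        gid: f.centroid_id for f in family for gid in f.member_ids
    }
    return TieredClusterSet(species, genus, family, sotu_to_gotu, gotu_to_fotu)


def occupancy_classes(tiered: TieredClusterSet) -> Dict[str, str]:
    """Occupancy class (distinct-sample count 1/2/3/>=4) per species cluster."""
    return {c.centroid_id: c.occupancy for c in tiered.species_clusters}


def remove_singletons(
    tiered: TieredClusterSet,
) -> Tuple[Dict[str, int], Dict[str, int]]:
    """Cluster counts before and after deleting single-OTU single-sample SOTUs.

    A species cluster is removed when it holds exactly one member record
    coming from exactly one sample; genus and family clusters emptied by the
    deletion disappear with it.
    """
    with_counts = tiered.counts()
    removed = {
        c.centroid_id
        for c in tiered.species_clusters
        if len(c.member_ids) == 1 and len(c.samples) == 1
    }
    surviving_sotus = [
        c for c in tiered.species_clusters if c.centroid_id not in removed
    ]
    surviving_gotus = {
        tiered.sotu_to_gotu[c.centroid_id] for c in surviving_sotus
    }
    surviving_fotus = {tiered.gotu_to_fotu[g] for g in surviving_gotus}
    without_counts = {
        "species": len(surviving_sotus),
        "genus": len(surviving_gotus),
        "family": len(surviving_fotus),
    }
    return with_counts, without_counts
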