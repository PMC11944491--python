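"""Aligned-region extraction, minimum-information filtering, dereplication.

This is the funnel from aligned OTUs to the analysis-ready sequence set:
cut a fixed window of alignment columns out of every record, drop records
carrying too few bases inside the window, and collapse exact duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Tuple

from .io_formats import GAP_CHARS, AlignedSeqRecord, SeqRecord


@dataclass(frozen=True)
class RegionSpec:
    """A window of alignment columns, 1-based inclusive.

    Defaults correspond to the V4/V5-spanning common region of the 16S gene
    in SILVA/SINA coordinates, with the information floor set to the number
    of E. coli bases falling inside that window (244).
    """

    start_col: int = 10300
    end_col: int = 25300
    min_informative_bases: int = 244

    def __post_init__(self):
        if not (1 <= self.start_col <= self.end_col):
            raise ValueError("require 1 <= start_col <= end_col")
        if self.min_informative_bases < 1:
            raise ValueError("min_informative_bases must be >= 1")

    def _check(self, rec: AlignedSeqRecord) -> None:
        if self.end_col > rec.alignment_length:
            raise ValueError(
                f"region {self.start_col}:{self.end_col} outside alignment "
                f"of length {rec.alignment_length} (record {rec.id!r})"
            )

    def columns(self, rec: AlignedSeqRecord) -> str:
        self._check(rec)
        return rec.aligned[self.start_col - 1 : self.end_col]


def extract_region(rec: AlignedSeqRecord, spec: RegionSpec, **seqrecord_kwargs) -> SeqRecord:
    """Ungapped subsequence of the window columns; provenance carried through."""
    sub = "".join(c for c in spec.columns(rec) if c not in GAP_CHARS)
    return SeqRecord(rec.id, sub, **seqrecord_kwargs)


def count_informative(rec: AlignedSeqRecord, spec: RegionSpec) -> int:
    """Number of non-gap characters inside the window (ambiguity codes count)."""
    return sum(1 for c in spec.columns(rec) if c not in GAP_CHARS)


def filter_by_information(
    records: Iterable[AlignedSeqRecord], spec: RegionSpec
) -> Tuple[List[AlignedSeqRecord], List[AlignedSeqRecord]]:
    """Partition records into (kept, discarded) by the >= min-bases rule."""
    kept, discarded = [], []
    for rec in records:
        (kept if count_informative(rec, spec) >= spec.min_informative_bases
         else discarded).append(rec)
    return kept, discarded


def dereplicate(records: Iterable[SeqRecord]) -> List[SeqRecord]:
    """Collapse records with byte-identical sequences.

    The surviving record takes the id of the highest-abundance member (ties:
    lexicographically smallest id), the per-sample counts are summed, and the
    output keeps first-seen sequence order.
    """
    groups: Dict[str, List[SeqRecord]] = {}
    for rec in records:
        groups.setdefault(rec.sequence, []).append(rec)
    out = []
    for seq, members in groups.items():
        rep = min(members, key=lambda r: (-r.abundance, r.id))
        counts: Dict[str, int] = {}
        for m in members:
            for sample, c in m.sample_counts.items():
                counts[sample] = counts.get(sample, 0) + c
        out.append(replace(rep, sample_counts=counts))
    return out
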