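"""Percent identity between sequences, best-hit search against a reference
database, and the reference-replacement / reference-appending rules.

The identity dialect is fixed package-wide: overlap (semi-global) alignment
with terminal gaps free, scored match +1 / mismatch -1 / gap -1, identity =
matched columns / interior alignment columns.  Amplicon sets mix partially
overlapping gene regions, so terminal overhangs carry no signal and are
excluded.  IUPAC ambiguity codes match only on exact symbol equality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from ._align import encode, overlap_align
from .io_formats import SeqRecord, TaxonomyLabel
from .region_prep import dereplicate

#: (species, genus, family) identity thresholds in percent.
DEFAULT_THRESHOLDS = (97.0, 93.0, 89.0)

#: Reference-replacement threshold (strict >).
DEFAULT_REPLACE_THRESHOLD = 98.0


@dataclass(frozen=True)
class IdentityResult:
    identity_pct: float
    matches: int
    scored_columns: int


@dataclass
class ReferenceDB:
    """Taxonomically labeled, gap-free reference sequences."""

    records: List[SeqRecord]
    taxonomy: Dict[str, TaxonomyLabel]

    def __post_init__(self):
        missing = [r.id for r in self.records if r.id not in self.taxonomy]
        if missing:
            raise ValueError(f"references without taxonomy: {missing[:5]}")

    def __len__(self):
        return len(self.records)


def pairwise_identity(a: str, b: str) -> IdentityResult:
    """Percent identity of the best overlap alignment of two DNA strings.

    Among equal-score alignments the one maximising matched columns is
    reported; identity(a, b) == identity(b, a) holds exactly.  Two strings
    with no positively scoring overlap get identity 0 over 0 columns.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    _, matches, columns = overlap_align(encode(a), encode(b))
    pct = 100.0 * matches / columns if columns else 0.0
    return IdentityResult(pct, matches, columns)


def best_hit(
    query: SeqRecord, db: ReferenceDB
) -> Optional[Tuple[str, IdentityResult]]:
    """Reference maximising identity to the query; ties -> smallest ref id."""
    if not db.records:
        return None
    best: Optional[Tuple[str, IdentityResult]] = None
    for ref in db.records:
        res = pairwise_identity(query.sequence, ref.sequence)
        if (
            best is None
            or res.identity_pct > best[1].identity_pct
            or (res.identity_pct == best[1].identity_pct and ref.id < best[0])
        ):
            best = (ref.id, res)
    return best


def replace_by_reference(
    records: Iterable[SeqRecord],
    db: ReferenceDB,
    threshold_pct: float = DEFAULT_REPLACE_THRESHOLD,
) -> Tuple[List[SeqRecord], List[Tuple[str, str, float]]]:
    """Swap each record's sequence for its best reference hit when identity
    is strictly above ``threshold_pct``.

    Provenance is retained and the record stays an amplicon record; records
    replaced by the same reference collapse into one via dereplication.
    Returns (records', log of (otu id, ref id, identity)).
    """
    out, log = [], []
    for rec in records:
        hit = best_hit(rec, db)
        if hit is not None and hit[1].identity_pct > threshold_pct:
            ref_id, res = hit
            ref_seq = next(r.sequence for r in db.records if r.id == ref_id)
            out.append(rec.with_sequence(ref_seq))
            log.append((rec.id, ref_id, res.identity_pct))
        else:
            out.append(rec)
    return dereplicate(out), log


def append_unmatched_refs(
    records: Sequence[SeqRecord],
    db: ReferenceDB,
    threshold_pct: float = DEFAULT_REPLACE_THRESHOLD,
) -> List[SeqRecord]:
    """Append every reference no dataset record matches above the threshold.

    Appended records represent biodiversity absent from the amplicon set;
    they carry abundance 1 under the pseudo-sample "refdb".
    """
    out = list(records)
    for ref in db.records:
        matched = any(
            pairwise_identity(rec.sequence, ref.sequence).identity_pct
            > threshold_pct
            for rec in records
        )
        if not matched:
            out.append(
                SeqRecord(
                    ref.id,
                    ref.sequence,
                    {"refdb": 1},
                    source="appended_reference",
                )
            )
    return out


def assign_taxonomy(
    query: SeqRecord,
    db: ReferenceDB,
    thresholds: Tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> TaxonomyLabel:
    """Copy the best hit's taxonomy, truncated by the identity achieved.

    >= species threshold keeps the full path, >= genus threshold keeps it
    through genus, >= family threshold through family; anything lower keeps
    only the domain.
    """
    hit = best_hit(query, db)
    if hit is None:
        raise ValueError("assign_taxonomy requires a non-empty reference db")
    ref_id, res = hit
    label = db.taxonomy[ref_id]
    species_t, genus_t, family_t = thresholds
    if res.identity_pct >= species_t:
        return label
    if res.identity_pct >= genus_t:
        return label.truncated("genus")
    if res.identity_pct >= family_t:
        return label.truncated("family")
    return label.truncated("domain")
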