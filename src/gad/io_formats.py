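"""Readers and writers for every external representation the pipeline touches.

Sequences travel as :class:`SeqRecord` (gap-free, uppercase, T not U) or
:class:`AlignedSeqRecord` (gap characters preserved).  Tabular inputs
(per-OTU provenance, sample metadata) are TSV; computed reports are JSON.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

logger = logging.getLogger("gad")

#: Closed environment vocabulary; unknown labels are mapped to "other".
ENVIRONMENTS = ("host", "plant", "soil", "freshwater", "saline_water", "other")

#: Taxonomic ranks, highest first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

GAP_CHARS = frozenset("-.")
_IUPAC = frozenset("ACGTRYSWKMBDHVN")

_SIZE_RE = re.compile(r";size=(\d+);?$")


class ParseError(ValueError):
    """Raised for malformed input files; the message names the offending record."""


@dataclass(frozen=True)
class SeqRecord:
    """One OTU (or reference) sequence with its provenance.

    ``sample_counts`` maps sample id -> read count in that sample; ``samples``
    and ``abundance`` derive from it.  Records read from bare FASTA (no
    provenance) use their own id as a placeholder sample.
    """

    id: str
    sequence: str
    sample_counts: Mapping[str, int] = field(default_factory=dict)
    source: str = "amplicon"  # amplicon | reference | appended_reference

    def __post_init__(self):
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _IUPAC
        if bad:
            raise ParseError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )
        if not self.sample_counts:
            object.__setattr__(self, "sample_counts", {self.id: 1})
        if any(c < 1 for c in self.sample_counts.values()):
            raise ParseError(f"record {self.id!r}: non-positive sample count")

    @property
    def samples(self) -> frozenset:
        return frozenset(self.sample_counts)

    @property
    def abundance(self) -> int:
        return sum(self.sample_counts.values())

    def with_sequence(self, sequence: str) -> "SeqRecord":
        return replace(self, sequence=sequence)


@dataclass(frozen=True)
class AlignedSeqRecord:
    """A sequence with alignment gap columns ('-' or '.') preserved."""

    id: str
    aligned: str

    @property
    def alignment_length(self) -> int:
        return len(self.aligned)

    def ungapped(self) -> str:
        return "".join(c for c in self.aligned if c not in GAP_CHARS)


@dataclass(frozen=True)
class TaxonomyLabel:
    """Seven-rank taxonomy path; unknown ranks are "UNK"+RANKNAME.

    The unknown-rank convention is hierarchical: once a rank is unknown every
    rank below it is unknown too.
    """

    domain: str
    phylum: str
    klass: str
    order: str
    family: str
    genus: str
    species: str

    def __post_init__(self):
        seen_unk = False
        for rank in RANKS:
            value = self.rank(rank)
            if seen_unk and not value.startswith("UNK"):
                raise ValueError(
                    f"rank {rank}={value!r} known below an unknown rank"
                )
            if value.startswith("UNK"):
                seen_unk = True

    def rank(self, name: str) -> str:
        return getattr(self, "klass" if name == "class" else name)

    @classmethod
    def from_ranks(cls, ranks: Mapping[str, str]) -> "TaxonomyLabel":
        vals = {}
        for r in RANKS:
            key = "klass" if r == "class" else r
            vals[key] = ranks.get(r) or "UNK" + r.upper()
        return cls(**vals)

    def truncated(self, depth: str) -> "TaxonomyLabel":
        """Copy with every rank below ``depth`` replaced by its UNK label."""
        cut = RANKS.index(depth)
        return TaxonomyLabel.from_ranks(
            {r: self.rank(r) for r in RANKS[: cut + 1]}
        )

    def as_list(self) -> List[str]:
        return [self.rank(r) for r in RANKS]


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path, size_annotations: bool = False) -> List[SeqRecord]:
    """Read gap-free FASTA into SeqRecords.

    With ``size_annotations``, headers of the USEARCH/VSEARCH dialect
    ``id;size=N`` set the record abundance to N; otherwise abundance is 1.
    Lowercase is uppercased and U mapped to T at read time.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid, abundance = rec.id, 1
        if size_annotations and ";" in rid:
            m = _SIZE_RE.search(rid)
            if not m:
                raise ParseError(f"record {rid!r}: malformed ;size= annotation")
            abundance = int(m.group(1))
            rid = rid[: m.start()]
        seq = _normalize(str(rec.seq))
        if not seq:
            raise ParseError(f"record {rid!r}: empty sequence")
        records.append(SeqRecord(rid, seq, {rid: abundance}))
    return records


def write_fasta(records: Iterable[SeqRecord], path, size_annotations: bool = False) -> None:
    bio = []
    for r in records:
        rid = f"{r.id};size={r.abundance}" if size_annotations else r.id
        bio.append(BioSeqRecord(Seq(r.sequence), id=rid, description=""))
    SeqIO.write(bio, str(path), "fasta")


def read_aligned_fasta(path) -> List[AlignedSeqRecord]:
    """Read an alignment; all records must share one alignment length."""
    records = []
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        aligned = _normalize(str(rec.seq))
        if length is None:
            length = len(aligned)
        elif len(aligned) != length:
            raise ParseError(
                f"record {rec.id!r}: aligned length {len(aligned)} != {length}"
            )
        records.append(AlignedSeqRecord(rec.id, aligned))
    return records


def write_aligned_fasta(records: Iterable[AlignedSeqRecord], path) -> None:
    bio = [BioSeqRecord(Seq(r.aligned), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_provenance_table(path) -> Dict[str, Dict[str, int]]:
    """TSV with header otu_id, sample_id, count -> {otu: {sample: count}}.

    Duplicate (otu, sample) rows are summed; zero/negative counts are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"otu_id": str, "sample_id": str})
    missing = {"otu_id", "sample_id", "count"} - set(df.columns)
    if missing:
        raise ParseError(f"provenance table missing columns {sorted(missing)}")
    if (df["count"] <= 0).any():
        row = df[df["count"] <= 0].iloc[0]
        raise ParseError(
            f"provenance row ({row['otu_id']},{row['sample_id']}): "
            f"non-positive count {row['count']}"
        )
    out: Dict[str, Dict[str, int]] = {}
    grouped = df.groupby(["otu_id", "sample_id"], sort=False)["count"].sum()
    for (otu, sample), count in grouped.items():
        out.setdefault(otu, {})[sample] = int(count)
    return out


def write_provenance_table(prov: Mapping[str, Mapping[str, int]], path) -> None:
    rows = [
        (otu, sample, count)
        for otu, per_sample in prov.items()
        for sample, count in per_sample.items()
    ]
    pd.DataFrame(rows, columns=["otu_id", "sample_id", "count"]).to_csv(
        path, sep="\t", index=False
    )


def attach_provenance(
    records: Iterable[SeqRecord], prov: Mapping[str, Mapping[str, int]]
) -> List[SeqRecord]:
    """Replace each record's placeholder provenance by the table's entry."""
    out = []
    for r in records:
        if r.id in prov:
            out.append(replace(r, sample_counts=dict(prov[r.id])))
        else:
            out.append(r)
    return out


def read_sample_metadata(path) -> Dict[str, str]:
    """TSV with header sample_id, environment -> {sample: environment}.

    Labels outside the closed vocabulary are mapped to "other" with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "environment"} - set(df.columns)
    if missing:
        raise ParseError(f"sample metadata missing columns {sorted(missing)}")
    meta = {}
    for _, row in df.iterrows():
        env = row["environment"]
        if env not in ENVIRONMENTS:
            logger.warning(
                "sample %s: unknown environment %r mapped to 'other'",
                row["sample_id"], env,
            )
            env = "other"
        meta[row["sample_id"]] = env
    return meta


def write_sample_metadata(meta: Mapping[str, str], path) -> None:
    pd.DataFrame(
        sorted(meta.items()), columns=["sample_id", "environment"]
    ).to_csv(path, sep="\t", index=False)


def read_taxonomy_table(path) -> Dict[str, TaxonomyLabel]:
    """TSV with header id, domain..species -> {id: TaxonomyLabel}."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = {}
    for _, row in df.iterrows():
        out[row["id"]] = TaxonomyLabel.from_ranks(
            {r: row.get(r, "") for r in RANKS}
        )
    return out


def write_taxonomy_table(taxonomy: Mapping[str, TaxonomyLabel], path) -> None:
    rows = [[rid] + label.as_list() for rid, label in taxonomy.items()]
    pd.DataFrame(rows, columns=["id"] + list(RANKS)).to_csv(
        path, sep="\t", index=False
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def records_to_json(records: Iterable[SeqRecord]) -> List[dict]:
    return [
        {
            "id": r.id,
            "sequence": r.sequence,
            "sample_counts": dict(r.sample_counts),
            "source": r.source,
        }
        for r in records
    ]


def records_from_json(data: Iterable[dict]) -> List[SeqRecord]:
    return [
        SeqRecord(d["id"], d["sequence"], d["sample_counts"], d["source"])
        for d in data
    ]
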