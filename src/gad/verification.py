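"""Occupancy-stratified verification of SOTU representatives against a
second (metagenome-derived) sequence collection.

Each representative's best-hit identity against the target set is computed
once; a representative counts as matched at cutoff c when that identity is
>= c.  Counts are stratified by the occupancy class of the representative's
species cluster and summed into a Total row.

Percentage formatting deliberately truncates (floors) instead of rounding —
one decimal place below 1%, whole percent otherwise — matching the
convention of the published verification table this module reproduces
(e.g. 61.94% prints as "61%", 0.749% as "0.7%").  Naive rounding gives
different strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

from .clustering import OCCUPANCY_CLASSES
from .io_formats import SeqRecord
from .similarity import pairwise_identity

logger = logging.getLogger("gad")

DEFAULT_CUTOFFS = (99.0, 97.0, 93.0, 89.0)


def format_percent(matched: int, total: int) -> str:
    """Truncated percentage string: one decimal below 1%, else whole percent."""
    if total <= 0:
        raise ValueError("format_percent requires total > 0")
    if not 0 <= matched <= total:
        raise ValueError("require 0 <= matched <= total")
    if matched == 0:
        return "0%"
    # integer arithmetic: no float rounding artifacts near the floor
    whole = matched * 100 // total
    if whole < 1:
        tenths = matched * 1000 // total
        return f"0.{tenths}%"
    return f"{whole}%"


@dataclass
class MatchRow:
    occupancy: str
    total: int
    matched: Dict[float, int]  # cutoff -> matched count

    def percent(self, cutoff: float) -> str:
        return format_percent(self.matched[cutoff], self.total)


@dataclass
class MatchTable:
    cutoffs: List[float]
    rows: Dict[str, MatchRow]  # occupancy class + "Total"

    def to_json(self) -> dict:
        return {
            "cutoffs": list(self.cutoffs),
            "rows": {
                name: {
                    "total": row.total,
                    "matched": {str(c): row.matched[c] for c in self.cutoffs},
                    "percent": {
                        str(c): row.percent(c) if row.total else "-"
                        for c in self.cutoffs
                    },
                }
                for name, row in self.rows.items()
            },
        }

    def to_tsv(self) -> str:
        header = "\t".join(["", "SOTUs"] + [f"{c:g}" for c in self.cutoffs])
        lines = [header]
        for name in list(OCCUPANCY_CLASSES) + ["Total"]:
            row = self.rows[name]
            cells = [name.capitalize() if name != "Total" else name, str(row.total)]
            for c in self.cutoffs:
                pct = row.percent(c) if row.total else "-"
                cells.append(f"{row.matched[c]} ({pct})")
            lines.append("\t".join(cells))
        return "\n".join(lines) + "\n"


def build_match_table(
    totals: Mapping[str, int],
    matched: Mapping[str, Mapping[float, int]],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> MatchTable:
    """Assemble a MatchTable from per-class totals and matched counts,
    deriving the Total row as the column-wise sum."""
    rows: Dict[str, MatchRow] = {}
    for cls in OCCUPANCY_CLASSES:
        rows[cls] = MatchRow(
            cls,
            int(totals.get(cls, 0)),
            {c: int(matched.get(cls, {}).get(c, 0)) for c in cutoffs},
        )
    rows["Total"] = MatchRow(
        "Total",
        sum(rows[cls].total for cls in OCCUPANCY_CLASSES),
        {
            c: sum(rows[cls].matched[c] for cls in OCCUPANCY_CLASSES)
            for c in cutoffs
        },
    )
    return MatchTable(list(cutoffs), rows)


def match_rates(
    sotu_reps: Sequence[SeqRecord],
    occupancy: Mapping[str, str],
    target_db: Sequence[SeqRecord],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> MatchTable:
    """Occupancy-stratified matched counts of representatives at each cutoff.

    Best-hit identity is computed once per representative and thresholds are
    applied afterwards, so monotonicity across decreasing cutoffs holds by
    construction.  An empty target set yields all-zero counts with a warning.
    """
    missing = [r.id for r in sotu_reps if r.id not in occupancy]
    if missing:
        raise ValueError(f"representatives without occupancy class: {missing[:5]}")
    if not target_db:
        logger.warning("empty target database: all matched counts are zero")
    totals: Dict[str, int] = {}
    matched: Dict[str, Dict[float, int]] = {}
    for rep in sotu_reps:
        cls = occupancy[rep.id]
        totals[cls] = totals.get(cls, 0) + 1
        best = 0.0
        for target in target_db:
            pct = pairwise_identity(rep.sequence, target.sequence).identity_pct
            if pct > best:
                best = pct
                if best == 100.0:
                    break
        row = matched.setdefault(cls, {c: 0 for c in cutoffs})
        for c in cutoffs:
            if best >= c:
                row[c] += 1
    return build_match_table(totals, matched, cutoffs)
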