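"""BLAST-hit taxonomy: bit-score filtering, LCA assignment, MAG annotation,
and composition normalization for time-series display.

Hits below a bit score of 100 are discarded (strict ``>``). The remaining
lineages of a query are collapsed to their lowest common ancestor,
optionally restricted to hits within a top-percent window of the best bit
score. A MAG inherits the assignment of its longest member contig.
Composition tables are rescaled to a fixed total (1000 by default,
no-hit bin excluded) with largest-remainder rounding so the total is
conserved exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

DEFAULT_MIN_BITSCORE = 100.0
ROOT_LABEL = "root"

__all__ = [
    "BlastHit",
    "TaxonAssignment",
    "filter_hits",
    "lca_assign",
    "blast_mag_annotation",
    "normalize_composition",
    "read_blast_outfmt6",
    "read_lineage_map",
    "assign_all",
]


@dataclasses.dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    bitscore: float
    lineage: tuple[str, ...] = ()

    @property
    def resolved(self) -> bool:
        return len(self.lineage) > 0


@dataclasses.dataclass(frozen=True)
class TaxonAssignment:
    query_id: str
    lineage: tuple[str, ...]
    status: str  # assigned | no_hit | unresolved

    def __post_init__(self) -> None:
        if self.status == "assigned" and not self.lineage:
            raise ValueError("assigned status requires a non-empty lineage")


def filter_hits(
    hits: Sequence[BlastHit], min_bitscore: float = DEFAULT_MIN_BITSCORE
) -> list[BlastHit]:
    """Keep hits with bitscore strictly greater than the cutoff; stable order."""
    return [h for h in hits if h.bitscore > min_bitscore]


def lca_assign(
    hits_for_query: Sequence[BlastHit],
    top_percent: float | None = 10.0,
    query_id: str | None = None,
) -> TaxonAssignment:
    """Lowest-common-ancestor assignment for one query's (filtered) hits.

    With ``top_percent`` set, only hits whose bitscore is within that
    percentage of the best bitscore participate. The assignment is the
    longest lineage prefix shared by all participating hits; lineages with
    incompatible roots collapse to the synthetic root (still 'assigned').
    Unresolved lineages are ignored; a query with no resolved hit is
    'unresolved', with no hit at all 'no_hit'.
    """
    qid = query_id or (hits_for_query[0].query_id if hits_for_query else "")
    if not hits_for_query:
        return TaxonAssignment(qid, (), "no_hit")
    resolved = [h for h in hits_for_query if h.resolved]
    if not resolved:
        return TaxonAssignment(qid, (), "unresolved")
    if top_percent is not None:
        best = max(h.bitscore for h in resolved)
        floor = (1.0 - top_percent / 100.0) * best
        resolved = [h for h in resolved if h.bitscore >= floor]
    lca = list(resolved[0].lineage)
    for h in resolved[1:]:
        depth = 0
        for a, b in zip(lca, h.lineage):
            if a != b:
                break
            depth += 1
        lca = lca[:depth]
        if not lca:
            break
    if not lca:
        return TaxonAssignment(qid, (ROOT_LABEL,), "assigned")
    return TaxonAssignment(qid, tuple(lca), "assigned")


def blast_mag_annotation(
    longest_contig_id: str, per_contig: Mapping[str, TaxonAssignment], mag_id: str = ""
) -> TaxonAssignment:
    """A MAG adopts the assignment of its longest member contig, whatever it is."""
    if longest_contig_id not in per_contig:
        raise ValueError(f"no assignment for longest contig {longest_contig_id!r}")
    src = per_contig[longest_contig_id]
    return TaxonAssignment(mag_id or src.query_id, src.lineage, src.status)


def normalize_composition(
    taxon_counts: Mapping[str, float],
    total: int = 1000,
    exclude_no_hit: bool = True,
    no_hit_label: str = "no_hit",
) -> dict[str, int]:
    """Rescale taxon counts to sum exactly to ``total``.

    The no-hit bin is dropped first when ``exclude_no_hit``. Integerization
    uses largest-remainder rounding (ties broken by lexicographic taxon
    name) so the output conserves ``total`` exactly.
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    counts = dict(taxon_counts)
    if exclude_no_hit:
        counts.pop(no_hit_label, None)
    grand = float(sum(counts.values()))
    if grand <= 0:
        raise ValueError("no non-zero counts to normalize")
    taxa = sorted(counts)
    exact = {t: counts[t] * total / grand for t in taxa}
    floors = {t: int(exact[t]) for t in taxa}
    short = total - sum(floors.values())
    by_remainder = sorted(taxa, key=lambda t: (-(exact[t] - floors[t]), t))
    for t in by_remainder[:short]:
        floors[t] += 1
    return floors


# ---------------------------------------------------------------------------
# I/O and batch driver


def read_blast_outfmt6(path: str | Path) -> pd.DataFrame:
    """Read BLAST -outfmt 6 (12 standard columns, no header)."""
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    return pd.read_csv(path, sep="\t", names=cols, dtype={"qseqid": str, "sseqid": str})


def read_lineage_map(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a subject-id -> semicolon-delimited-lineage TSV (header: sseqid, lineage)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        str(r.sseqid): tuple(x.strip() for x in str(r.lineage).split(";") if x.strip())
        for r in df.itertuples(index=False)
    }


def assign_all(
    blast_table: pd.DataFrame,
    lineage_map: Mapping[str, tuple[str, ...]],
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    top_percent: float | None = 10.0,
) -> list[TaxonAssignment]:
    """Filter + LCA for every query in a BLAST table; one assignment each."""
    hits_by_query: dict[str, list[BlastHit]] = {}
    for row in blast_table.itertuples(index=False):
        hit = BlastHit(
            query_id=str(row.qseqid),
            subject_id=str(row.sseqid),
            bitscore=float(row.bitscore),
            lineage=tuple(lineage_map.get(str(row.sseqid), ())),
        )
        hits_by_query.setdefault(hit.query_id, []).append(hit)
    out = []
    for qid in sorted(hits_by_query):
        kept = filter_hits(hits_by_query[qid], min_bitscore)
        out.append(lca_assign(kept, top_percent=top_percent, query_id=qid))
    return out
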