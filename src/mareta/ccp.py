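"""Classification by Clustering with Pfam (CCP).

A reference database stores, per known genome, the counts of each Pfam
domain accession found in its proteome. A query (a MAG's aggregated
domain counts) is assigned the taxonomy of the reference genome whose
count profile has the highest Pearson correlation with the query, the
correlation being computed over the union of accessions present in either
profile (absent accessions contribute zero). Queries carrying fewer than
``min_domains`` domain instances are reported unclassified rather than
matched on noise.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DB_FORMAT_VERSION = 1

SUPERKINGDOMS = {"Viruses", "Bacteria", "Archaea", "Eukaryota"}

__all__ = [
    "PfamProfile",
    "ReferenceEntry",
    "CCPAssignment",
    "build_reference_db",
    "aggregate_mag_profile",
    "ccp_classify",
    "annotation_agreement",
    "parse_pfam_hits",
    "save_reference_db",
    "load_reference_db",
]


@dataclasses.dataclass(frozen=True)
class PfamProfile:
    """Sparse Pfam accession -> count vector for a genome or a MAG."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.counts.items() if v < 1}
        if bad:
            raise ValueError(f"profile counts must be >= 1: {bad}")

    @property
    def total_domains(self) -> int:
        return int(sum(self.counts.values()))

    def __len__(self) -> int:
        return len(self.counts)


@dataclasses.dataclass(frozen=True)
class ReferenceEntry:
    genome_id: str
    lineage: tuple[str, ...]
    profile: PfamProfile

    def __post_init__(self) -> None:
        if not self.lineage:
            raise ValueError(f"{self.genome_id}: lineage must be non-empty")

    @property
    def superkingdom(self) -> str:
        return self.lineage[0]

    @property
    def zero_domain(self) -> bool:
        return len(self.profile) == 0


@dataclasses.dataclass(frozen=True)
class CCPAssignment:
    mag_id: str
    best_genome_id: str  # "unclassified" when no call could be made
    r_best: float
    lineage: tuple[str, ...]
    n_domains_used: int
    runners_up: tuple[tuple[str, float], ...] = ()

    @property
    def classified(self) -> bool:
        return self.best_genome_id != "unclassified"


def parse_pfam_hits(path: str | Path) -> pd.DataFrame:
    """Parse a Pfam hit table into (seq_id, pfam_accession) rows.

    Accepts either pfam_scan-style whitespace-delimited output (comment
    lines start with '#'; sequence id in column 1, accession in column 6)
    or a simplified two-column TSV with header (seq_id, pfam_accession).
    Only the sequence id and the accession are consumed; the accession
    version suffix (PF00001.21 -> PF00001) is stripped.
    """
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if not header_seen and fields[:2] == ["seq_id", "pfam_accession"]:
                header_seen = True
                continue
            if len(fields) >= 6 and fields[5].startswith("PF"):
                seq_id, acc = fields[0], fields[5]
            elif len(fields) >= 2:
                seq_id, acc = fields[0], fields[1]
            else:
                raise ValueError(f"{path}:{lineno}: malformed Pfam hit row: {line!r}")
            rows.append((seq_id, acc.split(".")[0]))
    return pd.DataFrame(rows, columns=["seq_id", "pfam_accession"])


def _profile_from_accessions(accessions: Iterable[str]) -> PfamProfile:
    counts: dict[str, int] = {}
    for acc in accessions:
        counts[acc] = counts.get(acc, 0) + 1
    return PfamProfile(counts)


def build_reference_db(
    hit_tables: Mapping[str, pd.DataFrame] | Sequence[tuple[str, pd.DataFrame]],
    taxonomy_map: Mapping[str, Sequence[str]],
) -> list[ReferenceEntry]:
    """Build per-genome domain-count profiles.

    ``hit_tables`` maps genome_id -> hit table (or a sequence of
    (genome_id, table) pairs; repeated genome ids have their counts
    summed). Genomes with zero hits are retained (their ``zero_domain``
    flag is set); a genome without a taxonomy entry is an error.
    """
    if isinstance(hit_tables, Mapping):
        pairs = list(hit_tables.items())
    else:
        pairs = list(hit_tables)
    acc_by_genome: dict[str, list[str]] = {}
    for genome_id, table in pairs:
        acc_by_genome.setdefault(genome_id, []).extend(table["pfam_accession"].tolist())
    missing = sorted(set(acc_by_genome) - set(taxonomy_map))
    if missing:
        raise ValueError(f"genomes without taxonomy: {missing}")
    entries = []
    for genome_id in sorted(acc_by_genome):
        entries.append(
            ReferenceEntry(
                genome_id=genome_id,
                lineage=tuple(taxonomy_map[genome_id]),
                profile=_profile_from_accessions(acc_by_genome[genome_id]),
            )
        )
    return entries


def aggregate_mag_profile(
    contig_hits: pd.DataFrame, member_contigs: Iterable[str]
) -> PfamProfile:
    """Sum per-contig Pfam counts over a MAG's member contigs.

    ``contig_hits`` has rows (seq_id, pfam_accession) where seq_id is the
    contig id. Members without hits contribute nothing.
    """
    members = set(member_contigs)
    if not members:
        raise ValueError("MAG has no member contigs")
    sub = contig_hits.loc[contig_hits["seq_id"].isin(members)]
    return _profile_from_accessions(sub["pfam_accession"].tolist())


def _union_correlation(q: Mapping[str, int], ref: Mapping[str, int]) -> float:
    """Pearson r over the union of accessions, zeros for absences; NaN if undefined."""
    keys = sorted(set(q) | set(ref))
    if len(keys) < 2:
        return float("nan")
    a = np.array([q.get(k, 0) for k in keys], dtype=float)
    b = np.array([ref.get(k, 0) for k in keys], dtype=float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def ccp_classify(
    query: PfamProfile,
    db: Sequence[ReferenceEntry],
    min_domains: int = 5,
    top_k: int = 3,
    mag_id: str = "",
) -> CCPAssignment:
    """Assign the query the taxonomy of the best-correlated reference.

    Ties at the best r are broken by the larger number of shared domain
    accessions, then by lexicographic genome id. The result is
    "unclassified" when the query holds fewer than ``min_domains`` domain
    instances or no reference yields a defined correlation.
    """
    if not db:
        raise ValueError("reference database is empty")
    n_used = query.total_domains
    if n_used < min_domains:
        return CCPAssignment(mag_id, "unclassified", float("nan"), (), n_used)

    scored = []
    for entry in db:
        r = _union_correlation(query.counts, entry.profile.counts)
        if np.isnan(r):
            continue
        shared = len(set(query.counts) & set(entry.profile.counts))
        scored.append((-r, -shared, entry.genome_id, r, entry))
    if not scored:
        return CCPAssignment(mag_id, "unclassified", float("nan"), (), n_used)
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    best = scored[0][4]
    runners = tuple((t[4].genome_id, t[3]) for t in scored[1 : top_k + 1])
    return CCPAssignment(
        mag_id=mag_id,
        best_genome_id=best.genome_id,
        r_best=scored[0][3],
        lineage=best.lineage,
        n_domains_used=n_used,
        runners_up=runners,
    )


def _rank_label(lineage: Sequence[str], rank: str) -> str | None:
    """Label used for agreement at a rank.

    rank='virus' compares the binary virus-vs-cellular label; an integer
    rank depth d compares lineage[:d]; named ranks map onto depth with
    superkingdom = 1.
    """
    if not lineage:
        return None
    if rank == "virus":
        return "virus" if lineage[0] == "Viruses" else "cellular"
    named = {"superkingdom": 1, "kingdom": 1, "phylum": 2, "class": 3,
             "order": 4, "family": 5, "genus": 6, "species": 7}
    depth = named.get(rank)
    if depth is None:
        raise ValueError(f"unknown rank: {rank}")
    if len(lineage) < depth:
        return None
    return ";".join(lineage[:depth])


def annotation_agreement(
    ccp_assignments: Sequence[CCPAssignment],
    blast_annotations: Sequence[tuple[str, Sequence[str]]],
    rank: str = "superkingdom",
) -> tuple[float, pd.DataFrame]:
    """Fraction of co-annotated MAGs on which CCP and BLAST agree.

    Only MAGs annotated by *both* methods (and resolvable at the
    requested rank) enter the denominator. Returns (agreement fraction,
    contingency table of CCP label x BLAST label counts).
    """
    ccp_by_mag = {
        a.mag_id: _rank_label(a.lineage, rank) for a in ccp_assignments if a.classified
    }
    blast_by_mag = {
        mag_id: _rank_label(tuple(lineage), rank)
        for mag_id, lineage in blast_annotations
        if lineage
    }
    shared = [
        m
        for m in sorted(set(ccp_by_mag) & set(blast_by_mag))
        if ccp_by_mag[m] is not None and blast_by_mag[m] is not None
    ]
    if not shared:
        raise ValueError("no co-annotated MAGs to compare")
    pairs = [(ccp_by_mag[m], blast_by_mag[m]) for m in shared]
    agreement = sum(c == b for c, b in pairs) / len(pairs)
    table = (
        pd.DataFrame(pairs, columns=["ccp", "blast"])
        .groupby(["ccp", "blast"])
        .size()
        .unstack(fill_value=0)
    )
    return agreement, table


# ---------------------------------------------------------------------------
# Database serialization: one JSON document, versioned, reloadable
# bit-identically (keys sorted, counts as plain ints).


def save_reference_db(db: Sequence[ReferenceEntry], path: str | Path) -> None:
    doc = {
        "format_version": DB_FORMAT_VERSION,
        "genomes": [
            {
                "genome_id": e.genome_id,
                "lineage": list(e.lineage),
                "profile": {k: int(v) for k, v in sorted(e.profile.counts.items())},
            }
            for e in sorted(db, key=lambda e: e.genome_id)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_reference_db(path: str | Path) -> list[ReferenceEntry]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != DB_FORMAT_VERSION:
        raise ValueError(f"unsupported database format: {doc.get('format_version')}")
    return [
        ReferenceEntry(
            genome_id=g["genome_id"],
            lineage=tuple(g["lineage"]),
            profile=PfamProfile(g["profile"]),
        )
        for g in doc["genomes"]
    ]
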