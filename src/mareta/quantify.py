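"""Per-contig abundance quantification in copies per liter of seawater.

Mapped-read counts are converted to absolute molecule counts with the
relation

    copies/L = m_DNA * (n_mapped / n_total) * N_A / (616 * L_bp) / V

where ``m_DNA`` is the total extracted DNA mass of the sample in grams,
``n_mapped / n_total`` the fraction of the sample's reads mapping to the
target at high identity, ``N_A`` Avogadro's number, 616 g/mol the average
molar mass of a DNA base pair, ``L_bp`` the target length in base pairs,
and ``V`` the filtered water volume in liters. The quantity is applied
per contig here and re-applied per MAG (summed member length) downstream.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AVOGADRO = 6.02e23
"""Avogadro's number as used in the quantification formula (molecules/mol)."""

BP_MOLAR_MASS_G = 616.0
"""Average molar mass of one double-stranded DNA base pair (g/mol)."""

DEFAULT_MIN_IDENTITY = 0.90

__all__ = [
    "AVOGADRO",
    "BP_MOLAR_MASS_G",
    "DEFAULT_MIN_IDENTITY",
    "SampleMeta",
    "ContigRecord",
    "filter_alignments",
    "copies_per_liter",
    "build_abundance_matrix",
    "read_sample_metadata",
    "read_contigs",
    "read_alignment_tsv",
    "read_alignment_sam",
    "write_abundance_matrix",
]


@dataclasses.dataclass(frozen=True)
class SampleMeta:
    """Metadata of one sequenced water sample.

    ``total_dna_g`` is the total extracted DNA mass in grams (whether this
    is per sample or per filter fraction is a property of the study design;
    it is a required input, not inferred). ``depth_layer`` is typically
    ``SUF`` (surface) or ``SCM`` (subsurface chlorophyll maximum), and
    ``filter_fraction`` a size window such as ``0.2-0.8``.
    """

    sample_id: str
    station: str
    date: _dt.date
    depth_layer: str
    filter_fraction: str
    water_volume_L: float
    total_dna_g: float
    total_reads: int

    def __post_init__(self) -> None:
        if self.water_volume_L <= 0:
            raise ValueError(f"sample {self.sample_id}: water_volume_L must be > 0")
        if self.total_dna_g <= 0:
            raise ValueError(f"sample {self.sample_id}: total_dna_g must be > 0")
        if self.total_reads < 1:
            raise ValueError(f"sample {self.sample_id}: total_reads must be >= 1")


@dataclasses.dataclass(frozen=True)
class ContigRecord:
    contig_id: str
    length_bp: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"contig {self.contig_id}: length_bp must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length_bp:
            raise ValueError(
                f"contig {self.contig_id}: sequence length {len(self.sequence)} "
                f"!= length_bp {self.length_bp}"
            )


def filter_alignments(
    alignments: pd.DataFrame,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    known_contigs: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Count reads per (contig, sample) above an identity cutoff.

    Parameters
    ----------
    alignments
        One row per aligned read with columns ``contig_id``, ``sample_id``
        and ``identity`` (fraction in [0, 1]).
    min_identity
        Strict lower bound: a read counts iff its identity is *greater
        than* this value. The default 0.90 mirrors the ">90% homology"
        extraction rule.
    known_contigs
        Optional universe of valid contig ids; an alignment to an unknown
        contig raises ``ValueError``.

    Returns
    -------
    DataFrame with columns ``contig_id``, ``sample_id``, ``mapped_reads``,
    sorted by (contig_id, sample_id).
    """
    required = {"contig_id", "sample_id", "identity"}
    missing = required - set(alignments.columns)
    if missing:
        raise ValueError(f"alignment table missing columns: {sorted(missing)}")
    ident = alignments["identity"].to_numpy(dtype=float)
    if len(ident) and (np.nanmin(ident) < 0 or np.nanmax(ident) > 1):
        bad = alignments.loc[(ident < 0) | (ident > 1)]
        raise ValueError(
            f"identity values outside [0,1] in {len(bad)} records "
            f"(first: {bad.iloc[0].to_dict() if len(bad) else None})"
        )
    if known_contigs is not None:
        known = set(known_contigs)
        unknown = set(alignments["contig_id"]) - known
        if unknown:
            raise ValueError(f"unknown contig ids in alignments: {sorted(unknown)[:10]}")
    kept = alignments.loc[ident > min_identity]
    counts = (
        kept.groupby(["contig_id", "sample_id"], sort=True)
        .size()
        .rename("mapped_reads")
        .reset_index()
    )
    return counts


def copies_per_liter(
    total_dna_g: float,
    mapped_reads: int,
    total_reads: int,
    target_length_bp: int,
    water_volume_L: float,
    bp_molar_mass_g: float = BP_MOLAR_MASS_G,
) -> float:
    """Absolute abundance of a target sequence in copies per liter.

    Linear in ``total_dna_g`` and in ``mapped_reads``; inversely
    proportional to ``water_volume_L`` and to ``target_length_bp``.
    """
    if target_length_bp <= 0:
        raise ValueError("target_length_bp must be > 0")
    if water_volume_L <= 0:
        raise ValueError("water_volume_L must be > 0")
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if mapped_reads < 0:
        raise ValueError("mapped_reads must be >= 0")
    if mapped_reads > total_reads:
        raise ValueError("mapped_reads cannot exceed total_reads")
    return (
        total_dna_g
        * (mapped_reads / total_reads)
        * (AVOGADRO / (bp_molar_mass_g * target_length_bp))
        / water_volume_L
    )


def build_abundance_matrix(
    samples: Sequence[SampleMeta],
    contigs: Sequence[ContigRecord],
    counts: pd.DataFrame,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Assemble the contig x sample copies-per-liter matrix.

    ``counts`` is a mapped-read count table as produced by
    :func:`filter_alignments`. If ``top_n`` is given, contigs are ranked
    by total mapped reads across samples (ties broken by lexicographic
    contig id) and only the top ``top_n`` are kept — the same device the
    study used to cap its contig set at the 5 million most-hit contigs.

    Rows are ordered by rank (total mapped reads descending, then id);
    columns by sample date then sample id.
    """
    if top_n is not None and top_n < 1:
        raise ValueError("top_n must be >= 1")
    sample_by_id = {s.sample_id: s for s in samples}
    if len(sample_by_id) != len(samples):
        raise ValueError("duplicate sample_id in metadata")
    contig_by_id = {c.contig_id: c for c in contigs}
    if len(contig_by_id) != len(contigs):
        raise ValueError("duplicate contig_id")

    missing_samples = sorted(set(counts["sample_id"]) - set(sample_by_id))
    if missing_samples:
        raise ValueError(f"samples in counts without metadata: {missing_samples}")
    missing_contigs = sorted(set(counts["contig_id"]) - set(contig_by_id))
    if missing_contigs:
        raise ValueError(f"contigs in counts without records: {missing_contigs[:10]}")

    wide = (
        counts.pivot_table(
            index="contig_id",
            columns="sample_id",
            values="mapped_reads",
            aggfunc="sum",
            fill_value=0,
        )
        .reindex(index=sorted(contig_by_id), columns=sorted(sample_by_id))
        .fillna(0)
        .astype(np.int64)
    )
    totals = wide.sum(axis=1)
    # rank: total mapped reads descending, contig_id ascending
    order = sorted(wide.index, key=lambda cid: (-totals[cid], cid))
    if top_n is not None:
        order = order[:top_n]
    wide = wide.loc[order]

    sample_order = sorted(sample_by_id, key=lambda sid: (sample_by_id[sid].date, sid))
    wide = wide[sample_order]

    lengths = np.array([contig_by_id[cid].length_bp for cid in wide.index], dtype=float)
    dna = np.array([sample_by_id[sid].total_dna_g for sid in sample_order])
    nreads = np.array([sample_by_id[sid].total_reads for sid in sample_order], dtype=float)
    vol = np.array([sample_by_id[sid].water_volume_L for sid in sample_order])

    per_sample = dna / nreads / vol  # grams per read per liter
    values = (
        wide.to_numpy(dtype=float)
        * per_sample[np.newaxis, :]
        * (AVOGADRO / (BP_MOLAR_MASS_G * lengths))[:, np.newaxis]
    )
    return pd.DataFrame(values, index=wide.index, columns=wide.columns)


# ---------------------------------------------------------------------------
# I/O


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata TSV.

    Expected header: sample_id, station, date (ISO-8601), depth_layer,
    filter_fraction, water_volume_L, total_dna_ng, total_reads. DNA mass
    is given in nanograms on disk (the natural bench unit) and converted
    to grams here.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "station": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                station=str(row.station),
                date=_dt.date.fromisoformat(str(row.date)),
                depth_layer=str(row.depth_layer),
                filter_fraction=str(row.filter_fraction),
                water_volume_L=float(row.water_volume_L),
                total_dna_g=float(row.total_dna_ng) * 1e-9,
                total_reads=int(row.total_reads),
            )
        )
    return out


def read_contigs(path: str | Path) -> list[ContigRecord]:
    """Read contigs from FASTA (.fa/.fasta/.fna) or a TSV (contig_id, length_bp)."""
    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta", ".fna"}:
        return [
            ContigRecord(rec.id, len(rec.seq), str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str})
    return [ContigRecord(str(r.contig_id), int(r.length_bp)) for r in df.itertuples(index=False)]


def read_alignment_tsv(path: str | Path) -> pd.DataFrame:
    """Read a pre-digested alignment TSV (read_id, contig_id, sample_id, identity)."""
    return pd.read_csv(
        path, sep="\t", dtype={"read_id": str, "contig_id": str, "sample_id": str}
    )


def read_alignment_sam(path: str | Path, sample_id: str) -> pd.DataFrame:
    """Extract per-read alignment identities from a SAM file for one sample.

    Identity = matching bases / aligned read bases, computed from the NM
    tag and the CIGAR string (insertions and deletions count as
    mismatches within the alignment). Unmapped and secondary records are
    skipped.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            aligned = aln.query_alignment_length or 0
            if aligned == 0:
                continue
            try:
                nm = aln.get_tag("NM")
            except KeyError:
                nm = 0
            # alignment span counting indels as differences
            span = aligned + sum(l for op, l in (aln.cigartuples or []) if op == 2)
            identity = max(0.0, 1.0 - nm / span) if span else 0.0
            rows.append((aln.query_name, aln.reference_name, sample_id, identity))
    return pd.DataFrame(rows, columns=["read_id", "contig_id", "sample_id", "identity"])


def write_abundance_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="contig_id", float_format="%.6g")
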