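"""Tandem-repeat (microsatellite) scanning of sequencing reads.

Reads are scanned for maximal tandem runs of primitive repeat units of
2-10 bp. Units are grouped by rotation class (TAG/AGT/GTA are the same
repeat) and named by the lexicographically smallest rotation. A read is a
*repeat read* when the bases covered by runs of its best single unit
class strictly exceed 70% of the read length (the >70-of-100-bp rule,
scaled proportionally for other read lengths). Reverse-complement classes
are distinct by default (AGT vs its complement class) and can be merged.

Runs are maximal periodic extensions: a run of period k extends as long
as each base equals the base k positions earlier, so partial trailing
unit copies count in whole bases. Runs containing N are split at the N.
"""

from __future__ import annotations

import dataclasses
import gzip
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

DEFAULT_UNIT_LENGTHS = range(2, 11)
DEFAULT_THRESHOLD_BP_PER_100 = 70
DEFAULT_MIN_COPIES = 2
MAX_N_FRACTION = 0.5

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "RepeatRun",
    "ReadRepeatCall",
    "canonical_rotation",
    "rotation_class",
    "is_primitive",
    "reverse_complement",
    "find_repeat_runs",
    "classify_read",
    "summarize_sample",
    "read_sequences",
    "scan_file",
]


def is_primitive(unit: str) -> bool:
    """True when the unit is not an integer power of a shorter string."""
    k = len(unit)
    for d in range(1, k):
        if k % d == 0 and unit == unit[:d] * (k // d):
            return False
    return True


def canonical_rotation(unit: str) -> str:
    """Lexicographically smallest rotation — the name of the rotation class."""
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def rotation_class(unit: str) -> list[str]:
    """All distinct rotations of a unit, alphabetically (the display alias)."""
    return sorted({unit[i:] + unit[:i] for i in range(len(unit))})


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass(frozen=True)
class RepeatRun:
    """One maximal tandem run: unit is the canonical rotation, [start, end)."""

    unit: str
    start: int
    end: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclasses.dataclass(frozen=True)
class ReadRepeatCall:
    read_id: str
    read_length: int
    best_unit: str | None
    repeat_bases: int
    is_repeat_read: bool
    skipped: bool = False  # >50% N; counted as scanned but never a repeat read


def _segments_without_n(seq: str) -> Iterator[tuple[int, int]]:
    """Maximal [start, end) stretches free of N."""
    start = None
    for i, base in enumerate(seq):
        if base == "N":
            if start is not None:
                yield start, i
                start = None
        elif start is None:
            start = i
    if start is not None:
        yield start, len(seq)


def find_repeat_runs(
    sequence: str,
    unit_lengths: Iterable[int] = DEFAULT_UNIT_LENGTHS,
    min_copies: int = DEFAULT_MIN_COPIES,
) -> list[RepeatRun]:
    """All maximal tandem runs of primitive units in the sequence.

    A run of period k starting at i extends while sequence[j] ==
    sequence[j-k]; it is reported when it spans at least ``min_copies``
    unit copies and its unit is primitive (so (TA)4 is a unit-2 run, never
    a unit-4 one). Each maximal run is reported once, attributed to the
    canonical rotation of its unit.
    """
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    seq = sequence.upper()
    runs: list[RepeatRun] = []
    for seg_start, seg_end in _segments_without_n(seq):
        seg_len = seg_end - seg_start
        for k in unit_lengths:
            if seg_len < min_copies * k:
                continue
            min_extra = (min_copies - 1) * k  # matched positions needed
            i = seg_start
            limit = seg_end - k
            while i < limit:
                if seq[i] != seq[i + k]:
                    i += 1
                    continue
                j = i
                while j < limit and seq[j] == seq[j + k]:
                    j += 1
                # periodic stretch [i, j + k), matched positions j - i
                if j - i >= min_extra and is_primitive(seq[i : i + k]):
                    runs.append(RepeatRun(canonical_rotation(seq[i : i + k]), i, j + k))
                i = j + 1
    runs.sort(key=lambda r: (r.start, r.end, r.unit))
    return runs


def _class_coverage(runs: Sequence[RepeatRun], merge_rc: bool) -> dict[str, int]:
    """Bases covered per rotation class (union of possibly overlapping runs)."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    for run in runs:
        key = run.unit
        if merge_rc:
            key = min(key, canonical_rotation(reverse_complement(key)))
        intervals.setdefault(key, []).append((run.start, run.end))
    coverage = {}
    for key, ivs in intervals.items():
        ivs.sort()
        total = 0
        cur_start, cur_end = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_end:
                total += cur_end - cur_start
                cur_start, cur_end = s, e
            else:
                cur_end = max(cur_end, e)
        total += cur_end - cur_start
        coverage[key] = total
    return coverage


def classify_read(
    read_id: str,
    sequence: str,
    threshold_bp_per_100: float = DEFAULT_THRESHOLD_BP_PER_100,
    unit_lengths: Iterable[int] = DEFAULT_UNIT_LENGTHS,
    min_copies: int = DEFAULT_MIN_COPIES,
    merge_rc: bool = False,
) -> ReadRepeatCall:
    """Classify a read by its single best repeat class.

    repeat_bases = bases covered by runs of the best class;
    is_repeat_read iff repeat_bases > threshold * read_length / 100
    (strict). Ties between classes go to the lexicographically smaller
    canonical unit. Reads with more than 50% N are skipped (still counted
    as scanned downstream).
    """
    seq = sequence.upper()
    n_len = len(seq)
    if n_len == 0 or seq.count("N") > MAX_N_FRACTION * n_len:
        return ReadRepeatCall(read_id, n_len, None, 0, False, skipped=True)
    runs = find_repeat_runs(seq, unit_lengths=unit_lengths, min_copies=min_copies)
    if not runs:
        return ReadRepeatCall(read_id, n_len, None, 0, False)
    coverage = _class_coverage(runs, merge_rc)
    best_unit = min(coverage, key=lambda u: (-coverage[u], u))
    repeat_bases = coverage[best_unit]
    is_repeat = repeat_bases > threshold_bp_per_100 * n_len / 100.0
    return ReadRepeatCall(read_id, n_len, best_unit, repeat_bases, is_repeat)


def summarize_sample(
    calls: Sequence[ReadRepeatCall], sample_id: str
) -> pd.DataFrame:
    """Per-unit-class repeat-read counts and fractions over ALL scanned reads.

    One row per class that has at least one repeat read, ranked by
    fraction descending then class name; columns sample_id, unit_class,
    rotations (display alias), repeat_reads, total_reads, fraction.
    """
    total = len(calls)
    if total == 0:
        raise ValueError(f"sample {sample_id}: zero reads")
    counts: dict[str, int] = {}
    for call in calls:
        if call.is_repeat_read and call.best_unit:
            counts[call.best_unit] = counts.get(call.best_unit, 0) + 1
    ranked = sorted(counts, key=lambda u: (-counts[u] / total, u))
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "unit_class": ranked,
            "rotations": ["/".join(rotation_class(u)) for u in ranked],
            "repeat_reads": [counts[u] for u in ranked],
            "total_reads": total,
            "fraction": [counts[u] / total for u in ranked],
        }
    )


# ---------------------------------------------------------------------------
# I/O


def read_sequences(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from FASTA or FASTQ, gzip-compressed or not."""
    from Bio import SeqIO

    path = Path(path)
    name = path.name.lower()
    opener = gzip.open if name.endswith(".gz") else open
    stem = name[:-3] if name.endswith(".gz") else name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq)


def scan_file(
    path: str | Path,
    sample_id: str,
    threshold_bp_per_100: float = DEFAULT_THRESHOLD_BP_PER_100,
    unit_lengths: Iterable[int] = DEFAULT_UNIT_LENGTHS,
    merge_rc: bool = False,
) -> tuple[list[ReadRepeatCall], pd.DataFrame]:
    """Scan one reads file; returns (per-read calls, per-sample report)."""
    unit_lengths = list(unit_lengths)
    calls = [
        classify_read(
            rid, seq,
            threshold_bp_per_100=threshold_bp_per_100,
            unit_lengths=unit_lengths,
            merge_rc=merge_rc,
        )
        for rid, seq in read_sequences(path)
    ]
    return calls, summarize_sample(calls, sample_id)
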