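"""Digital DNA chip (DDC): in-silico hybridization of reads against
environment-labeled probes.

Each probe carries a label (category, value) such as
(filter_fraction, "0.2-0.8") or (month, "December"). A probe is positive
when at least ``min_hits`` reads contain its sequence (either strand;
optionally within a Hamming mismatch budget). The positive/negative
pattern over all probes is laid out on a near-square grid — the chip —
and a simple majority vote over positive probes per category yields an
environmental inference for the sample.

Probe derivation (how environment-associated sequences are chosen) is
out of scope: probes are an input artifact.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from mareta.repeat_scan import reverse_complement

MIN_PROBE_LENGTH = 20

LABEL_CATEGORIES = (
    "filter_fraction",
    "station",
    "month",
    "temperature_band",
    "salinity_band",
    "nitrate_band",
    "phosphate_band",
)

__all__ = [
    "Probe",
    "ChipResult",
    "digital_hybridize",
    "infer_environment",
    "render_chip",
    "render_chip_ppm",
    "grid_shape",
    "read_probes",
    "write_chip_table",
]


@dataclasses.dataclass(frozen=True)
class Probe:
    probe_id: str
    sequence: str
    label_category: str
    label_value: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) < MIN_PROBE_LENGTH:
            raise ValueError(
                f"probe {self.probe_id}: sequence shorter than {MIN_PROBE_LENGTH} bp"
            )
        if set(seq) - set("ACGT"):
            raise ValueError(f"probe {self.probe_id}: degenerate bases not allowed")
        if not self.label_category or not self.label_value:
            raise ValueError(f"probe {self.probe_id}: empty label")


@dataclasses.dataclass(frozen=True)
class ChipResult:
    probe_ids: tuple[str, ...]
    hit_counts: tuple[int, ...]
    positive: tuple[bool, ...]
    min_hits: int
    layout: tuple[int, int]  # rows, cols

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "hit_count": self.hit_counts,
                "positive": self.positive,
            }
        )


def grid_shape(n_probes: int) -> tuple[int, int]:
    """Smallest near-square (rows, cols) grid holding n probes; cols >= rows.

    748 probes land on 27 x 28 with 8 blank cells.
    """
    if n_probes < 1:
        raise ValueError("need at least one probe")
    cols = math.isqrt(n_probes)
    if cols * cols < n_probes:
        cols += 1
    rows = math.ceil(n_probes / cols)
    return rows, cols


def _hamming_contains(read: str, probe: str, max_mismatches: int) -> bool:
    """True when some window of the read matches the probe with at most
    max_mismatches Hamming mismatches (probe-length windows only)."""
    m = len(probe)
    if m > len(read):
        return False
    if max_mismatches == 0:
        return probe in read
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    p = np.frombuffer(probe.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(r, m)
    return bool((windows != p).sum(axis=1).min() <= max_mismatches)


def digital_hybridize(
    reads: Iterable[tuple[str, str] | str],
    probes: Sequence[Probe],
    min_hits: int = 1,
    max_mismatches: int = 0,
) -> ChipResult:
    """Score every probe against the sample's reads.

    A read hits a probe when it contains the probe sequence or its
    reverse complement (shotgun reads are unstranded). hit_count is the
    number of hitting reads; positive iff hit_count >= min_hits.
    """
    if not probes:
        raise ValueError("empty probe set")
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    seqs = [
        (p.sequence.upper(), reverse_complement(p.sequence.upper())) for p in probes
    ]
    counts = [0] * len(probes)
    for read in reads:
        seq = (read[1] if isinstance(read, tuple) else read).upper()
        for i, (fwd, rev) in enumerate(seqs):
            if _hamming_contains(seq, fwd, max_mismatches) or _hamming_contains(
                seq, rev, max_mismatches
            ):
                counts[i] += 1
    return ChipResult(
        probe_ids=tuple(p.probe_id for p in probes),
        hit_counts=tuple(counts),
        positive=tuple(c >= min_hits for c in counts),
        min_hits=min_hits,
        layout=grid_shape(len(probes)),
    )


def infer_environment(
    chip: ChipResult, probes: Sequence[Probe]
) -> dict[str, list[str] | str]:
    """Majority vote of positive probes within each label category.

    Returns category -> list of winning value(s) (ties keep all, sorted),
    or the string 'undetermined' for categories with no positive probe.
    """
    if len(probes) != len(chip.probe_ids):
        raise ValueError("chip and probe list are inconsistent")
    votes: dict[str, dict[str, int]] = {}
    categories = []
    for probe, pos in zip(probes, chip.positive):
        if probe.label_category not in categories:
            categories.append(probe.label_category)
        if pos:
            cat = votes.setdefault(probe.label_category, {})
            cat[probe.label_value] = cat.get(probe.label_value, 0) + 1
    out: dict[str, list[str] | str] = {}
    for cat in categories:
        if cat not in votes:
            out[cat] = "undetermined"
        else:
            best = max(votes[cat].values())
            out[cat] = sorted(v for v, n in votes[cat].items() if n == best)
    return out


def render_chip(chip: ChipResult) -> str:
    """ASCII chip: '#' positive, '.' negative, ' ' blank (trailing cells)."""
    rows, cols = chip.layout
    cells = ["#" if p else "." for p in chip.positive]
    cells += [" "] * (rows * cols - len(cells))
    return "\n".join(
        "".join(cells[r * cols : (r + 1) * cols]) for r in range(rows)
    )


def render_chip_ppm(chip: ChipResult, cell_px: int = 4) -> str:
    """Plain-text PPM (P3) image of the chip.

    Positive spots are red, negative spots black, blank cells dark gray.
    Each probe cell is a cell_px x cell_px pixel block; output is
    bit-exact for a fixed chip.
    """
    rows, cols = chip.layout
    red, black, gray = (255, 0, 0), (0, 0, 0), (40, 40, 40)
    colors = [red if p else black for p in chip.positive]
    colors += [gray] * (rows * cols - len(colors))
    width, height = cols * cell_px, rows * cell_px
    lines = [f"P3 {width} {height} 255"]
    for r in range(rows):
        row_colors = colors[r * cols : (r + 1) * cols]
        pixel_row = " ".join(
            " ".join(map(str, c)) for c in row_colors for _ in range(cell_px)
        )
        for _ in range(cell_px):
            lines.append(pixel_row)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# I/O


def read_probes(path: str | Path) -> list[Probe]:
    """Read probes from TSV (probe_id, sequence, label_category, label_value)
    or FASTA with structured headers ``probe_id|category|value``."""
    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta", ".fna"}:
        from Bio import SeqIO

        probes = []
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.description.split()[0].split("|")
            if len(parts) != 3:
                raise ValueError(
                    f"probe header must be 'probe_id|category|value': {rec.description!r}"
                )
            probes.append(Probe(parts[0], str(rec.seq).upper(), parts[1], parts[2]))
        return probes
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        Probe(
            str(r.probe_id),
            str(r.sequence).upper(),
            str(r.label_category),
            str(r.label_value),
        )
        for r in df.itertuples(index=False)
    ]


def write_chip_table(chip: ChipResult, path: str | Path) -> None:
    chip.as_frame().to_csv(path, sep="\t", index=False)
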