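"""Seeded synthetic-data generators with known ground truth.

Every downstream stage can be exercised offline: reads with planted
tandem repeats at an exact planted fraction, a monthly community
abundance matrix with planted MAG membership and seasonal archetypes,
and Pfam reference/query profile pairs with a known source genome per
query. All generators are deterministic under a fixed seed
(numpy PCG64 via ``default_rng``).

Default sizes and noise levels mirror the study conditions the suite is
run under: 25 monthly samples spanning just over two years, 10%
coefficient of variation of multiplicative lognormal abundance noise,
binomial domain retention of 0.5 for thinned Pfam queries, and 100-bp
reads with the >70-bp repeat rule.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mareta import repeat_scan
from mareta.ccp import PfamProfile, ReferenceEntry
from mareta.quantify import SampleMeta

ARCHETYPES = ("complete", "incomplete", "transient", "irregular")

_BASES = np.array(list("ACGT"))

__all__ = [
    "ARCHETYPES",
    "FixtureSpec",
    "simulate_repeat_reads",
    "write_fastq",
    "archetype_template",
    "simulate_pattern_series",
    "simulate_community_timeseries",
    "simulate_pfam_profiles",
]


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    """Bundle of generator knobs for the CLI; library callers pass args directly."""

    seed: int = 0
    n_reads: int = 1000
    read_length: int = 100
    repeat_fraction: float = 0.05
    repeat_unit: str = "TAG"
    n_contigs: int = 500
    n_mags: int = 20
    n_samples: int = 25
    abundance_cv: float = 0.10
    n_refs: int = 50
    n_domains: int = 100
    n_queries: int = 200
    retention: float = 0.5
    contamination_rate: float = 0.02


# ---------------------------------------------------------------------------
# Reads with planted tandem repeats


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_repeat_reads(
    n_reads: int = 1000,
    read_length: int = 100,
    repeat_fraction: float = 0.05,
    unit: str = "TAG",
    seed: int = 0,
    threshold_bp_per_100: float = repeat_scan.DEFAULT_THRESHOLD_BP_PER_100,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Reads with an exact planted fraction of repeat reads.

    Exactly ``round(repeat_fraction * n_reads)`` reads carry one tandem
    run of the given unit class covering strictly more than the threshold
    fraction of the read; the rest are uniform random reads re-drawn
    (rejection sampling) until they contain no qualifying run of any
    class, so the planted fraction is exact by construction.

    Returns (reads, truth) where reads is a list of (read_id, sequence)
    and truth a DataFrame (read_id, is_repeat, unit_class).
    """
    if not 0 <= repeat_fraction <= 1:
        raise ValueError("repeat_fraction must be in [0, 1]")
    if not repeat_scan.is_primitive(unit.upper()):
        raise ValueError(f"repeat unit must be primitive: {unit}")
    rng = np.random.default_rng(seed)
    unit = unit.upper()
    k = len(unit)
    canon = repeat_scan.canonical_rotation(unit)
    n_repeat = round(repeat_fraction * n_reads)
    min_run = math.floor(threshold_bp_per_100 * read_length / 100) + 1
    if min_run > read_length:
        raise ValueError("threshold leaves no room for a qualifying run")

    is_repeat = np.zeros(n_reads, dtype=bool)
    is_repeat[rng.permutation(n_reads)[:n_repeat]] = True

    reads: list[tuple[str, str]] = []
    truth_rows = []
    for i in range(n_reads):
        read_id = f"read_{i:06d}"
        if is_repeat[i]:
            run_len = int(rng.integers(min_run, read_length + 1))
            start = int(rng.integers(0, read_length - run_len + 1))
            phase = int(rng.integers(0, k))
            rotated = unit[phase:] + unit[:phase]
            run = (rotated * (run_len // k + 2))[:run_len]
            seq = _random_seq(rng, start) + run + _random_seq(rng, read_length - start - run_len)
            truth_rows.append((read_id, True, canon))
        else:
            while True:
                seq = _random_seq(rng, read_length)
                call = repeat_scan.classify_read(
                    read_id, seq, threshold_bp_per_100=threshold_bp_per_100
                )
                if not call.is_repeat_read:
                    break
            truth_rows.append((read_id, False, ""))
        reads.append((read_id, seq))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "is_repeat", "unit_class"])
    return reads, truth


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write reads as plain FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Seasonal community time series


def archetype_template(
    archetype: str,
    n_months: int,
    phase: int = 3,
    centers: tuple[int, int] | None = None,
) -> np.ndarray:
    """Noise-free monthly abundance template of one seasonal archetype.

    complete: a sharpened 12-month sinusoid (annual bloom recurring every
    year of the span). incomplete: the same bloom with the final year's
    peak suppressed to 5%. transient: a single Gaussian pulse. irregular:
    two pulses whose separation is far from 12 months. ``phase`` is the
    month of the first bloom peak; ``centers`` overrides pulse locations.
    """
    t = np.arange(n_months, dtype=float)
    if archetype in ("complete", "incomplete"):
        bloom = ((1 + np.sin(2 * np.pi * (t - phase + 3) / 12)) / 2) ** 3
        template = 0.05 + bloom
        if archetype == "incomplete":
            last_peak = phase + 12 * ((n_months - 1 - phase) // 12)
            suppress = np.abs(t - last_peak) <= 4
            template = np.where(suppress, 0.05 + 0.05 * bloom, template)
        return template
    if archetype == "transient":
        c = centers[0] if centers else n_months // 2
        return 0.02 + np.exp(-(((t - c) / 1.5) ** 2))
    if archetype == "irregular":
        c1, c2 = centers if centers else (n_months // 4, n_months // 4 + 7)
        return (
            0.02
            + 0.9 * np.exp(-(((t - c1) / 1.5) ** 2))
            + 0.8 * np.exp(-(((t - c2) / 1.5) ** 2))
        )
    raise ValueError(f"unknown archetype: {archetype}")


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1 + cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2, sigma=sigma, size=shape)


def simulate_pattern_series(
    archetype: str,
    n_months: int = 31,
    cv: float = 0.10,
    seed: int = 0,
    start: _dt.date = _dt.date(2012, 3, 15),
) -> tuple[tuple[_dt.date, ...], np.ndarray]:
    """One noisy monthly series of the given archetype (the fixture bank).

    Pulse locations / bloom phase are drawn from ranges that keep the
    archetype realizable within the span (an annual bloom needs its
    repeat peaks inside the sampled window).
    """
    rng = np.random.default_rng(seed)
    max_phase = max(1, n_months - 1 - 24)
    if archetype in ("complete", "incomplete"):
        template = archetype_template(
            archetype, n_months, phase=int(rng.integers(1, max_phase + 1))
        )
    elif archetype == "transient":
        template = archetype_template(
            archetype, n_months, centers=(int(rng.integers(4, n_months - 4)), 0)
        )
    else:
        c1 = int(rng.integers(3, n_months - 11))
        gap = int(rng.choice([5, 6, 7, 8, 16, 17, 18]))
        if c1 + gap > n_months - 3:
            gap = int(rng.choice([5, 6, 7]))
        template = archetype_template(archetype, n_months, centers=(c1, c1 + gap))
    values = template * _lognormal_noise(rng, cv, n_months)
    dates = tuple(
        _dt.date(start.year + (start.month - 1 + m) // 12,
                 (start.month - 1 + m) % 12 + 1, 15)
        for m in range(n_months)
    )
    return dates, values


def simulate_community_timeseries(
    n_contigs: int = 500,
    n_mags: int = 20,
    n_samples: int = 25,
    cv: float = 0.10,
    seed: int = 0,
    start: _dt.date = _dt.date(2012, 3, 15),
    mean_abundance: float = 1e4,
) -> dict:
    """Monthly community abundance matrix with planted MAG structure.

    Each MAG gets a distinct seasonal template (archetypes cycled over
    the four classes; bloom phases drawn without replacement so no two
    sinusoidal MAGs coincide) and each member contig's profile is the
    MAG template scaled by a contig-specific positive factor times
    mean-1 lognormal noise of the stated CV. Contigs are dealt to MAGs
    round-robin so every MAG has members.

    Returns a dict with keys: ``abundance`` (contig x sample DataFrame of
    copies/L), ``samples`` (list of SampleMeta), ``membership``
    (contig_id -> mag label), ``archetypes`` (mag label -> archetype).
    """
    if n_mags > n_contigs:
        raise ValueError("n_mags must be <= n_contigs")
    rng = np.random.default_rng(seed)
    # distinct bloom phases while they last (phase space is 12 months wide)
    n_sinusoid = sum(
        1 for m in range(n_mags) if ARCHETYPES[m % len(ARCHETYPES)] in ("complete", "incomplete")
    )
    phases = np.concatenate([rng.permutation(12) for _ in range(n_sinusoid // 12 + 20)])
    phase_iter = iter(int(p) for p in phases)

    def distinct(candidate: np.ndarray) -> bool:
        # planted patterns must be mutually distinguishable at the
        # clustering radius; 0.90 leaves headroom below the 0.95 threshold
        return all(
            abs(np.corrcoef(candidate, t)[0, 1]) < 0.90 for t in templates.values()
        )

    templates: dict[str, np.ndarray] = {}
    archetypes = {}
    for m in range(n_mags):
        mag = f"TRUE{m:03d}"
        archetype = ARCHETYPES[m % len(ARCHETYPES)]
        archetypes[mag] = archetype
        if archetype in ("complete", "incomplete"):
            for _ in range(200):
                tpl = archetype_template(archetype, n_samples, phase=next(phase_iter))
                if distinct(tpl):
                    break
            else:
                raise RuntimeError("could not place a distinct sinusoid template")
        elif archetype == "transient":
            for _ in range(200):
                c = int(rng.integers(3, n_samples - 3))
                tpl = archetype_template(archetype, n_samples, centers=(c, 0))
                if distinct(tpl):
                    break
            else:
                raise RuntimeError("could not place a distinct transient template")
        else:
            for _ in range(200):
                c1 = int(rng.integers(2, n_samples - 10))
                gap = int(rng.choice([5, 6, 7, 8]))
                tpl = archetype_template(archetype, n_samples, centers=(c1, c1 + gap))
                if distinct(tpl):
                    break
            else:
                raise RuntimeError("could not place a distinct irregular template")
        templates[mag] = tpl

    mags = sorted(templates)
    membership = {}
    rows = []
    contig_ids = []
    for i in range(n_contigs):
        mag = mags[i % n_mags]
        cid = f"contig_{i:05d}"
        membership[cid] = mag
        scale = mean_abundance * rng.lognormal(0, 0.8)
        rows.append(templates[mag] * scale * _lognormal_noise(rng, cv, n_samples))
        contig_ids.append(cid)

    dates = [
        _dt.date(start.year + (start.month - 1 + m) // 12,
                 (start.month - 1 + m) % 12 + 1, 15)
        for m in range(n_samples)
    ]
    samples = [
        SampleMeta(
            sample_id=f"S{j:03d}",
            station="C5",
            date=dates[j],
            depth_layer="SUF",
            filter_fraction="0.2-0.8",
            water_volume_L=4.0,
            total_dna_g=50e-9,
            total_reads=1_000_000,
        )
        for j in range(n_samples)
    ]
    abundance = pd.DataFrame(
        np.vstack(rows), index=contig_ids, columns=[s.sample_id for s in samples]
    )
    return {
        "abundance": abundance,
        "samples": samples,
        "membership": membership,
        "archetypes": archetypes,
    }


# ---------------------------------------------------------------------------
# Pfam reference / query profiles


def simulate_pfam_profiles(
    n_refs: int = 50,
    n_domains: int = 100,
    n_queries: int = 200,
    retention: float = 0.5,
    contamination_rate: float = 0.02,
    seed: int = 0,
) -> tuple[list[ReferenceEntry], list[PfamProfile], list[str]]:
    """Reference genomes with sparse domain-count profiles plus thinned queries.

    Each reference holds counts over a random subset of the domain
    vocabulary (multinomial with Dirichlet weights). Each query binomially
    thins a chosen reference's domain instances at the given retention and
    adds uniform contamination domains at ``contamination_rate`` of the
    retained total. Returns (references, queries, truth genome ids).
    """
    if n_refs < 2 or n_domains < 20:
        raise ValueError("need n_refs >= 2 and n_domains >= 20")
    rng = np.random.default_rng(seed)
    vocab = [f"PF{i + 1:05d}" for i in range(n_domains)]
    kingdoms = ("Viruses", "Bacteria", "Archaea", "Eukaryota")

    refs = []
    for g in range(n_refs):
        n_present = int(rng.integers(20, max(21, n_domains // 2 + 1)))
        present = rng.choice(n_domains, size=n_present, replace=False)
        weights = rng.dirichlet(np.ones(n_present))
        total = int(rng.integers(150, 400))
        counts = rng.multinomial(total, weights)
        profile = {
            vocab[d]: int(c) for d, c in zip(present, counts) if c > 0
        }
        kd = kingdoms[g % 4]
        refs.append(
            ReferenceEntry(
                genome_id=f"G{g:04d}",
                lineage=(kd, f"Phylum{g % 7}", f"Genus{g}", f"Species{g}"),
                profile=PfamProfile(profile),
            )
        )

    queries = []
    truth = []
    for q in range(n_queries):
        src = refs[q % n_refs]
        counts = {}
        for acc, c in src.profile.counts.items():
            kept = int(rng.binomial(c, retention))
            if kept > 0:
                counts[acc] = kept
        n_contam = int(rng.poisson(contamination_rate * max(1, sum(counts.values()))))
        for _ in range(n_contam):
            acc = vocab[int(rng.integers(0, n_domains))]
            counts[acc] = counts.get(acc, 0) + 1
        if not counts:  # vanishingly unlikely at the stated sizes
            counts = {next(iter(src.profile.counts)): 1}
        queries.append(PfamProfile(counts))
        truth.append(src.genome_id)
    return refs, queries, truth
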