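"""Co-abundance clustering of contigs into MAGs.

Contigs whose copies-per-liter time profiles correlate at Pearson r >= 0.95
are grouped into one metagenome-assembled genome (MAG) by a greedy,
deterministic canopy procedure: the unassigned contig with the largest
total abundance seeds a canopy, every unassigned contig within the
correlation radius of the seed joins, the canopy centroid (mean profile)
is recomputed and membership re-gathered until stable, then the members
leave the pool and the next seed is taken. Contigs with a flat (zero
variance) profile have no defined correlation and are reported as
unclustered rather than allowed to seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from mareta.quantify import ContigRecord

__all__ = [
    "ClusterParams",
    "MAG",
    "profile_correlation",
    "canopy_cluster",
    "mag_summary",
    "write_membership",
    "write_mag_summary",
]


@dataclasses.dataclass(frozen=True)
class ClusterParams:
    """Knobs of the canopy clustering.

    r_threshold is the Pearson radius (default 0.95). seed_order
    'by_total_abundance' makes the result invariant to input row order;
    'input_order' follows the matrix as given. When refine is False the
    canopy is gathered once around the seed contig's own profile, without
    centroid refinement. log1p applies log(1+x) to profiles before
    correlating (off by default: raw abundance patterns are compared).
    """

    r_threshold: float = 0.95
    min_samples: int = 3
    max_iterations: int = 50
    seed_order: str = "by_total_abundance"
    refine: bool = True
    log1p: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.r_threshold <= 1:
            raise ValueError("r_threshold must be in (0, 1]")
        if self.min_samples < 3:
            raise ValueError("min_samples must be >= 3")
        if self.seed_order not in {"by_total_abundance", "input_order"}:
            raise ValueError(f"unknown seed_order: {self.seed_order}")


@dataclasses.dataclass
class MAG:
    mag_id: str
    contig_ids: list[str]
    length_bp: int = 0
    profile: np.ndarray | None = None
    profile_sum: np.ndarray | None = None
    longest_contig_id: str | None = None


def profile_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation of two abundance profiles.

    Returns NaN (the "undefined correlation" sentinel) when either vector
    has zero variance; callers must exclude such contigs from seeding.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("profiles must have equal length")
    if u.std() == 0 or v.std() == 0:
        return float("nan")
    return float(np.corrcoef(u, v)[0, 1])


def _row_correlations(z: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Pearson r of each standardized row in z against a raw centroid vector."""
    c = centroid - centroid.mean()
    sd = c.std()
    if sd == 0:
        return np.full(z.shape[0], np.nan)
    c /= sd
    return z @ c / z.shape[1]


def canopy_cluster(
    matrix: pd.DataFrame, params: ClusterParams | None = None
) -> tuple[list[MAG], list[str]]:
    """Cluster the abundance matrix rows into MAGs.

    Returns (mags, unclustered_contig_ids). Every input contig appears
    exactly once — as a member of exactly one MAG or in the unclustered
    list (zero-variance profiles only). Singleton MAGs are allowed.
    MAG ids are MAG00001, MAG00002, ... in seed order.
    """
    params = params or ClusterParams()
    if matrix.shape[1] < params.min_samples:
        raise ValueError(
            f"need >= {params.min_samples} samples, got {matrix.shape[1]}"
        )
    if matrix.empty:
        return [], []

    ids = np.asarray(matrix.index)
    X = matrix.to_numpy(dtype=float)
    if params.log1p:
        X = np.log1p(X)

    sd = X.std(axis=1)
    flat = sd == 0
    unclustered = [str(i) for i in ids[flat]]

    active_idx = np.flatnonzero(~flat)
    if active_idx.size == 0:
        return [], unclustered

    Xa = X[active_idx]
    ids_a = ids[active_idx]
    # standardized rows: correlation to any vector is a dot product
    Z = (Xa - Xa.mean(axis=1, keepdims=True)) / Xa.std(axis=1, keepdims=True)

    if params.seed_order == "by_total_abundance":
        totals = Xa.sum(axis=1)
        seed_sequence = sorted(
            range(len(ids_a)), key=lambda i: (-totals[i], str(ids_a[i]))
        )
    else:
        seed_sequence = list(range(len(ids_a)))

    unassigned = np.ones(len(ids_a), dtype=bool)
    mags: list[MAG] = []

    for seed in seed_sequence:
        if not unassigned[seed]:
            continue
        members = np.zeros(len(ids_a), dtype=bool)
        members[seed] = True
        centroid = Xa[seed]
        r = _row_correlations(Z, centroid)
        gather = unassigned & (r >= params.r_threshold)
        gather[seed] = True
        members = gather
        if params.refine:
            for _ in range(params.max_iterations):
                centroid = Xa[members].mean(axis=0)
                r = _row_correlations(Z, centroid)
                new_members = unassigned & (r >= params.r_threshold)
                new_members[seed] = True  # seed anchors its canopy
                if np.array_equal(new_members, members):
                    break
                members = new_members
        member_ids = sorted(str(i) for i in ids_a[members])
        mags.append(MAG(mag_id=f"MAG{len(mags) + 1:05d}", contig_ids=member_ids))
        unassigned &= ~members

    return mags, unclustered


def mag_summary(
    mags: Sequence[MAG],
    matrix: pd.DataFrame,
    contigs: Sequence[ContigRecord],
) -> list[MAG]:
    """Fill aggregate fields of each MAG in place (and return the list).

    length_bp = sum of member contig lengths; profile = per-sample mean of
    the members' copies-per-liter rows (the clustering centroid), with the
    per-sample sum also kept; longest_contig_id = the longest member,
    lexicographic id breaking length ties.
    """
    length_by_id = {c.contig_id: c.length_bp for c in contigs}
    for mag in mags:
        missing = [c for c in mag.contig_ids if c not in length_by_id]
        if missing:
            raise ValueError(f"{mag.mag_id}: contigs without metadata: {missing[:10]}")
        missing_rows = [c for c in mag.contig_ids if c not in matrix.index]
        if missing_rows:
            raise ValueError(
                f"{mag.mag_id}: contigs absent from abundance matrix: {missing_rows[:10]}"
            )
        rows = matrix.loc[mag.contig_ids].to_numpy(dtype=float)
        mag.length_bp = int(sum(length_by_id[c] for c in mag.contig_ids))
        mag.profile = rows.mean(axis=0)
        mag.profile_sum = rows.sum(axis=0)
        mag.longest_contig_id = min(
            mag.contig_ids, key=lambda c: (-length_by_id[c], c)
        )
    return list(mags)


def write_membership(mags: Sequence[MAG], unclustered: Sequence[str], path) -> None:
    rows = [(c, m.mag_id) for m in mags for c in m.contig_ids]
    rows += [(c, "unclustered") for c in unclustered]
    pd.DataFrame(rows, columns=["contig_id", "mag_id"]).to_csv(path, sep="\t", index=False)


def write_mag_summary(mags: Sequence[MAG], sample_ids: Sequence[str], path) -> None:
    rows = []
    for m in mags:
        row = {
            "mag_id": m.mag_id,
            "n_contigs": len(m.contig_ids),
            "length_bp": m.length_bp,
            "longest_contig_id": m.longest_contig_id,
        }
        if m.profile is not None:
            row.update({s: v for s, v in zip(sample_ids, m.profile)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
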