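"""Backbone-RMSD neighbour-count clustering of stitched ensembles.

Frames are aligned once to a common reference on the rigid-body selection
(the bulk backbone), the RMSD matrix is evaluated on the flexible
selection (N-terminus backbone), and the greedy neighbour-count algorithm
of Daura et al. extracts cluster centres: the frame with the most
neighbours within the cutoff becomes a centre, it and its neighbours are
removed, and the process repeats.  Two cutoff-search strategies are
provided — hit a target cluster count, or make the most-populated clusters
cover a target fraction of all frames.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .structio import Ensemble, select
from .stitcher import superpose

CUTOFF_RESOLUTION = 1e-4  # nm


@dataclasses.dataclass
class RmsdMatrix:
    values: np.ndarray  # (n, n) nm, symmetric, zero diagonal
    align_selection: object = None
    rmsd_selection: object = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if not np.allclose(v, v.T, atol=0.0):
            raise ValueError("RMSD matrix must be symmetric")
        if np.any(np.diag(v) != 0.0) or np.any(v < 0.0):
            raise ValueError("RMSD matrix needs a zero diagonal and no "
                             "negative entries")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass
class Clustering:
    """Ordered clusters; each is (central member id, member ids incl. centre)."""

    cutoff: float
    clusters: list[tuple[int, list[int]]]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[int, int]:
        out = {}
        for cid, (_, members) in enumerate(self.clusters):
            for m in members:
                out[m] = cid
        return out


def rmsd_matrix(ensemble: Ensemble, align_sel, rmsd_sel) -> RmsdMatrix:
    """All-against-all RMSD over ``rmsd_sel`` after alignment on ``align_sel``.

    Each frame is least-squares fitted to the first frame on the alignment
    selection; because the aligned region is rigid and shared, this single
    common reference is equivalent to pairwise optimal alignment.
    """
    if len(ensemble) < 2:
        raise ValueError("need at least two frames for an RMSD matrix")
    top = ensemble.topology
    ai = select(top, align_sel)
    ri = select(top, rmsd_sel)
    if len(ai) == 0 or len(ri) == 0:
        raise ValueError("empty alignment or RMSD selection")
    ref = ensemble.frames[0][ai]
    aligned = np.empty((len(ensemble), len(ri), 3))
    for k, frame in enumerate(ensemble.frames):
        rot, t, _ = superpose(frame[ai], ref)
        aligned[k] = frame[ri] @ rot.T + t
    diff = aligned[:, None, :, :] - aligned[None, :, :, :]
    values = np.sqrt(np.mean(np.sum(diff * diff, axis=-1), axis=-1))
    np.fill_diagonal(values, 0.0)
    values = 0.5 * (values + values.T)
    return RmsdMatrix(values, align_sel, rmsd_sel)


def daura_cluster(matrix: RmsdMatrix, cutoff: float) -> Clustering:
    """Greedy neighbour-count clustering at a fixed cutoff.

    Ties on neighbour count break toward the lowest frame id, which makes
    the partition deterministic.  Every frame lands in exactly one cluster;
    singletons are kept.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    v = matrix.values
    n = matrix.n
    neigh = v < cutoff
    np.fill_diagonal(neigh, True)
    alive = np.ones(n, dtype=bool)
    clusters: list[tuple[int, list[int]]] = []
    while alive.any():
        counts = (neigh & alive[None, :]).sum(axis=1)
        counts[~alive] = -1
        centre = int(np.argmax(counts))  # argmax takes the first max: lowest id
        members = np.nonzero(neigh[centre] & alive)[0]
        clusters.append((centre, members.tolist()))
        alive[members] = False
    return Clustering(float(cutoff), clusters)


def _count_at(matrix: RmsdMatrix, cutoff: float) -> int:
    return daura_cluster(matrix, cutoff).n_clusters


def cutoff_for_target_k(matrix: RmsdMatrix, k: int = 100):
    """Bisect for a cutoff yielding ``k`` clusters (1e-4 nm resolution).

    The cluster count decreases with the cutoff — up to rare local
    inversions of one or two clusters that are intrinsic to the greedy
    rule — but can jump past ``k``; when no cutoff attains exactly ``k``
    the nearest achievable count at the bisection boundary is returned
    with a warning.  Returns ``(cutoff, achieved_k)``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    res = CUTOFF_RESOLUTION
    lo = res
    hi = float(np.max(matrix.values)) + res
    n_lo = _count_at(matrix, lo)
    n_hi = _count_at(matrix, hi)
    if n_lo <= k:
        if n_lo != k:
            warnings.warn(
                f"target cluster count {k} unattainable; nearest achievable "
                f"is {n_lo} at cutoff {lo:.4f} nm", stacklevel=2,
            )
        return lo, n_lo
    if n_hi >= k:
        if n_hi != k:
            warnings.warn(
                f"target cluster count {k} unattainable; nearest achievable "
                f"is {n_hi} at cutoff {hi:.4f} nm", stacklevel=2,
            )
        return hi, n_hi
    # invariant: count(lo) > k > count(hi)
    while hi - lo > res:
        mid = round((lo + hi) / 2.0 / res) * res
        if mid <= lo or mid >= hi:
            break
        c = _count_at(matrix, mid)
        if c == k:
            return mid, k
        if c > k:
            lo = mid
        else:
            hi = mid
    c_lo, c_hi = _count_at(matrix, lo), _count_at(matrix, hi)
    if abs(c_hi - k) <= abs(c_lo - k):
        cutoff, achieved = hi, c_hi
    else:
        cutoff, achieved = lo, c_lo
    warnings.warn(
        f"target cluster count {k} unattainable; nearest achievable is "
        f"{achieved} at cutoff {cutoff:.4f} nm",
        stacklevel=2,
    )
    return cutoff, achieved


def _coverage_at(matrix: RmsdMatrix, cutoff: float, top_n: int) -> float:
    clustering = daura_cluster(matrix, cutoff)
    sizes = sorted((len(m) for _, m in clustering.clusters), reverse=True)
    return sum(sizes[:top_n]) / matrix.n


def cutoff_for_coverage(
    matrix: RmsdMatrix, top_n: int = 100, coverage: float = 0.80
) -> float:
    """Smallest grid cutoff whose ``top_n`` most-populated clusters hold at
    least ``coverage`` of all frames.

    Coverage is treated as non-decreasing in the cutoff (larger cutoffs
    merge clusters); a bisection on the 1e-4 nm grid is followed by a
    backward scan to the smallest qualifying grid value.  Unreachable
    coverage at the maximal cutoff is an error.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    res = CUTOFF_RESOLUTION
    hi = float(np.max(matrix.values)) + res
    if _coverage_at(matrix, hi, top_n) < coverage:
        raise ValueError(
            f"coverage {coverage} unreachable with top {top_n} clusters"
        )
    lo = res
    if _coverage_at(matrix, lo, top_n) >= coverage:
        return lo
    while hi - lo > res:
        mid = round((lo + hi) / 2.0 / res) * res
        if mid <= lo or mid >= hi:
            break
        if _coverage_at(matrix, mid, top_n) >= coverage:
            hi = mid
        else:
            lo = mid
    # ensure smallest grid value (guards non-monotone corner cases)
    while hi - res > 0 and _coverage_at(matrix, hi - res, top_n) >= coverage:
        hi -= res
    return round(hi / res) * res


def central_members(clustering: Clustering, ensemble: Ensemble) -> Ensemble:
    """Ensemble of cluster-centre frames, largest cluster first (ties by
    lowest centre id)."""
    order = sorted(
        range(clustering.n_clusters),
        key=lambda c: (-len(clustering.clusters[c][1]), clustering.clusters[c][0]),
    )
    frames, prov = [], []
    for rank, cid in enumerate(order):
        centre, members = clustering.clusters[cid]
        frames.append(ensemble.frames[centre].copy())
        p = dict(ensemble.provenance[centre])
        p.update(
            {"cluster_rank": rank, "cluster_size": len(members),
             "center_frame": int(centre)}
        )
        prov.append(p)
    return Ensemble(ensemble.topology, frames, prov)
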