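"""Dynamic residue networks: per-frame contact graphs, reachability, betweenness.

A residue interaction network (RIN) connects two residues when their
representative atoms (Cβ, Cα for glycine) lie within a distance cutoff —
6.7 Å by default, tested inclusively.  A dynamic residue network (DRN) is the
time-ordered sequence of RINs sampled along a trajectory (every 200 ps by
convention); reachability and betweenness are computed per frame and averaged
over the DRN so that only persistent changes survive.

Per-residue metrics:

* ``L_i`` — average shortest-path length from residue *i* to every residue it
  can reach (unweighted, breadth-first).  Pairs in different components are
  excluded from the average and reported in ``unreachable_count``; an isolated
  residue gets NaN.
* ``ΔL_i`` (time) — how ``L_i`` drifts over the trajectory.  The default
  convention is later-minus-first (positive when reachability degrades, i.e.
  paths lengthen); ``sign="literal"`` emits the opposite, first-minus-later
  average.
* ``BC`` — Brandes betweenness with fractional credit over all equal-length
  shortest paths, endpoints excluded, optionally rescaled per frame by the
  frame's maximum positive value so each frame spans [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .trajectory_io import ResidueFrameSet, subsample

__all__ = [
    "ResidueInteractionNetwork",
    "DynamicResidueNetwork",
    "ReachabilityProfile",
    "build_rin",
    "build_drn",
    "reachability",
    "betweenness",
    "average_over_drn",
    "delta_between",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = 6.7  # Å


@dataclass
class ResidueInteractionNetwork:
    """Symmetric boolean adjacency over residues for one frame."""

    adjacency: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(adj, False)
        self.adjacency = adj

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def graph(self) -> nx.Graph:
        return nx.from_numpy_array(self.adjacency)


@dataclass
class DynamicResidueNetwork:
    """Time-ordered RINs with per-frame reachability and betweenness."""

    rins: list[ResidueInteractionNetwork]
    interval_ps: float
    L: np.ndarray  # residues × frames, NaN where isolated
    bc: np.ndarray  # residues × frames (rescaled per frame)
    unreachable: np.ndarray  # residues × frames, excluded-pair counts


@dataclass
class ReachabilityProfile:
    """Time-averaged reachability and its drift over the trajectory."""

    L_mean: np.ndarray
    deltaL_time: np.ndarray
    unreachable_count: np.ndarray
    sign: str = "increase"


def build_rin(coords, cutoff: float = DEFAULT_CUTOFF, frame_index: int = 0) -> ResidueInteractionNetwork:
    """Contact graph of one frame: edge iff representative distance ≤ cutoff."""
    from scipy.spatial.distance import squareform, pdist

    coords = np.asarray(coords, dtype=float)
    dist = squareform(pdist(coords))
    adj = dist <= cutoff
    np.fill_diagonal(adj, False)
    return ResidueInteractionNetwork(adj, frame_index)


def reachability(rin: ResidueInteractionNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue average shortest-path length ``L_i`` and excluded-pair counts.

    ``L_i = (1/|reachable_i|) Σ_j L_ij`` over unweighted breadth-first path
    lengths; unreachable pairs are excluded (not penalized) and counted.
    """
    n = rin.n_nodes
    dist = shortest_path(csr_matrix(rin.adjacency.astype(np.int8)), method="D", unweighted=True)
    np.fill_diagonal(dist, np.inf)  # self-pairs never contribute
    finite = np.isfinite(dist)
    reach_counts = finite.sum(axis=1)
    with np.errstate(invalid="ignore"):
        L = np.where(reach_counts > 0, np.where(finite, dist, 0.0).sum(axis=1), np.nan)
        L = L / np.where(reach_counts > 0, reach_counts, 1)
    L[reach_counts == 0] = np.nan
    unreachable = (n - 1) - reach_counts
    return L, unreachable


def betweenness(rin: ResidueInteractionNetwork, rescale: str = "max") -> np.ndarray:
    """Betweenness centrality with all-shortest-paths fractional credit.

    ``rescale="max"`` divides by the frame's maximum positive value so the
    frame spans [0, 1] (an all-zero frame stays all-zero); ``"none"`` returns
    raw Brandes values (each unordered pair counted once).
    """
    if rescale not in ("max", "none"):
        raise ValueError(f"unknown rescale mode {rescale!r}")
    bc_dict = nx.betweenness_centrality(rin.graph(), normalized=False)
    bc = np.array([bc_dict[i] for i in range(rin.n_nodes)], dtype=float)
    if rescale == "max" and bc.max() > 0:
        bc = bc / bc.max()
    return bc


def build_drn(
    rfs: ResidueFrameSet,
    cutoff: float = DEFAULT_CUTOFF,
    interval_ps: float | None = None,
    rescale: str = "max",
) -> DynamicResidueNetwork:
    """Build the DRN of a trajectory and compute per-frame metrics.

    ``interval_ps`` resamples the trajectory first (must be a multiple of the
    stored frame spacing); by default the stored sampling is used as-is.
    """
    if interval_ps is not None:
        rfs = subsample(rfs, interval_ps)
    rins = [build_rin(rfs.coords[t], cutoff, frame_index=t) for t in range(rfs.n_frames)]
    n = rfs.n_residues
    L = np.empty((n, len(rins)))
    bc = np.empty((n, len(rins)))
    unreachable = np.empty((n, len(rins)))
    for t, rin in enumerate(rins):
        L[:, t], unreachable[:, t] = reachability(rin)
        bc[:, t] = betweenness(rin, rescale=rescale)
    return DynamicResidueNetwork(rins, rfs.frame_interval, L, bc, unreachable)


def average_over_drn(
    drn: DynamicResidueNetwork, sign: str = "increase"
) -> tuple[ReachabilityProfile, np.ndarray]:
    """Time means over the DRN: ``(ReachabilityProfile, mean BC)``.

    The reachability drift is ``ΔL_i = (1/F) Σ_n (L_i^n − L_i^0)`` under the
    default ``sign="increase"`` (positive when paths lengthen over time);
    ``sign="literal"`` emits ``(1/F) Σ_n (L_i^0 − L_i^n)``.
    """
    if sign not in ("increase", "literal"):
        raise ValueError(f"unknown sign convention {sign!r}")
    if drn.L.shape[1] < 2:
        raise ValueError("need at least 2 frames to average over a DRN")
    import warnings

    with warnings.catch_warnings():
        # residues isolated in every frame yield all-NaN rows; NaN is the sentinel
        warnings.simplefilter("ignore", category=RuntimeWarning)
        L_mean = np.nanmean(drn.L, axis=1)
        drift = np.nanmean(drn.L[:, 0:1] - drn.L, axis=1)  # literal first-minus-later
    if sign == "increase":
        drift = -drift
    profile = ReachabilityProfile(
        L_mean=L_mean,
        deltaL_time=drift,
        unreachable_count=drn.unreachable.sum(axis=1),
        sign=sign,
    )
    return profile, drn.bc.mean(axis=1)


def delta_between(
    bound: tuple[np.ndarray, np.ndarray], free: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Bound-minus-free differences of time-averaged (L, BC).

    Positive ΔL means the bound ensemble is less reachable (longer paths).
    """
    (L_b, bc_b), (L_f, bc_f) = bound, free
    L_b, bc_b, L_f, bc_f = map(np.asarray, (L_b, bc_b, L_f, bc_f))
    if L_b.shape != L_f.shape or bc_b.shape != bc_f.shape:
        raise ValueError("bound and free profiles cover different residue sets")
    return L_b - L_f, bc_b - bc_f
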