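"""Communication propensity (CP): inter-residue distance-fluctuation analysis.

CP for a residue pair is the time-mean squared fluctuation of the Cα–Cα
distance, ``CP_ij = ⟨(d_ij − d̄_ij)²⟩`` (Å²).  It behaves like a communication
time: pairs whose distance fluctuates weakly coordinate faster.  Because it is
built from internal distances it needs no superposition and is exactly
invariant under per-frame rigid transforms of the whole system.

The module also provides the ΔCP difference map between a ligand-free and a
ligand-bound ensemble (free − bound, so positive means faster communication
with ligand), the sequence-neighbour baseline (mean CP over intra-chain pairs
within ±4 positions, used as an auto threshold), and the long-range
fast-communication scan: for each residue, the fraction of partners that sit
beyond a distance floor (80 Å time-averaged) yet communicate at or below the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory_io import ResidueFrameSet

__all__ = [
    "CPMatrix",
    "FastCommProfile",
    "cp_matrix",
    "delta_cp",
    "neighbor_baseline",
    "fast_comm_fraction",
    "DEFAULT_DIST_FLOOR",
    "DEFAULT_NEIGHBOR_WINDOW",
]

DEFAULT_DIST_FLOOR = 80.0  # Å
DEFAULT_NEIGHBOR_WINDOW = 4


@dataclass
class CPMatrix:
    """Symmetric per-pair mean-square distance fluctuation (Å²)."""

    cp: np.ndarray
    d_mean: np.ndarray  # time-averaged Cα–Cα distances, Å
    n_frames_used: int
    residue_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        cp = np.asarray(self.cp, dtype=float)
        if cp.ndim != 2 or cp.shape[0] != cp.shape[1]:
            raise ValueError("cp must be square")
        if not np.allclose(cp, cp.T, atol=1e-9):
            raise ValueError("cp must be symmetric")
        if np.any(cp < -1e-9):
            raise ValueError("cp entries must be non-negative")
        np.fill_diagonal(cp, 0.0)
        self.cp = np.maximum(cp, 0.0)

    @property
    def n_residues(self) -> int:
        return self.cp.shape[0]


@dataclass
class FastCommProfile:
    """Per-residue fraction of far partners communicating at/below a threshold."""

    threshold: float  # Å²
    dist_floor: float  # Å
    fraction: np.ndarray


def cp_matrix(rfs: ResidueFrameSet) -> CPMatrix:
    """Communication-propensity matrix from a Cα representative trajectory.

    No superposition is applied: inter-residue distances are frame-internal.
    Requires at least 2 frames.
    """
    from scipy.spatial.distance import pdist, squareform

    if rfs.n_frames < 2:
        raise ValueError("CP needs at least 2 frames")
    if rfs.scheme != "CA":
        raise ValueError("CP is defined on Cα representatives; pass a scheme='CA' frame set")
    n = rfs.n_residues
    sum_d = np.zeros(n * (n - 1) // 2)
    sum_d2 = np.zeros_like(sum_d)
    for frame in rfs.coords:
        d = pdist(frame)
        sum_d += d
        sum_d2 += d * d
    f = rfs.n_frames
    mean_d = sum_d / f
    fluct = sum_d2 / f - mean_d**2
    return CPMatrix(
        cp=squareform(np.maximum(fluct, 0.0)),
        d_mean=squareform(mean_d),
        n_frames_used=f,
        residue_meta=rfs.residue_meta,
    )


def delta_cp(free: CPMatrix, bound: CPMatrix) -> np.ndarray:
    """ΔCP = CP(free) − CP(bound); positive where the bound system communicates
    faster (CP is a time-like cost, so a drop in CP is a gain in efficiency)."""
    if free.cp.shape != bound.cp.shape:
        raise ValueError(f"shape mismatch: {free.cp.shape} vs {bound.cp.shape}")
    return free.cp - bound.cp


def _chain_positions(cpm: CPMatrix) -> np.ndarray:
    if cpm.residue_meta is not None and "chain_id" in cpm.residue_meta:
        return cpm.residue_meta["chain_id"].to_numpy()
    return np.zeros(cpm.n_residues, dtype=int)  # single chain assumed


def neighbor_baseline(
    cpm: CPMatrix, window: int = DEFAULT_NEIGHBOR_WINDOW, exact: bool = False
) -> float:
    """Mean CP over sequence-neighbour pairs (intra-chain, |i−j| within ±window).

    ``exact=True`` restricts to |i−j| == window instead of 1..window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    chains = _chain_positions(cpm)
    n = cpm.n_residues
    values = []
    for i in range(n):
        lo = window if exact else 1
        for sep in range(lo, window + 1):
            j = i + sep
            if j < n and chains[i] == chains[j]:
                values.append(cpm.cp[i, j])
    if not values:
        raise ValueError("no neighbour pairs; chain shorter than the window")
    return float(np.mean(values))


def fast_comm_fraction(
    cpm: CPMatrix,
    threshold: float | None = None,
    dist_floor: float = DEFAULT_DIST_FLOOR,
    denominator: str = "all",
) -> FastCommProfile:
    """Long-range fast-communication scan.

    For each residue *i*, count partners *j* with time-averaged distance above
    ``dist_floor`` and ``cp[i, j] ≤ threshold``; report the count over N−1
    (``denominator="all"``, the whole-protein convention) or over the number of
    far partners (``"far-only"``).  ``threshold=None`` auto-sets the
    sequence-neighbour baseline.
    """
    if denominator not in ("all", "far-only"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    if threshold is None:
        threshold = neighbor_baseline(cpm)
    n = cpm.n_residues
    far = cpm.d_mean > dist_floor
    fast = far & (cpm.cp <= threshold)
    np.fill_diagonal(fast, False)
    np.fill_diagonal(far, False)
    counts = fast.sum(axis=1).astype(float)
    if denominator == "all":
        fraction = counts / max(n - 1, 1)
    else:
        far_counts = far.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            fraction = np.where(far_counts > 0, counts / np.maximum(far_counts, 1), 0.0)
    return FastCommProfile(threshold=float(threshold), dist_floor=float(dist_floor),
                           fraction=fraction)
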