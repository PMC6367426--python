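"""Superposition, RMSD/RMSF, centre-of-mass distance series and clustering.

All pairwise structural comparisons use least-squares rigid superposition
(Kabsch) with the proper-rotation correction: when the optimal orthogonal
transform is a reflection, the singular direction with the smallest singular
value is flipped so the returned rotation always has determinant +1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "SeriesSummary",
    "ClusterResult",
    "superpose",
    "rmsd_between",
    "rmsd_series",
    "rmsf",
    "delta_rmsf",
    "com_distance_series",
    "cluster_gromos",
]


class GeometryError(ValueError):
    """Raised for degenerate geometry or mismatched selections."""


@dataclass
class SeriesSummary:
    """A per-frame scalar series with its mean, standard deviation and histogram."""

    values: np.ndarray
    mean: float
    std: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray

    @classmethod
    def from_values(cls, values, bins="fd") -> "SeriesSummary":
        values = np.asarray(values, dtype=float)
        counts, edges = np.histogram(values, bins=bins)
        return cls(values, float(values.mean()), float(values.std()), edges, counts)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"frame": np.arange(len(self.values)), "value": self.values})


@dataclass
class ClusterResult:
    """Frame clusters, ordered by non-increasing size; one representative each."""

    clusters: list[list[int]]
    representatives: list[int]


def _as_coords(obj, selection=None) -> np.ndarray:
    coords = obj.coords if hasattr(obj, "coords") else np.asarray(obj, dtype=float)
    if selection is not None:
        selection = np.asarray(selection)
        if selection.size == 0:
            raise GeometryError("empty selection")
        coords = coords[..., selection, :]
    return coords


def superpose(mobile, reference, weights=None):
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` where
    ``mobile @ rotation + translation`` best matches ``reference``.  The
    rotation is always proper (det = +1).  Requires ≥ 3 non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise GeometryError(f"atom-count mismatch: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise GeometryError("need an (n>=3, 3) coordinate array")
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(mobile),) or np.any(w < 0) or w.sum() <= 0:
            raise GeometryError("weights must be non-negative with positive sum")
    w = w / w.sum()

    cm = w @ mobile
    cr = w @ reference
    p = mobile - cm
    q = reference - cr
    h = (p * w[:, None]).T @ q
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-10 * max(s[0], 1e-30):
        raise GeometryError("degenerate (collinear) geometry; superposition is ill-defined")
    d = np.sign(np.linalg.det(u) * np.linalg.det(vt))
    rotation = u @ np.diag([1.0, 1.0, d]) @ vt
    translation = cr - cm @ rotation
    fitted = mobile @ rotation + translation
    rmsd = float(np.sqrt((w * np.sum((fitted - reference) ** 2, axis=1)).sum()))
    return rotation, translation, rmsd


def rmsd_between(mobile, reference, weights=None) -> float:
    """Minimum RMSD between two frames after optimal superposition."""
    return superpose(mobile, reference, weights)[2]


def rmsd_series(ens, reference=None, selection=None, bins="fd") -> SeriesSummary:
    """Per-frame RMSD to a reference frame after per-frame superposition.

    ``reference`` defaults to frame 0.  The superposition and the RMSD both use
    the (non-empty) atom selection.
    """
    coords = _as_coords(ens, selection)
    if reference is None:
        ref = coords[0]
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.ndim != 2:
            raise GeometryError("reference must be a single frame (n_atoms, 3)")
        if selection is not None and ref.shape[0] != coords.shape[1]:
            ref = ref[np.asarray(selection)]
        if ref.shape != coords.shape[1:]:
            raise GeometryError(
                f"reference shape {ref.shape} does not match selection {coords.shape[1:]}"
            )
    values = np.array([rmsd_between(frame, ref) for frame in coords])
    return SeriesSummary.from_values(values, bins=bins)


def _superpose_frames_to(coords: np.ndarray, target: np.ndarray) -> np.ndarray:
    out = np.empty_like(coords)
    for i, frame in enumerate(coords):
        rot, trans, _ = superpose(frame, target)
        out[i] = frame @ rot + trans
    return out


def aligned_frames(
    obj, selection=None, max_passes: int = 50, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose every frame to an iteratively refined mean structure.

    Returns ``(fitted_coords, mean_structure)``.  The mean is refined until it
    is self-consistent (fitting target and fitted average agree within ``tol``
    Å, usually 3–5 passes), so that covariance analyses built on the fitted
    frames satisfy the exact PCA identities.
    """
    coords = _as_coords(obj, selection)
    mean = coords.mean(axis=0)
    fitted = coords
    for _ in range(max(1, max_passes)):
        fitted = _superpose_frames_to(coords, mean)
        new_mean = fitted.mean(axis=0)
        converged = np.abs(new_mean - mean).max() < tol
        mean = new_mean
        if converged:
            break
    return fitted, mean


def rmsf(obj, selection=None, superpose_frames: bool = True) -> np.ndarray:
    """Root-mean-square fluctuation per residue/atom, in Å.

    ``RMSF_i = sqrt(⟨|x_i(t) − ⟨x_i⟩|²⟩)`` after superposing each frame onto
    the (two-pass refined) mean structure; set ``superpose_frames=False`` for
    trajectories already sharing a lab frame.
    """
    coords = _as_coords(obj, selection)
    if coords.shape[0] < 2:
        raise GeometryError("RMSF needs at least 2 frames")
    if superpose_frames:
        coords, mean = aligned_frames(coords)
    else:
        mean = coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))


def delta_rmsf(bound: np.ndarray, free: np.ndarray) -> np.ndarray:
    """Bound-minus-free RMSF difference; negative where binding quiets a residue."""
    bound = np.asarray(bound, dtype=float)
    free = np.asarray(free, dtype=float)
    if bound.shape != free.shape:
        raise GeometryError(f"residue sets differ: {bound.shape} vs {free.shape}")
    return bound - free


def com_distance_series(
    obj, group_a: Sequence[int], group_b: Sequence[int],
    masses=None, bins="fd",
) -> SeriesSummary:
    """Per-frame distance between the centres of mass of two residue groups.

    Groups must be non-empty and disjoint.  Unit masses by default; pass
    per-atom ``masses`` for mass weighting.
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.size == 0 or group_b.size == 0:
        raise GeometryError("both groups must be non-empty")
    if np.intersect1d(group_a, group_b).size:
        raise GeometryError("groups must be disjoint")
    coords = _as_coords(obj)

    def com(idx):
        if masses is None:
            return coords[:, idx, :].mean(axis=1)
        m = np.asarray(masses, dtype=float)[idx]
        return (coords[:, idx, :] * m[None, :, None]).sum(axis=1) / m.sum()

    values = np.linalg.norm(com(group_a) - com(group_b), axis=1)
    return SeriesSummary.from_values(values, bins=bins)


def cluster_gromos(obj, selection=None, cutoff: float = 2.0) -> ClusterResult:
    """Greedy neighbour-count clustering of frames by pairwise RMSD (Daura).

    Iteratively: count, for every unassigned frame, its unassigned neighbours
    within ``cutoff`` (Å, inclusive); the frame with the most neighbours founds
    a cluster containing itself and those neighbours; remove them and repeat.
    Ties go to the lowest frame index.  Each cluster's representative is the
    member closest (fitted RMSD) to the member-average coordinates.
    """
    coords = _as_coords(obj, selection)
    n = coords.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = rmsd_between(coords[i], coords[j])

    remaining = list(range(n))
    clusters: list[list[int]] = []
    while remaining:
        idx = np.asarray(remaining)
        sub = dist[np.ix_(idx, idx)] <= cutoff
        counts = sub.sum(axis=1)  # includes self
        founder_pos = int(np.argmax(counts))  # argmax returns the first (lowest-index) max
        members = sorted(idx[sub[founder_pos]].tolist())
        clusters.append(members)
        remaining = [f for f in remaining if f not in set(members)]

    clusters.sort(key=lambda c: (-len(c), c[0]))
    representatives = []
    for members in clusters:
        ref = coords[members[0]]
        fitted = np.stack([_fit_onto(coords[m], ref) for m in members])
        avg = fitted.mean(axis=0)
        rms_to_avg = [rmsd_between(coords[m], avg) for m in members]
        representatives.append(members[int(np.argmin(rms_to_avg))])
    return ClusterResult(clusters, representatives)


def _fit_onto(frame, ref):
    rot, trans, _ = superpose(frame, ref)
    return frame @ rot + trans
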