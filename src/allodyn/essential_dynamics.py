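"""Essential dynamics: Cα covariance, eigenmodes, projections, interpolation.

The positional covariance ``C = ⟨(x − ⟨x⟩)(x − ⟨x⟩)ᵀ⟩`` is built over the Cα
coordinates of each retained frame (an initial equilibration window can be
skipped), after least-squares superposition of every frame onto an iteratively
refined mean structure.  Its eigenvectors, ordered by decreasing eigenvalue
(Å²), describe collective motions; the leading few typically capture the
functionally relevant subspace.  Trajectories are characterized by projecting
frames onto selected modes, by interpolating between the two most extreme
projections of a mode (porcupine/arrow data), and by projecting a query
ensemble onto modes fitted to a concatenated set of labelled reference-state
ensembles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import aligned_frames, superpose
from .trajectory_io import ResidueFrameSet

__all__ = [
    "EssentialModes",
    "ProjectionSet",
    "fit_modes",
    "variance_fractions",
    "project",
    "extreme_interpolation",
    "reference_projection",
    "DEFAULT_SKIP_INITIAL_PS",
]

DEFAULT_SKIP_INITIAL_PS = 10_000.0  # ps; drop the equilibration window when frames allow


@dataclass
class EssentialModes:
    """Mean structure and eigendecomposition of the positional covariance."""

    mean_coords: np.ndarray  # (N, 3) Å
    eigvecs: np.ndarray  # (3N, 3N), orthonormal columns, descending eigenvalue
    eigvals: np.ndarray  # (3N,) Å², descending, clipped at 0
    n_frames_used: int
    superposed: bool = True

    @property
    def variance_fraction(self) -> np.ndarray:
        total = self.eigvals.sum()
        return self.eigvals / total if total > 0 else np.zeros_like(self.eigvals)

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.variance_fraction)

    @property
    def n_atoms(self) -> int:
        return self.mean_coords.shape[0]


@dataclass
class ProjectionSet:
    """Per-frame scores on selected modes, with a source label per frame."""

    scores: np.ndarray  # frames × modes
    labels: np.ndarray  # per-frame source label
    mode_indices: tuple[int, ...]

    def to_frame(self):
        import pandas as pd

        data = {"label": self.labels}
        for k, m in enumerate(self.mode_indices):
            data[f"PC{m + 1}"] = self.scores[:, k]
        return pd.DataFrame(data)


def _retained_coords(rfs: ResidueFrameSet, skip_initial_ps: float) -> np.ndarray:
    keep = rfs.times_ps >= skip_initial_ps
    if keep.sum() < 2:
        if skip_initial_ps > 0:
            warnings.warn(
                f"skipping the first {skip_initial_ps:g} ps would leave "
                f"{int(keep.sum())} frames; using the full trajectory instead",
                stacklevel=3,
            )
        keep = np.ones(rfs.n_frames, dtype=bool)
    if keep.sum() < 2:
        raise ValueError("essential dynamics needs at least 2 frames")
    return rfs.coords[keep]


def fit_modes(
    rfs: ResidueFrameSet,
    skip_initial_ps: float = DEFAULT_SKIP_INITIAL_PS,
    superpose_frames: bool = True,
) -> EssentialModes:
    """Eigendecomposition of the Cα positional covariance.

    Frames before ``skip_initial_ps`` are dropped (falling back to the full
    trajectory, with a warning, when too few frames would remain).  With
    ``superpose_frames=True`` each frame is fitted to a two-pass refined mean
    structure first; disable for ensembles generated in a common lab frame,
    where the raw covariance is the planted one.
    """
    coords = _retained_coords(rfs, skip_initial_ps)
    if superpose_frames:
        fitted, mean = aligned_frames(coords)
    else:
        fitted, mean = coords, coords.mean(axis=0)
    flat = fitted.reshape(fitted.shape[0], -1) - mean.ravel()
    cov = flat.T @ flat / flat.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    return EssentialModes(
        mean_coords=mean,
        eigvecs=eigvecs[:, order],
        eigvals=np.maximum(eigvals[order], 0.0),
        n_frames_used=fitted.shape[0],
        superposed=superpose_frames,
    )


def variance_fractions(modes: EssentialModes, k: int) -> float:
    """Cumulative fraction of total positional variance in the first k modes."""
    if not 0 <= k <= modes.eigvals.size:
        raise ValueError(f"k={k} outside [0, {modes.eigvals.size}]")
    total = modes.eigvals.sum()
    return float(modes.eigvals[:k].sum() / total) if total > 0 else 0.0


def project(
    ens,
    modes: EssentialModes,
    mode_indices: Sequence[int] = (0, 1, 2),
    label: str = "query",
) -> ProjectionSet:
    """Project frames onto selected modes after fitting to the modes' mean.

    ``score(t, m) = (x_fit(t) − mean) · v_m``.  Skips the superposition when
    the modes were fitted without it.
    """
    coords = ens.coords if hasattr(ens, "coords") else np.asarray(ens, dtype=float)
    if coords.shape[1] != modes.n_atoms:
        raise ValueError(
            f"ensemble has {coords.shape[1]} atoms but modes were fitted on {modes.n_atoms}"
        )
    mode_indices = tuple(int(m) for m in mode_indices)
    vecs = modes.eigvecs[:, list(mode_indices)]
    mean_flat = modes.mean_coords.ravel()
    scores = np.empty((coords.shape[0], len(mode_indices)))
    for t, frame in enumerate(coords):
        if modes.superposed:
            rot, trans, _ = superpose(frame, modes.mean_coords)
            frame = frame @ rot + trans
        scores[t] = (frame.ravel() - mean_flat) @ vecs
    return ProjectionSet(scores, np.array([label] * coords.shape[0]), mode_indices)


def extreme_interpolation(
    modes: EssentialModes,
    mode_index: int,
    scores: np.ndarray,
    n_steps: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Structures interpolated between a mode's extreme projections.

    Returns ``(structures, displacements)``: ``n_steps`` coordinate frames
    ``mean + s·v`` with ``s`` spanning [min score, max score] linearly, and the
    per-atom displacement vectors (arrow data) over that span.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    scores = np.asarray(scores, dtype=float).ravel()
    smin, smax = float(scores.min()), float(scores.max())
    if modes.eigvals[mode_index] <= 0 or smax == smin:
        raise ValueError(f"mode {mode_index} has no variance to interpolate over")
    v = modes.eigvecs[:, mode_index].reshape(-1, 3)
    span = np.linspace(smin, smax, n_steps)
    structures = modes.mean_coords[None] + span[:, None, None] * v[None]
    displacements = (smax - smin) * v
    return structures, displacements


def reference_projection(
    references: Sequence[tuple[str, ResidueFrameSet]],
    query: ResidueFrameSet,
    k: int = 3,
    skip_initial_ps: float = 0.0,
    superpose_frames: bool = True,
) -> tuple[EssentialModes, ProjectionSet]:
    """Project a query ensemble onto modes fitted to concatenated references.

    The covariance is built from the labelled reference ensembles only (all
    frames superposed to the concatenated mean); the query and every reference
    are then projected onto the top-``k`` modes, yielding a labelled score
    table for pairwise scatter plots.
    """
    if not references:
        raise ValueError("need at least one labelled reference ensemble")
    n_res = query.n_residues
    for name, ref in references:
        if ref.n_residues != n_res:
            raise ValueError(f"reference {name!r} has {ref.n_residues} residues, query {n_res}")
    concat = np.concatenate([ref.coords for _, ref in references], axis=0)
    concat_rfs = ResidueFrameSet(
        concat, references[0][1].residue_meta, scheme=references[0][1].scheme,
        frame_interval=references[0][1].frame_interval,
    )
    modes = fit_modes(concat_rfs, skip_initial_ps=skip_initial_ps,
                      superpose_frames=superpose_frames)
    mode_indices = tuple(range(k))
    parts = [project(ref, modes, mode_indices, label=name) for name, ref in references]
    parts.append(project(query, modes, mode_indices, label="query"))
    return modes, ProjectionSet(
        np.concatenate([p.scores for p in parts]),
        np.concatenate([p.labels for p in parts]),
        mode_indices,
    )
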