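"""Time-resolved contact maps and persistence classification.

Inter-domain contacts (e.g. NTD against M-domain) are evaluated between
representative atoms at the residue-network cutoff (6.7 Å) on the network
sampling interval; a contact is called *stable* when it is present in at
least 70% of the sampled frames (inclusive threshold).

Ligand contacts are a distance-only surrogate: a residue is in contact when
any ligand atom lies within 4.0 Å of any of its atoms.  No chemical typing
(hydrophobic/H-bond classification) is attempted, and outputs are labelled
accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np

from .trajectory_io import ResidueFrameSet, TrajectoryEnsemble, subsample

__all__ = [
    "ContactTimeline",
    "contact_timeline",
    "persistence_filter",
    "ligand_contact_timeline",
    "DEFAULT_CONTACT_CUTOFF",
    "DEFAULT_LIGAND_CUTOFF",
    "DEFAULT_PERSISTENCE",
]

DEFAULT_CONTACT_CUTOFF = 6.7  # Å, residue-network cutoff
DEFAULT_LIGAND_CUTOFF = 4.0  # Å, heavy-atom ligand-contact surrogate
DEFAULT_PERSISTENCE = 0.70


@dataclass
class ContactTimeline:
    """Per-pair boolean presence over frames, with persistence fractions."""

    pairs: list[tuple[Hashable, Hashable]]
    presence: np.ndarray  # pairs × frames, bool
    frame_interval: float

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape[0] != len(self.pairs):
            raise ValueError("presence rows must match pair count")

    @property
    def n_frames(self) -> int:
        return self.presence.shape[1]

    @property
    def persistence(self) -> np.ndarray:
        """Fraction of frames each pair is in contact (row mean of presence)."""
        if self.presence.size == 0:
            return np.zeros(len(self.pairs))
        return self.presence.mean(axis=1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "pair_i": [p[0] + 1 if isinstance(p[0], (int, np.integer)) else p[0]
                           for p in self.pairs],
                "pair_j": [p[1] + 1 if isinstance(p[1], (int, np.integer)) else p[1]
                           for p in self.pairs],
                "persistence": self.persistence,
            }
        )


def contact_timeline(
    rfs: ResidueFrameSet,
    group_a: Sequence[int],
    group_b: Sequence[int],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    interval_ps: float | None = None,
    dense: bool = False,
) -> ContactTimeline:
    """Cross-group residue contacts over time (inclusive distance ≤ cutoff).

    Groups are disjoint residue-position sets; only cross-group pairs are
    evaluated.  Pairs never in contact are omitted unless ``dense=True``.
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("groups must be disjoint")
    if interval_ps is not None:
        rfs = subsample(rfs, interval_ps)

    diff = rfs.coords[:, group_a, None, :] - rfs.coords[:, None, group_b, :]
    within = np.sqrt((diff**2).sum(axis=3)) <= cutoff  # frames × |A| × |B|

    pairs: list[tuple[int, int]] = []
    rows: list[np.ndarray] = []
    for ai, i in enumerate(group_a):
        for bi, j in enumerate(group_b):
            series = within[:, ai, bi]
            if dense or series.any():
                pairs.append((int(i), int(j)))
                rows.append(series)
    presence = np.stack(rows) if rows else np.zeros((0, rfs.n_frames), dtype=bool)
    return ContactTimeline(pairs, presence, rfs.frame_interval)


def persistence_filter(
    tl: ContactTimeline, threshold: float = DEFAULT_PERSISTENCE
) -> list[tuple[tuple[Hashable, Hashable], float]]:
    """Pairs whose persistence is at least the threshold (inclusive).

    Returns ``[(pair, persistence), ...]`` sorted by descending persistence.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    persistence = tl.persistence
    keep = [(tl.pairs[k], float(persistence[k])) for k in range(len(tl.pairs))
            if persistence[k] >= threshold]
    return sorted(keep, key=lambda item: (-item[1], item[0]))


def ligand_contact_timeline(
    ens: TrajectoryEnsemble,
    ligand_resname: str = "LIG",
    cutoff: float = DEFAULT_LIGAND_CUTOFF,
    interval_ps: float | None = None,
) -> ContactTimeline:
    """Distance-only ligand–residue contact timeline (no chemical typing).

    A residue is in contact at frame *t* when any ligand atom is within
    ``cutoff`` of any of the residue's atoms.  Pairs are ``(residue_index,
    "ligand")``; residues never in contact are omitted.
    """
    if interval_ps is not None:
        ens = subsample(ens, interval_ps)
    is_lig = (ens.atom_meta["residue_name"] == ligand_resname).to_numpy()
    lig_atoms = np.flatnonzero(is_lig)
    if lig_atoms.size == 0:
        raise ValueError(f"no ligand atoms with residue_name {ligand_resname!r}")
    protein_atoms = np.flatnonzero(~is_lig)
    res_of_atom = ens.atom_meta["residue_index"].to_numpy()[protein_atoms]

    diff = ens.coords[:, protein_atoms, None, :] - ens.coords[:, None, lig_atoms, :]
    near = (np.sqrt((diff**2).sum(axis=3)) <= cutoff).any(axis=2)  # frames × protein atoms

    pairs: list[tuple[int, str]] = []
    rows: list[np.ndarray] = []
    for res in np.unique(res_of_atom):
        series = near[:, res_of_atom == res].any(axis=1)
        if series.any():
            pairs.append((int(res), "ligand"))
            rows.append(series)
    presence = np.stack(rows) if rows else np.zeros((0, ens.n_frames), dtype=bool)
    return ContactTimeline(pairs, presence, ens.frame_interval)
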