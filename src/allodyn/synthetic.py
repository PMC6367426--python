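"""Synthetic dimer trajectories with planted, analytically known structure.

The generator emulates the statistical features the analysis stack measures on
a chaperone-like homodimer — two protomers (chains A and B), each split into
an N-terminal, middle and C-terminal domain, arranged in an open "v-like"
geometry with the CTDs forming the dimer interface.  On top of the static
scaffold it plants:

* low-frequency collective modes — a linear *open_close* motion that changes
  the NTD–NTD separation and an axial *twist* that rotates the protomers in
  opposite senses — activated sinusoidally so every planted variance is
  closed-form (``a²/2`` per mode for amplitude ``a`` over whole cycles);
* i.i.d. Gaussian positional noise with a scalar or per-residue σ profile
  (expected RMSF ``σ√3``);
* contact pairs driven inside/outside the 6.7 Å network cutoff in an exact,
  seeded fraction of frames;
* an optional rigid pseudo-atom ligand tethered to an anchor residue.

Noise is added after the mode displacement in the lab frame and no frame is
re-superposed, so the planted covariance is exactly (low-rank modes + σ²·I)
and mode/variance recovery can be checked against closed forms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .trajectory_io import ATOM_META_COLUMNS, TrajectoryEnsemble

__all__ = [
    "LigandSpec",
    "SyntheticSpec",
    "PlantedTruth",
    "build_toy_dimer",
    "generate_trajectory",
    "scenario_free",
    "scenario_activator",
    "scenario_inhibitor",
    "spec_from_yaml",
    "truth_to_json",
]

DOMAINS = ("NTD", "M", "CTD")
RIN_CUTOFF = 6.7  # Å; construction must keep consecutive residues inside this
_BOND_LENGTH = 3.3  # Å; keeps second-neighbour pairs (6.6 Å) inside the 6.7 Å
# network cutoff so the toy RIN is redundant like a real Cβ contact network,
# not a bare path graph that fragments under noise
_ZIGZAG = 0.8  # Å, in-plane wiggle so arms are not collinear
_ARM_HALF_ANGLE = np.deg2rad(25.0)  # opening half-angle of the "v"
_VERTEX_GAP = 4.4  # Å between the two CTD terminal residues
_CONTACT_IN = 5.5  # Å, planted in-contact distance (< cutoff)
_CONTACT_OUT = 9.0  # Å, planted out-of-contact distance (> cutoff)
_MODE_CYCLES = {"open_close": 2, "twist": 3}  # whole cycles per trajectory


class SyntheticSpecError(ValueError):
    """Raised for contradictory or geometry-breaking generator specs."""


@dataclass(frozen=True)
class LigandSpec:
    """A rigid cluster of pseudo-atoms tethered to an anchor residue."""

    n_atoms: int = 8
    anchor_residue: int = 0
    offset: float = 5.0  # Å, displacement from the anchor, directed away from the dimer core
    noise_sigma: float = 0.3  # Å, positional noise of the rigid cluster as a whole


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic trajectory.

    Defaults describe the standard toy dimer: 20 residues per domain
    (120 residues total), 2000 frames at 200 ps, open/close amplitude 4 Å,
    twist 2 Å, isotropic noise σ = 0.5 Å.
    """

    n_res_per_domain: int = 20
    mode_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: {"open_close": 4.0, "twist": 2.0}
    )
    mode_bias: Mapping[str, float] = field(default_factory=dict)
    noise_sigma: float | np.ndarray = 0.5
    n_frames: int = 2000
    frame_interval_ps: float = 200.0
    seed: int = 0
    contact_plan: Mapping[tuple[int, int], float] = field(default_factory=dict)
    ligand: LigandSpec | None = None

    @property
    def n_residues(self) -> int:
        return 2 * 3 * self.n_res_per_domain

    def validate(self) -> None:
        if self.n_res_per_domain < 2:
            raise SyntheticSpecError("need at least 2 residues per domain")
        if self.n_frames < 1:
            raise SyntheticSpecError("n_frames must be >= 1")
        if self.frame_interval_ps <= 0:
            raise SyntheticSpecError("frame_interval_ps must be positive")
        sigma = np.asarray(self.noise_sigma, dtype=float)
        if np.any(sigma < 0):
            raise SyntheticSpecError("noise_sigma must be >= 0")
        if sigma.ndim == 1 and sigma.size != self.n_residues:
            raise SyntheticSpecError(
                f"noise_sigma profile has {sigma.size} entries for {self.n_residues} residues"
            )
        for name in list(self.mode_amplitudes) + list(self.mode_bias):
            if name not in _MODE_CYCLES:
                raise SyntheticSpecError(f"unknown mode {name!r}; known: {sorted(_MODE_CYCLES)}")
        seen_pairs = set()
        partners: set[int] = set()
        for (i, j), frac in self.contact_plan.items():
            pair = (min(i, j), max(i, j))
            if pair in seen_pairs:
                raise SyntheticSpecError(f"contact pair {pair} listed twice")
            seen_pairs.add(pair)
            if j in partners:
                raise SyntheticSpecError(f"residue {j} is the driven partner of two contact pairs")
            partners.add(j)
            if not 0.0 <= frac <= 1.0:
                raise SyntheticSpecError(f"persistence fraction {frac} outside [0, 1]")
            if not (0 <= i < self.n_residues and 0 <= j < self.n_residues):
                raise SyntheticSpecError(f"contact pair {pair} outside residue range")


@dataclass
class PlantedTruth:
    """Ground truth of one generated trajectory, for parameter-recovery tests."""

    mode_vectors: dict[str, np.ndarray]  # name -> unit 3N vector (protein only)
    expected_rmsf: np.ndarray  # per-residue Å, σ√3
    contact_truth: dict[tuple[int, int], float]  # planted pair -> exact fraction
    com_distance_params: dict[str, float]  # NTD(A)–NTD(B) distance mean & planted amplitude
    domain_map: dict[int, str]  # residue index -> NTD/M/CTD


def _sigma_profile(spec: SyntheticSpec) -> np.ndarray:
    sigma = np.asarray(spec.noise_sigma, dtype=float)
    if sigma.ndim == 0:
        return np.full(spec.n_residues, float(sigma))
    return sigma.copy()


def _mean_geometry(spec: SyntheticSpec) -> np.ndarray:
    """Planar v-shaped scaffold, one pseudo-Cα per residue, chain A then B."""
    n = spec.n_res_per_domain
    per_chain = 3 * n
    coords = np.zeros((2 * per_chain, 3))
    for c, sign in enumerate((-1.0, +1.0)):  # chain A left, chain B right
        arm = np.array([sign * np.sin(_ARM_HALF_ANGLE), 0.0, np.cos(_ARM_HALF_ANGLE)])
        perp = np.array([sign * np.cos(_ARM_HALF_ANGLE), 0.0, -np.sin(_ARM_HALF_ANGLE)])
        base = np.array([sign * _VERTEX_GAP / 2.0, 0.0, 0.0])
        for k in range(per_chain):
            # residue 0 = NTD start (top of the arm), residue 3n-1 = CTD end (vertex)
            s = (per_chain - 1 - k) * _BOND_LENGTH
            coords[c * per_chain + k] = base + s * arm + ((-1) ** k) * _ZIGZAG * perp
    return coords


def _domain_map(spec: SyntheticSpec) -> dict[int, str]:
    n = spec.n_res_per_domain
    out = {}
    for c in range(2):
        for d, name in enumerate(DOMAINS):
            for k in range(n):
                out[c * 3 * n + d * n + k] = name
    return out


def _rigid_basis(mean: np.ndarray) -> np.ndarray:
    """Orthonormal basis of rigid-body motions (3 translations + 3 rotations)."""
    n = mean.shape[0]
    centered = mean - mean.mean(axis=0)
    basis = []
    for ax in range(3):
        v = np.zeros((n, 3))
        v[:, ax] = 1.0
        basis.append(v.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        basis.append(np.cross(e, centered).ravel())
    q, _ = np.linalg.qr(np.column_stack(basis))
    return q


def _mode_vectors(spec: SyntheticSpec, mean: np.ndarray) -> dict[str, np.ndarray]:
    """Unit-norm, mutually orthogonal planted modes, free of rigid-body content."""
    n_res = mean.shape[0]
    per_chain = n_res // 2
    z = mean[:, 2]
    ramp = (z - z.min()) / (z.max() - z.min())  # 0 at the CTD vertex, 1 at the NTD tips

    open_close = np.zeros((n_res, 3))
    open_close[:per_chain, 0] = -ramp[:per_chain]  # chain A swings toward -x
    open_close[per_chain:, 0] = +ramp[per_chain:]  # chain B toward +x: positive = opening

    twist = np.zeros((n_res, 3))
    tangent = np.cross([0.0, 0.0, 1.0], mean - mean.mean(axis=0))
    twist[:per_chain] = tangent[:per_chain]
    twist[per_chain:] = -tangent[per_chain:]

    rigid = _rigid_basis(mean)
    vectors: dict[str, np.ndarray] = {}
    for name, raw in (("open_close", open_close.ravel()), ("twist", twist.ravel())):
        v = raw - rigid @ (rigid.T @ raw)
        for prev in vectors.values():
            v = v - prev * (prev @ v)
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            raise SyntheticSpecError(f"mode {name!r} vanished after rigid-body projection")
        vectors[name] = v / norm
    return vectors


def _connectivity_check(coords: np.ndarray, spec: SyntheticSpec) -> None:
    from scipy.spatial.distance import cdist

    per_chain = 3 * spec.n_res_per_domain
    for c, label in enumerate("AB"):
        arm = coords[c * per_chain : (c + 1) * per_chain]
        step = np.linalg.norm(np.diff(arm, axis=0), axis=1)
        if np.any(step > RIN_CUTOFF):
            raise SyntheticSpecError(
                f"chain {label} consecutive-residue distance {step.max():.2f} Å exceeds "
                f"the {RIN_CUTOFF} Å network cutoff; the residue network would disconnect"
            )
    n = spec.n_res_per_domain
    ctd_a = coords[2 * n : 3 * n]
    ctd_b = coords[per_chain + 2 * n : per_chain + 3 * n]
    if cdist(ctd_a, ctd_b).min() > RIN_CUTOFF:
        raise SyntheticSpecError("CTD–CTD interface is not within the network cutoff")


def _protein_meta(spec: SyntheticSpec) -> pd.DataFrame:
    n_res = spec.n_residues
    per_chain = n_res // 2
    return pd.DataFrame(
        {
            "residue_index": np.arange(n_res),
            "residue_name": ["ALA"] * n_res,
            "chain_id": ["A"] * per_chain + ["B"] * per_chain,
            "atom_name": ["CA"] * n_res,
        },
        columns=list(ATOM_META_COLUMNS),
    )


def build_toy_dimer(spec: SyntheticSpec) -> tuple[TrajectoryEnsemble, dict[int, str]]:
    """Mean structure of the v-shaped dimer plus its residue → domain map."""
    spec.validate()
    coords = _mean_geometry(spec)
    _connectivity_check(coords, spec)
    ens = TrajectoryEnsemble(coords[None, :, :], _protein_meta(spec), spec.frame_interval_ps)
    return ens, _domain_map(spec)


def _ligand_template(lig: LigandSpec) -> np.ndarray:
    """Deterministic compact cluster: points on a small spiral, 1.5 Å spacing."""
    t = np.arange(lig.n_atoms, dtype=float)
    return np.column_stack(
        [1.2 * np.cos(2.1 * t), 1.2 * np.sin(2.1 * t), 0.6 * (t - t.mean())]
    )


def generate_trajectory(spec: SyntheticSpec) -> tuple[TrajectoryEnsemble, PlantedTruth]:
    """Generate a seeded trajectory and the exact ground truth planted in it.

    Frame ``t`` of the protein part is
    ``mean + Σ_m (bias_m + a_m · sin(2π c_m t / F)) · v_m + ε_t`` with unit-norm
    mode vectors ``v_m``, whole-cycle counts ``c_m`` and i.i.d. Gaussian noise;
    contact-plan partners are then placed at an exact distance from their pair
    residue in a seeded choice of exactly ``round(fraction × F)`` frames.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mean = _mean_geometry(spec)
    _connectivity_check(mean, spec)
    domain_map = _domain_map(spec)
    modes = _mode_vectors(spec, mean)
    sigma = _sigma_profile(spec)
    n_res, n_frames = spec.n_residues, spec.n_frames

    t = np.arange(n_frames)
    coords = np.broadcast_to(mean, (n_frames, n_res, 3)).copy()
    for name, vec in modes.items():
        a = float(spec.mode_amplitudes.get(name, 0.0))
        b = float(spec.mode_bias.get(name, 0.0))
        if a == 0.0 and b == 0.0:
            continue
        score = b + a * np.sin(2.0 * np.pi * _MODE_CYCLES[name] * t / n_frames)
        coords += score[:, None, None] * vec.reshape(1, n_res, 3)
    coords += rng.standard_normal((n_frames, n_res, 3)) * sigma[None, :, None]

    contact_truth: dict[tuple[int, int], float] = {}
    for (i, j), frac in spec.contact_plan.items():
        k = int(round(frac * n_frames))
        in_contact = np.zeros(n_frames, dtype=bool)
        in_contact[rng.permutation(n_frames)[:k]] = True
        direction = mean[j] - mean[i]
        direction /= np.linalg.norm(direction)
        dist = np.where(in_contact, _CONTACT_IN, _CONTACT_OUT)
        coords[:, j, :] = coords[:, i, :] + dist[:, None] * direction[None, :]
        contact_truth[(min(i, j), max(i, j))] = k / n_frames

    meta = _protein_meta(spec)
    if spec.ligand is not None:
        lig = spec.ligand
        if not 0 <= lig.anchor_residue < n_res:
            raise SyntheticSpecError(f"ligand anchor {lig.anchor_residue} outside residue range")
        outward = mean[lig.anchor_residue] - mean.mean(axis=0)
        outward /= np.linalg.norm(outward)
        template = _ligand_template(lig) + lig.offset * outward
        lig_coords = (
            coords[:, lig.anchor_residue, None, :]
            + template[None, :, :]
            + rng.standard_normal((n_frames, 1, 3)) * lig.noise_sigma
        )
        coords = np.concatenate([coords, lig_coords], axis=1)
        lig_meta = pd.DataFrame(
            {
                "residue_index": [n_res] * lig.n_atoms,
                "residue_name": ["LIG"] * lig.n_atoms,
                "chain_id": ["L"] * lig.n_atoms,
                "atom_name": [f"C{i + 1}" for i in range(lig.n_atoms)],
            },
            columns=list(ATOM_META_COLUMNS),
        )
        meta = pd.concat([meta, lig_meta], ignore_index=True)

    ens = TrajectoryEnsemble(coords, meta, spec.frame_interval_ps)
    truth = PlantedTruth(
        mode_vectors=modes,
        expected_rmsf=sigma * np.sqrt(3.0),
        contact_truth=contact_truth,
        com_distance_params=_com_distance_params(spec, mean, modes, domain_map),
        domain_map=domain_map,
    )
    return ens, truth


def _com_distance_params(spec, mean, modes, domain_map) -> dict[str, float]:
    """Exact planted mean/amplitude of the NTD(A)–NTD(B) centre-of-mass distance."""
    n_res = mean.shape[0]
    idx = np.arange(n_res)
    ntd_a = idx[(idx < n_res // 2) & np.array([domain_map[i] == "NTD" for i in idx])]
    ntd_b = idx[(idx >= n_res // 2) & np.array([domain_map[i] == "NTD" for i in idx])]
    com_a, com_b = mean[ntd_a].mean(axis=0), mean[ntd_b].mean(axis=0)
    sep = com_a - com_b
    d0 = float(np.linalg.norm(sep))
    unit = sep / d0
    v = modes["open_close"].reshape(n_res, 3)
    per_unit_score = float((v[ntd_a].mean(axis=0) - v[ntd_b].mean(axis=0)) @ unit)
    a = float(spec.mode_amplitudes.get("open_close", 0.0))
    b = float(spec.mode_bias.get("open_close", 0.0))
    return {
        "mean": d0 + b * per_unit_score,
        "amplitude": abs(a * per_unit_score),
        "distance_per_unit_score": per_unit_score,
    }


# ---------------------------------------------------------------------------
# named study scenarios
# ---------------------------------------------------------------------------


def scenario_free(n_frames: int = 500, seed: int = 0) -> SyntheticSpec:
    """Ligand-free reference: default amplitudes and isotropic noise."""
    return SyntheticSpec(n_frames=n_frames, seed=seed)


def scenario_activator(n_frames: int = 500, seed: int = 1) -> SyntheticSpec:
    """Allosteric-activator signature: closing bias, doubled open/close
    amplitude and extra M-domain noise (more flexible, more closed)."""
    base = SyntheticSpec(n_frames=n_frames, seed=seed)
    sigma = _sigma_profile(base)
    for i, d in _domain_map(base).items():
        if d == "M":
            sigma[i] += 0.5
    return dataclasses.replace(
        base,
        mode_amplitudes={"open_close": 8.0, "twist": 2.0},
        mode_bias={"open_close": -4.0},
        noise_sigma=sigma,
        ligand=LigandSpec(anchor_residue=3 * base.n_res_per_domain - 1),
    )


def scenario_inhibitor(n_frames: int = 500, seed: int = 2) -> SyntheticSpec:
    """Allosteric-inhibitor signature: opening bias and quieter protomer-A NTD."""
    base = SyntheticSpec(n_frames=n_frames, seed=seed)
    sigma = _sigma_profile(base)
    per_chain = base.n_residues // 2
    for i, d in _domain_map(base).items():
        if d == "NTD" and i < per_chain:
            sigma[i] *= 0.5
    return dataclasses.replace(
        base,
        mode_bias={"open_close": +4.0},
        noise_sigma=sigma,
        ligand=LigandSpec(anchor_residue=3 * base.n_res_per_domain - 1),
    )


# ---------------------------------------------------------------------------
# serialization for the CLI
# ---------------------------------------------------------------------------


def spec_from_yaml(path: str | Path) -> SyntheticSpec:
    """Load a :class:`SyntheticSpec` from a YAML mapping.

    ``contact_plan`` entries are ``[i, j, fraction]`` triples; ``ligand`` is a
    mapping of :class:`LigandSpec` fields.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "contact_plan" in raw:
        raw["contact_plan"] = {
            (int(i), int(j)): float(f) for i, j, f in raw["contact_plan"]
        }
    if raw.get("ligand") is not None:
        raw["ligand"] = LigandSpec(**raw["ligand"])
    if isinstance(raw.get("noise_sigma"), list):
        raw["noise_sigma"] = np.asarray(raw["noise_sigma"], dtype=float)
    return SyntheticSpec(**raw)


def truth_to_json(truth: PlantedTruth, path: str | Path) -> Path:
    payload = {
        "mode_vectors": {k: v.tolist() for k, v in truth.mode_vectors.items()},
        "expected_rmsf": truth.expected_rmsf.tolist(),
        "contact_truth": [[i, j, f] for (i, j), f in truth.contact_truth.items()],
        "com_distance_params": truth.com_distance_params,
        "domain_map": {str(k): v for k, v in truth.domain_map.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))
    return Path(path)
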