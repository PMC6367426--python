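"""Coordinate-ensemble I/O and per-residue representative extraction.

Two on-disk dialects are supported: multi-model PDB (MODEL/ENDMDL delimits
frames) and a delimited plain-text coordinate table (columns ``frame,
atom_index, x, y, z`` with a sidecar atom-metadata TSV).  Coordinates are
Ångström internally; nanometre input is accepted via ``unit="nm"``.  Residues
are indexed 0-based internally and 1-based in every written table.

The frame spacing is not recoverable from a PDB file, so it is a caller-supplied
parameter (default 200 ps, the sampling interval used for network and contact
analyses).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryEnsemble",
    "ResidueFrameSet",
    "TrajectoryParseError",
    "RepresentativeAtomError",
    "SubsampleError",
    "read_trajectory",
    "write_trajectory",
    "select_representatives",
    "frame_set_from_coords",
    "subsample",
    "write_table",
    "write_vector",
    "write_matrix",
    "read_matrix",
]

ATOM_META_COLUMNS = ("residue_index", "residue_name", "chain_id", "atom_name")
#: representative-atom schemes: Cβ with Cα fallback (Cα for glycine), or plain Cα
SCHEMES = ("CB_or_CA_for_GLY", "CA")
DEFAULT_FRAME_INTERVAL_PS = 200.0


class TrajectoryParseError(ValueError):
    """Raised when an input file cannot be interpreted as a coordinate ensemble."""


class RepresentativeAtomError(ValueError):
    """Raised when a residue lacks the atoms required by the representative scheme."""


class SubsampleError(ValueError):
    """Raised when a requested sampling interval is not a multiple of the frame spacing."""


def _validate_coords(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError(f"coords must be (frames, atoms, 3), got {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates contain non-finite values")
    return coords


@dataclass
class TrajectoryEnsemble:
    """Frames × atoms × xyz coordinates (Å) with per-atom metadata.

    ``atom_meta`` is a DataFrame with columns ``residue_index`` (0-based,
    global across chains), ``residue_name``, ``chain_id`` and ``atom_name``;
    row *k* describes atom *k* of every frame.  All frames share one atom
    ordering.  ``frame_interval`` is the time between stored frames in ps.
    """

    coords: np.ndarray
    atom_meta: pd.DataFrame
    frame_interval: float = DEFAULT_FRAME_INTERVAL_PS

    def __post_init__(self) -> None:
        self.coords = _validate_coords(self.coords)
        if not isinstance(self.atom_meta, pd.DataFrame):
            self.atom_meta = pd.DataFrame(self.atom_meta)
        missing = set(ATOM_META_COLUMNS) - set(self.atom_meta.columns)
        if missing:
            raise ValueError(f"atom_meta missing columns: {sorted(missing)}")
        if len(self.atom_meta) != self.coords.shape[1]:
            raise ValueError(
                f"atom_meta has {len(self.atom_meta)} rows for {self.coords.shape[1]} atoms"
            )
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        self.atom_meta = self.atom_meta.reset_index(drop=True)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class ResidueFrameSet:
    """One representative coordinate per residue per frame.

    ``residue_meta`` columns: ``chain_id``, ``domain_label`` (NTD/M/CTD/other),
    ``residue_index`` (0-based global) and ``residue_name``.
    """

    coords: np.ndarray
    residue_meta: pd.DataFrame
    scheme: str = "CB_or_CA_for_GLY"
    frame_interval: float = DEFAULT_FRAME_INTERVAL_PS

    def __post_init__(self) -> None:
        self.coords = _validate_coords(self.coords)
        if len(self.residue_meta) != self.coords.shape[1]:
            raise ValueError("residue_meta rows must match residue count")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        self.residue_meta = self.residue_meta.reset_index(drop=True)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def indices(self, chain: str | None = None, domain: str | None = None) -> np.ndarray:
        """Residue positions matching an optional chain and/or domain label."""
        mask = np.ones(self.n_residues, dtype=bool)
        if chain is not None:
            mask &= (self.residue_meta["chain_id"] == chain).to_numpy()
        if domain is not None:
            mask &= (self.residue_meta["domain_label"] == domain).to_numpy()
        return np.flatnonzero(mask)

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------


def _pick_altloc(atom):
    """Deterministic altloc choice: highest occupancy, then first alphabetically."""
    if not atom.is_disordered():
        return atom
    children = atom.disordered_get_list()
    return sorted(children, key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()))[0]


def _read_pdb(path: Path, frame_interval: float) -> TrajectoryEnsemble:
    from Bio.PDB import PDBParser

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = PDBParser(QUIET=True).get_structure("traj", str(path))
    except ValueError as exc:
        raise TrajectoryParseError(f"{path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise TrajectoryParseError(f"{path}: no MODEL/ATOM records found")

    frames: list[np.ndarray] = []
    ref_identity: list[tuple] | None = None
    meta_rows: list[tuple] = []
    for model_no, model in enumerate(models, start=1):
        identity = []
        xyz = []
        for chain in model:
            for residue in chain:
                het, resseq, icode = residue.id
                for atom in residue:
                    atom = _pick_altloc(atom)
                    identity.append(
                        (chain.id, resseq, icode, residue.resname.strip(), atom.get_name())
                    )
                    xyz.append(atom.get_coord())
        if ref_identity is None:
            ref_identity = identity
            res_index: dict[tuple, int] = {}
            for cid, resseq, icode, resname, name in identity:
                key = (cid, resseq, icode)
                if key not in res_index:
                    res_index[key] = len(res_index)
                meta_rows.append((res_index[key], resname, cid, name))
        elif identity != ref_identity:
            raise TrajectoryParseError(
                f"{path}: model {model_no} atom records do not match model 1 "
                f"({len(identity)} atoms vs {len(ref_identity)})"
            )
        if not xyz:
            raise TrajectoryParseError(f"{path}: model {model_no} contains no atoms")
        # PDB stores 3 decimals; rounding recovers the written values exactly
        frames.append(np.asarray(xyz, dtype=float).round(3))

    meta = pd.DataFrame(meta_rows, columns=list(ATOM_META_COLUMNS))
    return TrajectoryEnsemble(np.stack(frames), meta, frame_interval)


def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.tsv")


def _read_coord_table(path: Path, frame_interval: float) -> TrajectoryEnsemble:
    table = pd.read_csv(path, sep="\t")
    required = {"frame", "atom_index", "x", "y", "z"}
    if table.empty or not required.issubset(table.columns):
        raise TrajectoryParseError(
            f"{path}: coordinate table needs non-empty columns {sorted(required)}"
        )
    meta = pd.read_csv(_meta_path(path), sep="\t")
    n_atoms = len(meta)
    frames = sorted(table["frame"].unique())
    coords = np.empty((len(frames), n_atoms, 3))
    for fi, frame in enumerate(frames):
        sub = table[table["frame"] == frame].sort_values("atom_index")
        if len(sub) != n_atoms:
            raise TrajectoryParseError(
                f"{path}: frame {frame} has {len(sub)} atoms, expected {n_atoms}"
            )
        coords[fi] = sub[["x", "y", "z"]].to_numpy()
    return TrajectoryEnsemble(coords, meta[list(ATOM_META_COLUMNS)], frame_interval)


def read_trajectory(
    path: str | Path,
    format: str = "pdb_multimodel",
    frame_interval: float = DEFAULT_FRAME_INTERVAL_PS,
    unit: str = "angstrom",
) -> TrajectoryEnsemble:
    """Read a coordinate ensemble.

    Parameters
    ----------
    format
        ``"pdb_multimodel"`` or ``"coord_table"`` (TSV + sidecar metadata).
    frame_interval
        Picoseconds between stored frames; not recoverable from either format.
    unit
        ``"angstrom"`` (default) or ``"nm"``; nm input is converted to Å.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "pdb_multimodel":
        ens = _read_pdb(path, frame_interval)
    elif format == "coord_table":
        ens = _read_coord_table(path, frame_interval)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    if unit == "nm":
        ens = replace(ens, coords=ens.coords * 10.0)
    elif unit != "angstrom":
        raise ValueError(f"unknown unit {unit!r}")
    return ens


def _format_pdb_atom_name(name: str) -> str:
    # standard PDB column layout: 1-3 character names start in column 14
    return f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"


def write_trajectory(ens: TrajectoryEnsemble, path: str | Path, format: str = "pdb_multimodel") -> Path:
    """Write an ensemble in the named dialect; residue ids are 1-based on disk."""
    path = Path(path)
    if format == "pdb_multimodel":
        meta = ens.atom_meta
        with open(path, "w") as fh:
            for fi in range(ens.n_frames):
                fh.write(f"MODEL     {fi + 1:4d}\n")
                for ai in range(ens.n_atoms):
                    row = meta.iloc[ai]
                    x, y, z = ens.coords[fi, ai]
                    name = _format_pdb_atom_name(str(row["atom_name"]))
                    element = str(row["atom_name"])[:1]
                    fh.write(
                        f"ATOM  {ai + 1 if ai < 99999 else 99999:5d} {name} "
                        f"{str(row['residue_name'])[:3]:>3s} {str(row['chain_id'])[:1]:1s}"
                        f"{int(row['residue_index']) + 1:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                        f"          {element:>2s}\n"
                    )
                fh.write("ENDMDL\n")
            fh.write("END\n")
    elif format == "coord_table":
        n_f, n_a = ens.n_frames, ens.n_atoms
        table = pd.DataFrame(
            {
                "frame": np.repeat(np.arange(n_f), n_a),
                "atom_index": np.tile(np.arange(n_a), n_f),
                "x": ens.coords[:, :, 0].ravel(),
                "y": ens.coords[:, :, 1].ravel(),
                "z": ens.coords[:, :, 2].ravel(),
            }
        )
        table.to_csv(path, sep="\t", index=False, float_format="%.6f")
        meta = ens.atom_meta.copy()
        meta.insert(0, "atom_index", np.arange(n_a))
        meta.to_csv(_meta_path(path), sep="\t", index=False)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    return path


# ---------------------------------------------------------------------------
# representatives and subsampling
# ---------------------------------------------------------------------------


def select_representatives(
    ens: TrajectoryEnsemble,
    scheme: str = "CB_or_CA_for_GLY",
    domain_map: Mapping[int, str] | None = None,
    exclude_resnames: Sequence[str] = ("LIG", "HOH"),
) -> ResidueFrameSet:
    """Reduce an all-atom ensemble to one representative coordinate per residue.

    Under ``CB_or_CA_for_GLY`` the Cβ atom represents each residue with Cα used
    for glycine (and as fallback when Cβ is absent); under ``CA`` the Cα atom is
    required.  ``domain_map`` maps global residue index → domain label
    (``NTD``/``M``/``CTD``/``other``); unmapped residues get ``other``.
    Residues whose name is in ``exclude_resnames`` (ligand, solvent) are skipped.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    meta = ens.atom_meta
    rows = []
    atom_rows = []
    for res_idx, group in meta.groupby("residue_index", sort=True):
        resname = str(group["residue_name"].iloc[0])
        if resname in exclude_resnames:
            continue
        by_name = {str(n): i for n, i in zip(group["atom_name"], group.index)}
        if scheme == "CA":
            want = "CA"
            if want not in by_name:
                raise RepresentativeAtomError(
                    f"residue {resname} {int(res_idx) + 1} (chain {group['chain_id'].iloc[0]}) "
                    f"has no CA atom"
                )
        else:
            want = "CA" if resname == "GLY" else "CB"
            if want not in by_name:
                want = "CA"
            if want not in by_name:
                raise RepresentativeAtomError(
                    f"residue {resname} {int(res_idx) + 1} (chain {group['chain_id'].iloc[0]}) "
                    f"has neither CB nor CA"
                )
        atom_rows.append(by_name[want])
        label = "other" if domain_map is None else str(domain_map.get(int(res_idx), "other"))
        rows.append((str(group["chain_id"].iloc[0]), label, int(res_idx), resname))
    if not rows:
        raise RepresentativeAtomError("no residues left after exclusions")
    res_meta = pd.DataFrame(rows, columns=["chain_id", "domain_label", "residue_index", "residue_name"])
    coords = ens.coords[:, atom_rows, :]
    return ResidueFrameSet(coords, res_meta, scheme=scheme, frame_interval=ens.frame_interval)


def frame_set_from_coords(
    coords,
    chain_ids: Sequence[str] | None = None,
    domains: Sequence[str] | None = None,
    scheme: str = "CA",
    frame_interval: float = DEFAULT_FRAME_INTERVAL_PS,
) -> ResidueFrameSet:
    """Wrap raw (frames, residues, 3) coordinates as a :class:`ResidueFrameSet`.

    Convenient when per-residue coordinates come from somewhere other than an
    all-atom ensemble (a coordinate table, another toolkit, a simulation of
    representative beads).  Chain ids default to a single chain ``A`` and
    domain labels to ``other``.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    meta = pd.DataFrame(
        {
            "chain_id": list(chain_ids) if chain_ids is not None else ["A"] * n,
            "domain_label": list(domains) if domains is not None else ["other"] * n,
            "residue_index": np.arange(n),
            "residue_name": ["ALA"] * n,
        }
    )
    return ResidueFrameSet(coords, meta, scheme=scheme, frame_interval=frame_interval)


def subsample(ens, interval_ps: float):
    """Keep every (interval_ps / frame_interval)-th frame, first frame retained.

    Works on :class:`TrajectoryEnsemble` and :class:`ResidueFrameSet` alike.
    The interval must be an integer multiple of the stored frame spacing.
    """
    ratio = interval_ps / ens.frame_interval
    stride = round(ratio)
    if stride < 1 or abs(ratio - stride) > 1e-9:
        raise SubsampleError(
            f"interval {interval_ps} ps is not an integer multiple of the "
            f"frame spacing {ens.frame_interval} ps"
        )
    if stride == 1:
        return ens
    return dataclasses.replace(ens, coords=ens.coords[::stride], frame_interval=interval_ps)


# ---------------------------------------------------------------------------
# delimited analysis products
# ---------------------------------------------------------------------------


def _default_ids(n: int) -> list[str]:
    return [str(i + 1) for i in range(n)]  # 1-based on disk


def write_vector(values, path, ids=None, id_name="residue", value_name="value") -> Path:
    values = np.asarray(values)
    ids = _default_ids(len(values)) if ids is None else [str(i) for i in ids]
    pd.DataFrame({id_name: ids, value_name: values}).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )
    return Path(path)


def write_matrix(matrix, path, ids=None) -> Path:
    matrix = np.asarray(matrix)
    ids = _default_ids(matrix.shape[0]) if ids is None else [str(i) for i in ids]
    frame = pd.DataFrame(matrix, index=ids, columns=ids[: matrix.shape[1]])
    frame.to_csv(path, sep="\t", index_label="id", float_format="%.10g")
    return Path(path)


def read_matrix(path) -> tuple[list[str], np.ndarray]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return [str(i) for i in frame.index], frame.to_numpy(dtype=float)


def write_table(obj, path, ids=None) -> Path:
    """Serialize an analysis product as delimited text.

    Vectors become two-column tables, matrices a dense grid with 1-based id
    headers; DataFrames and objects exposing ``to_frame()`` pass through.
    """
    if hasattr(obj, "to_frame") and not isinstance(obj, (pd.Series, np.ndarray)):
        obj.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")
        return Path(path)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=False, float_format="%.8g")
        return Path(path)
    if isinstance(obj, Mapping):
        pd.DataFrame(obj).to_csv(path, sep="\t", index=False, float_format="%.8g")
        return Path(path)
    arr = np.asarray(obj)
    if arr.ndim == 1:
        return write_vector(arr, path, ids=ids)
    if arr.ndim == 2:
        return write_matrix(arr, path, ids=ids)
    raise TypeError(f"cannot serialize object of type {type(obj)!r} with ndim {arr.ndim}")
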