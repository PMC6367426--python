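"""End-to-end free-vs-bound comparison workflow.

``run_all`` sequences the full analysis for one ligand-free ensemble and any
number of ligand-bound ensembles: per-complex RMSD/RMSF and NTD–NTD distance
summaries, dynamic-residue-network averages (L, ΔL over time, BC), NTD:M
contact timelines with stable-contact sets, communication-propensity matrices
with the long-range fast-communication scan, and essential-dynamics variance
fractions; then the bound-vs-free difference products.

Difference conventions, also printed in every table header: ΔRMSF, ΔL and ΔBC
are bound − free; ΔCP is free − bound (positive = faster communication with
ligand).  Outputs are deterministic delimited text under
``out_dir/{geometry,drn,contacts,cp,ed}/`` plus a machine-readable
``manifest.json`` recording parameters and input digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import comm_propensity as cpmod
from . import contacts as contactsmod
from . import drn as drnmod
from . import essential_dynamics as edmod
from . import geometry as geom
from .trajectory_io import (
    ResidueFrameSet,
    read_trajectory,
    select_representatives,
    write_matrix,
    write_table,
    write_vector,
)

__all__ = ["TrajectoryInput", "RunConfig", "PipelineError", "run_all", "config_from_yaml"]

logger = logging.getLogger("allodyn.pipeline")


class PipelineError(RuntimeError):
    """Raised after the run when one or more stages failed."""


@dataclass(frozen=True)
class TrajectoryInput:
    label: str
    path: str
    format: str = "pdb_multimodel"


@dataclass
class RunConfig:
    """Inputs and parameters for one comparison run."""

    trajectories: list[TrajectoryInput]
    free_label: str
    out_dir: str
    domain_map: dict[int, str] = field(default_factory=dict)
    scheme: str = "CB_or_CA_for_GLY"
    frame_interval_ps: float = 200.0
    network_cutoff: float = drnmod.DEFAULT_CUTOFF
    network_interval_ps: float | None = None
    persistence_threshold: float = contactsmod.DEFAULT_PERSISTENCE
    ligand_cutoff: float = contactsmod.DEFAULT_LIGAND_CUTOFF
    cp_dist_floor: float = cpmod.DEFAULT_DIST_FLOOR
    cp_threshold: float | None = None  # None = sequence-neighbour auto baseline
    ed_skip_ps: float = edmod.DEFAULT_SKIP_INITIAL_PS
    seed: int = 0

    def validate(self) -> None:
        labels = [t.label for t in self.trajectories]
        if len(set(labels)) != len(labels):
            raise ValueError("trajectory labels must be unique")
        if labels.count(self.free_label) != 1 or self.free_label not in labels:
            raise ValueError(f"exactly one trajectory must carry the free label "
                             f"{self.free_label!r}; have {labels}")
        for t in self.trajectories:
            if not Path(t.path).exists():
                raise FileNotFoundError(f"trajectory {t.label!r}: {t.path} does not exist")


def config_from_yaml(path: str | Path) -> RunConfig:
    """Load a run configuration from YAML.

    ``trajectories`` is a list of ``{label, path, format}`` mappings;
    ``domain_map`` may be an inline ``{residue(1-based): domain}`` mapping or a
    path to a two-column TSV (``residue``, ``domain``).
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["trajectories"] = [TrajectoryInput(**t) for t in raw["trajectories"]]
    dm = raw.get("domain_map", {})
    if isinstance(dm, str):
        table = pd.read_csv(dm, sep="\t")
        raw["domain_map"] = {int(r) - 1: str(d) for r, d in
                             zip(table["residue"], table["domain"])}
    else:
        raw["domain_map"] = {int(k) - 1: str(v) for k, v in dm.items()}
    return RunConfig(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _residue_ids(rfs: ResidueFrameSet) -> list[str]:
    return [f"{c}:{int(r) + 1}" for c, r in
            zip(rfs.residue_meta["chain_id"], rfs.residue_meta["residue_index"])]


def _analyze_complex(label: str, ens, config: RunConfig, out: Path) -> dict:
    result: dict = {"label": label}
    rfs = select_representatives(ens, config.scheme, config.domain_map)
    rfs_ca = select_representatives(ens, "CA", config.domain_map)
    ids = _residue_ids(rfs)
    result["rfs"] = rfs

    # geometry
    rmsd = geom.rmsd_series(rfs)
    result["rmsd"] = rmsd
    write_table(rmsd, out / "geometry" / f"{label}.rmsd.tsv")
    result["rmsf"] = geom.rmsf(rfs)
    write_vector(result["rmsf"], out / "geometry" / f"{label}.rmsf.tsv",
                 ids=ids, value_name="rmsf_A")
    ntd_a = rfs.indices(chain="A", domain="NTD")
    ntd_b = rfs.indices(chain="B", domain="NTD")
    if ntd_a.size and ntd_b.size:
        comdist = geom.com_distance_series(rfs, ntd_a, ntd_b)
        result["ntd_distance"] = comdist
        write_table(comdist, out / "geometry" / f"{label}.ntd_distance.tsv")

    # dynamic residue network
    drn = drnmod.build_drn(rfs, config.network_cutoff, config.network_interval_ps)
    profile, bc_mean = drnmod.average_over_drn(drn)
    result["L_mean"], result["deltaL_time"], result["bc_mean"] = (
        profile.L_mean, profile.deltaL_time, bc_mean)
    write_vector(profile.L_mean, out / "drn" / f"{label}.L.tsv", ids=ids, value_name="L_mean")
    write_vector(profile.deltaL_time, out / "drn" / f"{label}.deltaL_time.tsv",
                 ids=ids, value_name="deltaL_later_minus_first")
    write_vector(bc_mean, out / "drn" / f"{label}.bc.tsv", ids=ids, value_name="bc_mean")

    # inter-domain contacts per protomer
    stable: dict[str, list] = {}
    for chain in ("A", "B"):
        ntd = rfs.indices(chain=chain, domain="NTD")
        mdom = rfs.indices(chain=chain, domain="M")
        if not (ntd.size and mdom.size):
            continue
        tl = contactsmod.contact_timeline(rfs, ntd, mdom, config.network_cutoff,
                                          config.network_interval_ps)
        stable[chain] = contactsmod.persistence_filter(tl, config.persistence_threshold)
        write_table(tl, out / "contacts" / f"{label}.ntd_m.{chain}.tsv")
    result["stable_contacts"] = stable
    if (ens.atom_meta["residue_name"] == "LIG").any():
        lig_tl = contactsmod.ligand_contact_timeline(ens, cutoff=config.ligand_cutoff)
        result["ligand_contacts"] = lig_tl
        write_table(lig_tl, out / "contacts" / f"{label}.ligand.tsv")

    # communication propensity
    cpm = cpmod.cp_matrix(rfs_ca)
    result["cp"] = cpm
    write_matrix(cpm.cp, out / "cp" / f"{label}.cp.tsv", ids=ids)
    fast = cpmod.fast_comm_fraction(cpm, config.cp_threshold, config.cp_dist_floor)
    result["fast_comm"] = fast
    write_vector(fast.fraction, out / "cp" / f"{label}.fast_comm.tsv",
                 ids=ids, value_name="fast_fraction")

    # essential dynamics
    modes = edmod.fit_modes(rfs_ca, skip_initial_ps=config.ed_skip_ps)
    result["modes"] = modes
    result["ed_cumvar3"] = edmod.variance_fractions(modes, 3)
    write_vector(modes.eigvals[:20], out / "ed" / f"{label}.eigvals.tsv",
                 ids=[str(i + 1) for i in range(min(20, modes.eigvals.size))],
                 id_name="mode", value_name="eigval_A2")
    return result


def _compare(bound: dict, free: dict, out: Path, label: str, ids) -> dict:
    delta: dict = {}
    delta["delta_rmsf"] = geom.delta_rmsf(bound["rmsf"], free["rmsf"])
    write_vector(delta["delta_rmsf"], out / "geometry" / f"{label}.delta_rmsf.tsv",
                 ids=ids, value_name="delta_rmsf_bound_minus_free_A")
    dL, dBC = drnmod.delta_between((bound["L_mean"], bound["bc_mean"]),
                                   (free["L_mean"], free["bc_mean"]))
    delta["delta_L"], delta["delta_bc"] = dL, dBC
    write_vector(dL, out / "drn" / f"{label}.delta_L.tsv", ids=ids,
                 value_name="delta_L_bound_minus_free")
    write_vector(dBC, out / "drn" / f"{label}.delta_bc.tsv", ids=ids,
                 value_name="delta_bc_bound_minus_free")
    delta["delta_cp"] = cpmod.delta_cp(free["cp"], bound["cp"])
    write_matrix(delta["delta_cp"], out / "cp" / f"{label}.delta_cp.tsv", ids=ids)
    return delta


def run_all(config: RunConfig) -> dict:
    """Run the full comparison workflow; returns the in-memory report.

    Stage failures are logged, remaining independent stages still run, and a
    :class:`PipelineError` is raised at the end naming the failed stages.
    """
    config.validate()
    out = Path(config.out_dir)
    for sub in ("geometry", "drn", "contacts", "cp", "ed"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    report: dict = {"complexes": {}, "deltas": {}, "failures": []}
    for traj in config.trajectories:
        try:
            logger.info("analyzing %s (%s)", traj.label, traj.path)
            ens = read_trajectory(traj.path, traj.format, config.frame_interval_ps)
            report["complexes"][traj.label] = _analyze_complex(traj.label, ens, config, out)
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            logger.exception("stage failed for %s", traj.label)
            report["failures"].append(f"{traj.label}: {exc}")

    free = report["complexes"].get(config.free_label)
    if free is not None:
        ids = _residue_ids(free["rfs"])
        for label, bound in report["complexes"].items():
            if label == config.free_label:
                continue
            try:
                report["deltas"][label] = _compare(bound, free, out, label, ids)
            except Exception as exc:  # noqa: BLE001
                logger.exception("comparison failed for %s", label)
                report["failures"].append(f"delta {label}: {exc}")
    else:
        report["failures"].append(f"free complex {config.free_label!r} unavailable")

    manifest = {
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "trajectories"
        },
        "inputs": {t.label: {"path": t.path, "format": t.format, "sha256": _sha256(t.path)}
                   for t in config.trajectories if Path(t.path).exists()},
        "conventions": {
            "delta_rmsf": "bound - free", "delta_L": "bound - free",
            "delta_bc": "bound - free", "delta_cp": "free - bound",
            "residue_ids": "chain:1-based",
        },
        "failures": report["failures"],
    }
    manifest["parameters"]["domain_map"] = {
        str(k + 1): v for k, v in config.domain_map.items()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    if report["failures"]:
        raise PipelineError("; ".join(report["failures"]))
    return report
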