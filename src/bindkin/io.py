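"""Readers and writers for the package's text formats.

PDB (single- and multi-model, via biotite), XYZ frames, reaction
coordinate trajectories as TSV with '#' metadata headers, free-energy
profiles, count tensors, and YAML run configs.  Every writer has a reader
that round-trips it at the stated precision, and results carry JSON
metadata sidecars for provenance.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .discretize import BinGrid, CountTensor
from .estimators.profile import FreeEnergyProfile
from .structure import StructureFrame, Trajectory
from .synthdata.langevin import BiasSpec, EnsembleTrajectory

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# PDB / XYZ
# ---------------------------------------------------------------------------

def _atoms_to_frame(atoms: bst.AtomArray) -> StructureFrame:
    return StructureFrame(
        names=atoms.atom_name,
        resnames=atoms.res_name,
        resids=atoms.res_id,
        chains=atoms.chain_id,
        elements=atoms.element,
        coords=atoms.coord,
        hetero=atoms.hetero,
    )


def _frame_to_atoms(frame: StructureFrame) -> bst.AtomArray:
    atoms = bst.AtomArray(frame.n_atoms)
    atoms.atom_name = frame.names
    atoms.res_name = frame.resnames
    atoms.res_id = frame.resids
    atoms.chain_id = frame.chains
    atoms.element = frame.elements
    atoms.hetero = frame.hetero
    atoms.coord = frame.coords.astype(np.float32)
    return atoms


def read_pdb(path) -> list[StructureFrame]:
    """Read a PDB file; one StructureFrame per MODEL (one for plain files)."""
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure()
    except Exception as exc:  # biotite raises several parse error types
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    if isinstance(stack, bst.AtomArray):
        return [_atoms_to_frame(stack)]
    return [_atoms_to_frame(stack[i]) for i in range(stack.stack_depth())]


def write_pdb(frames, path) -> None:
    """Write one frame (plain) or several (MODEL/ENDMDL) as standard PDB."""
    if isinstance(frames, StructureFrame):
        frames = [frames]
    arrays = [_frame_to_atoms(f) for f in frames]
    pdb = PDBFile()
    if len(arrays) == 1:
        pdb.set_structure(arrays[0])
    else:
        pdb.set_structure(bst.stack(arrays))
    pdb.write(str(path))


def read_pdb_trajectory(path) -> Trajectory:
    """Multi-model PDB as a Trajectory (first model is the topology)."""
    frames = read_pdb(path)
    return Trajectory(topology=frames[0], coords=np.stack([f.coords for f in frames]))


def write_xyz(coords: np.ndarray, path, symbols=None, comment: str = "") -> None:
    """Write (n_frames, n_atoms, 3) coordinates as concatenated XYZ frames."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_atoms = coords.shape[1]
    symbols = symbols if symbols is not None else ["C"] * n_atoms
    with open(path, "w") as fh:
        for f in range(coords.shape[0]):
            fh.write(f"{n_atoms}\n{comment} frame {f}\n")
            for s, (x, y, z) in zip(symbols, coords[f]):
                fh.write(f"{s} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path) -> tuple[np.ndarray, list[str]]:
    """Read concatenated XYZ frames → ((n_frames, n_atoms, 3), symbols)."""
    frames, symbols = [], []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        block = lines[i + 2 : i + 2 + n]
        sym, xyz = [], []
        for ln in block:
            parts = ln.split()
            sym.append(parts[0])
            xyz.append([float(p) for p in parts[1:4]])
        frames.append(xyz)
        symbols = sym
        i += 2 + n
    return np.asarray(frames, dtype=float), symbols


# ---------------------------------------------------------------------------
# reaction-coordinate trajectories (TSV with '#' metadata header)
# ---------------------------------------------------------------------------

def write_traj_tsv(traj: EnsembleTrajectory, path) -> None:
    """Columns time_ns, z_angstrom; header lines carry bias and seed."""
    with open(path, "w") as fh:
        if traj.bias.is_biased:
            fh.write(f"#bias center={traj.bias.center:g} k={traj.bias.k_umb:g}\n")
        if traj.seed is not None:
            fh.write(f"#seed {traj.seed}\n")
        if traj.label:
            fh.write(f"#label {traj.label}\n")
        fh.write(f"#dt_ns {traj.dt:g}\n")
        fh.write("time_ns\tz_angstrom\n")
        for t, z in zip(traj.time_ns, traj.z):
            fh.write(f"{t:.6f}\t{z:.6f}\n")


def read_traj_tsv(path) -> EnsembleTrajectory:
    """Inverse of write_traj_tsv.  A file without bias metadata is treated
    as unbiased (a notice would be logged by the CLI layer)."""
    bias = BiasSpec()
    seed = None
    label = ""
    dt = None
    zs, ts = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("bias"):
                    kv = dict(p.split("=") for p in body.split()[1:])
                    bias = BiasSpec(center=float(kv["center"]), k_umb=float(kv["k"]))
                elif body.startswith("seed"):
                    seed = int(body.split()[1])
                elif body.startswith("label"):
                    label = body.split(None, 1)[1]
                elif body.startswith("dt_ns"):
                    dt = float(body.split()[1])
                continue
            if line.startswith("time_ns"):
                continue
            t, z = line.split("\t")
            ts.append(float(t))
            zs.append(float(z))
    if not zs:
        raise ValueError(f"trajectory file {path} has an empty body")
    if dt is None:
        dt = ts[1] - ts[0] if len(ts) > 1 else 1.0
    return EnsembleTrajectory(np.asarray(zs), dt=dt, bias=bias, label=label, seed=seed)


# ---------------------------------------------------------------------------
# profiles / counts / matrices
# ---------------------------------------------------------------------------

def write_profile_tsv(profile: FreeEnergyProfile, path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"#reference {profile.reference}\n#kt_kcal_mol {profile.kt:g}\n")
        fh.write("z_center\tF_kcal_mol\terr_kcal_mol\n")
        err = profile.errors if profile.errors is not None else np.full_like(profile.values, np.nan)
        for z, f, e in zip(profile.centers, profile.values, err):
            fh.write(f"{z:.4f}\t{f:.6f}\t{e:.6f}\n")
    if metadata:
        write_metadata_sidecar(path, metadata)


def read_profile_tsv(path) -> FreeEnergyProfile:
    reference, kt = "bulk-mean-zero", 1.0
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#reference"):
                reference = line.split()[1]
            elif line.startswith("#kt_kcal_mol"):
                kt = float(line.split()[1])
            elif line and not line.startswith(("#", "z_center")):
                rows.append([float(x) for x in line.split("\t")])
    arr = np.asarray(rows)
    err = arr[:, 2]
    return FreeEnergyProfile(
        centers=arr[:, 0], values=arr[:, 1], kt=kt,
        errors=None if np.all(np.isnan(err)) else err, reference=reference,
    )


def write_counts(counts: CountTensor, path) -> None:
    """Sparse triplet TSV (ensemble, i, j, count) + JSON header sidecar."""
    with open(path, "w") as fh:
        fh.write("ensemble\ti\tj\tcount\n")
        for k in range(counts.n_ensembles):
            ii, jj = np.nonzero(counts.counts[k])
            for i, j in zip(ii, jj):
                fh.write(f"{k}\t{i}\t{j}\t{counts.counts[k, i, j]}\n")
    write_metadata_sidecar(path, {
        "edges": counts.grid.edges.tolist(),
        "lag_steps": counts.lag_steps,
        "dt_ns": counts.dt,
        "mode": counts.mode,
        "labels": counts.labels,
    })


def read_counts(path) -> CountTensor:
    meta = json.loads(Path(str(path) + ".json").read_text())
    grid = BinGrid(np.asarray(meta["edges"]))
    labels = meta["labels"]
    counts = np.zeros((len(labels), grid.n_bins, grid.n_bins), dtype=np.int64)
    with open(path) as fh:
        next(fh)
        for line in fh:
            k, i, j, c = (int(x) for x in line.split())
            counts[k, i, j] = c
    return CountTensor(counts, grid=grid, lag_steps=meta["lag_steps"],
                       dt=meta["dt_ns"], mode=meta["mode"], labels=labels)


def write_matrix_tsv(matrix: np.ndarray, path, metadata: dict | None = None) -> None:
    np.savetxt(path, np.asarray(matrix), delimiter="\t", fmt="%.10g")
    if metadata:
        write_metadata_sidecar(path, metadata)


def read_matrix_tsv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)


# ---------------------------------------------------------------------------
# run config + metadata
# ---------------------------------------------------------------------------

_KNOWN_SECTIONS = {
    "synthdata", "discretize", "estimators", "kinetics", "structure",
    "fingerprints", "seed", "output_dir",
}


@dataclass
class RunConfig:
    """Validated analysis configuration; unknown sections are rejected."""

    synthdata: dict = field(default_factory=dict)
    discretize: dict = field(default_factory=dict)
    estimators: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)
    structure: dict = field(default_factory=dict)
    fingerprints: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_SECTIONS
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(**raw)

    def resolved_copy(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def run_metadata(seed: int | None = None, **params) -> dict:
    return {
        "tool": "bindkin",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "parameters": params,
    }


def write_metadata_sidecar(artifact_path, metadata: dict) -> None:
    Path(str(artifact_path) + ".json").write_text(json.dumps(metadata, indent=2))
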