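"""Structural statistics over coordinate trajectories.

Kabsch superposition, RMSD/RMSF, dynamic cross-correlation of Cα
displacements, correlation-weighted residue communication networks with
shortest paths, and per-frame dihedral/distance monitors.  Units: Å and
degrees; residue numbers are 1-based as in PDB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class StructureFrame:
    """A single structure: parallel per-atom record arrays + coordinates."""

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chains: np.ndarray
    elements: np.ndarray
    coords: np.ndarray  # (n_atoms, 3) Å
    hetero: np.ndarray = field(default=None)

    def __post_init__(self):
        self.names = np.asarray(self.names, dtype="U6")
        self.resnames = np.asarray(self.resnames, dtype="U4")
        self.resids = np.asarray(self.resids, dtype=int)
        self.chains = np.asarray(self.chains, dtype="U2")
        self.elements = np.asarray(self.elements, dtype="U2")
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.names.size
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.hetero is None:
            self.hetero = np.zeros(n, dtype=bool)
        self.hetero = np.asarray(self.hetero, dtype=bool)
        keys = list(zip(self.chains, self.resids, self.names))
        if len(set(keys)) != n:
            raise ValueError("duplicate (chain, resid, atom name) records")

    @property
    def n_atoms(self) -> int:
        return self.names.size

    def atom_index(self, chain: str, resid: int, name: str) -> int:
        hit = np.flatnonzero(
            (self.chains == chain) & (self.resids == resid) & (self.names == name)
        )
        if hit.size != 1:
            raise KeyError(f"atom ({chain!r}, {resid}, {name!r}) not found")
        return int(hit[0])


@dataclass
class Trajectory:
    """A topology frame plus a stack of coordinate frames."""

    topology: StructureFrame
    coords: np.ndarray  # (n_frames, n_atoms, 3)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> StructureFrame:
        f = StructureFrame(
            self.topology.names, self.topology.resnames, self.topology.resids,
            self.topology.chains, self.topology.elements, self.coords[i],
            hetero=self.topology.hetero,
        )
        return f


# ----------------------------------------------------------------------
# selections
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionSpec:
    """Predicate over atom records; fields are ANDed, None means 'any'."""

    names: tuple[str, ...] | None = None
    resid_range: tuple[int, int] | None = None
    chain: str | None = None

    def mask(self, frame: StructureFrame) -> np.ndarray:
        m = np.ones(frame.n_atoms, dtype=bool)
        if self.names is not None:
            m &= np.isin(frame.names, self.names)
        if self.resid_range is not None:
            lo, hi = self.resid_range
            m &= (frame.resids >= lo) & (frame.resids <= hi)
        if self.chain is not None:
            m &= frame.chains == self.chain
        if not m.any():
            raise ValueError(f"selection {self} matches no atoms")
        return m


CALPHA = SelectionSpec(names=("CA",))
BACKBONE = SelectionSpec(names=BACKBONE_NAMES)


def parse_selection(text: str) -> SelectionSpec:
    """Parse the mini-grammar: clauses joined by 'and'.

    Clauses: ``name CA[,CB]``, ``resid 10:50`` (or ``resid 10``),
    ``chain A``, and the shortcuts ``calpha`` / ``backbone`` / ``all``.
    """
    names = None
    resid_range = None
    chain = None
    for clause in (c.strip() for c in text.split(" and ")):
        tok = clause.split()
        if clause == "all":
            continue
        elif clause == "calpha":
            names = ("CA",)
        elif clause == "backbone":
            names = BACKBONE_NAMES
        elif tok[0] == "name" and len(tok) == 2:
            names = tuple(tok[1].split(","))
        elif tok[0] == "resid" and len(tok) == 2:
            parts = tok[1].split(":")
            resid_range = (int(parts[0]), int(parts[-1]))
        elif tok[0] == "chain" and len(tok) == 2:
            chain = tok[1]
        else:
            raise ValueError(f"cannot parse selection clause {clause!r}")
    return SelectionSpec(names=names, resid_range=resid_range, chain=chain)


def _resolve(sel) -> SelectionSpec:
    if isinstance(sel, SelectionSpec):
        return sel
    if isinstance(sel, str):
        return parse_selection(sel)
    raise TypeError(f"cannot interpret selection {sel!r}")


# ----------------------------------------------------------------------
# superposition / RMSD / RMSF
# ----------------------------------------------------------------------

def _pair_selection(mobile: StructureFrame, reference: StructureFrame, sel) -> tuple[np.ndarray, np.ndarray]:
    sel = _resolve(sel)
    mi, ri = np.flatnonzero(sel.mask(mobile)), np.flatnonzero(sel.mask(reference))
    key = lambda f, idx: list(zip(f.chains[idx], f.resids[idx], f.names[idx]))  # noqa: E731
    mk, rk = key(mobile, mi), key(reference, ri)
    if mk != rk:
        unpaired = set(mk) ^ set(rk)
        raise ValueError(f"selections do not map 1:1; unpaired atoms: {sorted(unpaired)[:10]}")
    return mi, ri


def superpose_coords(mobile_xyz: np.ndarray, ref_xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of one coordinate set onto another.

    Returns (rotation matrix, translation, RMSD).  The rotation is proper
    (det = +1, Kabsch); apply as ``x @ R.T + t``.
    """
    mc, rc = mobile_xyz.mean(axis=0), ref_xyz.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_xyz - rc, mobile_xyz - mc)
    R = rot.as_matrix()
    t = rc - mc @ R.T
    resid = mobile_xyz @ R.T + t - ref_xyz
    rmsd = np.sqrt(np.mean(np.sum(resid**2, axis=1)))
    return R, t, float(rmsd)


def kabsch_superpose(
    mobile: StructureFrame, reference: StructureFrame, sel=BACKBONE
) -> tuple[StructureFrame, float]:
    """Superpose ``mobile`` onto ``reference`` over the selection.

    Returns the transformed copy of the whole mobile frame and the RMSD
    (Å) over the selection after fitting.
    """
    mi, ri = _pair_selection(mobile, reference, sel)
    R, t, rmsd = superpose_coords(mobile.coords[mi], reference.coords[ri])
    moved = StructureFrame(
        mobile.names, mobile.resnames, mobile.resids, mobile.chains,
        mobile.elements, mobile.coords @ R.T + t, hetero=mobile.hetero,
    )
    return moved, rmsd


def rmsd_series(traj: Trajectory, reference: StructureFrame, sel=BACKBONE) -> np.ndarray:
    """Per-frame RMSD (Å) to the reference after per-frame superposition."""
    mi, ri = _pair_selection(traj.topology, reference, sel)
    ref = reference.coords[ri]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, out[f] = superpose_coords(traj.coords[f][mi], ref)
    return out


def _superpose_stack(coords: np.ndarray, ref: np.ndarray) -> np.ndarray:
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        R, t, _ = superpose_coords(coords[f], ref)
        out[f] = coords[f] @ R.T + t
    return out


def aligned_coords(traj: Trajectory, sel=CALPHA, iterations: int = 2) -> np.ndarray:
    """Selection coordinates after iterative superposition to the mean.

    Pass 1 fits to the first frame; each further pass fits to the current
    mean structure (two passes by default).
    """
    sel = _resolve(sel)
    idx = np.flatnonzero(sel.mask(traj.topology))
    xyz = traj.coords[:, idx, :].copy()
    ref = xyz[0]
    for _ in range(max(1, iterations)):
        xyz = _superpose_stack(xyz, ref)
        ref = xyz.mean(axis=0)
    return xyz


def rmsf(traj: Trajectory, sel=CALPHA, iterations: int = 2, superpose: bool = True) -> np.ndarray:
    """Per-atom RMSF (Å): sqrt(⟨|r_i − ⟨r_i⟩|²⟩) after mean-structure fitting."""
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if superpose:
        xyz = aligned_coords(traj, sel, iterations)
    else:
        sel = _resolve(sel)
        xyz = traj.coords[:, sel.mask(traj.topology), :]
    dev = xyz - xyz.mean(axis=0)
    return np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))


# ----------------------------------------------------------------------
# dynamic cross-correlation
# ----------------------------------------------------------------------

def dccm(traj: Trajectory | np.ndarray, sel=CALPHA, superpose: bool = True,
         iterations: int = 2) -> np.ndarray:
    """Dynamic cross-correlation matrix of displacement vectors.

    c_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨Δr_i²⟩⟨Δr_j²⟩) with Δr the deviation from
    each atom's trajectory mean.  Accepts a Trajectory (selection applied,
    superposed first by default) or a raw (n_frames, n_atoms, 3) array of
    already-aligned coordinates.  Rows of zero-variance atoms are NaN.
    """
    if isinstance(traj, Trajectory):
        if traj.n_frames < 2:
            raise ValueError("DCCM needs at least 2 frames")
        xyz = aligned_coords(traj, sel, iterations) if superpose else \
            traj.coords[:, _resolve(sel).mask(traj.topology), :]
    else:
        xyz = np.asarray(traj, dtype=float)
        if xyz.ndim != 3 or xyz.shape[0] < 2:
            raise ValueError("need an (n_frames>=2, n_atoms, 3) array")
    dev = xyz - xyz.mean(axis=0)
    cov = np.einsum("fia,fja->ij", dev, dev) / dev.shape[0]
    var = np.diag(cov).copy()
    dead = var <= 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance atoms; rows set to NaN", stacklevel=2)
        var[dead] = np.nan
    c = cov / np.sqrt(np.outer(var, var))
    excess = np.nanmax(np.abs(c)) - 1.0
    if excess > 1e-12:
        raise FloatingPointError(f"correlation exceeds 1 by {excess:.3g}")
    c = np.clip(c, -1.0, 1.0)
    if not dead.any():
        np.fill_diagonal(c, 1.0)
    return c


# ----------------------------------------------------------------------
# communication networks
# ----------------------------------------------------------------------

def contact_map(traj: Trajectory, sel=CALPHA, cutoff: float = 8.0,
                min_fraction: float = 0.75) -> list[tuple[int, int]]:
    """Residue pairs (0-based positions within the selection) whose selected
    atoms stay within ``cutoff`` Å in at least ``min_fraction`` of frames."""
    idx = np.flatnonzero(_resolve(sel).mask(traj.topology))
    xyz = traj.coords[:, idx, :]
    d = np.linalg.norm(xyz[:, :, None, :] - xyz[:, None, :, :], axis=-1)
    frac = np.mean(d <= cutoff, axis=0)
    n = idx.size
    return [(i, j) for i in range(n) for j in range(i + 1, n) if frac[i, j] >= min_fraction]


def communication_network(
    corr: np.ndarray,
    contacts: list[tuple[int, int]],
    labels=None,
) -> nx.Graph:
    """Correlation-weighted graph: edges only between contacting pairs,
    weight w_ij = −log|c_ij| (|c| floored away from 0 and capped below 1).

    Undefined correlations (NaN rows from rigid atoms) are excluded rather
    than zero-filled.  Nodes are residue labels if given, else indices.
    """
    corr = np.asarray(corr, dtype=float)
    g = nx.Graph()
    n = corr.shape[0]
    name = (lambda i: labels[i]) if labels is not None else (lambda i: i)
    for i in range(n):
        g.add_node(name(i))
    for i, j in contacts:
        c = corr[i, j]
        if not np.isfinite(c):
            continue
        a = np.clip(abs(c), 1e-12, 1.0 - 1e-12)
        g.add_edge(name(i), name(j), weight=float(-np.log(a)), correlation=float(c))
    return g


def shortest_path(graph: nx.Graph, source, target) -> tuple[list, float]:
    """Minimum-total-weight communication path and its length."""
    try:
        path = nx.dijkstra_path(graph, source, target, weight="weight")
    except nx.NetworkXNoPath as exc:
        raise ValueError(f"no communication path from {source!r} to {target!r}") from exc
    length = nx.path_weight(graph, path, weight="weight")
    return path, float(length)


# ----------------------------------------------------------------------
# monitors
# ----------------------------------------------------------------------

def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral in degrees, IUPAC convention: cis = 0°, trans = 180°,
    value in (−180°, 180°].  Collinear mid-bond geometry returns NaN."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    nb1 = np.linalg.norm(b1)
    v = b0 - (b0 @ b1) / nb1**2 * b1
    w = b2 - (b2 @ b1) / nb1**2 * b1
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        return float("nan")
    x = v @ w
    y = np.cross(b1 / nb1, v) @ w
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang == -180.0 else float(ang)


def dihedral_series(traj: Trajectory, atoms: list[tuple[str, int, str]]) -> np.ndarray:
    """Per-frame dihedral (degrees) over four (chain, resid, name) atoms."""
    if len(atoms) != 4:
        raise ValueError("a dihedral needs exactly 4 atom specs")
    idx = [traj.topology.atom_index(*a) for a in atoms]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        c = traj.coords[f]
        out[f] = dihedral(c[idx[0]], c[idx[1]], c[idx[2]], c[idx[3]])
    return out


def distance_series(traj: Trajectory, a: tuple[str, int, str], b: tuple[str, int, str]) -> np.ndarray:
    """Per-frame Euclidean distance (Å) between two atoms."""
    i, j = traj.topology.atom_index(*a), traj.topology.atom_index(*b)
    return np.linalg.norm(traj.coords[:, i, :] - traj.coords[:, j, :], axis=1)
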