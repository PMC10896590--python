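"""Ligand–residue interaction fingerprints.

Per-snapshot geometric detectors for salt bridges, hydrogen bonds,
hydrophobic contacts and single-water bridges, aggregated into
per-residue occupancy probabilities (the radar-chart data shape).  All
cutoffs are customary literature defaults and are recorded in the output
metadata; a residue–type pair counts at most once per snapshot no matter
how many atom pairs satisfy the criterion.

Ligand chemistry is declared, not perceived: a small template maps ligand
atom names to formal charge, polarity and donor hydrogens.  The shipped
template describes the morphine-like toy ligand (protonated tertiary
amine, phenol hydroxyl, apolar ring carbons).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .structure import StructureFrame

INTERACTION_TYPES = ("salt_bridge", "hbond", "hydrophobic", "water_bridge")
WATER_RESNAMES = ("HOH", "WAT", "TIP3", "SOL")


@dataclass(frozen=True)
class LigandAtomType:
    """Declared chemistry of one ligand heavy atom."""

    charge: int = 0
    polar: bool = False
    apolar: bool = False
    acceptor: bool = False
    donor_h: str | None = None


#: template for the toy morphine-like ligand (resname MLG)
TOY_LIGAND_TEMPLATE: dict[str, LigandAtomType] = {
    "N1": LigandAtomType(charge=+1, polar=True, donor_h="HN1"),
    "O1": LigandAtomType(polar=True, acceptor=True, donor_h="HO1"),
    "C1": LigandAtomType(apolar=True),
    "C2": LigandAtomType(apolar=True),
}

# ---------------------------------------------------------------------------
# protein typing tables (standard atom names)
# ---------------------------------------------------------------------------

RESIDUE_NEGATIVE = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
RESIDUE_POSITIVE = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
HIS_POSITIVE_ATOMS = ("ND1", "NE2")

_SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}
_SIDECHAIN_DONORS = {
    "SER": (("OG", "HG"),), "THR": (("OG1", "HG1"),), "TYR": (("OH", "HH"),),
    "ASN": (("ND2", "HD21"), ("ND2", "HD22")),
    "GLN": (("NE2", "HE21"), ("NE2", "HE22")),
    "LYS": (("NZ", "HZ1"), ("NZ", "HZ2"), ("NZ", "HZ3")),
    "ARG": (("NE", "HE"), ("NH1", "HH11"), ("NH2", "HH21")),
    "TRP": (("NE1", "HE1"),), "HIS": (("ND1", "HD1"), ("NE2", "HE2")),
}
_BACKBONE_ACCEPTOR = "O"
_BACKBONE_DONOR = ("N", "H")

_APOLAR_NAMES = {
    "CB", "CG", "CG1", "CG2", "CD", "CD1", "CD2", "CE", "CE1", "CE2",
    "CE3", "CZ", "CZ2", "CZ3", "CH2", "SD", "SG",
}
# carbons bonded to polar/charged groups are not hydrophobic partners
_APOLAR_EXCLUDE = {
    "ASP": {"CG"}, "ASN": {"CG"}, "GLU": {"CD"}, "GLN": {"CD"},
    "ARG": {"CD", "CZ"}, "TYR": {"CZ"}, "LYS": {"CE"},
}


@dataclass
class FingerprintConfig:
    """Detector cutoffs and ligand chemistry declaration."""

    ligand_resname: str = "MLG"
    ligand_template: dict[str, LigandAtomType] = field(
        default_factory=lambda: dict(TOY_LIGAND_TEMPLATE)
    )
    salt_bridge_cutoff: float = 4.0   # Å, N–O between opposite charges
    hbond_cutoff: float = 3.5         # Å, donor–acceptor heavy atoms
    hbond_angle: float = 135.0        # degrees, D–H···A
    hydrophobic_cutoff: float = 4.5   # Å, apolar–apolar heavy atoms
    charged_his: tuple[int, ...] = () # resids declared as HIS(+)
    enabled: tuple[str, ...] = INTERACTION_TYPES

    def metadata(self) -> dict:
        return {
            "salt_bridge_cutoff": self.salt_bridge_cutoff,
            "hbond_cutoff": self.hbond_cutoff,
            "hbond_angle": self.hbond_angle,
            "hydrophobic_cutoff": self.hydrophobic_cutoff,
            "enabled": list(self.enabled),
        }


@dataclass(frozen=True)
class InteractionEvent:
    """One detected interaction in one snapshot."""

    snapshot: int
    residue: str           # e.g. "ASP10"
    itype: str
    atoms: tuple[str, ...]
    distance: float
    angle: float | None = None
    distance_only: bool = False


def _angle_deg(a, b, c) -> float:
    """Angle at vertex b (degrees)."""
    u, v = np.asarray(a) - np.asarray(b), np.asarray(c) - np.asarray(b)
    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


class _Partitioned:
    """Atom indices of one frame split into ligand / residues / waters."""

    def __init__(self, frame: StructureFrame, config: FingerprintConfig):
        self.frame = frame
        self.config = config
        res = frame.resnames
        self.lig = np.flatnonzero(res == config.ligand_resname)
        if self.lig.size == 0:
            raise ValueError(f"no ligand atoms with resname {config.ligand_resname!r}")
        self.water = np.flatnonzero(np.isin(res, WATER_RESNAMES))
        other = np.setdiff1d(np.arange(frame.n_atoms), np.concatenate([self.lig, self.water]))
        self.residues: dict[str, np.ndarray] = {}
        for key in sorted(set(zip(frame.chains[other], frame.resids[other]))):
            m = other[(frame.chains[other] == key[0]) & (frame.resids[other] == key[1])]
            label = f"{frame.resnames[m][0]}{key[1]}"
            self.residues[label] = m
        # validate ligand annotation: every heavy atom must be declared
        heavy = [i for i in self.lig if frame.elements[i] != "H"]
        missing = [frame.names[i] for i in heavy if frame.names[i] not in config.ligand_template]
        if missing:
            raise ValueError(f"ligand atoms without template annotation: {missing}")

    def lig_atom(self, name: str) -> int | None:
        hit = self.lig[self.frame.names[self.lig] == name]
        return int(hit[0]) if hit.size else None


def _dist(frame, i, j) -> float:
    return float(np.linalg.norm(frame.coords[i] - frame.coords[j]))


def detect_salt_bridge(frame: StructureFrame, config: FingerprintConfig | None = None,
                       snapshot: int = 0) -> list[InteractionEvent]:
    """Opposite formal charges with any N–O (charged-group) pair ≤ cutoff."""
    config = config or FingerprintConfig()
    part = _Partitioned(frame, config)
    events = []
    lig_charged = [(n, t.charge) for n, t in config.ligand_template.items()
                   if t.charge != 0 and part.lig_atom(n) is not None]
    for label, idx in part.residues.items():
        resname = frame.resnames[idx[0]]
        resid = int(frame.resids[idx[0]])
        groups = []
        if resname in RESIDUE_NEGATIVE:
            groups.append((-1, RESIDUE_NEGATIVE[resname]))
        if resname in RESIDUE_POSITIVE:
            groups.append((+1, RESIDUE_POSITIVE[resname]))
        if resname == "HIS" and resid in config.charged_his:
            groups.append((+1, HIS_POSITIVE_ATOMS))
        best = None
        for lname, lcharge in lig_charged:
            li = part.lig_atom(lname)
            for rcharge, atom_names in groups:
                if lcharge * rcharge >= 0:
                    continue
                for an in atom_names:
                    hit = idx[frame.names[idx] == an]
                    if hit.size == 0:
                        continue
                    d = _dist(frame, li, int(hit[0]))
                    if d <= config.salt_bridge_cutoff and (best is None or d < best[0]):
                        best = (d, (lname, an))
        if best:
            events.append(InteractionEvent(snapshot, label, "salt_bridge", best[1], best[0]))
    return events


def _residue_acceptors(frame, idx, resname):
    names = frame.names[idx]
    wanted = set(_SIDECHAIN_ACCEPTORS.get(resname, ())) | {_BACKBONE_ACCEPTOR}
    return [int(i) for i, n in zip(idx, names) if n in wanted]


def _residue_donors(frame, idx, resname):
    names = list(frame.names[idx])
    pairs = list(_SIDECHAIN_DONORS.get(resname, ())) + [_BACKBONE_DONOR]
    out = []
    for heavy, hyd in pairs:
        if heavy in names:
            hi = idx[names.index(hyd)] if hyd in names else None
            out.append((int(idx[names.index(heavy)]), int(hi) if hi is not None else None))
    return out


def detect_hbond(frame: StructureFrame, config: FingerprintConfig | None = None,
                 snapshot: int = 0) -> list[InteractionEvent]:
    """Donor–acceptor heavy atoms ≤ cutoff with D–H···A ≥ angle cutoff.

    When the donor hydrogen is absent the pair is scored on distance only
    and the event is flagged ``distance_only``.  Waters are handled by the
    water-bridge detector, not here.
    """
    config = config or FingerprintConfig()
    part = _Partitioned(frame, config)
    lig_donors = []
    for n, t in config.ligand_template.items():
        li = part.lig_atom(n)
        if li is None or t.donor_h is None:
            continue
        lig_donors.append((li, part.lig_atom(t.donor_h)))
    lig_acceptors = [part.lig_atom(n) for n, t in config.ligand_template.items()
                     if t.acceptor and part.lig_atom(n) is not None]
    events = []
    for label, idx in part.residues.items():
        resname = frame.resnames[idx[0]]
        best = None
        cands = [(d, h, a) for d, h in lig_donors for a in _residue_acceptors(frame, idx, resname)]
        cands += [(d, h, a) for d, h in _residue_donors(frame, idx, resname) for a in lig_acceptors]
        for di, hi, ai in cands:
            d = _dist(frame, di, ai)
            if d > config.hbond_cutoff:
                continue
            if hi is not None:
                ang = _angle_deg(frame.coords[di], frame.coords[hi], frame.coords[ai])
                if ang < config.hbond_angle:
                    continue
            else:
                ang = None
            if best is None or d < best[0]:
                best = (d, ang, (frame.names[di], frame.names[ai]), hi is None)
        if best:
            events.append(InteractionEvent(snapshot, label, "hbond", best[2], best[0],
                                           angle=best[1], distance_only=best[3]))
    return events


def detect_hydrophobic(frame: StructureFrame, config: FingerprintConfig | None = None,
                       snapshot: int = 0) -> list[InteractionEvent]:
    """Apolar–apolar heavy-atom pair ≤ cutoff (both atoms must be apolar)."""
    config = config or FingerprintConfig()
    part = _Partitioned(frame, config)
    lig_apolar = [part.lig_atom(n) for n, t in config.ligand_template.items()
                  if t.apolar and part.lig_atom(n) is not None]
    events = []
    for label, idx in part.residues.items():
        resname = frame.resnames[idx[0]]
        allowed = _APOLAR_NAMES - _APOLAR_EXCLUDE.get(resname, set())
        res_apolar = [int(i) for i in idx if frame.names[i] in allowed]
        best = None
        for li in lig_apolar:
            for ri in res_apolar:
                d = _dist(frame, li, ri)
                if d <= config.hydrophobic_cutoff and (best is None or d < best[0]):
                    best = (d, (frame.names[li], frame.names[ri]))
        if best:
            events.append(InteractionEvent(snapshot, label, "hydrophobic", best[1], best[0]))
    return events


def detect_water_bridge(frame: StructureFrame, config: FingerprintConfig | None = None,
                        snapshot: int = 0) -> list[InteractionEvent]:
    """One water oxygen within H-bond distance of both a ligand polar atom
    and a residue polar atom (single-water bridges only)."""
    config = config or FingerprintConfig()
    part = _Partitioned(frame, config)
    lig_polar = [(n, part.lig_atom(n)) for n, t in config.ligand_template.items()
                 if t.polar and part.lig_atom(n) is not None]
    events = []
    waters = [int(i) for i in part.water if frame.elements[i] == "O"]
    for label, idx in part.residues.items():
        resname = frame.resnames[idx[0]]
        polar = set(_residue_acceptors(frame, idx, resname))
        polar |= {d for d, _ in _residue_donors(frame, idx, resname)}
        best = None
        for wi in waters:
            d_res = min((_dist(frame, wi, ri) for ri in polar), default=np.inf)
            if d_res > config.hbond_cutoff:
                continue
            for lname, li in lig_polar:
                d_lig = _dist(frame, wi, li)
                if d_lig <= config.hbond_cutoff:
                    key = max(d_lig, d_res)
                    if best is None or key < best[0]:
                        wlabel = f"{frame.resnames[wi]}{frame.resids[wi]}"
                        best = (key, (lname, wlabel), d_lig)
        if best:
            events.append(InteractionEvent(snapshot, label, "water_bridge", best[1], best[0]))
    return events


_DETECTORS = {
    "salt_bridge": detect_salt_bridge,
    "hbond": detect_hbond,
    "hydrophobic": detect_hydrophobic,
    "water_bridge": detect_water_bridge,
}


@dataclass
class FingerprintTable:
    """Residue × interaction-type occupancy probabilities over snapshots."""

    table: pd.DataFrame   # columns: residue, type, probability, n_events
    n_snapshots: int
    metadata: dict = field(default_factory=dict)

    def probability(self, residue: str, itype: str) -> float:
        hit = self.table[(self.table.residue == residue) & (self.table.type == itype)]
        return float(hit.probability.iloc[0]) if len(hit) else 0.0


def fingerprint(frames, config: FingerprintConfig | None = None) -> FingerprintTable:
    """Run all enabled detectors over the snapshots and aggregate.

    probability(residue, type) = snapshots with ≥1 such event / n_snapshots.
    """
    config = config or FingerprintConfig()
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to fingerprint")
    counts: dict[tuple[str, str], int] = {}
    for s, frame in enumerate(frames):
        seen = set()
        for itype in config.enabled:
            for ev in _DETECTORS[itype](frame, config, snapshot=s):
                seen.add((ev.residue, ev.itype))
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {"residue": r, "type": t, "probability": c / len(frames), "n_events": c}
        for (r, t), c in sorted(counts.items())
    ]
    table = pd.DataFrame(rows, columns=["residue", "type", "probability", "n_events"])
    return FingerprintTable(table=table, n_snapshots=len(frames), metadata=config.metadata())


def neutral_ligand_template(template: dict[str, LigandAtomType] | None = None) -> dict:
    """The same ligand with its amine deprotonated (formal charges zeroed)."""
    template = template or TOY_LIGAND_TEMPLATE
    return {n: replace(t, charge=0) for n, t in template.items()}
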