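"""Toy receptor–ligand complexes with known interaction geometry.

Each preset is a minimal complex — a morphine-like toy ligand (resname
MLG: charged tertiary-amine nitrogen, phenol-like hydroxyl, apolar
carbons) surrounded by an aspartate, a serine, a leucine and one water —
built so that exactly one interaction detector fires (or none, for the
moved-apart negative variants).  Geometry is placed analytically, so the
truth table of each preset is known by construction.
"""

from __future__ import annotations

import math

import numpy as np

from ..structure import StructureFrame

#: distance (Å) of the ligand amine N to ASP OD1 per preset (default: far)
_D_SALT_DEFAULT = 8.0
#: distance (Å) of the ligand phenol O to SER OG per preset (default: far)
_D_HB_DEFAULT = 4.9
#: distance (Å) of ligand C2 to LEU CD1 per preset (default: far)
_D_PHOB_DEFAULT = 6.5

PRESETS = (
    "apart",
    "salt_bridge_close",
    "salt_bridge_far",
    "hbond_close",
    "hbond_bent",
    "hbond_far",
    "hydrophobic_close",
    "hydrophobic_far",
    "water_bridge",
    "water_bridge_far",
)

#: interaction type each preset is built to trigger (None = silent)
PRESET_TRUTH = {
    "apart": None,
    "salt_bridge_close": "salt_bridge",
    "salt_bridge_far": None,
    "hbond_close": "hbond",
    "hbond_bent": None,
    "hbond_far": None,
    "hydrophobic_close": "hydrophobic",
    "hydrophobic_far": None,
    "water_bridge": "water_bridge",
    "water_bridge_far": None,
}


def _place_hydrogen(donor, acceptor, dha_angle_deg: float, bond: float = 0.96):
    """Place H so that |D−H| = bond and the D–H···A angle is as requested.

    Triangle solution in the D–A plane: law of cosines gives |HA| from the
    requested angle at H, then the angle at D fixes the direction.
    """
    donor, acceptor = np.asarray(donor, float), np.asarray(acceptor, float)
    d = float(np.linalg.norm(acceptor - donor))
    phi = math.radians(dha_angle_deg)
    ha = bond * math.cos(phi) + math.sqrt(max(bond**2 * math.cos(phi) ** 2 - bond**2 + d**2, 0.0))
    cos_alpha = (bond**2 + d**2 - ha**2) / (2.0 * bond * d)
    alpha = math.acos(min(1.0, max(-1.0, cos_alpha)))
    u = (acceptor - donor) / d
    # any unit vector perpendicular to u (D-A never parallel to z here)
    w = np.cross(u, [0.0, 0.0, 1.0])
    w /= np.linalg.norm(w)
    return donor + bond * (math.cos(alpha) * u + math.sin(alpha) * w)


def make_toy_complex(layout: str) -> StructureFrame:
    """Build the named geometry preset as a single structure frame.

    Raises ``KeyError`` listing the available presets for unknown names.
    """
    if layout not in PRESETS:
        raise KeyError(f"unknown preset {layout!r}; available: {list(PRESETS)}")

    d_salt = _D_SALT_DEFAULT
    d_hb, hb_angle = _D_HB_DEFAULT, 165.0
    d_phob = _D_PHOB_DEFAULT
    water_xy = (0.0, -8.0)

    if layout == "salt_bridge_close":
        d_salt = 3.5
    elif layout == "salt_bridge_far":
        d_salt = 6.5
    elif layout == "hbond_close":
        d_hb, hb_angle = 2.9, 165.0
    elif layout == "hbond_bent":
        d_hb, hb_angle = 2.9, 90.0
    elif layout == "hbond_far":
        d_hb, hb_angle = 3.8, 170.0
    elif layout == "hydrophobic_close":
        d_phob = 4.0
    elif layout == "hydrophobic_far":
        d_phob = 5.5
    elif layout in ("water_bridge", "water_bridge_far"):
        d_hb = 5.5  # SER pulled to 5.5 Å: too far for a direct H-bond

    o1 = np.array([-3.6, 1.3, 0.0])
    og = np.array([o1[0] - d_hb, 1.3, 0.0])

    if layout == "water_bridge":
        # equidistant (2.8 Å) from ligand O1 and SER OG
        mid_x = 0.5 * (o1[0] + og[0])
        off = math.sqrt(max(2.8**2 - (0.5 * d_hb) ** 2, 0.0))
        water_xy = (mid_x, 1.3 + off)
    elif layout == "water_bridge_far":
        # 2.8 Å from the ligand side but 5 Å from the residue side
        water_xy = (o1[0] + 0.9, 1.3 + 2.65)
        # verify by construction below

    # ligand hydroxyl hydrogen: aimed at SER OG for the H-bond presets,
    # otherwise pointing away (+y)
    if layout in ("hbond_close", "hbond_bent", "hbond_far"):
        ho1 = _place_hydrogen(o1, og, hb_angle)
    else:
        ho1 = o1 + np.array([0.0, 0.96, 0.0])

    cd_y = 1.3 + d_phob

    records = [
        # (chain, resid, resname, name, element, hetero, x, y, z)
        ("L", 1, "MLG", "N1", "N", True, 0.0, 0.0, 0.0),
        ("L", 1, "MLG", "HN1", "H", True, 0.0, 0.0, -1.0),
        ("L", 1, "MLG", "C1", "C", True, -1.5, 0.0, 0.0),
        ("L", 1, "MLG", "C2", "C", True, -2.2, 1.3, 0.0),
        ("L", 1, "MLG", "O1", "O", True, *o1),
        ("L", 1, "MLG", "HO1", "H", True, *ho1),
        # ASP 10, carboxylate toward the ligand amine (+x side)
        ("A", 10, "ASP", "OD1", "O", False, d_salt, 0.0, 0.0),
        ("A", 10, "ASP", "CG", "C", False, d_salt + 1.3, 0.4, 0.0),
        ("A", 10, "ASP", "OD2", "O", False, d_salt + 1.7, 1.6, 0.0),
        ("A", 10, "ASP", "CB", "C", False, d_salt + 2.2, -0.8, 0.0),
        ("A", 10, "ASP", "CA", "C", False, d_salt + 3.6, -0.8, 0.0),
        ("A", 10, "ASP", "N", "N", False, d_salt + 4.3, -2.0, 0.0),
        ("A", 10, "ASP", "C", "C", False, d_salt + 4.4, 0.4, 0.0),
        ("A", 10, "ASP", "O", "O", False, d_salt + 5.5, 0.6, 0.0),
        # SER 20, hydroxyl toward the ligand phenol (−x side)
        ("A", 20, "SER", "OG", "O", False, *og),
        ("A", 20, "SER", "HG", "H", False, og[0] - 0.9, 1.0, 0.3),
        ("A", 20, "SER", "CB", "C", False, og[0] - 1.4, 1.8, 0.0),
        ("A", 20, "SER", "CA", "C", False, og[0] - 2.6, 0.9, 0.0),
        ("A", 20, "SER", "N", "N", False, og[0] - 3.4, 1.9, 0.0),
        ("A", 20, "SER", "C", "C", False, og[0] - 3.2, -0.5, 0.0),
        ("A", 20, "SER", "O", "O", False, og[0] - 4.2, -0.9, 0.0),
        # LEU 30, side chain toward ligand C2 (+y side)
        ("A", 30, "LEU", "CD1", "C", False, -2.2, cd_y, 0.0),
        ("A", 30, "LEU", "CD2", "C", False, -1.2, cd_y + 1.0, 0.0),
        ("A", 30, "LEU", "CG", "C", False, -2.8, cd_y + 1.2, 0.0),
        ("A", 30, "LEU", "CB", "C", False, -2.6, cd_y + 2.6, 0.0),
        ("A", 30, "LEU", "CA", "C", False, -3.8, cd_y + 3.4, 0.0),
        ("A", 30, "LEU", "N", "N", False, -4.9, cd_y + 2.9, 0.0),
        ("A", 30, "LEU", "C", "C", False, -3.9, cd_y + 4.9, 0.0),
        ("A", 30, "LEU", "O", "O", False, -3.0, cd_y + 5.5, 0.0),
        # one water
        ("W", 99, "HOH", "O", "O", False, water_xy[0], water_xy[1], 0.0),
    ]
    return StructureFrame(
        names=np.array([r[3] for r in records]),
        resnames=np.array([r[2] for r in records]),
        resids=np.array([r[1] for r in records]),
        chains=np.array([r[0] for r in records]),
        elements=np.array([r[4] for r in records]),
        coords=np.array([[r[6], r[7], r[8]] for r in records]),
        hetero=np.array([r[5] for r in records]),
    )
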