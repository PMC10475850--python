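"""Amino-acid topology: idealized side-chain templates and chi torsions.

Side chains are described in internal coordinates (bond, angle, torsion)
relative to already-placed atoms and materialized with the standard
natural-extension-reference-frame (NeRF) construction.  Torsions are either
fixed values or tied to a chi variable with an offset, so a side chain is a
pure function of its chi vector.  These templates drive the synthetic
conformer pools and the re-construction of designed side chains; they use
textbook ideal bond lengths and angles.
"""

from __future__ import annotations

import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Names treated as backbone when splitting residues into backbone/side chain.
BACKBONE_SET = frozenset(BACKBONE_ATOMS) | {"OXT", "H", "HN", "HA", "HA2"}


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, in [-180, 180)."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(y, x))
    return float(((ang + 180.0) % 360.0) - 180.0)


def nerf_place(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Place atom d given reference atoms a-b-c, with |c-d| = bond,
    angle(b,c,d) = angle_deg and torsion(a,b,c,d) = torsion_deg."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms in NeRF placement")
    n /= nn
    m = np.cross(n, bc)
    ang = np.radians(180.0 - angle_deg)
    tor = -np.radians(torsion_deg)
    d_local = bond * np.array([
        np.cos(ang),
        np.sin(ang) * np.cos(tor),
        np.sin(ang) * np.sin(tor),
    ])
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


# Template entry: (atom, torsion_ref, angle_ref, parent, bond, angle, spec)
# where spec is ("chi", index, offset_deg) or ("fix", torsion_deg).
# References name earlier atoms of the residue (backbone or side chain).
_T = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", "N", "CA", "CB", 1.417, 110.8, ("chi", 1, 0.0))],
    "CYS": [("SG", "N", "CA", "CB", 1.808, 113.8, ("chi", 1, 0.0))],
    "THR": [("OG1", "N", "CA", "CB", 1.433, 109.6, ("chi", 1, 0.0)),
            ("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, -120.0))],
    "VAL": [("CG1", "N", "CA", "CB", 1.527, 110.5, ("chi", 1, 0.0)),
            ("CG2", "N", "CA", "CB", 1.527, 110.5, ("chi", 1, -122.5))],
    "LEU": [("CG", "N", "CA", "CB", 1.530, 116.3, ("chi", 1, 0.0)),
            ("CD1", "CA", "CB", "CG", 1.524, 110.7, ("chi", 2, 0.0)),
            ("CD2", "CA", "CB", "CG", 1.525, 110.4, ("chi", 2, 122.5))],
    "ILE": [("CG1", "N", "CA", "CB", 1.530, 110.4, ("chi", 1, 0.0)),
            ("CG2", "N", "CA", "CB", 1.530, 110.5, ("chi", 1, -122.0)),
            ("CD1", "CA", "CB", "CG1", 1.513, 113.8, ("chi", 2, 0.0))],
    "MET": [("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
            ("SD", "CA", "CB", "CG", 1.803, 112.7, ("chi", 2, 0.0)),
            ("CE", "CB", "CG", "SD", 1.791, 100.9, ("chi", 3, 0.0))],
    "PRO": [("CG", "N", "CA", "CB", 1.495, 104.5, ("chi", 1, 0.0)),
            ("CD", "CA", "CB", "CG", 1.507, 106.1, ("chi", 2, 0.0))],
    "PHE": [("CG", "N", "CA", "CB", 1.502, 113.8, ("chi", 1, 0.0)),
            ("CD1", "CA", "CB", "CG", 1.391, 120.8, ("chi", 2, 0.0)),
            ("CD2", "CA", "CB", "CG", 1.391, 120.8, ("chi", 2, 180.0)),
            ("CE1", "CB", "CG", "CD1", 1.393, 120.8, ("fix", 180.0)),
            ("CE2", "CB", "CG", "CD2", 1.393, 120.8, ("fix", 180.0)),
            ("CZ", "CG", "CD1", "CE1", 1.390, 120.0, ("fix", 0.0))],
    "TYR": [("CG", "N", "CA", "CB", 1.502, 113.8, ("chi", 1, 0.0)),
            ("CD1", "CA", "CB", "CG", 1.391, 120.8, ("chi", 2, 0.0)),
            ("CD2", "CA", "CB", "CG", 1.391, 120.8, ("chi", 2, 180.0)),
            ("CE1", "CB", "CG", "CD1", 1.393, 120.8, ("fix", 180.0)),
            ("CE2", "CB", "CG", "CD2", 1.393, 120.8, ("fix", 180.0)),
            ("CZ", "CG", "CD1", "CE1", 1.390, 120.0, ("fix", 0.0)),
            ("OH", "CD1", "CE1", "CZ", 1.380, 120.0, ("fix", 180.0))],
    "TRP": [("CG", "N", "CA", "CB", 1.498, 113.6, ("chi", 1, 0.0)),
            ("CD1", "CA", "CB", "CG", 1.370, 127.0, ("chi", 2, 0.0)),
            ("CD2", "CA", "CB", "CG", 1.433, 126.6, ("chi", 2, 180.0)),
            ("NE1", "CB", "CG", "CD1", 1.380, 110.2, ("fix", 180.0)),
            ("CE2", "CB", "CG", "CD2", 1.410, 107.2, ("fix", 180.0)),
            ("CE3", "CD1", "CG", "CD2", 1.400, 133.9, ("fix", 180.0)),
            ("CZ2", "CG", "CD2", "CE2", 1.400, 122.4, ("fix", 180.0)),
            ("CZ3", "CG", "CD2", "CE3", 1.391, 118.6, ("fix", 180.0)),
            ("CH2", "CD2", "CE2", "CZ2", 1.372, 117.5, ("fix", 0.0))],
    "HIS": [("CG", "N", "CA", "CB", 1.490, 113.8, ("chi", 1, 0.0)),
            ("ND1", "CA", "CB", "CG", 1.380, 122.7, ("chi", 2, 0.0)),
            ("CD2", "CA", "CB", "CG", 1.360, 131.0, ("chi", 2, 180.0)),
            ("CE1", "CB", "CG", "ND1", 1.320, 109.0, ("fix", 180.0)),
            ("NE2", "CB", "CG", "CD2", 1.370, 107.0, ("fix", 180.0))],
    "ASP": [("CG", "N", "CA", "CB", 1.516, 112.6, ("chi", 1, 0.0)),
            ("OD1", "CA", "CB", "CG", 1.249, 118.4, ("chi", 2, 0.0)),
            ("OD2", "CA", "CB", "CG", 1.249, 118.4, ("chi", 2, 180.0))],
    "ASN": [("CG", "N", "CA", "CB", 1.516, 112.6, ("chi", 1, 0.0)),
            ("OD1", "CA", "CB", "CG", 1.231, 120.8, ("chi", 2, 0.0)),
            ("ND2", "CA", "CB", "CG", 1.328, 116.4, ("chi", 2, 180.0))],
    "GLU": [("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
            ("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi", 2, 0.0)),
            ("OE1", "CB", "CG", "CD", 1.249, 118.4, ("chi", 3, 0.0)),
            ("OE2", "CB", "CG", "CD", 1.249, 118.4, ("chi", 3, 180.0))],
    "GLN": [("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
            ("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi", 2, 0.0)),
            ("OE1", "CB", "CG", "CD", 1.231, 120.8, ("chi", 3, 0.0)),
            ("NE2", "CB", "CG", "CD", 1.328, 116.4, ("chi", 3, 180.0))],
    "LYS": [("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
            ("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi", 2, 0.0)),
            ("CE", "CB", "CG", "CD", 1.520, 111.3, ("chi", 3, 0.0)),
            ("NZ", "CG", "CD", "CE", 1.489, 111.7, ("chi", 4, 0.0))],
    "ARG": [("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
            ("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi", 2, 0.0)),
            ("NE", "CB", "CG", "CD", 1.460, 111.8, ("chi", 3, 0.0)),
            ("CZ", "CG", "CD", "NE", 1.330, 124.4, ("chi", 4, 0.0)),
            ("NH1", "CD", "NE", "CZ", 1.330, 120.0, ("fix", 0.0)),
            ("NH2", "CD", "NE", "CZ", 1.330, 120.0, ("fix", 180.0))],
}

#: Chi torsion definitions: quadruples of atom names, per residue.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "SER": [("N", "CA", "CB", "OG")],
    "CYS": [("N", "CA", "CB", "SG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
}

#: Torsion symmetry period (degrees) of the LAST chi angle for residues whose
#: terminal group is two-fold symmetric; other torsions have period 360.
CHI_SYMMETRY: dict[str, float] = {
    "ASP": 180.0, "GLU": 180.0, "PHE": 180.0, "TYR": 180.0,
}


def n_chi(res_name: str) -> int:
    return len(CHI_ATOMS.get(res_name, []))


def side_chain_atom_names(res_name: str) -> list[str]:
    """Heavy side-chain atom names in template order (CB first; HA1 for GLY)."""
    if res_name == "GLY":
        return ["HA1"]
    if res_name == "ALA":
        return ["CB"]
    return ["CB"] + [entry[0] for entry in _T[res_name]]


def build_side_chain(res_name: str, n, ca, c, chis=None) -> dict[str, np.ndarray]:
    """Construct idealized side-chain coordinates from backbone N/CA/C.

    Parameters
    ----------
    res_name : three-letter residue code.
    n, ca, c : backbone coordinates.
    chis : sequence of chi torsions in degrees (defaults to -60 each).

    Returns a dict atom name -> coordinates, including CB (HA1 for GLY).
    """
    res_name = res_name.upper()
    if res_name not in _T and res_name not in ("ALA", "GLY"):
        raise KeyError(f"no template for residue {res_name!r}")
    nchi = n_chi(res_name)
    if chis is None:
        chis = [-60.0] * nchi
    if len(chis) < nchi:
        raise ValueError(f"{res_name} needs {nchi} chi angles, got {len(chis)}")

    coords: dict[str, np.ndarray] = {"N": np.asarray(n, float),
                                     "CA": np.asarray(ca, float),
                                     "C": np.asarray(c, float)}
    # Beta carbon (or glycine's Halpha1) from an improper-like placement.
    beta_name = "HA1" if res_name == "GLY" else "CB"
    beta_bond = 1.090 if res_name == "GLY" else 1.530
    coords[beta_name] = nerf_place(coords["N"], coords["C"], coords["CA"],
                                   beta_bond, 110.1, 122.68)
    for atom, t_ref, a_ref, parent, bond, angle, spec in _T.get(res_name, []):
        if spec[0] == "chi":
            torsion = float(chis[spec[1] - 1]) + spec[2]
        else:
            torsion = spec[1]
        coords[atom] = nerf_place(coords[t_ref], coords[a_ref], coords[parent],
                                  bond, angle, torsion)
    out = {beta_name: coords[beta_name]}
    for atom, *_ in _T.get(res_name, []):
        out[atom] = coords[atom]
    return out


def measure_chis(atom_lookup, res_name: str) -> list[float]:
    """Measure chi torsions (degrees) from a coordinate lookup.

    ``atom_lookup`` maps atom names to coordinates; missing atoms yield NaN.
    """
    out = []
    for quad in CHI_ATOMS.get(res_name, []):
        try:
            pts = [atom_lookup[a] for a in quad]
        except KeyError:
            out.append(float("nan"))
            continue
        out.append(dihedral(*pts))
    return out
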