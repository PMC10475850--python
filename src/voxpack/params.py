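"""Force-field parameter records and atom typing.

The package ships a small self-consistent parameter table
(``data/atom_types.tsv``) covering the heavy atoms of the 20 standard amino
acids (plus glycine's Halpha1, which serves in the Cbeta frame role).  Each
atom type carries the Lennard-Jones well depth and radius, a partial charge,
a per-area solvation coefficient, and a van der Waals radius.  Typing is a
lookup on (residue name, atom name).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path


@dataclass(frozen=True)
class AtomTypeParams:
    """Per-atom-type force-field record.

    Attributes
    ----------
    type_name : str
        Identifier of the atom type.
    lj_epsilon : float
        Lennard-Jones well depth (kcal/mol, stored positive).
    lj_sigma : float
        Lennard-Jones radius (Angstrom).
    partial_charge : float
        Partial charge (elementary charges).
    solvation_sigma : float
        Solvation free energy per unit surface area (kcal/mol/A^2).
    vdw_radius : float
        Van der Waals radius (Angstrom).
    """

    type_name: str
    lj_epsilon: float
    lj_sigma: float
    partial_charge: float
    solvation_sigma: float
    vdw_radius: float

    def __post_init__(self):
        if self.lj_sigma <= 0:
            raise ValueError(f"lj_sigma must be positive for {self.type_name}")
        if self.vdw_radius <= 0:
            raise ValueError(f"vdw_radius must be positive for {self.type_name}")
        if self.lj_epsilon < 0:
            raise ValueError(f"lj_epsilon must be non-negative for {self.type_name}")


#: Backbone atom types shared by all residues.
_BACKBONE_TYPES = {"N": "NB", "CA": "CA1", "C": "CQ", "O": "OB", "OXT": "OC"}

#: Side-chain atom -> type, per residue (heavy atoms; HA1 for glycine).
RESIDUE_ATOM_TYPES: dict[str, dict[str, str]] = {
    "ALA": {"CB": "CH3"},
    "GLY": {"HA1": "HVR"},
    "SER": {"CB": "CH2", "OG": "OP"},
    "CYS": {"CB": "CH2", "SG": "SM"},
    "THR": {"CB": "CH1", "OG1": "OP", "CG2": "CH3"},
    "VAL": {"CB": "CH1", "CG1": "CH3", "CG2": "CH3"},
    "LEU": {"CB": "CH2", "CG": "CH1", "CD1": "CH3", "CD2": "CH3"},
    "ILE": {"CB": "CH1", "CG1": "CH2", "CG2": "CH3", "CD1": "CH3"},
    "MET": {"CB": "CH2", "CG": "CH2", "SD": "SM", "CE": "CH3"},
    "PRO": {"CB": "CH2", "CG": "CH2", "CD": "CH2"},
    "PHE": {"CB": "CH2", "CG": "CAR", "CD1": "CAR", "CD2": "CAR",
            "CE1": "CAR", "CE2": "CAR", "CZ": "CAR"},
    "TYR": {"CB": "CH2", "CG": "CAR", "CD1": "CAR", "CD2": "CAR",
            "CE1": "CAR", "CE2": "CAR", "CZ": "CRP", "OH": "OP"},
    "TRP": {"CB": "CH2", "CG": "CAR", "CD1": "CAR", "CD2": "CAR", "NE1": "NP",
            "CE2": "CRP", "CE3": "CAR", "CZ2": "CAR", "CZ3": "CAR", "CH2": "CAR"},
    "HIS": {"CB": "CH2", "CG": "CAR", "ND1": "NP", "CD2": "CAR",
            "CE1": "CRP", "NE2": "NP"},
    "ASP": {"CB": "CH2", "CG": "CQ", "OD1": "OC", "OD2": "OC"},
    "GLU": {"CB": "CH2", "CG": "CH2", "CD": "CQ", "OE1": "OC", "OE2": "OC"},
    "ASN": {"CB": "CH2", "CG": "CQ", "OD1": "OB", "ND2": "NP"},
    "GLN": {"CB": "CH2", "CG": "CH2", "CD": "CQ", "OE1": "OB", "NE2": "NP"},
    "LYS": {"CB": "CH2", "CG": "CH2", "CD": "CH2", "CE": "CH2", "NZ": "NC"},
    "ARG": {"CB": "CH2", "CG": "CH2", "CD": "CH2", "NE": "NC",
            "CZ": "CRP", "NH1": "NC", "NH2": "NC"},
}

STANDARD_AMINO_ACIDS = tuple(sorted(RESIDUE_ATOM_TYPES))

#: One-letter <-> three-letter codes.
ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}


class UnknownAtomError(KeyError):
    """Raised when an atom cannot be matched to the parameter table."""


class ParameterTable:
    """A collection of :class:`AtomTypeParams`, keyed by type name.

    Provides the (residue name, atom name) -> parameters lookup used to
    type structures and rotamer pools.
    """

    def __init__(self, types: dict[str, AtomTypeParams]):
        self.types = dict(types)
        payload = "\n".join(
            f"{t.type_name}\t{t.lj_epsilon}\t{t.lj_sigma}\t{t.partial_charge}"
            f"\t{t.solvation_sigma}\t{t.vdw_radius}"
            for t in sorted(self.types.values(), key=lambda t: t.type_name)
        )
        #: Stable digest of the table contents (stored in library metadata).
        self.digest = hashlib.sha256(payload.encode()).hexdigest()[:16]

    def __getitem__(self, type_name: str) -> AtomTypeParams:
        return self.types[type_name]

    def atom_params(self, res_name: str, atom_name: str) -> AtomTypeParams:
        """Look up parameters for an atom by residue and atom name."""
        res_name = res_name.upper()
        atom_name = atom_name.upper()
        if atom_name in _BACKBONE_TYPES:
            return self.types[_BACKBONE_TYPES[atom_name]]
        try:
            side = RESIDUE_ATOM_TYPES[res_name]
        except KeyError:
            raise UnknownAtomError(f"unknown residue {res_name!r}") from None
        try:
            return self.types[side[atom_name]]
        except KeyError:
            raise UnknownAtomError(
                f"atom {atom_name!r} of residue {res_name!r} not in parameter table"
            ) from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ParameterTable":
        """Load a table from TSV with columns: type_name, epsilon, sigma,
        charge, solv_sigma, vdw_radius."""
        types = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["type_name", "epsilon", "sigma", "charge",
                        "solv_sigma", "vdw_radius"]
            if header != expected:
                raise ValueError(f"bad parameter table header: {header}")
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, eps, sig, q, ssolv, rvdw = line.split("\t")
                types[name] = AtomTypeParams(
                    name, float(eps), float(sig), float(q),
                    float(ssolv), float(rvdw),
                )
        return cls(types)

    @classmethod
    def bundled(cls) -> "ParameterTable":
        """The parameter table shipped with the package."""
        ref = resources.files("voxpack.data").joinpath("atom_types.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)
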