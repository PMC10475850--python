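"""Typed protein structures and PDB input/output.

A :class:`TypedStructure` is an ordered list of residues whose atoms carry
references into a :class:`~voxpack.params.ParameterTable`.  PDB parsing and
writing are delegated to biotite; parsing keeps the highest-occupancy
altloc, rejects insertion codes, and uses the first model only.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from . import chem, geometry
from .params import AtomTypeParams, ParameterTable, UnknownAtomError, THREE_TO_ONE


class StructureError(ValueError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    params: AtomTypeParams

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coord.copy(), self.params)


@dataclass
class Residue:
    name: str
    seq_id: int          #: author numbering from the PDB (1-based)
    chain: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.name} {self.chain}:{self.seq_id} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def cbeta_role(self) -> Atom:
        """The atom filling the Cbeta frame role (HA1 for glycine)."""
        if self.name == "GLY":
            return self.atom("HA1")
        return self.atom("CB")

    def backbone_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name in chem.BACKBONE_SET]

    def side_chain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name not in chem.BACKBONE_SET]

    def coord_lookup(self) -> dict[str, np.ndarray]:
        return {a.name: a.coord for a in self.atoms}

    def copy(self) -> "Residue":
        return Residue(self.name, self.seq_id, self.chain,
                       [a.copy() for a in self.atoms])


class TypedStructure:
    """An ordered, force-field-typed single-chain structure."""

    def __init__(self, residues: list[Residue], table: ParameterTable):
        self.residues = residues
        self.table = table

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> Residue:
        return self.residues[i]

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.residues)

    def copy(self) -> "TypedStructure":
        return TypedStructure([r.copy() for r in self.residues], self.table)

    def all_atoms(self):
        """Yield (residue index, Atom) pairs in order."""
        for i, res in enumerate(self.residues):
            for a in res.atoms:
                yield i, a

    def atom_arrays(self):
        """Coordinates plus per-atom parameter arrays for vectorized scoring.

        Returns (coords (N,3), eps, sigma, charge, solv_sigma, vdw, res_index).
        """
        coords, eps, sig, q, ssolv, rv, ridx = [], [], [], [], [], [], []
        for i, a in self.all_atoms():
            coords.append(a.coord)
            p = a.params
            eps.append(p.lj_epsilon)
            sig.append(p.lj_sigma)
            q.append(p.partial_charge)
            ssolv.append(p.solvation_sigma)
            rv.append(p.vdw_radius)
            ridx.append(i)
        return (np.asarray(coords, float), np.asarray(eps), np.asarray(sig),
                np.asarray(q), np.asarray(ssolv), np.asarray(rv),
                np.asarray(ridx, dtype=int))

    # -- backbone dihedrals ------------------------------------------------

    def phi_psi(self, i: int) -> tuple[float, float]:
        """Backbone (phi, psi) in degrees for residue i.

        Raises StructureError at chain termini where the torsion is undefined.
        """
        if i <= 0 or i >= len(self.residues) - 1:
            raise StructureError(f"phi/psi undefined for terminal residue {i}")
        prev, cur, nxt = self.residues[i - 1], self.residues[i], self.residues[i + 1]
        phi = chem.dihedral(prev.atom("C").coord, cur.atom("N").coord,
                            cur.atom("CA").coord, cur.atom("C").coord)
        psi = chem.dihedral(cur.atom("N").coord, cur.atom("CA").coord,
                            cur.atom("C").coord, nxt.atom("N").coord)
        return phi, psi

    def interior_indices(self) -> list[int]:
        """Residue indices with defined (phi, psi): all but the termini."""
        return list(range(1, len(self.residues) - 1))

    # -- frame helpers -----------------------------------------------------

    def frame_atoms(self, i: int):
        """(CA, Cbeta-role, N) coordinates of residue i."""
        res = self.residues[i]
        return (res.atom("CA").coord, res.cbeta_role.coord, res.atom("N").coord)

    # -- biotite interop and PDB I/O ---------------------------------------

    def to_atom_array(self) -> bst.AtomArray:
        n = sum(len(r.atoms) for r in self.residues)
        arr = bst.AtomArray(n)
        k = 0
        for res in self.residues:
            for a in res.atoms:
                arr.coord[k] = a.coord
                arr.atom_name[k] = a.name
                arr.res_name[k] = res.name
                arr.res_id[k] = res.seq_id
                arr.chain_id[k] = res.chain
                arr.element[k] = a.element
                arr.hetero[k] = False
                k += 1
        return arr

    def write_pdb(self, path: str | Path) -> None:
        pdb = PDBFile()
        pdb.set_structure(self.to_atom_array())
        pdb.write(str(path))


def _element_of(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:1].isdigit():
        name = name[1:]
    for two in ("CL", "BR"):
        if name.upper().startswith(two):
            return two.capitalize()
    return name[:1].upper()


def structure_from_residue_dicts(residue_specs, table: ParameterTable,
                                 chain: str = "A") -> TypedStructure:
    """Build a TypedStructure from (res_name, seq_id, {atom: coord}) triples."""
    residues = []
    for res_name, seq_id, atom_coords in residue_specs:
        res = Residue(res_name, seq_id, chain)
        for name, coord in atom_coords.items():
            params = table.atom_params(res_name, name)
            res.atoms.append(Atom(name, _element_of(name),
                                  np.asarray(coord, float), params))
        residues.append(res)
    return TypedStructure(residues, table)


def read_structure(path: str | Path, table: ParameterTable | None = None,
                   permissive: bool = False) -> TypedStructure:
    """Read a PDB file into a typed structure.

    Parameters
    ----------
    path : PDB file with ATOM records; first model only.
    table : parameter table (defaults to the bundled one).
    permissive : if True, atoms that cannot be typed are dropped with a
        notice instead of raising.

    Raises
    ------
    StructureError
        If a residue misses a backbone atom (N, CA, C) or cannot be typed.
    """
    table = table or ParameterTable.bundled()
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1, altloc="occupancy")
    arr = arr[~arr.hetero]
    if np.any(arr.ins_code != ""):
        raise StructureError("insertion codes are not supported")

    skipped: list[str] = []
    starts = bst.get_residue_starts(arr, add_exclusive_stop=True)
    residues: list[Residue] = []
    for s, e in zip(starts[:-1], starts[1:]):
        res_name = str(arr.res_name[s])
        res = Residue(res_name, int(arr.res_id[s]), str(arr.chain_id[s]))
        names_here = {str(arr.atom_name[k]) for k in range(s, e)}
        for k in range(s, e):
            name = str(arr.atom_name[k])
            if name.startswith("H"):
                # Heavy-atom model, except glycine's alpha hydrogen, which
                # fills the Cbeta frame role (PDB v3 names it HA2).
                if res_name != "GLY" or name not in ("HA1", "HA2"):
                    continue
                if name == "HA2":
                    if "HA1" in names_here:
                        continue
                    name = "HA1"
            try:
                p = table.atom_params(res_name, name)
            except UnknownAtomError as err:
                if permissive:
                    # Fall back to a generic type for the atom's element.
                    generic = {"C": "CH2", "N": "NP", "O": "OP",
                               "S": "SM", "H": "HVR"}.get(_element_of(name))
                    if generic and generic in table.types:
                        p = table.types[generic]
                        skipped.append(
                            f"{res_name} {res.chain}:{res.seq_id} {name} "
                            f"-> generic {generic}")
                    else:
                        skipped.append(
                            f"{res_name} {res.chain}:{res.seq_id} {name} dropped")
                        continue
                else:
                    raise StructureError(str(err)) from err
            res.atoms.append(Atom(name, str(arr.element[k]) or _element_of(name),
                                  arr.coord[k].astype(float), p))
        residues.append(res)

    for res in residues:
        for needed in ("N", "CA", "C"):
            if not res.has_atom(needed):
                raise StructureError(
                    f"residue {res.name} {res.chain}:{res.seq_id} is missing "
                    f"backbone atom {needed}")
        if res.name == "GLY" and not res.has_atom("HA1"):
            _add_virtual_ha1(res, table)
        elif res.name != "GLY" and not res.has_atom("CB"):
            raise StructureError(
                f"residue {res.name} {res.chain}:{res.seq_id} is missing CB")
    struct = TypedStructure(residues, table)
    struct.skipped_atoms = skipped
    return struct


def _add_virtual_ha1(res: Residue, table: ParameterTable) -> None:
    """Construct glycine's Halpha1 at the ideal position so the backbone
    frame is always defined."""
    coord = chem.nerf_place(res.atom("N").coord, res.atom("C").coord,
                            res.atom("CA").coord, 1.090, 110.1, 122.68)
    res.atoms.append(Atom("HA1", "H", coord, table.atom_params("GLY", "HA1")))


def transformed_copy(struct: TypedStructure, rot: np.ndarray,
                     shift: np.ndarray) -> TypedStructure:
    """Apply a global rigid motion x -> rot @ x + shift to a structure copy."""
    out = struct.copy()
    for _, a in out.all_atoms():
        a.coord = rot @ a.coord + np.asarray(shift, float)
    return out
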