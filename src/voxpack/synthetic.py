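"""Synthetic conformer pools, toy structures, and brute-force oracles.

These generators stand in for the MD trajectories of capped amino acids
from which production rotamer libraries are built: they produce pools with
*known* rotameric cluster structure (chi-space Gaussian modes with chosen
weights), so that library statistics can be checked against the generating
mixture.  The brute-force energy functions evaluate the same pairwise
potentials as the tensor engine by direct double loops, either with exact
distances or with environment atoms snapped to voxel centres, and serve as
independent oracles for the tensorized evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import h5py

from . import chem
from .constants import BORN_K, COULOMB_K, EPS_P, EPS_S
from .geometry import GridGeometry
from .params import ParameterTable
from .structure import TypedStructure, structure_from_residue_dicts


# ---------------------------------------------------------------------------
# conformer pools
# ---------------------------------------------------------------------------

@dataclass
class ConformerPool:
    """A stack of capped-amino-acid conformers with per-frame (phi, psi)."""

    aa: str
    coords: np.ndarray          #: (F, A, 3)
    phi: np.ndarray             #: (F,) degrees
    psi: np.ndarray             #: (F,) degrees
    atom_names: list[str]
    mode_labels: np.ndarray | None = None  #: generating mode per frame

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["aa"] = self.aa
            fh.create_dataset("coords", data=self.coords)
            fh.create_dataset("phi", data=self.phi)
            fh.create_dataset("psi", data=self.psi)
            fh.create_dataset("atom_names",
                              data=np.array(self.atom_names, dtype="S8"))

    @classmethod
    def load(cls, path) -> "ConformerPool":
        with h5py.File(path, "r") as fh:
            return cls(str(fh.attrs["aa"]), fh["coords"][()], fh["phi"][()],
                       fh["psi"][()],
                       [s.decode() for s in fh["atom_names"][()]])


@dataclass
class PoolRecipe:
    """Generator recipe for a synthetic conformer pool.

    ``modes`` are (chi_means_deg, spread_deg, weight) triples; weights must
    sum to one.  ``bin_probs`` assigns (phi, psi)-bin probabilities; frames
    sample their backbone torsions near the bin centre (clipped inside the
    bin so occupancies are exact).
    """

    aa: str
    modes: list[tuple[tuple, float, float]]
    frames: int = 5000
    bin_probs: dict[int, float] = field(default_factory=lambda: {19: 1.0})
    angle_jitter: float = 6.0  #: sd of the (phi, psi) scatter, degrees
    seed: int = 0

    def __post_init__(self):
        w = sum(m[2] for m in self.modes)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("mode weights must sum to 1")
        if abs(sum(self.bin_probs.values()) - 1.0) > 1e-9:
            raise ValueError("bin probabilities must sum to 1")


def _ideal_backbone(psi: float):
    """Backbone N/CA/C/O of one capped residue; O placed from psi."""
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    a = math.radians(180.0 - 111.2)
    c = ca + 1.525 * np.array([math.cos(a), math.sin(a), 0.0])
    o = chem.nerf_place(n, ca, c, 1.231, 120.8, psi - 180.0)
    return n, ca, c, o


def generate_conformer_pool(recipe: PoolRecipe) -> ConformerPool:
    """Deterministic synthetic pool with the recipe's cluster structure."""
    from .library import bin_center
    rng = np.random.default_rng(recipe.seed)
    aa = recipe.aa.upper()
    sc_names = chem.side_chain_atom_names(aa)
    names = ["N", "CA", "C", "O"] + sc_names
    nchi = chem.n_chi(aa)
    bins = sorted(recipe.bin_probs)
    probs = np.array([recipe.bin_probs[b] for b in bins])
    mode_w = np.array([m[2] for m in recipe.modes])

    coords = np.empty((recipe.frames, len(names), 3))
    phis = np.empty(recipe.frames)
    psis = np.empty(recipe.frames)
    labels = np.empty(recipe.frames, dtype=int)
    bin_draw = rng.choice(len(bins), size=recipe.frames, p=probs)
    mode_draw = rng.choice(len(recipe.modes), size=recipe.frames, p=mode_w)
    for f in range(recipe.frames):
        cphi, cpsi = bin_center(bins[bin_draw[f]])
        # clip inside the 60-degree cell so bin occupancies are exact
        phi = float(np.clip(cphi + rng.normal(0, recipe.angle_jitter),
                            cphi - 29.9, cphi + 29.9))
        psi = float(np.clip(cpsi + rng.normal(0, recipe.angle_jitter),
                            cpsi - 29.9, cpsi + 29.9))
        means, spread, _ = recipe.modes[mode_draw[f]]
        chis = [float(means[i]) + (rng.normal(0, spread) if spread > 0 else 0.0)
                for i in range(nchi)]
        n, ca, c, o = _ideal_backbone(psi)
        side = chem.build_side_chain(aa, n, ca, c, chis)
        frame_coords = [n, ca, c, o] + [side[nm] for nm in sc_names]
        coords[f] = np.asarray(frame_coords)
        phis[f], psis[f] = phi, psi
        labels[f] = mode_draw[f]
    return ConformerPool(aa, coords, phis, psis, names, labels)


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

# canonical torsions, chosen off the 60-degree bin edges
_KIND_TORSIONS = {
    "helix": (-57.0, -47.0),
    "strand": (-115.0, 125.0),
}


def generate_toy_structure(kind: str, length: int = 8,
                           table: ParameterTable | None = None,
                           sequence: str | None = None,
                           separation: float = 8.0,
                           chis: dict[int, list[float]] | None = None
                           ) -> TypedStructure:
    """Deterministic ideal-geometry toy structures.

    kinds: ``helix`` (all residues near (-60, -45)), ``strand`` (extended,
    (-120, 120), ~3.3 A rise per residue — positions decouple quickly),
    ``hairpin`` (a helical and a strand segment, populating two backbone
    bins), ``probe`` (two disconnected residues whose Calpha atoms sit
    ``separation`` apart on the x-axis, for locality/cutoff tests).
    """
    table = table or ParameterTable.bundled()
    if sequence is None:
        sequence = "A" * (2 if kind == "probe" else length)
    from .params import ONE_TO_THREE
    res_names = [ONE_TO_THREE[c.upper()] for c in sequence]
    chis = chis or {}

    if kind == "probe":
        specs = []
        for i, rn in enumerate(res_names[:2]):
            n, ca, c, o = _ideal_backbone(-45.0)
            shift = np.array([separation * i, 0.0, 0.0])
            atoms = {"N": n + shift, "CA": ca + shift, "C": c + shift,
                     "O": o + shift}
            side = chem.build_side_chain(rn, atoms["N"], atoms["CA"],
                                         atoms["C"], chis.get(i))
            atoms.update({k: v + shift for k, v in side.items()})
            specs.append((rn, i + 1, atoms))
        return structure_from_residue_dicts(specs, table)

    length = len(res_names)
    if length < 2:
        raise ValueError("need length >= 2")
    if kind in ("helix", "strand"):
        torsions = [_KIND_TORSIONS[kind]] * length
    elif kind == "hairpin":
        half = length // 2
        torsions = ([_KIND_TORSIONS["helix"]] * half
                    + [_KIND_TORSIONS["strand"]] * (length - half))
    else:
        raise ValueError(f"unknown toy kind {kind!r}")

    # Backbone chain by natural extension; torsions: psi_i links to N_{i+1},
    # omega fixed trans, phi_{i+1} sets C_{i+1}.
    n_at = [np.array([0.0, 0.0, 0.0])]
    ca_at = [np.array([1.458, 0.0, 0.0])]
    a = math.radians(180.0 - 111.2)
    c_at = [ca_at[0] + 1.525 * np.array([math.cos(a), math.sin(a), 0.0])]
    for i in range(length - 1):
        psi_i = torsions[i][1]
        n_next = chem.nerf_place(n_at[i], ca_at[i], c_at[i], 1.329, 116.2, psi_i)
        ca_next = chem.nerf_place(ca_at[i], c_at[i], n_next, 1.458, 121.7, 180.0)
        phi_next = torsions[i + 1][0]
        c_next = chem.nerf_place(c_at[i], n_next, ca_next, 1.525, 111.2, phi_next)
        n_at.append(n_next)
        ca_at.append(ca_next)
        c_at.append(c_next)
    specs = []
    for i, rn in enumerate(res_names):
        psi_i = torsions[i][1]
        o = chem.nerf_place(n_at[i], ca_at[i], c_at[i], 1.231, 120.8,
                            psi_i - 180.0)
        atoms = {"N": n_at[i], "CA": ca_at[i], "C": c_at[i], "O": o}
        atoms.update(chem.build_side_chain(rn, n_at[i], ca_at[i], c_at[i],
                                           chis.get(i)))
        specs.append((rn, i + 1, atoms))
    return structure_from_residue_dicts(specs, table)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def _pair_dist(p, q):
    return math.sqrt((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2
                     + (p[2] - q[2]) ** 2)


def _lj_scalar(r, eps, sigma, geom):
    chard = sigma / 2.0
    if r > geom.clr:
        return 0.0
    if r > sigma - geom.csoft:
        x6 = (sigma / r) ** 6
        return eps * (x6 * x6 - x6)
    if r > sigma - chard:
        return eps * (sigma / r) ** 2
    return eps * sigma ** 4 / (sigma - chard) ** 4


def brute_force_energy(env, rot, geom: GridGeometry | None = None,
                       mode: str = "voxel-snapped",
                       eps_p: float = EPS_P, eps_s: float = EPS_S,
                       terms=("lj", "elec", "solv")) -> dict:
    """Direct double-loop two-body energies; the oracle for the engine.

    ``env`` and ``rot`` are (coords, eps, sigma, charge, solv_sigma, vdw)
    tuples.  In ``voxel-snapped`` mode environment atoms are snapped to
    their voxel centre (atoms outside the cube are dropped) and the
    solvation term is evaluated by explicit per-atom crust/core voxel
    counting; in ``continuous`` mode exact positions are used and
    solvation (whose definition is the voxel discretization) is omitted.

    Returns dict with lj, coulomb, elec (assembled, incl. Born self-terms),
    solv (or None), b_bar.
    """
    geom = geom or GridGeometry()
    e_coords = np.asarray(env[0], dtype=float).reshape(-1, 3)
    r_coords = np.asarray(rot[0], dtype=float).reshape(-1, 3)
    e_par = [np.atleast_1d(np.asarray(a, dtype=float)) for a in env[1:]]
    r_par = [np.atleast_1d(np.asarray(a, dtype=float)) for a in rot[1:]]

    if mode == "voxel-snapped":
        if e_coords.shape[0]:
            idx = geom.voxel_indices(e_coords)
            inside = geom.in_box(idx)
            e_coords = geom.center_of(idx[inside])
            e_par = [a[inside] for a in e_par]
    elif mode != "continuous":
        raise ValueError(f"unknown mode {mode!r}")

    lj = 0.0
    coul = 0.0
    for i in range(e_coords.shape[0]):
        qi = e_par[2][i]
        for j in range(r_coords.shape[0]):
            d = _pair_dist(e_coords[i], r_coords[j])
            lj += _lj_scalar(d, r_par[0][j], r_par[1][j], geom)
            if d <= geom.clr:
                rr = max(d, geom.voxel / 2.0)
                coul += COULOMB_K * qi * r_par[2][j] / (rr * rr)

    if "elec" not in terms and "solv" not in terms:
        return {"lj": lj, "coulomb": coul, "elec": None, "solv": None,
                "b_bar": None, "bracket": None}

    # Born radius from the vdW-filled volume fraction of the cube,
    # counted per voxel with an independent loop.
    filled: set[int] = set()
    crust_by_atom: list[tuple[set[int], float]] = []
    for i in range(e_coords.shape[0]):
        x = e_coords[i]
        rv = e_par[4][i]
        core, crust = _sphere_voxels(x, rv, geom)
        filled |= core
        area = 4.0 * math.pi * rv ** 2
        val = e_par[3][i] * area / len(crust) if crust else 0.0
        crust_by_atom.append((crust, val))
    if filled:
        b_bar = geom.dbox * len(filled) / geom.n_voxels
    elif r_par[4].size:
        b_bar = float(np.mean(r_par[4]))
    else:
        b_bar = 2.0

    rbar = geom.rbar
    f_gb = math.sqrt(rbar ** 2 + b_bar ** 2
                     * math.exp(-rbar ** 2 / (4.0 * b_bar ** 2)))
    bracket = 1.0 - eps_p * rbar / f_gb * (1.0 / eps_p - 1.0 / eps_s)
    q2 = float(np.sum(e_par[2] ** 2)) + float(np.sum(r_par[2] ** 2))
    self_term = -BORN_K * q2 / b_bar * (1.0 / eps_p - 1.0 / eps_s)
    elec = bracket * coul + self_term

    solv = None
    if mode == "voxel-snapped" and "solv" in terms:
        rot_core: set[int] = set()
        rot_crust_atoms = []
        for j in range(r_coords.shape[0]):
            rv = r_par[4][j]
            core, crust = _sphere_voxels(r_coords[j], rv, geom)
            rot_core |= core
            area = 4.0 * math.pi * rv ** 2
            val = r_par[3][j] * area / len(crust) if crust else 0.0
            rot_crust_atoms.append((crust, val))
        env_core = filled
        solv = 0.0
        for crust, val in crust_by_atom:      # env crust buried by rotamer
            for v in crust:
                if v in rot_core and v not in env_core:
                    solv -= val
        for crust, val in rot_crust_atoms:    # rotamer crust buried by env
            for v in crust:
                if v in env_core and v not in rot_core:
                    solv -= val
    return {"lj": lj, "coulomb": coul, "elec": elec, "solv": solv,
            "b_bar": b_bar, "bracket": bracket}


def _sphere_voxels(x, rv, geom: GridGeometry):
    """(core, crust) voxel flat-index sets of one atom, by direct search."""
    d = geom.dims
    half = geom.dbox / 2.0
    r_out = rv + geom.crust
    core: set[int] = set()
    crust: set[int] = set()
    lo = [max(int(math.floor((x[i] - r_out + half) / geom.voxel)), 0)
          for i in range(3)]
    hi = [min(int(math.floor((x[i] + r_out + half) / geom.voxel)), d - 1)
          for i in range(3)]
    for ix in range(lo[0], hi[0] + 1):
        cx = -half + (ix + 0.5) * geom.voxel
        for iy in range(lo[1], hi[1] + 1):
            cy = -half + (iy + 0.5) * geom.voxel
            for iz in range(lo[2], hi[2] + 1):
                cz = -half + (iz + 0.5) * geom.voxel
                dist = math.sqrt((cx - x[0]) ** 2 + (cy - x[1]) ** 2
                                 + (cz - x[2]) ** 2)
                flat = ix * d * d + iy * d + iz
                if dist <= rv:
                    core.add(flat)
                elif dist <= r_out:
                    crust.add(flat)
    return core, crust


# ---------------------------------------------------------------------------
# Monte-Carlo cube distance
# ---------------------------------------------------------------------------

def mean_pair_distance_mc(n_samples: int, seed: int = 0, dim: int = 3):
    """Mean distance between independent uniform point pairs in the unit
    hypercube, with its standard error.  For dim=3 this converges to
    ~0.6617 (the constant used for the cube-average interatomic
    distance); the dim=1 analogue is exactly 1/3."""
    if n_samples < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    total = 0.0
    total2 = 0.0
    done = 0
    while done < n_samples:
        m = min(n_samples - done, 1_000_000)
        p = rng.random((m, dim))
        q = rng.random((m, dim))
        dist = np.sqrt(np.sum((p - q) ** 2, axis=1))
        total += float(dist.sum())
        total2 += float((dist ** 2).sum())
        done += m
    mean = total / n_samples
    var = max(total2 / n_samples - mean ** 2, 0.0)
    se = math.sqrt(var / n_samples)
    return mean, se
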