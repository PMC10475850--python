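"""Voxelized two-body energy evaluation.

The non-bonded energy between an inbound side chain (2nd body) and its
molecular environment (1st body) is evaluated as element-wise products of
precomputed rotamer field tensors with run-time environment tensors on a
shared 22 A / 0.5 A voxel grid in the residue backbone frame:

* piecewise Lennard-Jones with a soft repulsive band and a flat core
  plateau, parameterized by the inbound atom only;
* screened Coulomb electrostatics with a distance-dependent dielectric
  eps(r) = r, a Generalized-Born-style solvation correction using cube
  averages (rbar = 0.6617 dbox, shared Born radius bbar), and per-charge
  Born self-terms;
* a surface-area solvation term from voxelized atomic crusts (vdW radii
  inflated by 0.5 A) with core-mask occlusion.

Totals follow a weighted five-term sum with the rotamer's own-backbone
reference energies subtracted from each interaction term; a clash cap on
the LJ term (tiered scoring) skips the remaining terms for hopeless
placements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import BORN_K, COULOMB_K, DEFAULT_MAX_LJ, EPS_P, EPS_S
from .geometry import GridGeometry, frame_transform
from . import chem


@dataclass(frozen=True)
class Weights:
    """Weights of the five energy terms."""

    w_pp: float = 1.0
    w_k: float = 1.0
    w_lj: float = 1.0
    w_solv: float = 1.0
    w_elec: float = 0.25


#: Default Born radius (A) when the environment fills no volume at all and
#: no probe atoms are available to estimate one.
_BBAR_FALLBACK = 2.0


# ---------------------------------------------------------------------------
# pairwise potentials (shared by the tensor builders and the brute-force
# oracle, so that both discretized routes agree)
# ---------------------------------------------------------------------------

def _lj_piecewise(r, eps_j, sigma_j, geom: GridGeometry):
    """Vectorized piecewise LJ; finite everywhere, zero beyond the cutoff."""
    r = np.asarray(r, dtype=float)
    eps_j = np.asarray(eps_j, dtype=float)
    sigma_j = np.asarray(sigma_j, dtype=float)
    chard = sigma_j / 2.0
    soft_lo = sigma_j - geom.csoft
    hard_lo = sigma_j - chard
    rr = np.clip(r, 1e-12, None)
    out = np.zeros(np.broadcast(rr, sigma_j).shape)
    # attractive / standard branch
    m1 = (rr > soft_lo) & (rr <= geom.clr)
    s_over_r6 = np.where(m1, (sigma_j / rr) ** 6, 0.0)
    out = np.where(m1, eps_j * (s_over_r6 ** 2 - s_over_r6), out)
    # soft repulsive band across the atomic crust
    m2 = (rr > hard_lo) & (rr <= soft_lo)
    out = np.where(m2, eps_j * (sigma_j / rr) ** 2, out)
    # flat plateau at the atomic core
    m3 = rr <= hard_lo
    out = np.where(m3, eps_j * sigma_j ** 4 / (sigma_j - chard) ** 4, out)
    return out


def lj_pairwise(r: float, eps_j: float, sigma_j: float,
                geom: GridGeometry | None = None) -> float:
    """Piecewise Lennard-Jones energy (kcal/mol) of one atom pair.

    Only the inbound atom's parameters enter (asymmetric by design).
    Zero beyond the long-range cutoff.
    """
    geom = geom or GridGeometry()
    if np.any(np.asarray(r) <= 0):
        raise ValueError("interatomic distance must be positive")
    res = _lj_piecewise(r, eps_j, sigma_j, geom)
    return float(res) if np.isscalar(r) else res


def coulomb_factor(r, geom: GridGeometry):
    """332 / (eps(r) * r) with eps(r) = r, zero beyond the cutoff.

    Distances are clamped below at half a voxel, consistent with the grid
    discretization (a source atom and a voxel centre can coincide).
    """
    r = np.asarray(r, dtype=float)
    rr = np.clip(r, geom.voxel / 2.0, None)
    return np.where(r <= geom.clr, COULOMB_K / (rr * rr), 0.0)


def gb_bracket(b_bar: float, geom: GridGeometry,
               eps_p: float = EPS_P, eps_s: float = EPS_S) -> float:
    """The Generalized-Born screening factor applied to the Coulomb term.

    Uses the cube-average interatomic distance rbar = 0.6617 dbox and the
    shared average Born radius bbar.
    """
    if b_bar <= 0:
        raise ValueError("Born radius must be positive")
    rbar = geom.rbar
    f_gb = np.sqrt(rbar ** 2 + b_bar ** 2 * np.exp(-rbar ** 2 / (4.0 * b_bar ** 2)))
    return float(1.0 - eps_p * rbar / f_gb * (1.0 / eps_p - 1.0 / eps_s))


def born_self(q, b_bar, eps_p: float = EPS_P, eps_s: float = EPS_S):
    """Born self-energy -166 q^2 / bbar * (1/eps_p - 1/eps_s), per charge."""
    if np.any(np.asarray(b_bar) <= 0):
        raise ValueError("Born radius must be positive")
    q = np.asarray(q, dtype=float)
    return -BORN_K * q ** 2 / b_bar * (1.0 / eps_p - 1.0 / eps_s)


def elec_pairwise(r: float, q_i: float, q_j: float, b_bar: float,
                  geom: GridGeometry | None = None,
                  eps_p: float = EPS_P, eps_s: float = EPS_S,
                  include_self: bool = True) -> float:
    """Screened pair electrostatics (kcal/mol) for one (i, j) pair.

    The interaction part applies within the cutoff; the Born self-term of
    charge i is added once when ``include_self`` is set.
    """
    geom = geom or GridGeometry()
    if r <= 0:
        raise ValueError("interatomic distance must be positive")
    inter = float(coulomb_factor(r, geom)) * q_i * q_j * gb_bracket(
        b_bar, geom, eps_p, eps_s)
    if include_self:
        inter += float(born_self(q_i, b_bar, eps_p, eps_s))
    return inter


# ---------------------------------------------------------------------------
# tensors
# ---------------------------------------------------------------------------

def _crust_and_core(coords, vdw, solv_sigma, geom: GridGeometry):
    """Voxelized solvation crust and core mask of a set of atoms.

    The crust of an atom is the voxel shell whose centres fall within
    (vdw, vdw + 0.5] of the atom centre; it carries the atom's total
    surface solvation energy sigma_solv * 4 pi vdw^2 split evenly over its
    crust voxels (the radial inflation is corrected back to the vdW
    surface area).  The core mask marks voxels within the vdW radius.
    """
    crust = np.zeros(geom.n_voxels)
    core = np.zeros(geom.n_voxels, dtype=bool)
    d = geom.dims
    half = geom.dbox / 2.0
    for x, rv, ssig in zip(np.atleast_2d(coords), np.atleast_1d(vdw),
                           np.atleast_1d(solv_sigma)):
        r_out = rv + geom.crust
        lo = np.maximum(np.floor((x - r_out + half) / geom.voxel).astype(int), 0)
        hi = np.minimum(np.floor((x + r_out + half) / geom.voxel).astype(int), d - 1)
        if np.any(lo > hi):
            continue
        ax = [(-half + (np.arange(lo[i], hi[i] + 1) + 0.5) * geom.voxel)
              for i in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        dist = np.sqrt((gx - x[0]) ** 2 + (gy - x[1]) ** 2 + (gz - x[2]) ** 2)
        ix, iy, iz = np.meshgrid(np.arange(lo[0], hi[0] + 1),
                                 np.arange(lo[1], hi[1] + 1),
                                 np.arange(lo[2], hi[2] + 1), indexing="ij")
        flat = (ix * d * d + iy * d + iz).ravel()
        dist = dist.ravel()
        in_core = dist <= rv
        in_crust = (dist > rv) & (dist <= r_out)
        core[flat[in_core]] = True
        n_crust = int(in_crust.sum())
        if n_crust:
            area = 4.0 * np.pi * rv ** 2
            np.add.at(crust, flat[in_crust], ssig * area / n_crust)
    return crust, core


def build_rotamer_field_tensors(coords, eps, sigma, charge, solv_sigma, vdw,
                                geom: GridGeometry | None = None) -> dict:
    """Precompute a rotamer's field tensors on the shared grid.

    Returns a dict with flat (n_voxels,) arrays: ``lj_field`` (kcal/mol per
    occupying atom), ``elec_field`` (kcal/mol per unit environment charge,
    before the GB bracket), ``solv_crust`` and ``core_mask``.  All-zero for
    an empty atom set (e.g. a glycine with no side chain).
    """
    geom = geom or GridGeometry()
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n_vox = geom.n_voxels
    if coords.size == 0:
        return {"lj_field": np.zeros(n_vox), "elec_field": np.zeros(n_vox),
                "solv_crust": np.zeros(n_vox),
                "core_mask": np.zeros(n_vox, dtype=bool)}
    centers = geom.voxel_centers()
    lj = np.zeros(n_vox)
    el = np.zeros(n_vox)
    for x, e, s, q in zip(coords, np.atleast_1d(eps), np.atleast_1d(sigma),
                          np.atleast_1d(charge)):
        dist = np.sqrt(np.sum((centers - x) ** 2, axis=1))
        near = dist <= geom.clr
        lj[near] += _lj_piecewise(dist[near], e, s, geom)
        el[near] += q * coulomb_factor(dist[near], geom)
    crust, core = _crust_and_core(coords, vdw, solv_sigma, geom)
    return {"lj_field": lj, "elec_field": el,
            "solv_crust": crust, "core_mask": core}


@dataclass
class EnvironmentTensors:
    """Run-time projection of the environment onto the grid."""

    occupancy: np.ndarray        #: (n_voxels,) atom counts
    charge: np.ndarray           #: (n_voxels,) summed partial charges
    solv_crust: np.ndarray       #: (n_voxels,) crust energies
    core_mask: np.ndarray        #: (n_voxels,) bool
    filled_fraction: float       #: vdW-filled volume fraction of the cube
    b_bar: float | None          #: average Born radius, None if no volume filled
    coords: np.ndarray           #: framed coordinates of in-box atoms
    eps: np.ndarray
    sigma: np.ndarray
    q: np.ndarray
    solv_sigma: np.ndarray
    vdw: np.ndarray
    geom: GridGeometry
    frame: tuple | None = None   #: (rotation, origin) of the frame transform

    @property
    def sum_q2(self) -> float:
        return float(np.sum(self.q ** 2))

    def effective_b_bar(self, probe_vdw=None) -> float:
        """bbar, falling back to the probe atoms' mean vdW radius for an
        environment that fills no volume."""
        if self.b_bar is not None:
            return self.b_bar
        if probe_vdw is not None and np.size(probe_vdw) > 0:
            return float(np.mean(probe_vdw))
        return _BBAR_FALLBACK


def env_from_atoms(coords, eps, sigma, charge, solv_sigma, vdw,
                   geom: GridGeometry | None = None,
                   frame=None) -> EnvironmentTensors:
    """Project typed atoms (already in frame coordinates) onto the grid.

    Atoms outside the cube are ignored entirely.  bbar is the cube side
    scaled by the vdW-filled volume fraction of the cube.
    """
    geom = geom or GridGeometry()
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    arrs = [np.atleast_1d(np.asarray(a, dtype=float))
            for a in (eps, sigma, charge, solv_sigma, vdw)]
    if coords.shape[0]:
        idx3 = geom.voxel_indices(coords)
        inside = geom.in_box(idx3)
    else:
        inside = np.zeros(0, dtype=bool)
    coords = coords[inside]
    eps, sigma, charge, solv_sigma, vdw = (a[inside] for a in arrs)

    occ = np.zeros(geom.n_voxels)
    chg = np.zeros(geom.n_voxels)
    if coords.shape[0]:
        flat = geom.flat_index(geom.voxel_indices(coords))
        np.add.at(occ, flat, 1.0)
        np.add.at(chg, flat, charge)
        # The 1st body is its voxel projection: crust and core masks are
        # built from the snapped positions, making them (and the Born
        # radius) pure functions of the occupancy pattern.
        coords = geom.snap(coords)
        crust, core = _crust_and_core(coords, vdw, solv_sigma, geom)
    else:
        crust = np.zeros(geom.n_voxels)
        core = np.zeros(geom.n_voxels, dtype=bool)
    filled = float(np.count_nonzero(core)) / geom.n_voxels
    b_bar = geom.dbox * filled if filled > 0 else None
    return EnvironmentTensors(occ, chg, crust, core, filled, b_bar,
                              coords, eps, sigma, charge, solv_sigma, vdw,
                              geom, frame)


def voxelize_environment(structure, position: int,
                         geom: GridGeometry | None = None) -> EnvironmentTensors:
    """Build environment tensors for a designable position.

    The whole structure is rigidly mapped into the position's backbone
    frame, the target residue's side-chain atoms are deleted, and the
    remaining atoms within the cube are projected onto the grid.
    """
    geom = geom or GridGeometry()
    ca, cb, n = structure.frame_atoms(position)
    rot, origin = frame_transform(ca, cb, n)
    coords, eps, sigma, q, ssolv, vdw, ridx = structure.atom_arrays()
    # Drop the target side chain (keep its backbone).
    keep = np.ones(coords.shape[0], dtype=bool)
    for k, (i, a) in enumerate(structure.all_atoms()):
        if i == position and a.name not in chem.BACKBONE_SET:
            keep[k] = False
    framed = (coords[keep] - origin) @ rot.T
    return env_from_atoms(framed, eps[keep], sigma[keep], q[keep],
                          ssolv[keep], vdw[keep], geom, frame=(rot, origin))


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

@dataclass
class EnergyBreakdown:
    """The five weighted terms of the total design energy."""

    dg_pp: float
    dg_k: float
    dg_lj: float
    dg_lj_ref: float
    dg_solv: float
    dg_solv_ref: float
    dg_elec: float
    dg_elec_ref: float
    weights: Weights
    clash: bool = False

    @property
    def total(self) -> float:
        w = self.weights
        return (w.w_pp * self.dg_pp + w.w_k * self.dg_k
                + w.w_lj * (self.dg_lj - self.dg_lj_ref)
                + w.w_solv * (self.dg_solv - self.dg_solv_ref)
                + w.w_elec * (self.dg_elec - self.dg_elec_ref))


def solvation_energy(env: EnvironmentTensors, rot_crust: np.ndarray,
                     rot_core: np.ndarray) -> float:
    """Two-body solvation energy change on placing the rotamer.

    Computed as dG(1,2) - dG(1) - dG(2) from the exposed-crust sums of the
    separate and combined bodies; only mutually occluded crust voxels
    contribute.
    """
    crust1, core1 = env.solv_crust, env.core_mask
    rot_core = rot_core.astype(bool)
    term_a = -float(np.sum(crust1[(~core1) & rot_core]))
    term_b = -float(np.sum(rot_crust[core1 & (~rot_core)]))
    return term_a + term_b


def score_stack(env: EnvironmentTensors, stack, dg_pp,
                weights: Weights | None = None,
                max_lj: float = DEFAULT_MAX_LJ,
                eps_p: float = EPS_P, eps_s: float = EPS_S):
    """Score all k rotamers of a bin stack against an environment.

    ``stack`` provides float arrays lj (k,V), elec (k,V), crust (k,V),
    core (k,V) bool, plus per-rotamer dg_k, refs (k,3: lj/solv/elec),
    sum_q2 and mean_vdw.  Returns dict of per-rotamer arrays, including the
    weighted ``total``.
    """
    weights = weights or Weights()
    k = stack.lj.shape[0]
    occ_idx = np.nonzero(env.occupancy)[0]
    dg_lj = stack.lj[:, occ_idx].astype(float) @ env.occupancy[occ_idx]
    clash = dg_lj > max_lj

    q_idx = np.nonzero(env.charge)[0]
    coul = stack.elec[:, q_idx].astype(float) @ env.charge[q_idx]
    b_bar = np.array([env.effective_b_bar(stack.mean_vdw[i:i + 1])
                      for i in range(k)])
    bracket = np.array([gb_bracket(b, env.geom, eps_p, eps_s) for b in b_bar])
    self_terms = born_self(np.sqrt(env.sum_q2 + stack.sum_q2), b_bar,
                           eps_p, eps_s)
    dg_elec = bracket * coul + self_terms

    idx_a = np.nonzero(env.solv_crust * (~env.core_mask))[0]
    a_vals = env.solv_crust[idx_a]
    term_a = -(stack.core[:, idx_a].astype(float) @ a_vals)
    idx_b = np.nonzero(env.core_mask)[0]
    crust_b = stack.crust[:, idx_b].astype(float)
    core_b = stack.core[:, idx_b]
    term_b = -np.sum(crust_b * (~core_b), axis=1)
    dg_solv = term_a + term_b

    ref_lj = stack.refs[:, 0]
    ref_solv = np.where(clash, 0.0, stack.refs[:, 1])
    ref_elec = np.where(clash, 0.0, stack.refs[:, 2])
    dg_solv = np.where(clash, 0.0, dg_solv)
    dg_elec = np.where(clash, 0.0, dg_elec)

    total = (weights.w_pp * dg_pp + weights.w_k * stack.dg_k
             + weights.w_lj * (dg_lj - ref_lj)
             + weights.w_solv * (dg_solv - ref_solv)
             + weights.w_elec * (dg_elec - ref_elec))
    return {"dg_lj": dg_lj, "dg_solv": dg_solv, "dg_elec": dg_elec,
            "ref_lj": ref_lj, "ref_solv": ref_solv, "ref_elec": ref_elec,
            "dg_k": stack.dg_k.copy(), "dg_pp": np.full(k, dg_pp),
            "clash": clash, "total": total}


def score_rotamer(env: EnvironmentTensors, tensors: dict, dg_pp: float,
                  dg_k: float = 0.0, refs=(0.0, 0.0, 0.0),
                  weights: Weights | None = None,
                  max_lj: float = DEFAULT_MAX_LJ,
                  rot_q=None, rot_vdw=None,
                  eps_p: float = EPS_P, eps_s: float = EPS_S) -> EnergyBreakdown:
    """Score a single rotamer (given its field tensors) against an environment.

    ``tensors`` is the dict from :func:`build_rotamer_field_tensors`;
    ``refs`` are the precomputed own-backbone reference energies
    (LJ, solvation, electrostatics).  Implements tiered scoring: if the LJ
    term exceeds ``max_lj``, solvation and electrostatics are skipped and
    the clash flag is set.
    """
    weights = weights or Weights()
    if tensors["lj_field"].shape[0] != env.occupancy.shape[0]:
        raise ValueError("rotamer tensors and environment use different grids")
    dg_lj = float(tensors["lj_field"] @ env.occupancy)
    if dg_lj > max_lj:
        return EnergyBreakdown(dg_pp, dg_k, dg_lj, refs[0], 0.0, 0.0, 0.0, 0.0,
                               weights, clash=True)
    b_bar = env.effective_b_bar(rot_vdw)
    sum_q2 = env.sum_q2 + (float(np.sum(np.asarray(rot_q) ** 2))
                           if rot_q is not None else 0.0)
    dg_elec = (gb_bracket(b_bar, env.geom, eps_p, eps_s)
               * float(tensors["elec_field"] @ env.charge)
               + float(born_self(np.sqrt(sum_q2), b_bar, eps_p, eps_s)))
    dg_solv = solvation_energy(env, tensors["solv_crust"], tensors["core_mask"])
    return EnergyBreakdown(dg_pp, dg_k, dg_lj, refs[0], dg_solv, refs[1],
                           dg_elec, refs[2], weights, clash=False)


def compute_reference_energies(side_coords, side_params, bb_coords, bb_params,
                               geom: GridGeometry | None = None,
                               tensors: dict | None = None):
    """Own-backbone reference energies of a framed rotamer.

    The environment is the rotamer's own backbone atoms from the same
    pooled conformer, voxelized with the run-time scheme, so that placing
    the rotamer back onto its own backbone in an otherwise empty
    environment cancels each interaction term exactly.

    ``side_params`` / ``bb_params`` are (eps, sigma, charge, solv_sigma,
    vdw) array tuples.  Returns (dG_LJ_ref, dG_solv_ref, dG_elec_ref).
    """
    geom = geom or GridGeometry()
    side_coords = np.asarray(side_coords, dtype=float).reshape(-1, 3)
    if side_coords.shape[0] == 0:
        return 0.0, 0.0, 0.0
    if tensors is None:
        tensors = build_rotamer_field_tensors(side_coords, *side_params, geom=geom)
    env = env_from_atoms(np.asarray(bb_coords, float).reshape(-1, 3),
                         *bb_params, geom=geom)
    bd = score_rotamer(env, tensors, 0.0, 0.0, (0.0, 0.0, 0.0),
                       Weights(), max_lj=np.inf,
                       rot_q=side_params[2], rot_vdw=side_params[4])
    return bd.dg_lj, bd.dg_solv, bd.dg_elec


def per_residue_energies(structure, library, weights: Weights | None = None,
                         max_lj: float = DEFAULT_MAX_LJ):
    """Score every interior residue's current side chain.

    Each residue is represented by the nearest library rotamer (by
    side-chain RMSD) of its own amino acid in its (phi, psi) bin and scored
    against its environment.  Returns a list of dicts with ``position``,
    ``total`` (None if unscoreable), ``rotamer``, ``clash`` and ``flag``.
    """
    weights = weights if weights is not None else Weights()
    out = []
    for i in structure.interior_indices():
        res = structure[i]
        try:
            phi, psi = structure.phi_psi(i)
        except Exception:
            out.append({"position": i, "total": None, "flag": "no-torsions"})
            continue
        entry = library.lookup(res.name, phi, psi)
        if entry is None:
            out.append({"position": i, "total": None, "flag": "empty-bin"})
            continue
        rid = _nearest_rotamer(structure, i, entry)
        if rid is None:
            out.append({"position": i, "total": None, "flag": "missing-atoms"})
            continue
        env = voxelize_environment(structure, i, library.geometry)
        scores = score_stack(env, entry.stack, entry.dg_pp, weights, max_lj)
        out.append({"position": i, "total": float(scores["total"][rid]),
                    "rotamer": int(rid), "clash": bool(scores["clash"][rid]),
                    "flag": None})
    return out


def _nearest_rotamer(structure, position: int, entry):
    """Index of the library rotamer closest (side-chain RMSD) to the
    residue's current side chain, in the residue's backbone frame."""
    res = structure[position]
    lookup = res.coord_lookup()
    try:
        cur = np.array([lookup[name] for name in entry.atom_names])
    except KeyError:
        return None
    ca, cb, n = structure.frame_atoms(position)
    rot, origin = frame_transform(ca, cb, n)
    framed = (cur - origin) @ rot.T
    diff = entry.stack.coords.astype(float) - framed[None, :, :]
    msd = np.mean(np.sum(diff ** 2, axis=2), axis=1)
    return int(np.argmin(msd))
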