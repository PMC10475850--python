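"""Discrete rotamer libraries from conformer pools.

A library holds, per amino acid and per 60-degree (phi, psi) bin, exactly
``k`` rotamers obtained by fixed-k k-means clustering of frame-aligned
conformers, together with statistical free energies derived from pool
occupancies:

* dG_pp = -kB T ln(O(phi,psi)_m / N) for the backbone bin,
* dG_k  = -kB T ln(O(k_n | bin) / O(bin)) for each cluster,

with kB = 0.001985875 kcal/(mol K) and T = 298 K.  Bins with fewer pool
conformers than ``k`` are excluded outright.  Every rotamer carries its
own-backbone reference energies and precomputed field tensors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import h5py
from sklearn.cluster import KMeans

from . import chem, engine
from .constants import KBT
from .geometry import GridGeometry, align_to_frame
from .params import ParameterTable


N_BINS = 36
_BIN_DEG = 60.0


def wrap_angle(a):
    """Wrap angles (degrees) into [-180, 180)."""
    return ((np.asarray(a, dtype=float) + 180.0) % 360.0) - 180.0


def assign_phi_psi_bin(phi, psi):
    """Index of the 6x6 backbone dihedral bin, cells [lo, lo+60) per axis.

    Accepts scalars or arrays; out-of-range angles are wrapped.
    """
    phi = wrap_angle(phi)
    psi = wrap_angle(psi)
    ix = np.clip(np.floor((phi + 180.0) / _BIN_DEG).astype(int), 0, 5)
    iy = np.clip(np.floor((psi + 180.0) / _BIN_DEG).astype(int), 0, 5)
    idx = ix * 6 + iy
    return int(idx) if np.isscalar(phi) or idx.ndim == 0 else idx


def bin_center(bin_index: int) -> tuple[float, float]:
    """(phi, psi) centre of a bin (degrees)."""
    ix, iy = divmod(int(bin_index), 6)
    return (-180.0 + (ix + 0.5) * _BIN_DEG, -180.0 + (iy + 0.5) * _BIN_DEG)


def backbone_bin_energy(occupancy: int, total: int) -> float:
    """Statistical free energy of a backbone bin, -kB T ln(occ/total)."""
    if not 0 < occupancy <= total:
        raise ValueError("need 0 < occupancy <= total")
    return -KBT * float(np.log(occupancy / total))


def cluster_energy(cluster_occupancy: int, bin_occupancy: int) -> float:
    """Statistical free energy of a rotamer cluster within its bin."""
    if not 0 < cluster_occupancy <= bin_occupancy:
        raise ValueError("need 0 < cluster_occupancy <= bin_occupancy")
    return -KBT * float(np.log(cluster_occupancy / bin_occupancy))


class BinTooSmall(Exception):
    """Signal: a bin's pool occupancy is below k, so it is excluded."""


def cluster_conformers(framed: np.ndarray, k: int, seed: int = 0):
    """Fixed-k clustering of frame-aligned conformers.

    Parameters
    ----------
    framed : (F, A, 3) conformer stack, canonically ordered by frame index.
    k : number of clusters.

    Returns (labels (F,), representatives (k,) frame indices,
    occupancies (k,)).  The representative of a cluster is the member with
    the lowest RMSD to the cluster-mean coordinates (ties: lowest frame
    index).  Raises :class:`BinTooSmall` if F < k.
    """
    framed = np.asarray(framed, dtype=float)
    n = framed.shape[0]
    if n < k:
        raise BinTooSmall(f"pool of {n} conformers cannot yield {k} clusters")
    feats = framed.reshape(n, -1)
    km = KMeans(n_clusters=k, n_init=4, tol=1e-6, random_state=seed)
    labels = km.fit_predict(feats)
    reps = np.empty(k, dtype=int)
    occ = np.empty(k, dtype=int)
    for c in range(k):
        members = np.nonzero(labels == c)[0]
        occ[c] = members.size
        mean = framed[members].mean(axis=0)
        rmsd = np.sqrt(np.mean(np.sum((framed[members] - mean) ** 2, axis=2),
                               axis=1))
        reps[c] = members[int(np.argmin(rmsd))]  # argmin -> lowest index on ties
    return labels, reps, occ


@dataclass
class RotamerStack:
    """Per-bin stacked rotamer data used by the scoring engine."""

    coords: np.ndarray       #: (k, n_sc, 3) float32, frame coordinates
    lj: np.ndarray           #: (k, V) float32
    elec: np.ndarray         #: (k, V) float32
    crust: np.ndarray        #: (k, V) float32
    core: np.ndarray         #: (k, V) bool
    dg_k: np.ndarray         #: (k,) float64
    refs: np.ndarray         #: (k, 3) float64: LJ, solvation, electrostatics
    occupancy: np.ndarray    #: (k,) int
    sum_q2: np.ndarray       #: (k,) float64
    mean_vdw: np.ndarray     #: (k,) float64
    frame_index: np.ndarray  #: (k,) int, provenance of the representative


@dataclass
class BinEntry:
    """One populated (phi, psi) bin of one amino acid."""

    aa: str
    bin_index: int
    occupancy: int
    dg_pp: float
    atom_names: list[str]
    bb_coords: np.ndarray    #: (k, n_bb, 3) representative backbone coords
    stack: RotamerStack

    @property
    def k(self) -> int:
        return self.stack.dg_k.shape[0]

    def rotamer_coords(self, rid: int) -> np.ndarray:
        return self.stack.coords[rid].astype(float)


@dataclass
class Rotamer:
    """A single rotamer view (convenience; the engine uses the stacks)."""

    aa: str
    bin_index: int
    rotamer_id: int
    atom_names: list[str]
    coords: np.ndarray
    occupancy: int
    dg_k: float
    refs: tuple[float, float, float]


class RotamerLibrary:
    """Per amino acid x (phi, psi)-bin rotamer sets with field tensors."""

    def __init__(self, k: int, table: ParameterTable,
                 geometry: GridGeometry | None = None):
        self.k = k
        self.table = table
        self.geometry = geometry or GridGeometry()
        #: aa -> {bin_index: BinEntry}
        self.bins: dict[str, dict[int, BinEntry]] = {}
        #: aa -> {bin_index: (occupancy, dg_pp)} for ALL occupied bins
        self.bin_stats: dict[str, dict[int, tuple[int, float]]] = {}
        self.pool_totals: dict[str, int] = {}

    # -- access ------------------------------------------------------------

    def amino_acids(self):
        return sorted(self.bins)

    def get(self, aa: str, bin_index: int) -> BinEntry | None:
        return self.bins.get(aa, {}).get(int(bin_index))

    def lookup(self, aa: str, phi: float, psi: float) -> BinEntry | None:
        return self.get(aa, assign_phi_psi_bin(phi, psi))

    def rotamer(self, aa: str, bin_index: int, rid: int) -> Rotamer:
        e = self.bins[aa][bin_index]
        s = e.stack
        return Rotamer(aa, bin_index, rid, e.atom_names,
                       s.coords[rid].astype(float), int(s.occupancy[rid]),
                       float(s.dg_k[rid]), tuple(s.refs[rid]))

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["k"] = self.k
            fh.attrs["kb"] = 0.001985875
            fh.attrs["T"] = 298.0
            fh.attrs["dbox"] = self.geometry.dbox
            fh.attrs["voxel"] = self.geometry.voxel
            fh.attrs["clr"] = self.geometry.clr
            fh.attrs["csoft"] = self.geometry.csoft
            fh.attrs["params_digest"] = self.table.digest
            for aa, bins in self.bins.items():
                g_aa = fh.create_group(aa)
                g_aa.attrs["pool_total"] = self.pool_totals.get(aa, 0)
                stats = self.bin_stats.get(aa, {})
                g_aa.create_dataset(
                    "occupancy_stats",
                    data=np.array([(b, o, g) for b, (o, g) in sorted(stats.items())],
                                  dtype=np.float64).reshape(-1, 3))
                for b, entry in bins.items():
                    g = g_aa.create_group(f"bin_{b:02d}")
                    g.attrs["occupancy"] = entry.occupancy
                    g.attrs["dg_pp"] = entry.dg_pp
                    g.attrs["atom_names"] = ",".join(entry.atom_names)
                    g.create_dataset("bb_coords", data=entry.bb_coords)
                    s = entry.stack
                    g.create_dataset("coords", data=s.coords)
                    g.create_dataset("lj", data=s.lj)
                    g.create_dataset("elec", data=s.elec)
                    g.create_dataset("crust", data=s.crust)
                    g.create_dataset("core", data=s.core)
                    g.create_dataset("dg_k", data=s.dg_k)
                    g.create_dataset("refs", data=s.refs)
                    g.create_dataset("occ", data=s.occupancy)
                    g.create_dataset("sum_q2", data=s.sum_q2)
                    g.create_dataset("mean_vdw", data=s.mean_vdw)
                    g.create_dataset("frame_index", data=s.frame_index)

    @classmethod
    def load(cls, path: str | Path, table: ParameterTable | None = None
             ) -> "RotamerLibrary":
        table = table or ParameterTable.bundled()
        with h5py.File(path, "r") as fh:
            geom = GridGeometry(dbox=float(fh.attrs["dbox"]),
                                voxel=float(fh.attrs["voxel"]),
                                clr=float(fh.attrs["clr"]),
                                csoft=float(fh.attrs["csoft"]))
            lib = cls(int(fh.attrs["k"]), table, geom)
            if fh.attrs["params_digest"] != table.digest:
                raise ValueError("library was built with a different parameter table")
            for aa in fh:
                g_aa = fh[aa]
                lib.pool_totals[aa] = int(g_aa.attrs["pool_total"])
                lib.bin_stats[aa] = {int(b): (int(o), float(g))
                                     for b, o, g in g_aa["occupancy_stats"][()]}
                lib.bins[aa] = {}
                for name in g_aa:
                    if not name.startswith("bin_"):
                        continue
                    g = g_aa[name]
                    b = int(name.split("_")[1])
                    stack = RotamerStack(
                        coords=g["coords"][()], lj=g["lj"][()],
                        elec=g["elec"][()], crust=g["crust"][()],
                        core=g["core"][()].astype(bool), dg_k=g["dg_k"][()],
                        refs=g["refs"][()], occupancy=g["occ"][()],
                        sum_q2=g["sum_q2"][()], mean_vdw=g["mean_vdw"][()],
                        frame_index=g["frame_index"][()])
                    lib.bins[aa][b] = BinEntry(
                        aa, b, int(g.attrs["occupancy"]),
                        float(g.attrs["dg_pp"]),
                        str(g.attrs["atom_names"]).split(","),
                        g["bb_coords"][()], stack)
        return lib


def _pool_param_arrays(aa: str, atom_names, table: ParameterTable):
    ps = [table.atom_params(aa, nm) for nm in atom_names]
    return (np.array([p.lj_epsilon for p in ps]),
            np.array([p.lj_sigma for p in ps]),
            np.array([p.partial_charge for p in ps]),
            np.array([p.solvation_sigma for p in ps]),
            np.array([p.vdw_radius for p in ps]))


def build_library(pools, k: int, table: ParameterTable | None = None,
                  geometry: GridGeometry | None = None, seed: int = 0,
                  verbose: bool = False) -> RotamerLibrary:
    """Build a rotamer library from per-amino-acid conformer pools.

    Parameters
    ----------
    pools : dict aa -> pool with attributes ``coords`` (F, A, 3), ``phi``
        (F,), ``psi`` (F,) and ``atom_names`` (backbone first:
        N, CA, C, O, then side chain).
    k : rotamers per populated bin.
    seed : seeds the k-means initialization; the build is deterministic.

    Amino acids without a single populated bin are dropped with a notice.
    """
    table = table or ParameterTable.bundled()
    geometry = geometry or GridGeometry()
    lib = RotamerLibrary(k, table, geometry)
    for aa, pool in sorted(pools.items()):
        coords = np.asarray(pool.coords, dtype=float)
        names = list(pool.atom_names)
        n_frames = coords.shape[0]
        if n_frames == 0:
            continue
        i_ca, i_n = names.index("CA"), names.index("N")
        i_cb = names.index("HA1" if aa == "GLY" else "CB")
        bb_idx = [names.index(nm) for nm in chem.BACKBONE_ATOMS if nm in names]
        sc_idx = [j for j, nm in enumerate(names) if nm not in chem.BACKBONE_SET]
        sc_names = [names[j] for j in sc_idx]
        bins = assign_phi_psi_bin(np.asarray(pool.phi), np.asarray(pool.psi))
        bins = np.atleast_1d(bins)
        lib.pool_totals[aa] = n_frames
        lib.bin_stats[aa] = {}
        lib.bins[aa] = {}
        eps_s, sig_s, q_s, ss_s, rv_s = _pool_param_arrays(aa, sc_names, table)
        bb_params = _pool_param_arrays(aa, [names[j] for j in bb_idx], table)
        for b in sorted(set(int(x) for x in bins)):
            members = np.nonzero(bins == b)[0]
            occ_bin = members.size
            dg_pp = backbone_bin_energy(occ_bin, n_frames)
            lib.bin_stats[aa][b] = (occ_bin, dg_pp)
            if occ_bin < k:
                continue  # bin not represented in the library
            framed = np.empty_like(coords[members])
            for jj, f in enumerate(members):
                framed[jj] = align_to_frame(coords[f], coords[f, i_ca],
                                            coords[f, i_cb], coords[f, i_n])
            try:
                labels, reps, occs = cluster_conformers(framed, k,
                                                        seed=seed + b)
            except BinTooSmall:
                continue
            order = np.lexsort((reps, -occs))  # by occupancy desc, then frame
            reps, occs = reps[order], occs[order]
            entry = _make_bin_entry(aa, b, occ_bin, dg_pp, framed, reps, occs,
                                    sc_idx, sc_names, bb_idx,
                                    (eps_s, sig_s, q_s, ss_s, rv_s),
                                    bb_params, geometry)
            lib.bins[aa][b] = entry
        if not lib.bins[aa]:
            del lib.bins[aa]
            if verbose:
                print(f"note: no populated bin for {aa}; amino acid absent")
    return lib


def _make_bin_entry(aa, b, occ_bin, dg_pp, framed, reps, occs, sc_idx,
                    sc_names, bb_idx, sc_params, bb_params,
                    geometry) -> BinEntry:
    k = reps.size
    n_vox = geometry.n_voxels
    coords32 = np.empty((k, len(sc_idx), 3), dtype=np.float32)
    lj = np.empty((k, n_vox), dtype=np.float32)
    elec = np.empty((k, n_vox), dtype=np.float32)
    crust = np.empty((k, n_vox), dtype=np.float32)
    core = np.empty((k, n_vox), dtype=bool)
    dg_k = np.empty(k)
    refs = np.empty((k, 3))
    sum_q2 = np.empty(k)
    mean_vdw = np.empty(k)
    bb_coords = np.empty((k, len(bb_idx), 3))
    eps_s, sig_s, q_s, ss_s, rv_s = sc_params
    for r in range(k):
        conf = framed[reps[r]]
        side = conf[sc_idx]
        bb = conf[bb_idx]
        coords32[r] = side.astype(np.float32)
        bb_coords[r] = bb
        tensors = engine.build_rotamer_field_tensors(
            side, eps_s, sig_s, q_s, ss_s, rv_s, geom=geometry)
        lj[r] = tensors["lj_field"].astype(np.float32)
        elec[r] = tensors["elec_field"].astype(np.float32)
        crust[r] = tensors["solv_crust"].astype(np.float32)
        core[r] = tensors["core_mask"]
        # References with the stored (float32) tensors, so that library
        # scoring reproduces the cancellation at storage precision.
        stored = {"lj_field": lj[r].astype(float),
                  "elec_field": elec[r].astype(float),
                  "solv_crust": crust[r].astype(float),
                  "core_mask": core[r]}
        refs[r] = engine.compute_reference_energies(
            side, (eps_s, sig_s, q_s, ss_s, rv_s), bb, bb_params,
            geom=geometry, tensors=stored)
        dg_k[r] = cluster_energy(int(occs[r]), occ_bin)
        sum_q2[r] = float(np.sum(q_s ** 2))
        mean_vdw[r] = float(np.mean(rv_s)) if rv_s.size else 2.0
    stack = RotamerStack(coords32, lj, elec, crust, core, dg_k, refs,
                         occs.astype(int), sum_q2, mean_vdw,
                         reps.astype(int))
    return BinEntry(aa, b, int(occ_bin), float(dg_pp), list(sc_names),
                    bb_coords, stack)
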