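"""Design samplers: single-point mutagenesis, repack-all, and the
few-to-many-to-few decision-tree swarm.

All three routines are deterministic given their seed.  Energies come from
the tensor engine; side chains are always placed as library rotamers,
transformed from the backbone frame of the target position into world
coordinates.  Tie-breaking is lexicographic on (objective, branch id,
amino acid, rotamer id) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import engine
from .constants import DEFAULT_MAX_LJ, SP_MAX_LJ
from .engine import Weights, score_stack, voxelize_environment
from .geometry import from_frame
from .params import THREE_TO_ONE
from .specfile import DesignSpec
from .structure import Atom, TypedStructure


class SamplerError(ValueError):
    pass


def place_rotamer(structure: TypedStructure, position: int, aa: str,
                  entry, rid: int) -> None:
    """Replace the side chain at ``position`` with a library rotamer
    (in place).  The residue is renamed to ``aa``."""
    res = structure[position]
    ca, cb, n = structure.frame_atoms(position)
    world = from_frame(entry.stack.coords[rid].astype(float), ca, cb, n)
    from . import chem
    kept = [a for a in res.atoms if a.name in chem.BACKBONE_SET]
    res.name = aa
    res.atoms = kept
    for name, coord in zip(entry.atom_names, world):
        params = structure.table.atom_params(aa, name)
        res.atoms.append(Atom(name, name[:1], coord, params))


def _position_total(structure, position, library, weights, max_lj,
                    rid: int | None = None):
    """Energy of the current side chain at a position, or None if
    unscoreable.

    With ``rid`` the placement is known and that rotamer is scored;
    otherwise the nearest library rotamer (by side-chain RMSD) of the
    residue's own amino acid stands in for the off-library side chain.
    """
    res = structure[position]
    try:
        phi, psi = structure.phi_psi(position)
    except Exception:
        return None
    entry = library.lookup(res.name, phi, psi)
    if entry is None:
        return None
    if rid is None:
        rid = engine._nearest_rotamer(structure, position, entry)
    if rid is None:
        return None
    env = voxelize_environment(structure, position, library.geometry)
    scores = score_stack(env, entry.stack, entry.dg_pp, weights, max_lj)
    return float(scores["total"][rid])


# ---------------------------------------------------------------------------
# single-point mutagenesis (sp)
# ---------------------------------------------------------------------------

@dataclass
class SinglePointResult:
    position: int
    wt_aa: str
    energies: dict[str, float]          #: best total per amino acid
    best_rotamer: dict[str, int]
    ddg: dict[str, float]               #: energy relative to wild type
    skipped: list[str]
    weights: Weights
    max_lj: float


def single_point(structure: TypedStructure, position: int, target_aas,
                 library, weights: Weights | None = None,
                 max_lj: float = SP_MAX_LJ) -> SinglePointResult:
    """Estimate mutant energies at one position without combinatorial
    optimization: for each target amino acid, the lowest-energy rotamer in
    the position's backbone bin.  ddG is reported against the wild type.

    The side-chain conformational term is excluded by default (w_k = 0),
    as recommended for mutagenesis tasks.
    """
    weights = weights if weights is not None else Weights(w_k=0.0)
    phi, psi = structure.phi_psi(position)
    wt = structure[position].name
    aas = list(dict.fromkeys(list(target_aas) + [wt]))
    env = voxelize_environment(structure, position, library.geometry)
    energies, best_rot, skipped = {}, {}, []
    for aa in aas:
        entry = library.lookup(aa, phi, psi)
        if entry is None:
            skipped.append(aa)
            continue
        scores = score_stack(env, entry.stack, entry.dg_pp, weights, max_lj)
        rid = int(np.argmin(scores["total"]))
        energies[aa] = float(scores["total"][rid])
        best_rot[aa] = rid
    if wt not in energies:
        raise SamplerError(
            f"wild-type {wt} has no rotamers in the backbone bin at "
            f"position {position}; ddG reference undefined")
    ddg = {aa: e - energies[wt] for aa, e in energies.items()}
    return SinglePointResult(position, wt, energies, best_rot, ddg,
                             skipped, weights, max_lj)


# ---------------------------------------------------------------------------
# repack-all (ra)
# ---------------------------------------------------------------------------

@dataclass
class RepackResult:
    structure: TypedStructure
    objective_history: list[float]      #: mean per-residue energy per round
    per_residue: list[dict]
    placements: dict[int, tuple[str, int]]
    notices: list[str] = field(default_factory=list)

    @property
    def objective(self) -> float:
        return self.objective_history[-1]


def repack_all(structure: TypedStructure, library,
               weights: Weights | None = None,
               max_lj: float = DEFAULT_MAX_LJ, rounds: int = 10
               ) -> RepackResult:
    """Repack every interior residue's side chain, N- to C-terminus, for a
    number of successive rounds (10 by default).

    Each residue is replaced by its lowest-energy same-amino-acid rotamer
    against the current environment.  The side-chain conformational term
    is included (w_k = 1 default).  A round that fails to improve the
    round-end objective (mean per-residue energy) reverts and stops, so
    the reported objective history is non-increasing.
    """
    weights = weights if weights is not None else Weights()
    struct = structure.copy()
    notices: list[str] = []
    placements: dict[int, tuple[str, int]] = {}
    history: list[float] = []
    per_res: list[dict] = []
    for rnd in range(rounds):
        snapshot = struct.copy()
        snap_placements = dict(placements)
        for i in struct.interior_indices():
            res = struct[i]
            try:
                phi, psi = struct.phi_psi(i)
            except Exception:
                continue
            entry = library.lookup(res.name, phi, psi)
            if entry is None:
                if rnd == 0:
                    notices.append(f"position {i} ({res.name}): empty bin, skipped")
                continue
            env = voxelize_environment(struct, i, library.geometry)
            scores = score_stack(env, entry.stack, entry.dg_pp, weights, max_lj)
            rid = int(np.argmin(scores["total"]))
            place_rotamer(struct, i, res.name, entry, rid)
            placements[i] = (res.name, rid)
        evals = []
        for i in struct.interior_indices():
            rid = placements.get(i, (None, None))[1]
            tot = _position_total(struct, i, library, weights, max_lj, rid=rid)
            evals.append({"position": i, "total": tot,
                          "flag": None if tot is not None else "unscoreable"})
        totals = [e["total"] for e in evals if e["total"] is not None]
        obj = float(np.mean(totals)) if totals else float("nan")
        if history and obj > history[-1] + 1e-9:
            struct = snapshot
            placements = snap_placements
            notices.append(f"round {rnd + 1} did not improve; stopped early")
            break
        history.append(obj)
        per_res = evals
    return RepackResult(struct, history, per_res, placements, notices)


def select_designable_positions(structure: TypedStructure, library,
                                threshold: float = 20.0,
                                weights: Weights | None = None,
                                max_lj: float = DEFAULT_MAX_LJ,
                                rounds: int = 10) -> list[int]:
    """Positions whose per-residue energy after a repack-all pass exceeds
    ``threshold`` (kcal/mol; 20 by default), in ascending order."""
    result = repack_all(structure, library, weights, max_lj, rounds)
    return sorted(e["position"] for e in result.per_residue
                  if e["total"] is not None and e["total"] > threshold)


# ---------------------------------------------------------------------------
# few-to-many-to-few decision-tree swarm (cs_f2m2f)
# ---------------------------------------------------------------------------

@dataclass
class Decoy:
    """One output design of the combinatorial sampler."""

    sequence: str
    rotamer_ids: dict[int, tuple[str, int]]
    structure: TypedStructure
    objective: float                    #: mean per-residue energy
    total: float                        #: summed energy over focus positions
    path_id: int
    seed: int


class DecoyList(list):
    """List of decoys with sampler statistics attached."""

    stats: dict


@dataclass
class _Branch:
    struct: TypedStructure
    decided: dict[int, tuple[str, int]]
    objective: float
    total: float
    bid: int


def _branch_objective(struct, focus, library, weights, max_lj, decided=None):
    """Mean and summed per-residue energy over the focus positions,
    scoring recorded placements directly."""
    decided = decided or {}
    totals = []
    for pos in focus:
        rid = decided[pos][1] if pos in decided else None
        t = _position_total(struct, pos, library, weights, max_lj, rid=rid)
        if t is not None:
            totals.append(t)
    if not totals:
        return float("inf"), float("inf")
    return float(np.mean(totals)), float(np.sum(totals))


def _refresh_repackables(struct, rpk, library, weights, max_lj, decided):
    """One N->C same-amino-acid repack pass over the repackable positions."""
    for pos in sorted(rpk):
        res = struct[pos]
        try:
            phi, psi = struct.phi_psi(pos)
        except Exception:
            continue
        entry = library.lookup(res.name, phi, psi)
        if entry is None:
            continue
        env = voxelize_environment(struct, pos, library.geometry)
        scores = score_stack(env, entry.stack, entry.dg_pp, weights, max_lj)
        rid = int(np.argmin(scores["total"]))
        place_rotamer(struct, pos, res.name, entry, rid)
        decided[pos] = (res.name, rid)


def cs_f2m2f(structure: TypedStructure, spec: DesignSpec, library
             ) -> DecoyList:
    """Combinatorial design by a decision-tree swarm.

    Mutable positions form the depth levels of a decision tree; at each
    level every surviving branch expands to its top ``m_mutations`` amino
    acids (ranked by single-position energy in that branch's context,
    best rotamer each), repackable residues are refreshed within each
    expanded branch, and the expanded set is trimmed back to ``n_paths``
    survivors by ascending objective (mean per-residue energy over the
    mutable and repackable positions).  Each parent branch also survives
    into the expansion unmutated, so the incumbent best never worsens; the
    traversal is repeated ``n_iters`` times from the incumbent survivors.

    Deterministic given ``spec.random_seed`` (which also drives the
    optional scrambling of the position order).  Returns the final
    ``n_paths`` decoys in ascending objective; ``.stats`` carries the
    per-level count of mutation-candidate rotamer scorings.
    """
    mut, rpk = spec.resolve(structure)
    weights = spec.weights
    max_lj = spec.max_lj
    rng = np.random.default_rng(spec.random_seed)
    order = list(range(len(mut)))
    if spec.scramble_order:
        order = [int(i) for i in rng.permutation(len(mut))]
    focus = sorted({p for p, _ in mut} | set(rpk))

    obj0, tot0 = _branch_objective(structure, focus, library, weights, max_lj)
    root = _Branch(structure.copy(), {}, obj0, tot0, 0)
    survivors = [root]
    next_bid = 1
    level_scorings: list[int] = []
    notices: list[str] = []

    for it in range(spec.n_iters):
        for li in order:
            pos, allowed = mut[li]
            allowed_sorted = sorted(set(allowed))
            scorings = 0
            children: list[_Branch] = list(survivors)  # parents carry through
            for branch in survivors:
                try:
                    phi, psi = branch.struct.phi_psi(pos)
                except Exception:
                    notices.append(f"position {pos}: no torsions; kept as is")
                    continue
                env = voxelize_environment(branch.struct, pos, library.geometry)
                cand = []
                for aa in allowed_sorted:
                    entry = library.lookup(aa, phi, psi)
                    if entry is None:
                        continue
                    scores = score_stack(env, entry.stack, entry.dg_pp,
                                         weights, max_lj)
                    scorings += entry.k
                    rid = int(np.argmin(scores["total"]))
                    cand.append((float(scores["total"][rid]), aa, rid))
                if not cand:
                    notices.append(
                        f"position {pos}: no feasible mutation in branch "
                        f"{branch.bid}; carries current residue")
                    continue
                cand.sort()
                for _, aa, rid in cand[:spec.m_mutations]:
                    child_struct = branch.struct.copy()
                    entry = library.lookup(aa, phi, psi)
                    place_rotamer(child_struct, pos, aa, entry, rid)
                    decided = dict(branch.decided)
                    decided[pos] = (aa, rid)
                    _refresh_repackables(child_struct, rpk, library, weights,
                                         max_lj, decided)
                    obj, tot = _branch_objective(child_struct, focus, library,
                                                 weights, max_lj, decided)
                    children.append(_Branch(child_struct, decided, obj, tot,
                                            next_bid))
                    next_bid += 1
            parent_ids = {b.bid for b in survivors}
            # On exact objective ties a freshly placed branch beats the
            # carried-through parent, so decided positions are recorded.
            children.sort(key=lambda b: (b.objective, b.bid in parent_ids,
                                         b.bid))
            survivors = children[:spec.n_paths]
            level_scorings.append(scorings)

    decoys = DecoyList()
    for rank, b in enumerate(survivors):
        decoys.append(Decoy(b.struct.sequence, dict(b.decided), b.struct,
                            b.objective, b.total, rank, spec.random_seed))
    decoys.stats = {
        "level_scorings": level_scorings,
        "work_bound": spec.n_paths * spec.m_mutations * library.k,
        "notices": notices,
        "order": order,
    }
    return decoys


def run_replicas(structure: TypedStructure, spec: DesignSpec, library,
                 replicas: int = 1) -> DecoyList:
    """Run several independent sampler replicas (seed looped from the spec
    seed) and merge their decoys, de-duplicated by sequence, ascending
    objective."""
    import dataclasses
    merged: dict[str, Decoy] = {}
    all_stats = []
    for r in range(replicas):
        rspec = dataclasses.replace(spec, random_seed=spec.random_seed + r,
                                    scramble_order=spec.scramble_order or replicas > 1)
        decoys = cs_f2m2f(structure, rspec, library)
        all_stats.append(decoys.stats)
        for d in decoys:
            if d.sequence not in merged or d.objective < merged[d.sequence].objective:
                merged[d.sequence] = d
    out = DecoyList(sorted(merged.values(), key=lambda d: (d.objective, d.seed)))
    out.stats = {"replicas": all_stats}
    return out
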