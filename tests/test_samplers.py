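"""Design samplers: single-point, repack-all, decision-tree swarm."""

import dataclasses

import numpy as np
import pytest

import voxpack as vp
from voxpack import engine
from voxpack.engine import score_stack, voxelize_environment
from voxpack.samplers import SamplerError, place_rotamer
from voxpack.specfile import DesignSpec, Position
from conftest import HELIX_BIN

AAS = ["ALA", "LEU", "SER", "VAL"]


# ---------------------------------------------------------------------------
# single-point (sp)
# ---------------------------------------------------------------------------

def test_sp_wild_type_ddg_is_zero(helix, lib):
    sp = vp.single_point(helix, 3, AAS, lib)
    assert sp.ddg[helix[3].name] == 0.0


def test_sp_matches_exhaustive_rotamer_loop(helix, lib):
    """The reported minimum equals an explicit loop over every rotamer of
    every candidate amino acid."""
    pos = 2
    sp = vp.single_point(helix, pos, AAS, lib)
    phi, psi = helix.phi_psi(pos)
    env = voxelize_environment(helix, pos, lib.geometry)
    for aa in AAS:
        entry = lib.lookup(aa, phi, psi)
        best = np.inf
        best_rid = None
        scores = score_stack(env, entry.stack, entry.dg_pp, sp.weights,
                             sp.max_lj)
        for rid in range(entry.k):
            if scores["total"][rid] < best:
                best, best_rid = float(scores["total"][rid]), rid
        assert sp.energies[aa] == pytest.approx(best, rel=1e-12)
        assert sp.best_rotamer[aa] == best_rid


def test_sp_default_parameters_echoed(helix, lib):
    """The mutagenesis defaults (max_lj 10, w_k 0, w_elec 0.25) are applied
    and reported back."""
    sp = vp.single_point(helix, 3, AAS, lib)
    assert sp.max_lj == 10.0
    assert sp.weights.w_k == 0.0
    assert sp.weights.w_elec == 0.25
    assert sp.weights.w_pp == sp.weights.w_lj == sp.weights.w_solv == 1.0


def test_sp_skips_amino_acids_without_rotamers(helix, lib):
    sp = vp.single_point(helix, 3, AAS + ["TRP"], lib)
    assert "TRP" in sp.skipped and "TRP" not in sp.energies


# ---------------------------------------------------------------------------
# repack-all (ra)
# ---------------------------------------------------------------------------

def test_ra_objective_monotone_and_fixed_point(helix, lib):
    """The round objective never increases, and a structure already at its
    per-position optimum is unchanged by further rounds."""
    res = vp.repack_all(helix, lib, rounds=10)
    hist = res.objective_history
    assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))
    # idempotence: repacking the result again changes nothing
    res2 = vp.repack_all(res.structure, lib, rounds=3)
    assert res2.structure.sequence == res.structure.sequence
    c1 = np.vstack([a.coord for _, a in res.structure.all_atoms()])
    c2 = np.vstack([a.coord for _, a in res2.structure.all_atoms()])
    assert np.abs(c1 - c2).max() < 1e-9
    assert res2.objective == pytest.approx(res.objective, abs=1e-9)


@pytest.mark.parametrize("seed", range(4))
def test_ra_monotone_on_random_fixtures(seed, table, lib):
    """Monotone objective across rounds for randomized starting chi."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ALSV"), size=7))
    chis = {i: [float(rng.choice([-170, -60, 60]))] * 4 for i in range(7)}
    s = vp.generate_toy_structure("helix", 7, table, sequence=seq, chis=chis)
    res = vp.repack_all(s, lib, rounds=10)
    hist = res.objective_history
    assert len(hist) >= 1
    assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))


def test_ra_default_rounds_is_ten(helix, lib):
    import inspect
    assert inspect.signature(vp.repack_all).parameters["rounds"].default == 10


def test_ra_skips_unscoreable_residues(table, lib):
    s = vp.generate_toy_structure("helix", 6, table, sequence="AAGAAA")
    res = vp.repack_all(s, lib, rounds=2)
    assert any("empty bin" in n for n in res.notices)
    assert s[2].name == "GLY"  # untouched


# ---------------------------------------------------------------------------
# decision-tree swarm (cs_f2m2f)
# ---------------------------------------------------------------------------

def _strand_spec(**kw):
    base = dict(
        mut_res=[(Position("A", 3), AAS), (Position("A", 13), AAS),
                 (Position("A", 23), AAS)],
        rpk_res=[], m_mutations=4, n_paths=64, n_iters=1,
        weights=vp.Weights(w_k=0.0), max_lj=10.0, random_seed=0)
    base.update(kw)
    return DesignSpec(**base)


@pytest.fixture(scope="module")
def strand(table):
    """Extended chain whose mutable positions (2, 12, 22) are so far apart
    that each sits outside the others' simulation cubes: the objective
    decomposes exactly over positions."""
    s = vp.generate_toy_structure("strand", 25, table)
    ca = {i: s[i].atom("CA").coord for i in (2, 12, 22)}
    for i in (2, 12):
        assert np.linalg.norm(ca[i] - ca[i + 10]) > 22.0 * np.sqrt(3) / 2 + 5
    return s


def test_cs_equals_exhaustive_enumeration_on_toy(strand, lib):
    """With n_paths >= 4^3 the swarm recovers the optimum of brute-force
    enumeration over all 64 sequences of a 3-position x 4-amino-acid toy
    with decoupled positions."""
    spec = _strand_spec()
    decoys = vp.cs_f2m2f(strand, spec, lib)
    # independent per-position argmin (valid because positions decouple)
    best_sum = 0.0
    best_seq = list(strand.sequence)
    for pos in (2, 12, 22):
        sp = vp.single_point(strand, pos, AAS, lib,
                             weights=spec.weights, max_lj=spec.max_lj)
        aa, e = min(sp.energies.items(), key=lambda kv: (kv[1], kv[0]))
        best_sum += e
        best_seq[pos] = vp.THREE_TO_ONE[aa]
    assert decoys[0].sequence == "".join(best_seq)
    assert decoys[0].objective == pytest.approx(best_sum / 3.0, rel=1e-9)


def test_cs_degenerate_tree_equals_single_point(strand, lib):
    """One position, m_mutations >= alphabet, n_paths = 1, n_iters = 1
    reduces to the single-point argmin."""
    spec = _strand_spec(mut_res=[(Position("A", 13), AAS)], n_paths=1)
    decoys = vp.cs_f2m2f(strand, spec, lib)
    sp = vp.single_point(strand, 12, AAS, lib, weights=spec.weights,
                         max_lj=spec.max_lj)
    best_aa, _ = min(sp.energies.items(), key=lambda kv: (kv[1], kv[0]))
    aa, rid = decoys[0].rotamer_ids[12]
    assert aa == best_aa
    assert rid == sp.best_rotamer[best_aa]


def test_cs_trimming_contract(strand, lib):
    """Survivors never exceed n_paths and come out ascending in objective."""
    spec = _strand_spec(n_paths=3, n_iters=1)
    decoys = vp.cs_f2m2f(strand, spec, lib)
    assert len(decoys) == 3
    objs = [d.objective for d in decoys]
    assert objs == sorted(objs)


def test_cs_deterministic_given_seed(strand, lib):
    spec = _strand_spec(n_paths=5, scramble_order=True, random_seed=77)
    d1 = vp.cs_f2m2f(strand, spec, lib)
    d2 = vp.cs_f2m2f(strand, spec, lib)
    assert [(d.sequence, d.objective, tuple(sorted(d.rotamer_ids.items())))
            for d in d1] == \
           [(d.sequence, d.objective, tuple(sorted(d.rotamer_ids.items())))
            for d in d2]


def test_cs_work_bound(strand, lib):
    """Per level, at most n_paths x m_mutations x k mutation-candidate
    rotamer scorings (here |alphabet| = m_mutations)."""
    spec = _strand_spec(n_paths=4, m_mutations=4, n_iters=2)
    decoys = vp.cs_f2m2f(strand, spec, lib)
    bound = spec.n_paths * spec.m_mutations * lib.k
    assert decoys.stats["work_bound"] == bound
    assert all(c <= bound for c in decoys.stats["level_scorings"])


def test_cs_more_iterations_never_worsen_incumbent(strand, lib):
    spec1 = _strand_spec(n_paths=2, m_mutations=2, n_iters=1, random_seed=5)
    spec2 = dataclasses.replace(spec1, n_iters=3)
    b1 = vp.cs_f2m2f(strand, spec1, lib)[0].objective
    b2 = vp.cs_f2m2f(strand, spec2, lib)[0].objective
    assert b2 <= b1 + 1e-12


def test_cs_more_paths_never_worsen_on_shared_ordering(strand, lib):
    spec_small = _strand_spec(n_paths=1, m_mutations=2, random_seed=3)
    spec_big = dataclasses.replace(spec_small, n_paths=6)
    b_small = vp.cs_f2m2f(strand, spec_small, lib)[0].objective
    b_big = vp.cs_f2m2f(strand, spec_big, lib)[0].objective
    assert b_big <= b_small + 1e-12


def test_cs_repackables_are_refreshed(table, lib):
    """Repackable residues are re-optimized within surviving branches."""
    s = vp.generate_toy_structure("helix", 8, table, sequence="ALVALSLA",
                                  chis={4: [60.0, 60.0]})
    spec = DesignSpec(mut_res=[(Position("A", 4), AAS)],
                      rpk_res=[Position("A", 5)], m_mutations=2, n_paths=2,
                      n_iters=1, weights=vp.Weights(w_k=0.0), max_lj=10.0)
    decoys = vp.cs_f2m2f(s, spec, lib)
    assert 4 in decoys[0].rotamer_ids          # repack placement recorded
    assert decoys[0].rotamer_ids[4][0] == "LEU"  # same-aa repack


def test_run_replicas_dedupes_by_sequence(strand, lib):
    spec = _strand_spec(n_paths=3, scramble_order=True)
    merged = vp.run_replicas(strand, spec, lib, replicas=3)
    seqs = [d.sequence for d in merged]
    assert len(seqs) == len(set(seqs))
    objs = [d.objective for d in merged]
    assert objs == sorted(objs)


def test_place_rotamer_renames_and_rebuilds(helix, lib):
    s = helix.copy()
    entry = lib.get("SER", HELIX_BIN)
    place_rotamer(s, 3, "SER", entry, 0)
    assert s[3].name == "SER"
    assert s[3].has_atom("OG") and s[3].has_atom("CB")
    assert s.sequence == "ALVSLSLA"
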