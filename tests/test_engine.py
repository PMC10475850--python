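"""Voxelized energy engine: pairwise potentials, field tensors,
environment projection, and the tensor-vs-brute-force equivalence."""

import numpy as np
import pytest

import voxpack as vp
from voxpack import engine, synthetic
from voxpack.engine import (born_self, coulomb_factor, env_from_atoms,
                            gb_bracket, score_rotamer, solvation_energy,
                            voxelize_environment)
from conftest import HELIX_BIN


# ---------------------------------------------------------------------------
# closed-form pairwise checks
# ---------------------------------------------------------------------------

def test_lj_branch_values(geom):
    eps, sig = 0.2, 3.6
    # zero crossing of the attractive branch at r = sigma
    assert vp.lj_pairwise(sig, eps, sig, geom) == 0.0
    # minimum -eps/4 at r = 2^(1/6) sigma for this unprefactored form
    assert vp.lj_pairwise(2 ** (1 / 6) * sig, eps, sig, geom) == pytest.approx(
        -eps / 4, rel=1e-12)
    # flat 16 eps plateau below sigma - c_hard with c_hard = sigma/2
    for r in (0.1, 0.5, sig / 2):
        assert vp.lj_pairwise(r, eps, sig, geom) == pytest.approx(16 * eps,
                                                                  rel=1e-12)
    # soft band value
    r = sig - 0.3  # inside (sigma - sigma/2, sigma - 0.25]
    assert vp.lj_pairwise(r, eps, sig, geom) == pytest.approx(
        eps * sig ** 2 / r ** 2, rel=1e-12)
    # zero beyond cutoff
    assert vp.lj_pairwise(7.01, eps, sig, geom) == 0.0
    with pytest.raises(ValueError):
        vp.lj_pairwise(-1.0, eps, sig, geom)


def test_lj_branches_are_continuous_in_energy_order(geom):
    """The piecewise branches meet without a sign-inverting jump: the soft
    band dominates the attractive branch near the crust, and the plateau
    caps the soft band."""
    eps, sig = 0.15, 3.8
    r = np.linspace(0.2, 7.0, 2000)
    e = vp.lj_pairwise(r, eps, sig, geom)
    assert np.all(np.isfinite(e))
    assert e.max() == pytest.approx(16 * eps)


def test_elec_reduces_to_coulomb_when_dielectrics_match(geom):
    """With eps_p = eps_s both GB corrections vanish: 332 q_i q_j / r^2."""
    val = vp.elec_pairwise(4.0, 1.0, 1.0, b_bar=2.0, geom=geom,
                           eps_p=75.0, eps_s=75.0, include_self=False)
    assert val == pytest.approx(332.0 / 16.0, rel=1e-12)
    # leading factor before the bracket at r=4 with eps(r)=r
    assert float(coulomb_factor(4.0, geom)) == pytest.approx(20.75, rel=1e-12)


def test_born_self_term_arithmetic():
    """-166/2 * (1/8 - 1/75) per unit charge at b_bar = 2 A."""
    assert float(born_self(1.0, 2.0)) == pytest.approx(-9.26833, abs=5e-6)
    with pytest.raises(ValueError):
        born_self(1.0, -1.0)


def test_gb_bracket_properties(geom):
    assert gb_bracket(2.0, geom, 75.0, 75.0) == pytest.approx(1.0)
    b = gb_bracket(2.0, geom)
    assert 0.0 < b < 1.0


# ---------------------------------------------------------------------------
# field tensors
# ---------------------------------------------------------------------------

def test_single_atom_field_has_cubic_symmetry(geom):
    """A source at the grid centre produces an LJ field invariant under
    the 48 cube symmetries (axis permutations and flips)."""
    tensors = engine.build_rotamer_field_tensors(
        np.array([[0.25, 0.25, 0.25]]),  # a voxel centre: exact symmetry
        np.array([0.2]), np.array([3.5]), np.array([0.5]),
        np.array([0.01]), np.array([1.8]), geom=geom)
    f = tensors["lj_field"].reshape(44, 44, 44)
    # The grid centres are symmetric about the atom under index reversal
    # around voxel 22 paired with 22 -> i <-> 44+ -1 - ... use the mirror
    # through the occupied voxel: i -> 45 - i is out of range, so compare
    # the symmetric sub-block around index 22.
    sub = f[1:44, 1:44, 1:44]  # 43^3 block centred on voxel (22,22,22)
    for perm in [(0, 1, 2), (1, 0, 2), (2, 1, 0), (0, 2, 1), (1, 2, 0),
                 (2, 0, 1)]:
        assert np.allclose(sub, np.transpose(sub, perm), atol=1e-12)
    for ax in range(3):
        assert np.allclose(sub, np.flip(sub, axis=ax), atol=1e-12)


def test_fields_vanish_beyond_cutoff(geom):
    coords = np.array([[1.0, -2.0, 0.5]])
    tensors = engine.build_rotamer_field_tensors(
        coords, np.array([0.2]), np.array([3.5]), np.array([-0.4]),
        np.array([0.01]), np.array([1.8]), geom=geom)
    centers = geom.voxel_centers()
    far = np.linalg.norm(centers - coords[0], axis=1) > geom.clr
    assert np.all(tensors["lj_field"][far] == 0.0)
    assert np.all(tensors["elec_field"][far] == 0.0)


def test_empty_atom_set_gives_zero_fields(geom):
    tensors = engine.build_rotamer_field_tensors(
        np.zeros((0, 3)), np.zeros(0), np.zeros(0), np.zeros(0),
        np.zeros(0), np.zeros(0), geom=geom)
    for name in ("lj_field", "elec_field", "solv_crust"):
        assert not tensors[name].any()
    assert not tensors["core_mask"].any()


# ---------------------------------------------------------------------------
# environment projection
# ---------------------------------------------------------------------------

def test_environment_conservation_laws(geom, rand_atoms):
    """Occupancy totals the in-box atoms; the charge tensor totals their
    partial charges; out-of-box atoms are ignored."""
    rng = np.random.default_rng(2)
    atoms = rand_atoms(rng, 30, scale=14.0)  # some atoms outside the cube
    env = env_from_atoms(*atoms, geom=geom)
    idx = geom.voxel_indices(atoms[0])
    inside = geom.in_box(idx)
    assert env.occupancy.sum() == inside.sum()
    assert env.charge.sum() == pytest.approx(atoms[3][inside].sum(), abs=1e-12)


def test_empty_environment_and_born_fallback(geom):
    env = env_from_atoms(np.zeros((0, 3)), *(np.zeros(0),) * 5, geom=geom)
    assert env.filled_fraction == 0.0 and env.b_bar is None
    assert env.effective_b_bar(np.array([1.9])) == pytest.approx(1.9)
    assert env.effective_b_bar() == pytest.approx(2.0)


def test_born_radius_scales_with_filled_volume(geom, rand_atoms):
    rng = np.random.default_rng(4)
    small = rand_atoms(rng, 3, scale=3.0)
    big = rand_atoms(rng, 40, scale=8.0)
    e1, e2 = env_from_atoms(*small, geom=geom), env_from_atoms(*big, geom=geom)
    assert 0 < e1.filled_fraction < e2.filled_fraction
    assert e1.b_bar == pytest.approx(geom.dbox * e1.filled_fraction)


# ---------------------------------------------------------------------------
# solvation
# ---------------------------------------------------------------------------

def test_solvation_zero_without_mutual_occlusion(geom, table):
    p = table["CH3"]
    mk = lambda c: engine.build_rotamer_field_tensors(
        np.array([c]), np.array([p.lj_epsilon]), np.array([p.lj_sigma]),
        np.array([p.partial_charge]), np.array([p.solvation_sigma]),
        np.array([p.vdw_radius]), geom=geom)
    env = env_from_atoms(np.array([[9.0, 9.0, 9.0]]),
                         np.array([p.lj_epsilon]), np.array([p.lj_sigma]),
                         np.array([p.partial_charge]),
                         np.array([p.solvation_sigma]),
                         np.array([p.vdw_radius]), geom=geom)
    t = mk([-9.0, -9.0, -9.0])
    assert solvation_energy(env, t["solv_crust"], t["core_mask"]) == 0.0


def test_fully_engulfed_atom_buries_its_whole_crust(geom, table):
    """An environment atom whose crust lies entirely inside the rotamer
    core contributes exactly -sigma_solv * A of newly buried surface."""
    small = table["HVR"]   # vdw 1.32 -> crust within 1.82 A
    big = table["CH1"]     # vdw 2.27 engulfs it when concentric
    env = env_from_atoms(np.array([[0.25, 0.25, 0.25]]),
                         np.array([small.lj_epsilon]),
                         np.array([small.lj_sigma]), np.array([0.0]),
                         np.array([small.solvation_sigma]),
                         np.array([small.vdw_radius]), geom=geom)
    t = engine.build_rotamer_field_tensors(
        np.array([[0.25, 0.25, 0.25]]), np.array([big.lj_epsilon]),
        np.array([big.lj_sigma]), np.array([0.0]),
        np.array([big.solvation_sigma]), np.array([big.vdw_radius]),
        geom=geom)
    got = solvation_energy(env, t["solv_crust"], t["core_mask"])
    area = 4 * np.pi * small.vdw_radius ** 2
    assert got == pytest.approx(-small.solvation_sigma * area, rel=1e-9)


def test_solvation_is_linear_in_sigma(geom, rand_atoms):
    rng = np.random.default_rng(8)
    env_atoms = rand_atoms(rng, 6, scale=3.0)
    rot_atoms = rand_atoms(rng, 3, scale=2.0)
    env1 = env_from_atoms(*env_atoms, geom=geom)
    doubled = list(env_atoms)
    doubled[4] = env_atoms[4] * 2.0
    env2 = env_from_atoms(*doubled, geom=geom)
    t1 = engine.build_rotamer_field_tensors(rot_atoms[0], *rot_atoms[1:],
                                            geom=geom)
    r2 = list(rot_atoms)
    r2[4] = rot_atoms[4] * 2.0
    t2 = engine.build_rotamer_field_tensors(r2[0], *r2[1:], geom=geom)
    s1 = solvation_energy(env1, t1["solv_crust"], t1["core_mask"])
    s2 = solvation_energy(env2, t2["solv_crust"], t2["core_mask"])
    assert s2 == pytest.approx(2 * s1, rel=1e-9)


# ---------------------------------------------------------------------------
# assembled scoring
# ---------------------------------------------------------------------------

def test_tensor_engine_matches_brute_force_oracle(geom, rand_atoms):
    """Voxel-snapped double-loop energies equal the tensor evaluation:
    LJ to 1e-12 relative, assembled electrostatics to 1e-9."""
    rng = np.random.default_rng(23)
    for _ in range(15):
        env_atoms = rand_atoms(rng, int(rng.integers(3, 14)))
        rot_atoms = rand_atoms(rng, int(rng.integers(1, 6)), scale=3.0)
        oracle = synthetic.brute_force_energy(env_atoms, rot_atoms, geom)
        env = env_from_atoms(*env_atoms, geom=geom)
        t = engine.build_rotamer_field_tensors(rot_atoms[0], *rot_atoms[1:],
                                               geom=geom)
        bd = score_rotamer(env, t, 0.0, 0.0, (0, 0, 0), vp.Weights(),
                           max_lj=np.inf, rot_q=rot_atoms[3],
                           rot_vdw=rot_atoms[5])
        solv = solvation_energy(env, t["solv_crust"], t["core_mask"])
        assert bd.dg_lj == pytest.approx(oracle["lj"], rel=1e-12, abs=1e-12)
        assert bd.dg_elec == pytest.approx(oracle["elec"], rel=1e-9)
        assert solv == pytest.approx(oracle["solv"], rel=1e-9, abs=1e-12)


def test_clash_cap_skips_remaining_terms(geom, table):
    """A rotamer overlapping environment atoms trips the tiered-scoring
    cap at max_lj = 5 and reports the LJ term only."""
    p = table["CQ"]
    coords = np.array([[0.1, 0.1, 0.1], [0.6, 0.1, 0.1], [0.1, 0.6, 0.1]])
    args = (np.full(3, p.lj_epsilon), np.full(3, p.lj_sigma),
            np.full(3, p.partial_charge), np.full(3, p.solvation_sigma),
            np.full(3, p.vdw_radius))
    env = env_from_atoms(coords, *args, geom=geom)
    t = engine.build_rotamer_field_tensors(coords, *args, geom=geom)
    bd = score_rotamer(env, t, 0.0, 0.0, (1.0, 1.0, 1.0), vp.Weights(),
                       max_lj=5.0, rot_q=args[2], rot_vdw=args[4])
    assert bd.clash and bd.dg_lj > 5.0
    assert bd.dg_solv == 0.0 and bd.dg_elec == 0.0
    assert bd.dg_solv_ref == 0.0 and bd.dg_elec_ref == 0.0
    assert bd.total == pytest.approx(bd.dg_lj - bd.dg_lj_ref)


def test_energy_breakdown_total_identity(geom, rand_atoms):
    rng = np.random.default_rng(11)
    env_atoms = rand_atoms(rng, 8)
    rot_atoms = rand_atoms(rng, 3, scale=3.0)
    env = env_from_atoms(*env_atoms, geom=geom)
    t = engine.build_rotamer_field_tensors(rot_atoms[0], *rot_atoms[1:],
                                           geom=geom)
    w = vp.Weights(0.7, 0.3, 1.1, 0.9, 0.25)
    bd = score_rotamer(env, t, 0.4, 0.2, (0.1, -0.2, 0.3), w, max_lj=np.inf,
                       rot_q=rot_atoms[3], rot_vdw=rot_atoms[5])
    expect = (w.w_pp * bd.dg_pp + w.w_k * bd.dg_k
              + w.w_lj * (bd.dg_lj - bd.dg_lj_ref)
              + w.w_solv * (bd.dg_solv - bd.dg_solv_ref)
              + w.w_elec * (bd.dg_elec - bd.dg_elec_ref))
    assert bd.total == pytest.approx(expect, rel=1e-12)


def test_cutoff_locality_of_interaction_terms(geom, table):
    """Moving an environment atom between positions beyond the cutoff of
    every rotamer atom changes neither the LJ sum nor the Coulomb part."""
    p = table["CH2"]
    rot = (np.array([[0.0, 0.0, 1.5]]), np.array([p.lj_epsilon]),
           np.array([p.lj_sigma]), np.array([p.partial_charge]),
           np.array([p.solvation_sigma]), np.array([p.vdw_radius]))
    t = engine.build_rotamer_field_tensors(rot[0], *rot[1:], geom=geom)

    def lj_coul(far_x):
        coords = np.array([[2.0, 0.0, 1.0], [far_x, 0.0, 1.5]])
        args = (np.full(2, p.lj_epsilon), np.full(2, p.lj_sigma),
                np.full(2, p.partial_charge), np.full(2, p.solvation_sigma),
                np.full(2, p.vdw_radius))
        env = env_from_atoms(coords, *args, geom=geom)
        return (float(t["lj_field"] @ env.occupancy),
                float(t["elec_field"] @ env.charge))

    base = lj_coul(8.5)   # beyond 7 A + voxel diagonal from the rotamer atom
    moved = lj_coul(10.3)
    assert base == moved


def test_per_residue_energies_on_helix(helix, lib):
    """Interior residues score finite; terminal residues are excluded; a
    residue whose bin is unpopulated is flagged unscoreable."""
    rows = engine.per_residue_energies(helix, lib)
    assert [r["position"] for r in rows] == helix.interior_indices()
    assert all(np.isfinite(r["total"]) for r in rows)

    # force an empty bin: glycine is not in this library
    seq = "AAGAA"
    s = vp.generate_toy_structure("helix", 5, helix.table, sequence=seq)
    rows = engine.per_residue_energies(s, lib)
    flags = {r["position"]: r["flag"] for r in rows}
    assert flags[2] == "empty-bin"


def test_energy_invariant_under_global_rigid_motion(helix, lib):
    """Frame alignment absorbs a global rotation+translation of the input
    structure (<= 1e-6 kcal/mol on per-residue totals)."""
    from scipy.spatial.transform import Rotation
    from voxpack.structure import transformed_copy
    rot = Rotation.from_euler("zyx", [0.4, -1.2, 2.2]).as_matrix()
    moved = transformed_copy(helix, rot, np.array([13.0, -4.0, 7.5]))
    r1 = engine.per_residue_energies(helix, lib)
    r2 = engine.per_residue_energies(moved, lib)
    for a, b in zip(r1, r2):
        assert a["total"] == pytest.approx(b["total"], abs=1e-6)
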