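"""Recovery benchmarks, ddG correlation, and chelation fits."""

import numpy as np
import pytest

import voxpack as vp
from voxpack.constants import KD_CU_ZINCON, ZINCON_EPSILON
from voxpack.evaluation import (_cu_zi_from_kex, cu_zincon_concentration,
                                kex_of_concentrations, torsion_correct)


# ---------------------------------------------------------------------------
# torsion comparison
# ---------------------------------------------------------------------------

def test_circular_difference_range_and_wrap():
    """The circular difference lives in [0, 180]; -175 vs 175 differ by 10."""
    assert vp.circular_difference(-175.0, 175.0) == pytest.approx(10.0)
    assert vp.circular_difference(0.0, 180.0) == pytest.approx(180.0)
    rng = np.random.default_rng(0)
    for a, b in rng.uniform(-360, 360, size=(200, 2)):
        d = vp.circular_difference(a, b)
        assert 0.0 <= d <= 180.0


def test_torsion_tolerance_is_a_closed_bound():
    """An error of exactly 40 degrees still counts as correct."""
    assert torsion_correct(10.0, 50.0)
    assert not torsion_correct(10.0, 50.0001)
    # two-fold symmetric terminal group: 0 vs 180 are the same state
    assert torsion_correct(0.0, 180.0, period=180.0)


# ---------------------------------------------------------------------------
# rotamer recovery
# ---------------------------------------------------------------------------

def test_rotamer_recovery_of_library_side_chains(helix, lib):
    """Side chains placed from the library are recovered at 100% chi1 and
    chi1&2 (zero-noise self-recovery)."""
    native = vp.repack_all(helix, lib, rounds=2).structure
    report = vp.rotamer_recovery(native, lib, rounds=3)
    assert report.chi1_accuracy == 100.0
    assert report.chi12_accuracy == 100.0
    # Gly/Ala carry no chi1 and never enter the denominators
    assert all(r["aa"] not in ("GLY", "ALA") for r in report.records)


def test_rotamer_recovery_buried_flag_uses_sasa(helix, lib):
    report = vp.rotamer_recovery(helix, lib, rounds=1)
    assert all(isinstance(r["buried"], bool) for r in report.records)
    # a small helix is fully solvent-exposed at a 5 A^2 threshold
    assert report.chi1_accuracy_core is None


# ---------------------------------------------------------------------------
# sequence recovery
# ---------------------------------------------------------------------------

def test_sequence_recovery_on_engineered_optimum(table, lib):
    """A poly-Ala helix whose native residue is the energetic optimum at
    every interior position recovers 100% over the library alphabet."""
    s = vp.generate_toy_structure("helix", 8, table)
    # engineered-fixture premise: ALA must be the sp optimum everywhere
    for i in s.interior_indices():
        sp = vp.single_point(s, i, ["ALA", "LEU", "SER", "VAL"], lib)
        assert min(sp.energies, key=lambda a: (sp.energies[a], a)) == "ALA"
    pct, records = vp.sequence_recovery(
        s, lib, target_aas=["ALA", "LEU", "SER", "VAL"])
    assert pct == 100.0
    assert len(records) == len(s.interior_indices())


def test_sequence_recovery_undefined_for_tiny_chain(table, lib):
    """After terminal exclusion a two-residue chain has no scoreable
    positions: recovery is reported as not applicable."""
    s = vp.generate_toy_structure("helix", 2, table)
    pct, records = vp.sequence_recovery(s, lib,
                                        target_aas=["ALA", "SER"])
    assert pct is None and records == []


def test_sequence_recovery_excludes_unscoreable_positions(table, lib):
    s = vp.generate_toy_structure("helix", 6, table, sequence="AAGAAA")
    pct, records = vp.sequence_recovery(s, lib,
                                        target_aas=["ALA", "SER", "VAL"])
    flags = {r["position"]: r["flag"] for r in records}
    assert flags[2] == "unscoreable"  # glycine absent from this library
    assert pct is not None


# ---------------------------------------------------------------------------
# ddG benchmark
# ---------------------------------------------------------------------------

def test_ddg_pearson_limits_and_formula(helix, lib):
    """R = 1 against the predictions themselves, R = -1 against their
    negation, and R matches the covariance formula to 1e-12."""
    muts = [(pos, helix.sequence[pos], m, 0.0)
            for pos in (1, 2, 3, 4, 5)
            for m in ("A", "L", "S", "V")
            if m != helix.sequence[pos]]
    base = vp.ddg_benchmark(muts, helix, lib)
    preds = [r["ddg_pred"] for r in base["predictions"]]
    perfect = [(m[0], m[1], m[2], p) for m, p in zip(muts, preds)]
    assert vp.ddg_benchmark(perfect, helix, lib)["pearson_r"] == pytest.approx(1.0)
    inverted = [(m[0], m[1], m[2], -p) for m, p in zip(muts, preds)]
    assert vp.ddg_benchmark(inverted, helix, lib)["pearson_r"] == pytest.approx(-1.0)

    rng = np.random.default_rng(1)
    exp = rng.normal(size=len(preds))
    res = vp.ddg_benchmark([(m[0], m[1], m[2], e)
                            for m, e in zip(muts, exp)], helix, lib)
    x, y = np.asarray(preds), exp
    manual = (np.mean((x - x.mean()) * (y - y.mean()))
              / (x.std() * y.std()))
    assert res["pearson_r"] == pytest.approx(manual, abs=1e-12)


def test_ddg_unresolvable_mutants_are_listed(helix, lib):
    res = vp.ddg_benchmark([(0, "A", "L", 1.0),      # terminal
                            (3, "W", "L", 1.0),      # wrong wild type
                            (99, "A", "L", 1.0)],    # out of range
                           helix, lib)
    assert res["n"] == 0 and len(res["excluded"]) == 3


# ---------------------------------------------------------------------------
# chelation
# ---------------------------------------------------------------------------

def test_kex_identities():
    assert kex_of_concentrations(1e-5, 1e-5, 1e-5, 1e-5) == 1.0
    assert vp.kd_des_from_kex(1.0) == pytest.approx(4.68e-17)
    assert cu_zincon_concentration(0.261) == pytest.approx(1e-5)


def test_fit_kex_recovers_generating_constant():
    """A noiseless titration generated from the exchange equilibrium
    returns the generating Kex to 1e-6 relative."""
    zt, ct = 50e-6, 20e-6
    des = np.array([2.5, 5, 10, 20, 40, 80, 160]) * 1e-6
    for true_k in (0.3, 1.0, 3.0, 12.0):
        cuzi = np.array([_cu_zi_from_kex(true_k, zt, ct, d) for d in des])
        fit = vp.fit_kex(cuzi * ZINCON_EPSILON, zt, ct, des)
        assert fit.kex == pytest.approx(true_k, rel=1e-6)
        assert fit.kd_des == pytest.approx(KD_CU_ZINCON / true_k, rel=1e-6)


def test_fit_kex_flags_overrange_absorbance():
    zt, ct = 50e-6, 20e-6
    a_ok = _cu_zi_from_kex(2.0, zt, ct, 40e-6) * ZINCON_EPSILON
    a_bad = (ct * 1.5) * ZINCON_EPSILON  # implies more complex than copper
    fit = vp.fit_kex([a_ok, a_bad], zt, ct, [40e-6, 40e-6])
    assert fit.flagged == [1]


def test_fit_koff_exact_recovery():
    """Noiseless first-order decay is inverted to 1e-9."""
    t = np.arange(0.0, 49.0)
    for koff in (0.03, 0.094, 0.4):
        y = 100.0 * np.exp(-koff * t)
        fit = vp.fit_koff(t, y)
        assert fit.koff == pytest.approx(koff, rel=1e-9)
        assert fit.cu0_bound == pytest.approx(100.0, rel=1e-9)


def test_fit_koff_recovery_under_noise():
    """2% Gaussian noise on 48 hourly points: the mean fitted rate over
    100 seeds stays within 5% of the generating constant."""
    t = np.arange(0.0, 49.0)
    koff = 0.094
    fits = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        y = 100.0 * np.exp(-koff * t) * (1 + rng.normal(0, 0.02, t.size))
        fits.append(vp.fit_koff(t, np.clip(y, 1e-6, None)).koff)
    assert np.mean(fits) == pytest.approx(koff, rel=0.05)


def test_fit_koff_flags_non_decaying_data():
    t = np.arange(0.0, 10.0)
    fit = vp.fit_koff(t, np.full_like(t, 80.0))
    assert fit.koff == pytest.approx(0.0, abs=1e-8)
    assert fit.flagged
    with pytest.raises(ValueError):
        vp.fit_koff([0.0, 1.0], [10.0, 5.0])


# ---------------------------------------------------------------------------
# protein efficiency
# ---------------------------------------------------------------------------

def test_binding_efficiency_identities():
    assert vp.binding_efficiency(1.0, 18.0) == 0.0
    e1 = vp.binding_efficiency(1e-9, 20.0)
    assert vp.binding_efficiency(1e-9, 10.0) == pytest.approx(2 * e1)
    with pytest.raises(ValueError):
        vp.binding_efficiency(-1.0, 10.0)


def test_binding_efficiency_worked_example():
    """Kd = 9.2 nM at 18 kDa gives about -2.5 kJ/kDa, matching the
    published rounded figure of -2.6 within a few percent."""
    val = vp.binding_efficiency(9.2e-9, 18.0)
    assert val == pytest.approx(-2.547, abs=0.001)
    assert val == pytest.approx(-2.6, rel=0.025)
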