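"""Shared fixtures: parameter table, synthetic pools, a small library.

The session library covers four amino acids (ALA, SER, VAL, LEU) in the
helical and extended backbone bins, built from seeded synthetic pools with
known rotameric modes.  Pool sizes and k are scaled down for test speed;
the statistics they exercise are size-independent.
"""

import numpy as np
import pytest

import voxpack as vp

HELIX_BIN = vp.assign_phi_psi_bin(-57.0, -47.0)
STRAND_BIN = vp.assign_phi_psi_bin(-115.0, 125.0)

POOL_MODES = {
    "ALA": [((), 0.0, 1.0)],
    "SER": [((-60.0,), 8.0, 0.4), ((60.0,), 8.0, 0.3), ((180.0,), 8.0, 0.3)],
    "VAL": [((-60.0,), 8.0, 0.6), ((180.0,), 8.0, 0.4)],
    "LEU": [((-60.0, 180.0), 8.0, 0.5), ((180.0, 60.0), 8.0, 0.3),
            ((60.0, -60.0), 8.0, 0.2)],
}


@pytest.fixture(scope="session")
def table():
    return vp.ParameterTable.bundled()


@pytest.fixture(scope="session")
def geom():
    return vp.GridGeometry()


@pytest.fixture(scope="session")
def pools():
    out = {}
    for aa, modes in POOL_MODES.items():
        out[aa] = vp.generate_conformer_pool(vp.PoolRecipe(
            aa, modes=modes, frames=900,
            bin_probs={HELIX_BIN: 0.55, STRAND_BIN: 0.45}, seed=11))
    return out


@pytest.fixture(scope="session")
def lib(pools, table):
    """k=6 library over ALA/SER/VAL/LEU in the helix and strand bins."""
    return vp.build_library(pools, k=6, table=table, seed=1)


@pytest.fixture(scope="session")
def helix(table):
    return vp.generate_toy_structure("helix", 8, table, sequence="ALVALSLA")


@pytest.fixture()
def rand_atoms(table):
    """Factory for random typed atom sets (coords + parameter arrays)."""
    types = sorted(table.types.values(), key=lambda p: p.type_name)

    def factory(rng, n, scale=6.0):
        coords = rng.uniform(-scale, scale, size=(n, 3))
        ps = [types[rng.integers(len(types))] for _ in range(n)]
        return (coords,
                np.array([p.lj_epsilon for p in ps]),
                np.array([p.lj_sigma for p in ps]),
                np.array([p.partial_charge for p in ps]),
                np.array([p.solvation_sigma for p in ps]),
                np.array([p.vdw_radius for p in ps]))

    return factory
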