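"""Score a rotamer against a voxelized environment, term by term.

The structure is mapped into the target residue's backbone frame, its
side chain is deleted, and the surroundings are projected onto a
22 A / 0.5 A voxel grid.  Each candidate rotamer's precomputed field
tensors are contracted with the environment tensors; the brute-force
double loop over snapped atom pairs reproduces the same numbers, which is
the engine's defining property.
"""

import numpy as np
import voxpack as vp
from voxpack import engine, synthetic
from voxpack.library import _pool_param_arrays

HELIX_BIN = vp.assign_phi_psi_bin(-57, -47)

pools = {
    "ALA": vp.generate_conformer_pool(vp.PoolRecipe(
        "ALA", modes=[((), 0.0, 1.0)], frames=400,
        bin_probs={HELIX_BIN: 1.0}, seed=3)),
    "LEU": vp.generate_conformer_pool(vp.PoolRecipe(
        "LEU", modes=[((-60.0, 180.0), 8.0, 1.0)], frames=400,
        bin_probs={HELIX_BIN: 1.0}, seed=3)),
}
lib = vp.build_library(pools, k=3, seed=1)
helix = vp.generate_toy_structure("helix", 8, lib.table, sequence="AALAAALA")

pos = 2  # the interior leucine
env = engine.voxelize_environment(helix, pos, lib.geometry)
print(f"environment: {int(env.occupancy.sum())} atoms in the cube, "
      f"filled fraction {env.filled_fraction:.4f}, "
      f"Born radius bbar = {env.b_bar:.2f} A")

phi, psi = helix.phi_psi(pos)
entry = lib.lookup("LEU", phi, psi)
scores = engine.score_stack(env, entry.stack, entry.dg_pp,
                            vp.Weights(w_k=0.0), max_lj=10.0)
best = int(np.argmin(scores["total"]))
print(f"best LEU rotamer: #{best}")
print(f"  dG_LJ   = {scores['dg_lj'][best]:8.3f}  (ref {scores['ref_lj'][best]:.3f})")
print(f"  dG_solv = {scores['dg_solv'][best]:8.3f}  (ref {scores['ref_solv'][best]:.3f})")
print(f"  dG_elec = {scores['dg_elec'][best]:8.3f}  (ref {scores['ref_elec'][best]:.3f})")
print(f"  total   = {scores['total'][best]:8.3f} kcal/mol "
      "(references subtracted so the score measures the new environment)")

# cross-check one rotamer against the independent double-loop oracle
scp = _pool_param_arrays("LEU", entry.atom_names, lib.table)
oracle = synthetic.brute_force_energy(
    (env.coords, env.eps, env.sigma, env.q, env.solv_sigma, env.vdw),
    (entry.stack.coords[best].astype(float), *scp), lib.geometry,
    terms=("lj",))
tensors = engine.build_rotamer_field_tensors(
    entry.stack.coords[best].astype(float), *scp, geom=lib.geometry)
dg_lj = float(tensors["lj_field"] @ env.occupancy)
print(f"oracle LJ {oracle['lj']:.9f} vs tensor LJ {dg_lj:.9f} "
      f"(difference {abs(oracle['lj'] - dg_lj):.2e})")
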