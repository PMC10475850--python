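"""The three design routines on a toy helix.

Single-point (sp) scans one position without combinatorial optimization;
repack-all (ra) sweeps every residue N->C for up to 10 rounds; the
few-to-many-to-few swarm (cs_f2m2f) explores mutations down a decision
tree, keeping the n_paths lowest-energy branches at each level.
"""

import voxpack as vp
from voxpack.specfile import DesignSpec, Position

HELIX_BIN = vp.assign_phi_psi_bin(-57, -47)
MODES = {
    "ALA": [((), 0.0, 1.0)],
    "SER": [((-60.0,), 8.0, 0.4), ((60.0,), 8.0, 0.3), ((180.0,), 8.0, 0.3)],
    "VAL": [((-60.0,), 8.0, 0.6), ((180.0,), 8.0, 0.4)],
    "LEU": [((-60.0, 180.0), 8.0, 0.5), ((180.0, 60.0), 8.0, 0.3),
            ((60.0, -60.0), 8.0, 0.2)],
}
pools = {aa: vp.generate_conformer_pool(vp.PoolRecipe(
    aa, modes=m, frames=700, bin_probs={HELIX_BIN: 1.0}, seed=5))
    for aa, m in MODES.items()}
lib = vp.build_library(pools, k=5, seed=1)
helix = vp.generate_toy_structure("helix", 8, lib.table, sequence="ALVALSLA")

# -- single point ----------------------------------------------------------
sp = vp.single_point(helix, 3, ["ALA", "LEU", "SER", "VAL"], lib)
print("sp at position 3 (wild type ALA), ddG in kcal/mol vs wild type:")
for aa, ddg in sorted(sp.ddg.items(), key=lambda kv: kv[1]):
    print(f"  {aa}: {ddg:7.3f}")
print("positive ddG = predicted destabilizing substitution\n")

# -- repack all ------------------------------------------------------------
ra = vp.repack_all(helix, lib)
print("ra objective (mean per-residue energy, kcal/mol) per round:",
      " ".join(f"{x:.3f}" for x in ra.objective_history))
print("the sweep is deterministic and stops at a fixed point\n")

# -- decision-tree swarm ---------------------------------------------------
spec = DesignSpec(
    mut_res=[(Position("A", 4), ["ALA", "LEU", "SER", "VAL"]),
             (Position("A", 6), ["ALA", "LEU", "SER", "VAL"])],
    rpk_res=[Position("A", 5)], m_mutations=2, n_paths=3, n_iters=2,
    weights=vp.Weights(w_k=0.0), max_lj=10.0, random_seed=4,
    scramble_order=True)
decoys = vp.cs_f2m2f(helix, spec, lib)
print("cs_f2m2f decoys (ascending mean per-residue energy):")
for d in decoys:
    print(f"  {d.sequence}  objective {d.objective:7.3f} kcal/mol")
bound = spec.n_paths * 4 * lib.k  # n_paths x |alphabet| x k candidates
print("mutation-candidate scorings per level:",
      decoys.stats["level_scorings"], f"(at most {bound})")
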