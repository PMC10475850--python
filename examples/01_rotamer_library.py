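"""Build a discrete rotamer library from a synthetic conformer pool.

A leucine pool with three chi-space modes (weights 0.5/0.3/0.2) stands in
for an MD trajectory of the capped amino acid.  The build bins frames by
backbone (phi, psi), clusters each bin into exactly k rotamers, and
attaches statistical free energies: dG_pp from bin occupancy and dG_k
from cluster occupancy (kB T = 0.59179 kcal/mol at 298 K).
"""

import numpy as np
import voxpack as vp

HELIX_BIN = vp.assign_phi_psi_bin(-57, -47)

recipe = vp.PoolRecipe(
    "LEU",
    modes=[((-60.0, 180.0), 8.0, 0.5),   # (chi1, chi2) means, spread, weight
           ((180.0, 60.0), 8.0, 0.3),
           ((60.0, -60.0), 8.0, 0.2)],
    frames=3000, bin_probs={HELIX_BIN: 1.0}, seed=7)
pool = vp.generate_conformer_pool(recipe)
lib = vp.build_library({"LEU": pool}, k=3, seed=1)

entry = lib.get("LEU", HELIX_BIN)
print(f"populated bins: {sorted(lib.bins['LEU'])} (helical bin only)")
print(f"bin occupancy {entry.occupancy} frames, dG_pp = {entry.dg_pp:.4f} kcal/mol")
print("rotamer  occupancy  weight   dG_k (kcal/mol)")
for r in range(entry.k):
    occ = entry.stack.occupancy[r]
    print(f"   {r}      {occ:5d}     {occ / entry.occupancy:.3f}   "
          f"{entry.stack.dg_k[r]:8.4f}")
z = np.sum(np.exp(-entry.stack.dg_k / vp.KBT))
print(f"Boltzmann sum over clusters: {z:.12f} (should be 1: clusters "
      "partition the bin)")
print("The recovered cluster weights match the generating 0.5/0.3/0.2 "
      "mixture up to sampling noise; lower dG_k marks more populated "
      "(more favorable) side-chain conformations.")
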