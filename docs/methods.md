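# Methods

This note records the model as implemented, the defaults and why they
hold, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Grid and frames

All two-body energies live on a cube of side d_box = 22 Å with 0.5 Å
voxels (44³ = 85,184), centred on the target residue's Cα.  Voxel index
= ⌊(x + d_box/2)/voxel⌋ per axis with half-open cells; an atom exactly on
the + boundary is outside.  The backbone frame puts Cα at the origin and
Cα→Cβ along +z.  The remaining degree of freedom is fixed by rotating
Cα→N into the xz half-plane with positive x; "N in the xy-plane" is
geometrically incompatible with Cβ on z for tetrahedral geometry, so the
half-plane convention is used consistently end-to-end (every consumer of
frame coordinates uses the same transform, so any fixed convention is
self-consistent).

The environment (1st body) is identified with its voxel projection:
occupancy and charge tensors by construction, and also the solvation
crust/core masks and the Born radius, which are computed from
voxel-snapped atom positions.  This makes every environment-side quantity
a pure function of the grid contents and is what lets an independent
double-loop oracle over snapped positions reproduce the tensor results to
floating-point precision.  Rotamer (2nd body) fields are evaluated at
exact atom positions against voxel centres and precomputed once per
library rotamer.

## Energy terms

* **Lennard-Jones** (per pair, inbound atom j's parameters only): the
  standard ε(σ¹²/r¹² − σ⁶/r⁶) for (σ − 0.25 Å) < r ≤ 7 Å, a soft
  ε σ²/r² band down to σ − σ/2, and a constant ε σ⁴/(σ − σ/2)⁴ = 16 ε
  core plateau.  The asymmetry (no mixing rule) is deliberate: it lets
  the whole field be precomputed per rotamer atom.  The environment
  occupancy is a single aggregated channel; per-type rescaling of 1st
  body atoms is out of scope.
* **Electrostatics**: 332 q_i q_j / (ε(r)·r) with ε(r) = r and a 7 Å
  cutoff, times a Generalized-Born screening bracket
  1 − ε_p r̄ (r̄² + b̄² e^(−r̄²/4b̄²))^(−1/2) (1/ε_p − 1/ε_s)
  evaluated once per scoring call with the cube averages r̄ = 0.6617 d_box
  and shared Born radius b̄, plus Born self-terms −166 q²/b̄ (1/ε_p −
  1/ε_s) summed over the in-box environment charges and the rotamer
  charges, each once (a switch could restrict this to one body; both
  bodies is the default because the self-energy of the inbound side chain
  changes with burial exactly like the environment's).  ε_p = 8,
  ε_s = 75.  Distances are clamped below at half a voxel so a source atom
  coinciding with a voxel centre stays finite.
* **Born radius**: b̄ = d_box × (fraction of voxels inside the
  environment's vdW core mask).  The filled-volume fraction is measured
  on the core mask, not on occupancy-touched voxels: atom-count voxels
  occupy ~0.1% of the grid for realistic environments and would give
  b̄ ≈ 0.03 Å and absurd self-energies, whereas vdW-filled volume gives
  the intended few-Å radii that grow with burial.  An environment that
  fills no volume falls back to the mean vdW radius of the probe atoms
  (2.0 Å if there are none) so the self-term stays defined.
* **Solvation**: each atom's crust is the voxel shell within
  (r_vdW, r_vdW + 0.5 Å]; it carries the atom's full vdW-surface
  solvation energy σ_solv·4π r_vdW² split evenly over its crust voxels,
  which conserves per-atom totals under the radial inflation.  Exposed
  crust = crust voxels outside every core of the combined body;
  ΔG_solv = ΔG_1,2 − ΔG_1 − ΔG_2 reduces to the mutually occluded crust
  voxels, so two bodies that do not touch contribute exactly zero.
* **References**: each rotamer stores its LJ/solvation/electrostatics
  against its own pooled backbone (N, Cα, C, O), computed with the same
  code path and with the tensors at storage precision, so placing a
  rotamer back onto its own backbone in an empty environment cancels each
  interaction term exactly.
* **Tiered scoring**: if ΔG_LJ exceeds max_lj (5 kcal/mol default;
  10 for single-point scans), solvation and electrostatics (and their
  references) are skipped and the placement is ranked by the internal
  terms plus the capped LJ difference, with a clash flag.

The weight on the electrostatic difference is w_elec (default 0.25, the
value that compensates the softened repulsion); w_k defaults to 0 for
mutagenesis routines and 1 for repacking, because ΔG_k is not comparable
across amino-acid types.

## Library construction

Pools are (frames × atoms × 3) stacks with per-frame (φ, ψ).  Binning is
6×6 over the full torus, cells [lo, lo + 60°).  ΔG_pp uses each amino
acid's total pool size; the Boltzmann sums over occupied bins and over
clusters within a bin are exactly one, which the tests assert to 1e-12.
k-means uses k-means++ with 4 restarts, tolerance 1e-6, seeded; pools
are in canonical frame order before clustering, so builds are
deterministic and order-independent.  The cluster representative is the
member with the lowest RMSD to the cluster mean (ties: lowest frame
index); rotamers are ordered by descending occupancy.  Field tensors are
stored float32 (coordinates too); energies float64.  References are
computed from the float32-cast tensors so serialization round-trips are
bit-exact and library scoring reproduces the reference cancellation at
storage precision.

## Samplers

* `repack_all` replaces each interior residue N→C by its lowest-energy
  same-amino-acid rotamer against the current environment, for up to 10
  rounds.  Because the pair energy is asymmetric, a greedy sweep is not
  formally monotone in the summed objective, so a round whose end-of-round
  objective (mean per-residue energy of the recorded placements) is worse
  than the previous round's reverts and stops.  In practice the toy
  fixtures reach a fixed point after one round.
* `cs_f2m2f` ranks candidate amino acids within a branch by their best
  single-position energy in that branch's context (decided positions
  fixed, undecided at their current residue), keeps the top m_mutations,
  refreshes repackable residues with one N→C same-amino-acid pass per
  expanded branch, then trims the expansion to n_paths by objective.
  Refresh happens before trimming.  Every parent branch also passes
  through the expansion unmutated: this implements the wild-type
  fallback for infeasible levels and makes the incumbent best objective
  monotone across levels and iterations.  On exact objective ties a
  freshly placed branch outranks a carried parent (so decided positions
  are recorded); all other ties break lexicographically on
  (objective, branch id, amino acid, rotamer id).  Branch objectives
  score recorded placements directly; only never-placed side chains are
  matched to their nearest library rotamer by side-chain RMSD — the two
  can differ for amino acids whose rotamers are geometrically degenerate
  (alanine) but carry different provenance references.
* Replicas loop seeds internally and de-duplicate merged decoys by
  sequence.

No Metropolis acceptance anywhere: diversity comes from scrambled
position order across replicas, and runs are reproducible bit-for-bit
from the seed.

## Synthetic data

`generate_conformer_pool` emulates the *rotameric cluster structure* of
capped-amino-acid MD: Gaussian modes in χ-torsion space (idealized bond
lengths/angles via NeRF construction), backbone torsions jittered around
bin centres (clipped inside the cell so bin occupancies are exact), all
seeded.  It does not emulate solvent structure, correlated backbone/side
chain motion, anharmonic wells, or exchange kinetics — so passing tests
demonstrate the statistics and mechanics of the pipeline, not force-field
accuracy on real proteins.  Default study conditions: 5000 frames per
pool and k = 50 where a production-like build is wanted; the test suite
uses 300–3000-frame pools with k = 3–25 (the statistics under test are
size-independent and these sizes keep the suite under a minute).
Toy structures are ideal-geometry helices ((φ, ψ) = (−57°, −47°)),
extended strands (−115°, 125°), hairpins (two bins), and two-residue
probes; torsions are chosen off the 60° bin edges so scoring is robust to
rounding.  Glycine carries Hα1 as its frame/side-chain atom; structures
read without hydrogens get a virtual Hα1 at the ideal position.

The brute-force oracle evaluates the same pairwise formulas by explicit
Python double loops — with exact distances ("continuous") or with
environment atoms snapped to voxel centres ("voxel-snapped") — and its
own independent crust/core voxel counting.  Solvation exists only in
voxel-snapped mode because the crust discretization *is* the solvation
model.  Voxel-snapped LJ agrees with the engine to ~1e-15 relative
(floating-point summation order is the only difference); assembled
electrostatics to better than 1e-9.

## Chelation analysis

`fit_kex` converts 599 nm absorbances to [Cu²⁺:ZI] by Beer–Lambert
(ε = 26100 M⁻¹cm⁻¹), closes the mass balances treating free Cu²⁺ as
negligible (both ligands bind orders of magnitude below the totals), and
fits K_ex by least squares on log-concentration residuals of the exchange
quadratic; K_d,des = 4.68×10⁻¹⁷ M / K_ex.  Samples whose absorbance
implies more complex than total copper are flagged and excluded.
`fit_koff` is a bounded nonlinear least-squares fit of
Cu₀·e^(−K_off·t); series with no measurable decay over the observation
window return K_off ≈ 0 with a flag.  Protein efficiency is
R·T·ln(K_d)/MW with R = 8.314×10⁻³ kJ mol⁻¹ K⁻¹ at T = 298 K.

## Evaluation conventions

χ torsions follow the standard heavy-atom quadruples; the terminal
torsion of Asp/Glu/Phe/Tyr is compared modulo 180° (two-fold symmetric
groups).  A prediction is correct within ±40° (closed bound, circular
difference).  Buried residues have side-chain SASA < 5 Å² by
Shrake–Rupley with a 1.4 Å probe — the field-standard probe, which the
cutoff's source leaves unstated.  Terminal residues are excluded from
repacking, recovery denominators, and per-residue scoring because their
(φ, ψ) are undefined.  The ΔΔG harness reports Pearson R with its
two-sided p-value and lists unresolvable mutants rather than failing.

## Known limitations

Single-channel environment occupancy (no per-type first-body rescaling);
isotropic charges; no backbone motion; solvation and Born radii inherit
the 0.5 Å discretization; the exchange-equilibrium fit assumes 1:1
binding and negligible free copper; recovery benchmarks against real PDB
ensembles require externally supplied structures (the harness accepts
them but ships none).
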