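"""Physical constants and default model parameters.

All energies are in kcal/mol, distances in Angstrom, charges in elementary
charge units, unless stated otherwise.
"""

#: Boltzmann constant in kcal/(mol K), as used for the statistical free energies.
KB = 0.001985875

#: Reference temperature (K) for the rotamer-library free energies.
T_REF = 298.0

#: kB*T at the reference temperature.
KBT = KB * T_REF

#: Coulomb prefactor, kcal Angstrom / (mol e^2).
COULOMB_K = 332.0

#: Half of the Coulomb prefactor, appearing in the Born self-energy term.
BORN_K = 166.0

#: Dielectric constant of the protein interior.
EPS_P = 8.0

#: Dielectric constant of water.
EPS_S = 75.0

#: Mean distance between two uniform random points in a cube, in units of the
#: cube side (Robbins constant); used as the average interatomic distance of
#: the simulation cube in the screened electrostatics.
RBAR_FACTOR = 0.6617

#: Default clash cap on the Lennard-Jones term (kcal/mol) for tiered scoring.
DEFAULT_MAX_LJ = 5.0

#: Clash cap used by the single-point mutagenesis benchmarks.
SP_MAX_LJ = 10.0

#: Molar absorption coefficient of the Cu(2+):Zincon complex at 599 nm,
#: pH 7.4 (1/(M cm)).
ZINCON_EPSILON = 26100.0

#: Dissociation constant of the Cu(2+):Zincon complex at pH 7.4 (M).
KD_CU_ZINCON = 4.68e-17

#: Gas constant in kJ/(mol K), for protein-efficiency conversions.
R_KJ = 8.314e-3
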