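# OPLS-UA parameter set, version 1
#
# United-atom force-field constants for thiolate ligands on gold.
# Units: energies kcal/mol, lengths Angstrom, angles degrees (theta0),
# bond k in kcal/mol/A^2, angle k in kcal/mol/rad^2, charges in e.
# Harmonic convention: E = k (x - x0)^2  (no 1/2 factor).
#
# Bead LJ/charge values and bonded constants follow the published OPLS-UA
# parameterisation for alkanes, thiols and ethers; the S-Au Morse constants
# follow the gold-thiolate Morse literature.  Everything here is
# configuration, overridable per run.
version: 1
temperature: 298.15          # K
lj_cutoff: 10.0              # A
coul_cutoff: 12.0            # A
dielectric: 24.35            # ethanol-like, dimensionless
debye_length: 5.0            # A  (kappa = 1/debye_length = 0.2 1/A)
one_four_scale: 0.5          # OPLS 1-4 nonbonded scaling
mixing_rule: geometric       # OPLS: geometric for both epsilon and sigma
core_guard:                  # purely repulsive wall keeping beads off the core
  enabled: true
  r_guard: 2.5               # A
  k_guard: 50.0              # kcal/mol/A^2

beads:
  S:       {mass: 32.060, lj_epsilon: 0.250, lj_sigma: 3.550, charge: 0.0}
  CH2:     {mass: 14.027, lj_epsilon: 0.118, lj_sigma: 3.905, charge: 0.0}
  CH3:     {mass: 15.035, lj_epsilon: 0.175, lj_sigma: 3.905, charge: 0.0}
  O_ether: {mass: 15.999, lj_epsilon: 0.170, lj_sigma: 3.000, charge: 0.0}

# Partial charges are assigned per topology position (ether O and its two
# alpha carbons); see the PEG/DDT topology builders.

bonds:        # E = k (r - r0)^2
  S-C: {k: 222.0, r0: 1.810}
  C-C: {k: 260.0, r0: 1.526}
  C-O: {k: 320.0, r0: 1.410}

angles:       # E = k (theta - theta0)^2
  S-C-C: {k: 62.5, theta0_deg: 114.4}
  C-C-C: {k: 63.0, theta0_deg: 112.4}
  C-C-O: {k: 50.0, theta0_deg: 109.5}
  C-O-C: {k: 60.0, theta0_deg: 111.8}

dihedrals:    # OPLS Fourier: E = 1/2 [V1(1+cos) + V2(1-cos2) + V3(1+cos3) + V4(1-cos4)]
  C-C-C-C: {v: [1.411, -0.271, 3.145, 0.0]}
  S-C-C-C: {v: [1.262, -0.198, 0.465, 0.0]}
  S-C-C-O: {v: [1.262, -0.198, 0.465, 0.0]}
  C-C-O-C: {v: [1.300, -0.250, 0.660, 0.0]}
  C-O-C-C: {v: [1.300, -0.250, 0.660, 0.0]}

morse_s_au:   # E = D_e [(1 - exp(-alpha (r - r_e)))^2 - 1]
  D_e: 8.763       # kcal/mol
  alpha: 1.47      # 1/A
  r_e: 2.65        # A
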