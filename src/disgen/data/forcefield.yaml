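# Default residue-level force-field parameter tables.
#
# volumes are mean amino-acid residue volumes in cubic Angstrom (Zamyatnin,
# Prog. Biophys. Mol. Biol. 1972); the per-residue bead radius sigma_i is the
# radius of a sphere of equivalent volume, computed at load time and
# convertible to nm.  Every table here is overridable via a user config.
constants:
  k_bond: 4184.0        # kJ mol^-1 nm^-2
  l0: 0.38              # nm
  k_angle: 4.184        # kJ mol^-1 rad^-2
  theta0_deg: 180.0
  eps_polar: 0.40       # kJ mol^-1
  eps_nonpolar: 0.41    # kJ mol^-1
  eps_cation_pi: 0.30   # kJ mol^-1, added for (R,K) x (F,Y,W) pairs
  A0_polar: 0.05
  kappa: 1.0            # Debye screening length, nm
  cutoff: 3.0           # non-bonded truncation, nm
residue_volumes_A3:
  A: 88.6
  R: 173.4
  N: 114.1
  D: 111.1
  C: 108.5
  Q: 143.8
  E: 138.4
  G: 60.1
  H: 153.2
  I: 166.7
  L: 166.7
  K: 168.6
  M: 162.9
  F: 189.9
  P: 112.7
  S: 89.0
  T: 116.1
  W: 227.8
  Y: 193.6
  V: 140.0
charges:
  R: 1
  K: 1
  D: -1
  E: -1
polar:   [R, K, D, E, N, Q, H, S, T, Y, C, W]
nonpolar: [A, V, L, I, P, F, M, G]
cation_residues: [R, K]
aromatic_residues: [F, Y, W]
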