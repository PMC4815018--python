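# Regression spec: a 20-residue extended peptide carrying ten engineered
# Lys-NZ / Glu-OE1 pairs whose salt bridges follow fixed presence schedules.
# After the 20% equilibration trim, 200 frames are analysed, so every
# scheduled persistence is realised by an exact frame count (100% -> 200
# frames, ..., 1% -> 2 frames).  Expected summary: 10 unique bridges,
# 4 unstable (<5%), mean persistence 32.0%.
n_residues: 20
geometry: extended
chains: monomer
sigma_profile: 0.05
n_frames: 250
seed: 2016
equilibration_fraction: 0.2
substitutions:
  1: LYS
  2: GLU
  3: LYS
  4: GLU
  5: LYS
  6: GLU
  7: LYS
  8: GLU
  9: LYS
  10: GLU
  11: LYS
  12: GLU
  13: LYS
  14: GLU
  15: LYS
  16: GLU
  17: LYS
  18: GLU
  19: LYS
  20: GLU
schedules:
  - {atom_a: [A, 1, NZ], atom_b: [A, 2, OE1], persistence: 100}
  - {atom_a: [A, 3, NZ], atom_b: [A, 4, OE1], persistence: 80}
  - {atom_a: [A, 5, NZ], atom_b: [A, 6, OE1], persistence: 60}
  - {atom_a: [A, 7, NZ], atom_b: [A, 8, OE1], persistence: 40}
  - {atom_a: [A, 9, NZ], atom_b: [A, 10, OE1], persistence: 20}
  - {atom_a: [A, 11, NZ], atom_b: [A, 12, OE1], persistence: 10}
  - {atom_a: [A, 13, NZ], atom_b: [A, 14, OE1], persistence: 4}
  - {atom_a: [A, 15, NZ], atom_b: [A, 16, OE1], persistence: 3}
  - {atom_a: [A, 17, NZ], atom_b: [A, 18, OE1], persistence: 2}
  - {atom_a: [A, 19, NZ], atom_b: [A, 20, OE1], persistence: 1}
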