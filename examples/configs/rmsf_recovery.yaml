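# Regression spec: 20-residue ideal helix, iid Gaussian displacement of
# sigma = 0.30 A on every atom plus rigid-body jitter each frame.  The
# superposition fit removes the jitter, so the recovered per-residue backbone
# RMSF should sit at sigma * sqrt(3) = 0.520 A (2000 analysed frames).
n_residues: 20
geometry: helix
chains: monomer
sigma_profile: 0.30
n_frames: 2500
seed: 2016
equilibration_fraction: 0.2
jitter: true
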