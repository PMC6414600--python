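# A small synthetic study: one correlated block and one planted H-bond.
n_residues: 30
n_frames: 2000
sigma: 0.5
correlation_blocks: [[[12, 13, 14, 15, 16], 0.8]]
hbond_schedule: [[[12, "N2"], [23, "O2"], 0.75]]
seed: 42
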