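# Demo: two synthetic states of one riboswitch-like chain.
# The "holo" state strengthens the internal correlation block and the
# long-range planted hydrogen bond, mimicking ligand-stabilized coupling.
seed: 2026
output_dir: demo_out
parameters:
  hbond_distance: 3.5
  hbond_angle: 30.0
  contact_cutoff: 4.5
  contact_persistence: 0.75
  node_selection: "C5'"
  n_pcs: 3
  k_paths: 200
  source: 8
  sink: 23
systems:
  apo:
    synthetic:
      n_residues: 30
      n_frames: 1500
      correlation_blocks: [[[12, 13, 14, 15, 16], 0.5]]
      hbond_schedule: [[[12, "N2"], [23, "O2"], 0.68]]
      seed: 101
  holo:
    synthetic:
      n_residues: 30
      n_frames: 1500
      correlation_blocks: [[[12, 13, 14, 15, 16], 0.8]]
      hbond_schedule: [[[12, "N2"], [23, "O2"], 0.9]]
      seed: 102
comparisons:
  - [apo, holo]
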