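# Demo run: six synthetic systems spanning collapsed- to extended-dominated
# mixtures. Weights are (w_collapsed, w_extended, w_other); jitter_sigma is
# the per-atom RMS displacement in angstrom.
systems:
  - system: {triplet: CCA, amino_acid: ALA, attachment: 2p, chirality: L}
    synth: {weights: [0.10, 0.55, 0.35], jitter_sigma: 0.3, n_frames: 200, seed: 1}
  - system: {triplet: GGU, amino_acid: GLY, attachment: 3p, chirality: L}
    synth: {weights: [0.20, 0.46, 0.34], jitter_sigma: 0.3, n_frames: 200, seed: 18}
  - system: {triplet: AUC, amino_acid: SER, attachment: 2p, chirality: D}
    synth: {weights: [0.30, 0.37, 0.33], jitter_sigma: 0.3, n_frames: 200, seed: 35}
  - system: {triplet: CGA, amino_acid: VAL, attachment: 3p, chirality: D}
    synth: {weights: [0.40, 0.28, 0.32], jitter_sigma: 0.3, n_frames: 200, seed: 52}
  - system: {triplet: CCA, amino_acid: LEU, attachment: 2p, chirality: L}
    synth: {weights: [0.50, 0.19, 0.31], jitter_sigma: 0.3, n_frames: 200, seed: 69}
  - system: {triplet: UUA, amino_acid: PHE, attachment: 3p, chirality: L}
    synth: {weights: [0.60, 0.10, 0.30], jitter_sigma: 0.3, n_frames: 200, seed: 86}
# analysis parameters (defaults shown explicitly)
cluster_cutoff: 0.5      # A, master-ensemble cluster perimeter
assign_cutoff: 1.5       # A, state-membership shell
stack_cutoff: 5.0        # A, base-base COG
contact_cutoff: 8.0      # A, sidechain-base COG
probe_radius: 1.4        # A, solvent probe
n_sphere_points: 196
normalization: 48.4      # A^2, or "dataset-max"
master_stride: 1
outdir: demo_out
seed: 1
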