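# Two-state lysine titration at 0.5 mM Mg2+ (reduced cohort for a quick run)
seed: 1
states: [U, F_LB]
fret_means: [0.32, 0.69]
fret_sigmas: [0.05, 0.05]
base_rates:
  - [0.0, 0.0]
  - [0.18, 0.0]          # F_LB -> U undocking, lysine-independent
ligand_laws:
  U->F_LB: {type: hill, k_max: 1.22, K_D: 310.0, n: 3.1}
conditions:
  - {mg_mM: 0.5, lysine_uM: 75.0}
  - {mg_mM: 0.5, lysine_uM: 150.0}
  - {mg_mM: 0.5, lysine_uM: 300.0}
  - {mg_mM: 0.5, lysine_uM: 500.0}
  - {mg_mM: 0.5, lysine_uM: 750.0}
  - {mg_mM: 0.5, lysine_uM: 1000.0}
n_molecules: 60
frame_dt: 0.05           # s; use 0.2 for slow-dynamics cohorts
duration: 60.0           # s per molecule
photophysics:
  total_intensity: 1000.0
  noise_sd: 60.0
  leakage_fraction: 0.12
  bleach_lifetime: 120.0
alpha: 0.88
hmm_iterations: 5
max_baum_welch_traces: 30
dwell_fit_method: histogram_lsq
out_dir: fretfold_run
make_plots: true
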