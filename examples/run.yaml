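# Example end-to-end run: 4-subject synthetic cohort at 48^3, all stages.
# lesionrate run --config examples/run.yaml
out_dir: run
seed: 7
stages: [phantom, segment, repair, longitudinal, groupmaps, volumes, vbm]

phantom:
  grid_shape: [48, 48, 48]
  n_subjects: 4
  times_years: [0.0, 1.0, 2.0]
  atrophy_rate_mean: -0.010
  atrophy_rate_sd: 0.004
  wmh_growth_mean: 0.5
  wmh_growth_sd: 0.2
  rate_correlation_rho: -0.7

segment:
  wmh_threshold: 0.5
  max_iter: 60
  tol: 1.0e-5
  min_component_voxels: 5
  tpm_smoothing_fwhm_mm: 4.0

longitudinal:
  n_outer_iters: 2
  iters: [20, 15, 8]

groupmaps:
  fwhm_mm: 6.0
  min_count: 1

volumes:
  threshold: 0.2

vbm:
  model: gm_vs_wmhrate
  side: negative
  n_perm: 200
  alpha: 0.05

limits:
  max_grid: 128
  max_subjects: 200
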