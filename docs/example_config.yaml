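# Example pipeline configuration for `gbcmvpa run-all --config ...` or
# gbcmvpa.pipeline.PipelineConfig.from_yaml.  Every value shown is the
# default; omit any block to keep the defaults.

manifest: results/cohort/manifest.json
output_dir: results/pipeline
seed: 0

preproc:
  n_discard: 10            # volumes dropped for scanner stabilization
  detrend_order: 1         # first-order polynomial trend
  band_hz: [0.01, 0.08]    # ideal band-pass, Hz
  regress_motion: true     # 6 rigid-body parameters
  regress_global: true
  regress_wm: true
  regress_csf: true
  rotations_in_degrees: false

qc:
  fd_radius_mm: 50.0       # head radius for the rotation arc length
  fd_flag_mm: 0.3          # FD > 0.3 mm flags a volume
  mean_fd_max_mm: 0.3
  max_flag_fraction: 0.5   # fail when flagged volumes reach half the series

gbc:
  r_threshold: 0.25        # one-sided: r >= 0.25 edges only
  variant: weighted-z      # or binary-count
  standardize: true        # z across the GM mask
  fwhm_mm: 6.0             # mask-restricted Gaussian smoothing

model:
  algorithm: svm           # svm | gpc-binary | gpc-multiclass
  svm_cost: 1.0
  center_features: true    # train-fold mean-centering

permutation:
  n_perm: 1000
  seed: 0
  voxel_p_threshold: 0.001
  min_cluster_voxels: 30   # strict '>': a 31-voxel cluster survives
  connectivity: 26

correlation:
  alpha: 0.05
  n_rois: 12
  bonferroni: pairwise     # alpha / (m (m-1) / 2); or per-roi

clinical_score: hdrs17
correlation_group: DET
covariate_columns: [age, education_years, mmse, hars14]
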