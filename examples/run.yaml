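Q_guv_ul_per_h: 33.4
device:
  branch_height_um: 40.0
  branch_lengths_um:
  - 4150.0
  - 4700.0
  - 4150.0
  - 4700.0
  - 4150.0
  branch_width_um: 300.0
  calibrate_thresholds: false
  pinch_height_um: 40.0
  pinch_length_um: 80.0
  pinch_width_um: 20.0
  viscosity_pa_s: 0.00125
fret:
  R_guv_um: 10.0
  calibration_baseline: 0.25
  calibration_levels:
  - 0.0
  - 0.1
  - 0.2
  - 0.3
  - 0.4
  - 0.5
  calibration_noise_sd: 0.0
  calibration_slope: 0.26
  enabled: true
  guv_count_per_image: 10
  n_images: 1
  r_suv_um: 0.065
  suv_label_mol_percent: 0.1
  x_transfer_true_mol_percent: 0.073
imaging:
  accumulator_threshold: 0.45
  annulus_halfwidth_px: 2.0
  background_margin_px: 4.0
  blur_quantile: 0.2
  canny_sigma: 2.0
  histogram_bins: 64
  radius_max_px: 30
  radius_min_px: 14
  refine_mode: disk
out_dir: null
physics:
  ca_critical: 0.001
  eta_continuous_pa_s: 0.00125
  eta_droplet_pa_s: 0.009375
  profile_factor: 1.0
  stretch_modulus_n_per_m: 0.25
ratio: 1.6
seed: 1
synthetic:
  background_mean: 48.0
  droplet_count: 12
  droplet_diameter_large_um: 30.0
  droplet_median_um: 3.0
  droplet_sigma_ln: 1.0
  free_dye_level: 3200.0
  guv_count: 30
  guv_diameter_mean_um: 20.6
  guv_diameter_sd_um: 2.2
  image_size_px: 512
  lumen_intensity: 2500.0
  noise_sd: 15.0
  out_of_focus_fraction: 0.1
  pixel_size_um: 0.5
  psf_sigma_px: 1.0
  ring_width_px: 4.0
  viscosity_ratio: 7.5
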