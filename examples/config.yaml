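# Example pipeline configuration for `lungmorph all --config examples/config.yaml`.
# Synthetic mode generates the cohort; switch to from_masks to analyze your
# own NIfTI/NRRD segmentations listed in a manifest CSV
# (columns: subject_id, phase {inspiration, expiration}, path).

mode: synthetic
seed: 1
out_dir: lungmorph_out

phantom:
  lung_semi_axes: [40.0, 70.0, 140.0]   # mm (LR, AP, CC) per lung at expiration
  spacing: [1.4, 1.4, 1.5]              # mm; breath-hold MRI geometry
  shape: dome                           # dome | cuboid
  noise_amplitude: 0.0                  # mm of seeded boundary jitter

cohort:
  n_patients: 10
  n_controls: 6
  cc_ratio_means: [1.35, 1.82]          # weak diaphragm vs healthy
  cc_ratio_sd: 0.17
  link_slope: 75.0                      # FVC_supine %pred per CC-ratio unit
  link_intercept: -58.25
  noise_sd: 5.0                         # %pred noise on the spirometry links

morphometry:
  orientation: RAS
  sparsify_step: 2        # emulate every-second-slice manual annotation

stats:
  mode: auto              # exact below exact_cap labelings, else normal approx
  exact_cap: 200000
  include_controls_in_correlations: false
  alpha: 0.05

# from_masks mode instead:
# mode: from_masks
# masks_manifest: masks/manifest.csv
# cohort_csv: cohort.csv     # spirometry table to join for statistics

write_images: false
write_masks: false
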