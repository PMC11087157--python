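# Miniature demo pipeline: two adult phantom sizes, a 120 kV baseline and
# two virtual-monochromatic targets, three replicate acquisitions each.
seed: 20240
replicates: 3
grid:
  pixel_spacing_mm: 2.5
  n_slices: 3
  slice_thickness_mm: 5.0
phantom:
  study: dect
  sizes: [small_adult, medium_adult]
  background_hu: 0.0
acquisition:
  scanner_label: demo_dect
  recon_label: ir
  baseline: {mode: SECT, energy: 120}
  targets:
    - {mode: DECT-VMI, energy: 50}
    - {mode: DECT-VMI, energy: 60}
  ctdi_by_size:
    small_adult: 10.0
    medium_adult: 18.0
contrast_model:
  kv_to_kev: {100: 58.0, 120: 65.0}
noise_model:
  sigma_ref_hu: 10.0
  d_ref_cm: 20.0
  ctdi_ref_mgy: 10.0
  size_coeff_per_cm: 0.09
  recon_factors: {ir: 0.9}
measure:
  roi_fraction: 0.7
  slice_fraction: 0.6
  mode: geometry
plan:
  baseline_energy: 120
  baseline_mode: SECT
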