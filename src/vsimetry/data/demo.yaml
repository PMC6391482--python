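# Demo pipeline run: small noiseless phantom through every stage.
stages: [simulate, relax, perfuse, vsi, histo, validate]
seed: 7
simulate:
  grid_shape: [32, 32, 8]
  n_timepoints: 40
  noise_sigma: 5.0       # SNR ~ 200 at the tissue S0
  dwi_noise_sigma: 5.0
  n_targets: 4
  slide_shape: [384, 384]
  slide_um_per_px: 2.0
  vessels_per_slide: 25
relax:
  smooth: true
perfuse:
  leak_mode: bidirectional
vsi:
  constant_k: 0.867
histo:
  n_rois: 3
  roi_size: 160
validate:
  statistic: median
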