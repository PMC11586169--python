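# Full synthetic study: 96 fruit, 2048-wavelength transmission spectra.
# Stages: simulate -> absorbance -> Monte-Carlo outlier removal -> 3:1 split
# -> GF+MSC -> full-spectrum PLSR -> bin(16) -> BVS-PLS -> SA(k=20) -> report.
simulate:
  n_samples: 96
  n_wavelengths: 2048
  seed: 1
preprocess:
  method: gf+msc
  gf_window: 11
outlier:
  enabled: true
  n_runs: 500
  k_sigma: 2.5
selection:
  enabled: true
  bin_width: 16
  k: 20
  cv: "kfold:5"
  fast_lv: true
plsr_max_lv: 20
master_seed: 1
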