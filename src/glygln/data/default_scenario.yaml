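# Default scenario: glucose plus glutamine at the assay's nutrient levels,
# no modulators, sampled like the plate reader (350 cycles, 0.34 min/cycle).
units:
  time: minute
  concentrations: model_units_nominally_uM
scenario:
  Glc_ex: 7500.0
  Gln_ex: 2000.0
  Oligomycin: 0.0
  "2DG": 0.0
  Capacity_Glc: 200.0
  Capacity_Gln: 100.0
  Capacity_M: 50.0
  horizon_min: 120.0
  n_samples: 350
  sample_interval_min: 0.34
  clamp_modulator_factors: false
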