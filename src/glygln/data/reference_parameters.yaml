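# Calibrated reference rate constants for the glycolysis-glutaminolysis model.
#
# Calibrated against the behaviour of the measured assay responses: the
# glucose-only extracellular-lactate signal plateaus at ~83 min; adding
# glutamine roughly halves final extracellular lactate while ETC output
# overtakes it; oligomycin at dose 8.7 restores lactate to the glucose-only
# level; 2-deoxyglucose at dose 9.9 suppresses it with a slow late rise fed
# by glutaminolysis.  kf_5 = kf_6 makes the glucose-only ETC and
# cell-component curves coincide.
units:
  time: minute
  rate_constants: per_minute
  concentrations: model_units_nominally_uM
rate_constants:
  kf_Glc: 1.45e-4
  kf_Gln: 2.80e-4
  kf_1: 0.1
  kf_2: 0.8
  kf_3: 0.1
  kf_4: 0.03
  kf_5: 0.5
  kf_6: 0.5
  kf_7: 0.005
  kr_1: 0.01
  kr_2: 0.05
  kr_3: 0.01
  kr_4: 0.005
  i1: 0.1
  i2: 0.1133
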