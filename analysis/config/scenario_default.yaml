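# Default synthetic-trial scenario (the study conditions; see docs/methods.md).
# Survival families use the package's pinned parameterizations; times in months.
n_per_arm: 179
covariates:
  male: 0.9160
  age: [61.48, 8.0]      # mean, sd
  brain_met: 0.0392
  stage_iv: 0.6583
  smoker: 0.8459
  ecog1: 0.8543
pfs:
  active: [exponential, [0.1260]]    # ln(2)/5.5 per month
  control: [exponential, [0.1415]]   # ln(2)/4.9
pps:                                 # post-progression survival; OS = PFS + PPS
  active: [exponential, [0.0533]]    # ln(2)/13
  control: [exponential, [0.0866]]   # ln(2)/8
crossover_prob: 0.45
crossover_accel: 1.3
censor_time: 24.0
seed: 20240
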