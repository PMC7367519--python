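# Example trial configuration for `actitrial run-all --config ... --out ...`.
# Fields map 1:1 to actitrial.TrialConfig; omitted fields keep their defaults.
n_per_arm: 5
participant_sd: 25.0
residual_sd: 20.0
baseline_mean_by_arm:
  IG: 70.0
  DG: 70.0
true_exposure_effects:
  0: 0.0
  12: 13.0
  25: 6.0
  38: 3.0
true_secular_trend:
  0: 0.0
  13: 2.0
  26: 4.0
  39: 1.0
skew_outlier_rate: 0.04
dropout_rate: 0.06
wear_days_per_assessment: 7
seed: 20260930
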