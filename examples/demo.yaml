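# Demo profile: 240 simulated patients over the shipped six-pattern palette,
# all six benchmark algorithms at both horizons. Matches
# glucluster.pipeline.default_demo_config().
n_patients: 240
seed: 1
horizons_min: [15, 30]
algorithms: [mtsc, wmtsc, holt, gbt_global, rf_cluster, gbt_cluster]
k_range: [2, 10]
split: [0.7, 0.1, 0.2]
hyperparams:
  random_forest:
    n_estimators: 150
  gradient_boosting:
    n_estimators: 150
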