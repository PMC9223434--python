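# Randomized drug-target ranking of the production-degradation toy model.
model: linear_chain
horizon: 10.0
n_points: 1000
n_samples: 1000
seed: 42
distribution:
  kind: lognormal
  log_location: -2.08
  log_scale: 0.61
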