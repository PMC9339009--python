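# Pareto-distributed synaptic decay times: power-law retention regime.
experiment: hetero
seed: 1
output_dir: out/heavy_tail
parameters:
  alpha: 1.5
  r0: 5.0
  b: 0.25
  tau_min: 20.0
  T: 20000.0
  n_realizations: 2
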