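# Equilibrium consolidation at moderate rehearsal drive (b*lam*tau = 1.5).
# Desk-scale realization count; raise n_realizations for smoother tails.
experiment: simulate
seed: 1
output_dir: out/moderate_drive
parameters:
  N: 8000
  f: 0.01
  tau: 160.0
  lam_tau: 5.0
  b: 0.3
  n_realizations: 4
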