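# Three-locus trait adapting from new mutation only (theta_bg = 1):
# the optimum jumps from 0 to 3 gamma; frequencies are recorded when the
# trait mean has advanced one mutational step.
model:
  L: 3
  gamma: 1.0
  Ne: 10000
  mu: 2.5e-5          # theta_bg = 2 Ne mu (d - 1) = 1
  sigma_before: 0.01  # Ne sigma gamma^2 = 100
  zopt0: 0.0
  zopt_new: 3.0
stops:
  cz_values: [1.0]
  max_generations: 3000000
run:
  directional_only: true
  from_sgv: false
  replicate_count: 2000
  seed: 1
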