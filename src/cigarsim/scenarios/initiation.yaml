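# Nationwide US flavored-cigar ban: cigar users prevented per cohort of
# 18-year-olds through deterred initiation and continuing use.
model: initiation
inputs:
  cohort_size: 4200000             # 18-year-olds in the US, 2016
  current_use_prevalence: 0.072    # every-day/some-day cigar use at age 18
  flavored_initiation_fraction: 0.654   # current users who initiated with a flavored product
  continuing_prevalence_ratio: 1.56     # adjusted PR, flavored vs non-flavored initiates
distributions:
  initiation_reduction:            # flavored initiates deterred from ever trying cigars
    min: 0.0
    mode: 0.325
    max: 0.65
  continuing_reduction:            # drop in continuing use; mode = 1 - 1/PR, bounds from PR CI (1.29, 1.87)
    min: 0.225
    mode: 0.359
    max: 0.465
simulation:
  n_iterations: 1000
  seed: 20190904
  interval_mass: 0.90
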