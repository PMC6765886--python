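# Nationwide US flavored-cigar ban: mortality benefit from increased
# cessation among existing exclusive cigar smokers.
model: mortality
inputs:
  attributable_deaths: 5200        # premature deaths/year, exclusive regular cigar smoking
  machine_made_share: 0.92         # share of US cigar sales that are machine-made
  flavored_retail_share: 0.521     # flavored share of machine-made retail sales
distributions:
  consumption_reduction:           # proportional drop in total cigar consumption
    min: 0.15
    mode: 0.30
    max: 0.45
  cessation_fraction:              # share of the drop that is complete cessation
    min: 0.25
    mode: 0.50
    max: 0.75
simulation:
  n_iterations: 1000
  seed: 20190904
  interval_mass: 0.90
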