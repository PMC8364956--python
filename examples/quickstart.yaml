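# Quick-start experiment: mid-sized synthetic panel, both roster scenarios,
# all three combiner families, desk-scale base networks.
synthetic:
  n_states: 3
  counties_per_state: 8
  years: [2000, 2014]
  noise_sd: 8.0
test_year: 2014
scenarios:
  - name: homogeneous
    k: 3
  - name: heterogeneous
    filter_counts: [2, 3]
combiners: [bem, gem, "stacked:ols"]
spec:
  n_filters: 2
  epochs: 40
seed: 7
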