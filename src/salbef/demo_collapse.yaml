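# Hypersaline-collapse variant of the demo scenario: narrow tolerance
# breadths and a sparse halophile pool, so at 20% NaCl most low-richness
# communities lack a competent halophile and their yields collapse by orders
# of magnitude, steepening the diversity-functioning exponent; strong
# selection (halophile dominance) at 20%.
sim:
  n_strains: 40
  richness_levels: [5, 10, 20, 40]
  replicate_counts: [4, 8, 16, 3]
  salinities: [0.9, 3.5, 7.0, 15.0, 20.0]
  theta_by_salinity:
    0.9: 0.05
    3.5: 0.10
    7.0: 0.25
    15.0: 0.70
    20.0: 0.80
  phi_by_salinity:
    0.9: 0.50
    3.5: 0.35
    7.0: 0.20
    15.0: 0.06
    20.0: 0.02
  noise_sd: 0.05
  detection_floor: 0.001
  seed: 0
  halotolerance_skew: 2.6
  halotolerance_cost: 1.8
  y_ref: 1.2
  sigma_range: [0.9, 1.5]
  stratified_communities: false
alpha: 0.05
trend_range: [0.0, 15.0]
partition_route: member
abundance_rule: monoculture
stats_groups: [D]
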