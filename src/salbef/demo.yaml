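# Demo scenario: the full microcosm study design with the qualitative
# salinity pattern — selection dominance (theta) rising with salinity stress
# up to 15% NaCl then dropping at 20%, complementarity (phi) declining.
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
    20.0: 0.15
  phi_by_salinity:
    0.9: 0.50
    3.5: 0.35
    7.0: 0.20
    15.0: 0.06
    20.0: 0.02
  noise_sd: 0.05
  detection_floor: 0.01
  seed: 0
  halotolerance_skew: 1.8
  halotolerance_cost: 1.0
  y_ref: 1.2
  sigma_range: [2.0, 4.5]
  stratified_communities: false
alpha: 0.05
trend_range: [0.0, 15.0]
partition_route: member
abundance_rule: monoculture
stats_groups: [D]
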