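# Serum-stability simulation: five disease conditions + QC bridge,
# 0 h / 20 h, three replicates. Fold changes emulate incubation trends
# (fatty acid release, PA hydrolysis).
design: stability
species: [FA(20:4), 12-HETE, LPA(18:1), PA(36:2)]
replicates: 3
times: [0.0, 20.0]
set_effect_sigma: 1.0
noise_sigma: 0.1
true_fold:
  - {species: FA(20:4), condition: alzheimer, time_h: 20.0, fold: 1.8}
  - {species: FA(20:4), condition: parkinson, time_h: 20.0, fold: 1.8}
  - {species: FA(20:4), condition: depression, time_h: 20.0, fold: 1.8}
  - {species: FA(20:4), condition: schizophrenia, time_h: 20.0, fold: 1.8}
  - {species: FA(20:4), condition: stroke, time_h: 20.0, fold: 1.8}
  - {species: PA(36:2), condition: alzheimer, time_h: 20.0, fold: 0.5}
  - {species: PA(36:2), condition: parkinson, time_h: 20.0, fold: 0.5}
  - {species: PA(36:2), condition: depression, time_h: 20.0, fold: 0.5}
  - {species: PA(36:2), condition: schizophrenia, time_h: 20.0, fold: 0.5}
  - {species: PA(36:2), condition: stroke, time_h: 20.0, fold: 0.5}
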