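# Demo pipeline config: simulate a small family cohort, preprocess the
# FFQ-style survey records, estimate familial correlations and heritability.
seed: 42
simulate:
  n_families: 300
  generations: 3
  h2: 0.2
  c_spouse: 0.2
  c_house: 0.15
preprocess:
  gram: [carbohydrate, protein, fat]
  percent: [carbohydrate, fat]
  density: [protein]
fcor:
  relations: all
  alpha: 0.05
h2:
  estimator: ML
  kinship_scale: 2.0
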