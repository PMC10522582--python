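# Example simulation config: a two-arm cohort with paired pre/post proteomes.
cohort:
  n_per_arm: [53, 55]
  # per-arm probabilities over [CR, PR, SD, PD, NE]; defaults used if omitted
  censor_prob: 0.1
  seed: 1
proteome:
  n_proteins: 300
  n_spiked_per_archetype: 5
  effect_size: 2.0        # log2 shift
  patient_sd: 0.5
  residual_sd: 0.5
  dropout_prob: 0.05
  library_size_range: [50000, 150000]
  seed: 2
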