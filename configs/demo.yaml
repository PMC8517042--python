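# Demo run: synthetic cohorts with one planted genotype-specific effect
# (the A→F transition probability drives postpubertal social interaction in
# wild-type pups).  Reproduce with:
#   usvsyntax run-all --config configs/demo.yaml --outdir demo_run
simulate:
  n_pups: {WT: 14, DEL: 10}
  seed: 0
  effect_spec:
    - {feature: "A→F", behavior: social_interaction, genotype: WT, beta: 150.0}
  noise_sd:
    social_interaction: 4.0
    social_habituation: 4.0
    olfactory_response: 4.0
    olfactory_habituation: 4.0
n_trees: 200
rf_seed: 0
cutoff: 0.25
min_calls: 11
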