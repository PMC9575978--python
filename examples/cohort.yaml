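# Cohort-only configuration for incentdce.synth.cohort_config_from_yaml.
seed: 11
n_per_income: {low: 150, middle: 155, high: 155}
planted: {nontrader: 3, dominance_failer: 15, never_enroller: 12}
rescale_unit: 10
sampler: softmax
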