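# Full-pipeline configuration: the 460-completer study conditions.
# Per-stage seeds derive deterministically from the master seed unless
# overridden (design_seed / cohort_seed / fit_seed / postfit_seed).
seed: 11
n_sets: 30
n_blocks: 3
design_restarts: 8
n_per_income: {low: 150, middle: 155, high: 155}
planted: {nontrader: 3, dominance_failer: 15, never_enroller: 12}
n_draws: 200
wta_draws: 10000
uptake_amounts: [50, 100, 200, 350, 500, 750, 1000]
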