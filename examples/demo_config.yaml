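# Demo pipeline config: small synthetic cohort, reduced MCMC.
# Run:  nof1series report examples/demo_config.yaml --out-dir scratch/demo
synthetic:
  n_participants: 8
  missing_prob: 0.47
outcomes: [stress_today, stress_next]
mcmc:
  n_chains: 2
  burn_in: 500
  kept_iterations: 1000
analysis:
  clinical_threshold: 0.5
  responder_prob_threshold: 0.70
seed: 42
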