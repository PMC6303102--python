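# Master config for `ttftimer run-all --config examples/pipeline.yaml`.
# Screens 60000 random circuits (~4 min on one CPU), scores the consistent
# ones, positions them in Decay-Relay space, and runs the synthetic in-vivo
# positioning demo against a decay-dominant circuit from the ensemble.
seed: 8
outdir: out/
screen:
  n_circuits: 60000
  chunk_size: 8000
robustness:
  tol: 0.10   # relative phase-duration distance counted as 'close'
  eps: 0.20   # production noise amplitude
invivo:
  enabled: true
  n_per_stage: 10
  noise_sd: 0.2
  effect: 0.6
  robust_cutoff: 80.0
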