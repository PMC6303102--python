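# Default TTF regulatory circuit of the embryonic neuroblast timer.
# Forward relay activations propagate the cascade Hb -> Kr -> Pdm -> Cas;
# forward decay repressions gate Pdm and Cas on the decay of their upstream
# repressors; one backward repression (Cas -| Pdm) shuts off the Pdm phase.
# 7 threshold-bearing edges + 6 production/basal + 4 degradation rates
# = 17 free parameters.
ttfs: [Hb, Kr, Pdm, Cas]
interactions:
  - {source: Hb, target: Kr, sign: activation, klass: forward-relay}
  - {source: Kr, target: Pdm, sign: activation, klass: forward-relay}
  - {source: Hb, target: Pdm, sign: repression, klass: forward-decay}
  - {source: Pdm, target: Cas, sign: activation, klass: forward-relay}
  - {source: Kr, target: Cas, sign: repression, klass: forward-decay}
  - {source: Hb, target: Cas, sign: repression, klass: forward-decay}
  - {source: Cas, target: Pdm, sign: repression, klass: backward}
constants:
  hill_n: 4          # Hill steepness; null selects sharp (step) regulation
  t_off: 45.0        # minutes of external input driving Hb (one cell cycle)
  horizon: 400.0     # simulated minutes, spans the full cascade
  dt: 0.125          # integrator step, minutes
  grid_step: 1.0     # trajectory output step, minutes
  on_fraction: 0.05  # "on" threshold as fraction of a TTF's maximal level
  identity_fraction: 0.05
  min_phase: 2.0     # minutes; shorter phases treated as grid artifacts
  sustain: 10.0      # minutes above threshold required to call induction
  division_period: 45.0
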