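# Expected on-TTF phase sequences per genotype, editable transcription of the
# published expression summaries for the NB7-1 lineage.  Only the order of
# on-sets is compared, never durations.  Because the model induces Kr solely
# through Hb (Kr's external induction is deliberately not modeled), the
# hb_del entry describes the model-reachable mutant sequence: Pdm and Cas are
# de-repressed through their basal production once both repressors are absent.
genotypes:
  - name: wt
    perturbation: {kind: none}
    expected:
      - [Hb]
      - [Hb, Kr]
      - [Kr]
      - [Kr, Pdm]
      - [Pdm]
      - [Pdm, Cas]
      - [Cas]
  - name: hb_del
    perturbation: {kind: deletion, target: Hb}
    expected:
      - [Pdm]
      - [Pdm, Cas]
      - [Cas]
  - name: kr_del
    perturbation: {kind: deletion, target: Kr}
    expected:
      - [Hb]
      - [Pdm]
      - [Pdm, Cas]
      - [Cas]
  - name: pdm_del
    perturbation: {kind: deletion, target: Pdm}
    expected:
      - [Hb]
      - [Hb, Kr]
      - [Kr]
      - [Cas]
  - name: hb_const
    perturbation: {kind: constitutive, target: Hb}
    expected:
      - [Hb]
      - [Hb, Kr]
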