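# Reconstructed stage-to-minute table on the cascade clock (minutes from
# cascade onset).  The published figures use embryonic stage labels on the
# time axis without printing the minute mapping; these boundaries are a
# package default and every stage-dependent output carries this table's hash.
stages:
  S9:   [0, 25]
  S10E: [25, 40]
  S10:  [40, 55]
  S11E: [55, 110]
  S11:  [110, 220]
  S12:  [220, 340]
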