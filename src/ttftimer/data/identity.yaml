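# Mapping from co-expressed TTF sets to neuronal identity labels for the
# NB7-1 lineage.  Hb-only and Hb+Kr phases yield the same early fates, so
# they share a label and are merged when phase durations are scored.
identity_map:
  "Hb": "fate-1/2"
  "Hb+Kr": "fate-1/2"
  "Kr": "fate-3"
  "Kr+Pdm": "fate-4"
  "Pdm": "fate-5/6"
  "Pdm+Cas": "fate-7"
  "Cas": "fate-late"
  "": "none"
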