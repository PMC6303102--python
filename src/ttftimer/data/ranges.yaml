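# Reconstructed default sampling ranges for the random-circuit screen.
# All draws are log-uniform.  Degradation spans two orders of magnitude
# around 0.05 1/min (the rate implied by the ~15 min Hb half-life).
# Production/basal units are arbitrary: only ratios of levels to thresholds
# matter, so regulation thresholds are sampled as a fraction (1-10%) of the
# source TTF's maximal level, the range implied by Pdm starting to express
# when Hb has decayed to 1-10% of its peak.
production: [0.01, 10.0]
# Basal (activator-independent) transcription is weak relative to activated
# production: in vivo it produces only small early transient bumps, not full
# inductions, so its range sits two orders below the regulated rates.
basal: [0.001, 1.0]
degradation: [0.005, 0.5]
threshold_fraction: [0.01, 0.10]
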