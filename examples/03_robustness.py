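"""Score a circuit's robustness to combinatorial production-rate noise.

Re-simulates a circuit under all 2^6 = 64 combinations of +/-20% on its six
production parameters and reports the percentage of combinations whose
identity-merged phase durations all stay within 10% of the unperturbed ones.
"""

from ttftimer import load_fixture, robustness_score

for name in ("consistent", "robust", "decay_dominant"):
    params = load_fixture(name)
    score = robustness_score(params)
    print(f"{name:15s} robustness score = {score:5.1f} / 100")

print(
    "\nA score of 100 means every one of the 64 noise patterns left all"
    "\nfate-relevant phase durations within 10%; robust circuits keep the"
    "\ntimer synchronized with the ~45-min division cycle despite noisy"
    "\nproduction rates."
)
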