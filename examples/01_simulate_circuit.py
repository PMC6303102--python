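"""Simulate one TTF circuit and read off its expression phases.

Loads the packaged reference circuit (a parameter set consistent with the
wild-type and mutant phenotypes), integrates the four ODEs from zero initial
conditions, and prints the resulting sequence of expression/co-expression
phases plus the progeny identities at 45-min divisions.
"""

from ttftimer import (
    load_fixture,
    load_identity_map,
    progeny_identities,
    simulate,
    trajectory_to_phases,
)

params = load_fixture("consistent")
traj = simulate(params)
phases = trajectory_to_phases(traj, params.on_thresholds())

print("wild-type phase sequence (on-TTFs, start-end in minutes):")
for ph in phases:
    members = "+".join(sorted(ph.on_set)) or "-"
    print(f"  {members:10s} {ph.start:6.1f} - {ph.end:6.1f}")

identity_map = load_identity_map()
fates = progeny_identities(traj, None, identity_map, params.identity_thresholds())
print("\nGMC identities at successive 45-min divisions:")
print(" ", " -> ".join(fates))
print(
    "\nEach line is a maximal interval with a constant set of TTFs above"
    "\ntheir on-thresholds; the fate sequence is what the lineage inherits."
)
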