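"""Position a 'measured' circuit in Decay-Relay space from staged staining data.

Full measurement-side pipeline on synthetic data with known ground truth:
1. screen a random ensemble and score it;
2. pick a decay-dominant circuit as the hidden truth and simulate its
   induction stages for wild type and deletion mutants;
3. generate noisy per-cell staining tables (log TTF/En ratios by stage);
4. run the staging statistics and place the circuit, with error bars,
   in Decay-Relay space.
"""

from ttftimer import (
    generate_staining_dataset,
    load_stage_table,
    position_from_measurements,
    run_screen,
    select_positioning_truth,
)
from ttftimer.circuit import build_default_topology
from ttftimer.decay_relay import compute_perturbation_shifts, significance_scores
from ttftimer.robustness import score_records

topology = build_default_topology()
stage_table = load_stage_table()

print("screening 60000 random circuits...")
records = run_screen(60_000, seed=8, chunk_size=8000)
cons = records[records["consistent"]].copy()
cons = score_records(cons, topology)
cons = compute_perturbation_shifts(cons, topology)
cons = significance_scores(cons)
print(f"  {len(cons)} consistent, "
      f"{int((cons['robustness_score'] > 80).sum())} robust (score > 80)")

truth, sim_cfg = select_positioning_truth(cons, stage_table, topology)
print(f"hidden truth circuit: {truth.params_id or 'screened draw'} "
      f"(decay-dominant, stage-callable inductions)")

staining = generate_staining_dataset(sim_cfg, seed=99)
pos = position_from_measurements(staining, cons, stage_table)
print(
    f"\nrecovered position: decay = {pos.decay_significance:.1f} "
    f"[{pos.decay_range[0]:.1f}, {pos.decay_range[1]:.1f}], "
    f"relay = {pos.relay_significance:.1f} "
    f"[{pos.relay_range[0]:.1f}, {pos.relay_range[1]:.1f}]"
)
print(
    "\nThe diamond lands in the decay-dominant half with error bars"
    "\nexcluding the relay half, recovering the hidden circuit's regime"
    "\nfrom stage-resolution staining alone."
)
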