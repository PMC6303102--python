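# Methods

## The circuit model

The model tracks the concentrations of the four TTFs (Hb, Kr, Pdm, Cas) in a
single neuroblast with one ODE per factor:

```
dX/dt = [ β_X · Π_Y A(Y; T_YX) + β0_X ] · Π_Z R(Z; T_ZX) − α_X · X
```

`A(Y;T) = (Y/T)^n / (1+(Y/T)^n)` and `R(Z;T) = 1/(1+(Z/T)^n)` are
dimensionless Hill regulation terms in [0, 1]; a step-function option
(`hill_n: null`) replaces them with sharp thresholds. Regulation depends
only on ratios `Y/T`, so production rates and thresholds carry arbitrary
concentration units and only their ratios matter; the package exploits this
in a scale-invariance property test.

The default topology contains the six experimentally described forward
edges — relay activations Hb→Kr, Kr→Pdm, Pdm→Cas and decay repressions
Hb⊣Pdm, Kr⊣Cas, Hb⊣Cas — plus one backward repression Cas⊣Pdm that ends the
Pdm phase. Hb has no upstream activator; its production is gated by an
external input active on `[0, t_off)` with `t_off = 45` min (one division
cycle). Kr's experimentally observed cascade-external induction is *not*
modeled: Kr is induced solely through Hb, which matters for interpreting the
hb-deletion genotype (below). Basal production `β0` exists only for Pdm and
Cas and is multiplied by the repression terms but not the activation terms;
this is what produces the small early transient bursts before the repressors
have accumulated, as seen in stained embryos.

Free parameters: 4 production rates, 2 basal rates, 4 degradation rates,
7 regulation thresholds — 17 in total. Structural constants (not free):
Hill exponent `n = 4`, `t_off = 45` min, horizon 400 min (the duration of
the full cascade), integrator step 0.125 min, output grid 1 min, on/identity
thresholds at 5% of a TTF's maximal level `(β+β0)/α`, minimum phase duration
2 min, induction sustain requirement 10 min, division period 45 min.

Integration uses a fixed-step classic Runge–Kutta scheme vectorized over
whole batches of circuits (the screen integrates thousands of parameter sets
simultaneously). At step 0.125 min the relative error against the
closed-form single-species solution is below 10⁻⁶ across the sampled
degradation range (unit-tested); phase boundaries and induction times are
located by linear interpolation between grid samples, so durations are not
quantized to the output grid.

## Phases, identities, consistency

A TTF is "on" where its level is at or above its on-threshold (5% of its
maximal level, inside the 1–10% range implied by Pdm starting to express
when Hb has decayed to 1–10% of peak). Phases shorter than 2 min are merged
into their neighbor as grid artifacts. A circuit is *consistent* when, for
the wild type and every perturbed genotype in the phenotype table, the
ordered list of non-empty on-sets equals the expected list exactly —
durations are never compared, because the reference phenotype data has low
temporal resolution. Leading/gap phases with an empty on-set are dropped
before comparison since every simulation starts from zero levels.

The shipped phenotype table encodes: the seven-phase wild type
({Hb}, {Hb,Kr}, {Kr}, {Kr,Pdm}, {Pdm}, {Pdm,Cas}, {Cas}); `kr_del`
({Hb}, {Pdm}, {Pdm,Cas}, {Cas}); `pdm_del` ({Hb}, {Hb,Kr}, {Kr}, {Cas});
constitutive Hb (locked in {Hb}, {Hb,Kr}); and `hb_del`
({Pdm}, {Pdm,Cas}, {Cas}). The `hb_del` entry deserves a note: because the
model induces Kr only through Hb, deleting Hb silences Kr, and Pdm/Cas are
de-repressed through their basal production. A mutant sequence containing a
Kr phase would be unreachable for *every* parameter set, so the table
describes the model-reachable mutant. The table is a config file precisely
so that better phenotype transcriptions can be dropped in.

Progeny identity: at each division the set of TTFs above the identity
threshold maps to a fate label. Hb-only and Hb+Kr phases share a fate label
(both produce the first two fates), so they merge into a single phase for
duration-based scoring; the other on-sets keep distinct labels.

## Perturbations

* **Deletion** zeroes the target's production rates (`β`, `β0`).
* **Constitutive expression** fixes every regulation term on the target's
  production at 1, including Hb's external gate.
* **Link removal** abolishes one interaction. For a repression edge the
  term becomes 1 (the target is de-repressed and can only be induced
  earlier). For an activation edge the activation *input* is abolished, so
  the regulated production term vanishes and only basal production remains
  (induction can only be delayed) — exactly the effect the activator's
  deletion has on this one target. This choice is forced by two
  observations: the measured deletion and link-removal shifts must correlate
  tightly for the translation step to make sense, and the largest observable
  relay-removal shift is a *delay* to the end of the staged window. Setting
  an activation term to 1 would instead produce constitutive production and
  pure advances.

Exactly one perturbation may be applied to a circuit; stacking raises.

## The screen

Every free parameter is drawn log-uniformly. Reconstructed default ranges
(`ranges.yaml`): production 0.01–10 (arbitrary units); basal production
0.001–1, two orders below the regulated rates because basal transcription
produces only small transient bumps in vivo, not full inductions;
degradation 0.005–0.5 1/min, two orders centred on the 0.05 1/min implied by
the ~15-min Hb half-life; thresholds as a fraction 0.01–0.1 of the source
TTF's maximal level. Each draw uses its own seed substream derived from
`(seed, draw index)`, so results are independent of chunking; records stream
to CSV in bounded-memory chunks. With these ranges roughly 0.1% of draws
are consistent; the published range table is unavailable, so the yield is a
property of the reconstruction, not a target.

## Robustness score

Each consistent circuit is re-simulated under all 2⁶ = 64 combinations of
±20% applied to the six production parameters (degradation rates are left
fixed: they set the time scale and affect all circuits alike; threshold
noise is subsumed because only level/threshold ratios matter). Phase
sequences of the noisy variants are called against the *original* circuit's
on-thresholds, identity-merged, and compared: a combination is "close" when
the fate order is unchanged and every duration is within 10% of the
original. The score is the percentage of close combinations.

The final phase is open-ended — it is truncated by the simulation horizon,
not terminated by the circuit — so its "duration to the horizon" measures an
arbitrary structural constant and registers any common upstream timing
shift. It therefore participates in the order check but not the duration
comparison (`is_close(compare_final=True)` restores the stricter variant).

## Decay–Relay space

For each consistent circuit, eight perturbed simulations measure the
induction-time shifts `Δt = 100·(t_pert − t_wt)/t_wt` of Pdm and Cas under
link removals (decay: Hb⊣Pdm, Kr⊣Cas — Hb⊣Cas stays intact because Hb has
normally decayed by Cas time; relay: Kr→Pdm, Pdm→Cas) and under the
corresponding TTF deletions. A perturbed TTF that is never induced before
the horizon is capped at the horizon and flagged; capped shifts are floors,
not measurements, so correlation analyses exclude them by default (config
option).

Significance coordinates: per TTF and link type, |Δt| is normalized to the
maximal |Δt| in the ensemble (the largest shift maps to 100 exactly), and
the Pdm and Cas contributions are averaged, giving decay and relay
significances in [0, 100]. Deletion sensitivity (the Hb-Kr space) uses the
signed Pdm shifts under Hb and Kr deletion. Density maps bin coordinates
20×20 over [0, 100]²; empty bins are absent, not zero.

In this reconstruction every consistent circuit's Pdm induction is gated by
Hb decay — a structural consequence of thresholds at 1–10% of source maxima
(any activator crosses such a threshold long before a repressor decays
through it) together with the basal-driven `hb_del` constraint. The
absolute relay-dominant third of the plane is therefore empty, and
ensemble-level comparisons of "decay-leaning" versus "relay-leaning"
circuits use terciles of the signed difference
`decay_significance − relay_significance` instead of absolute bands: the
most decay-leaning third versus the most relay-leaning third. On ensembles
of ≥100 consistent circuits the decay-leaning tercile is reproducibly the
more robust one; at a few dozen circuits the comparison is underpowered,
which is why the acceptance analyses run a 1.6×10⁵-draw screen (~100
consistent circuits, a few minutes on one CPU) rather than the minimal
2×10⁴.

## One-step timer theory

Accumulation timer: `t = −ln(1 − Tr·k/β)/k`, requiring `Tr < β/k`; decay
timer: `t = ln(P0/Tr)/k`. Under a production fold-change `f` the decay
delay shifts by `ln(f)/k` independently of the threshold, while the
accumulation shift is `ln((1 − c)/(1 − c/f))/k` with `c = Tr·k/β`, which
vanishes as `c → 0`, crosses the decay shift at `c = 1/3` (for `f = 1/2`)
and diverges as `c → f`. The correct statement of the design asymmetry is
therefore not "accumulation always shifts more" but "decay sensitivity is
threshold-independent while accumulation sensitivity grows without bound
near the steady state" — the tests assert exactly this, including the
crossover.

## Measurement-side statistics

Inputs are per-cell records (genotype, stage, TTF, log TTF/Engrailed
intensity ratio, nuclear volume) over the ordered stages S9, S10E, S10,
S11E, S11, S12.

* **Volume filter**: cells further than 2 SD from the mean wild-type volume
  are excluded (presumed dividing or misidentified). With fewer than 3
  reference cells the filter is the identity.
* **Stage summaries**: n, mean, SD, SEM = SD/√n, 95% half-width 1.96·SEM.
* **Induction calling**: background = mean of the wild-type S10E and S10
  stage means; the induction stage is the first stage, scanning in order
  but skipping S9 (early transients), whose mean − 1.96·SEM exceeds the
  background; `None` if no stage qualifies. The rule scans five stages with
  a per-stage 95% band, so its family-wise false-call rate under a truly
  flat profile is ~15–20% by construction (measured ~20% at n = 10/stage);
  its strength is sensitivity, not specificity, and analyses that need a
  null should not read `None` as a calibrated 5% test.
* **Measured shifts**: induction times are stage midpoints with half the
  stage duration as margin; the shift interval is worst-case interval
  arithmetic over both midpoint intervals. If a mutant is already induced
  at the earliest scannable stage the onset is only upper-bounded and the
  interval is left-censored down to −100%.
* **Translation**: a measured deletion-shift interval is placed on the
  deletion vs link-removal correlation cloud, and the maximal link-removal
  range reached by robust circuits (score > 80) inside the interval is
  returned. With a desk-scale ensemble the robust subset can be sparse; the
  pipeline-level procedure then snaps to the nearest robust circuit
  (logged), while the low-level operation keeps its strict error contract.
* **Positioning**: the link ranges are combined exactly like the simulated
  significance scores, with the stated maximal-observable normalizers: Pdm
  decay by 100% (induction at t = 0), relay removals by the delay to the
  middle of the last stage, Cas decay by the largest simulated shift (Hb
  still represses Cas, so t = 0 is unreachable). Error bars propagate the
  range endpoints through the same arithmetic.

The stage-to-minute table is a reconstruction on the cascade clock (the
source figures use stage labels without printing minutes): S9 0–25,
S10E 25–40, S10 40–55, S11E 55–110, S11 110–220, S12 220–340. It is
aligned so that typical consistent circuits induce Pdm after the background
stages — the protocol's own precondition; all stage-dependent outputs carry
the table's hash. The wild type must induce Pdm and Cas in a callable,
non-final stage for the procedure to apply (`stageable_wild_type`).

## Synthetic staining generator

Per record: `log_ratio = baseline + effect·1[stage ≥ induction stage] +
transient·1[stage = S9] + Gaussian noise` (log-normal intensities), with an
optional linear ramp instead of the step for stress-testing the caller.
Volumes are Gaussian with a configurable fraction of outliers planted at
exactly ±3 SD. Defaults: 10 cells per stage and genotype (the scale of the
real per-stage counts), noise SD 0.2 log units, effect 0.6 (3 SD — the real
induction jumps are several SD), baseline 0. The generator emulates the
*structure* of the confocal quantification, not imaging physics: no
segmentation errors, no stage-assignment uncertainty, no correlated
staining batch effects. Passing recovery tests therefore validates the
statistical procedures given correctly staged, independently noisy
measurements — not the upstream image analysis.

Fixture circuits (`data/fixtures.csv`) were found by screening with the
recorded seed (202): a consistent reference, a robust circuit (score 100)
and a robust decay-dominant circuit with stage-callable wild-type inductions
(score 87.5). No relay-dominant consistent circuit exists under the default
ranges (see above), so that fixture is absent and requesting it raises the
documented budget error.

## Numerical and policy choices

* Ties at thresholds count as "on"; interpolated crossings resolve
  durations below the 1-min grid.
* NaN encodes NOT_INDUCED in tabular records; the API returns an explicit
  sentinel.
* Per-draw seed substreams make the screen invariant to chunking; all
  pipeline seeds are explicit in config, never clock-derived.
* A solver failure in a screen draw flags the record and continues; in a
  robustness combination it counts as "not close"; in `simulate` it raises
  with the parameter-set id.

## Known limitations

* The published equation, range and phenotype tables are unavailable; the
  equation form, ranges and mutant sequences are reconstructions controlled
  by config files, and the consistency yield (~0.1%) is not comparable to
  the published ~10%.
* Kr's external induction is not modeled, so `hb_del` genotype predictions
  diverge from real hb mutants (where Kr persists); the in-vivo positioning
  pipeline is validated against the model's own ground truth, not real
  embryos.
* Degradation-rate noise is excluded from the robustness score by design;
  the score is conditional on fixed time scales.
* The stage clock is a reconstruction; measured Δt values depend on it and
  carry its hash, and only regime-level conclusions (decay vs relay half)
  should be read off the synthetic positioning.
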