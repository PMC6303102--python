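# Record file schemas

## `records.csv` (screen output, one row per sampled circuit)

| column | meaning |
|---|---|
| `draw` | draw index within the screen (seed substream key) |
| `params_id` | stable id `s<seed>-d<draw>` |
| `beta_Hb` … `beta_Cas` | production rates, concentration/min |
| `beta0_Pdm`, `beta0_Cas` | basal production rates |
| `alpha_Hb` … `alpha_Cas` | degradation rates, 1/min |
| `T_HbKr`, `T_KrPdm`, `T_HbPdm`, `T_PdmCas`, `T_KrCas`, `T_HbCas`, `T_CasPdm` | regulation thresholds (concentration), keyed source→target |
| `consistent` | phase sequences match every genotype's phenotype |
| `failed` | numerical failure during integration (record kept, not scored) |
| `fail_genotype` | first genotype whose sequence mismatched (empty if consistent) |
| `t_wt_Hb` … `t_wt_Cas` | wild-type induction times, minutes; empty cell = never induced (NOT_INDUCED) |

## columns added by `score` and `position`

| column | meaning |
|---|---|
| `robustness_score` | percent of the 64 ±20% production-noise combinations that are 'close' |
| `t_<name>` / `d_<name>` / `capped_<name>` | perturbed induction time (min), signed percent shift, horizon-cap flag, for `<name>` in `pdm_rm_decay`, `pdm_rm_relay`, `cas_rm_decay`, `cas_rm_relay`, `pdm_del_hb`, `pdm_del_kr`, `cas_del_kr`, `cas_del_pdm` |
| `n_<link name>` | ensemble-normalized absolute shift in [0, 100] |
| `decay_significance`, `relay_significance` | Decay–Relay coordinates in [0, 100] |
| `hb_deletion_shift`, `kr_deletion_shift` | signed Pdm shifts under Hb/Kr deletion (the Hb-Kr sensitivity plane) |

## `density.json`

`counts` (bins×bins integer), `x_edges`/`y_edges` (bin boundaries over
[0, 100]), `mean` (per-bin mean robustness score, `null` where the bin is
empty).

## staining measurement CSV

`genotype, stage, ttf, log_ratio, volume` (+ `planted_outlier` when
generated synthetically); stage labels from the configured stage list.
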