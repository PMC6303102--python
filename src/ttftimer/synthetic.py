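"""Synthetic data with known ground truth.

Two generators live here.  :func:`generate_staining_dataset` emulates the
structure of the confocal quantification -- per-neuroblast log(TTF/En)
intensity ratios grouped by embryonic stage, with Gaussian noise on the log
scale (equivalently log-normal intensities), an optional early stage-9
transient, and nuclear volumes containing planted outliers.  It exists so
that the measurement-side statistics can be validated by parameter recovery:
the true induction stage is an input.

:func:`find_fixture_circuits` searches the random screen for named reference
circuits (a consistent circuit, a robust decay-dominant circuit, a
relay-dominant circuit) so that tests and examples can run on known-good
parameter sets; the fixtures found for the packaged seed are shipped under
``ttftimer/data/fixtures.csv`` together with the seed that found them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import config as _config
from .circuit import (
    CircuitTopology,
    DEFAULT_CONSTANTS,
    ParameterSet,
    Perturbation,
    StructuralConstants,
    build_default_topology,
    simulate,
)
from .decay_relay import (
    NOT_INDUCED,
    compute_perturbation_shifts,
    significance_scores,
)
from .errors import FixtureSearchError, ValidationError
from .invivo import DEFAULT_STAGES, StageTable
from .robustness import score_records
from .screen import ParameterRanges, run_screen

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# staining generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InductionSpec:
    """Ground truth for one (genotype, TTF): induction stage and effect size."""

    stage: str | None  # None = never induced
    effect: float = 0.6  # log-ratio units added from the induction stage on
    transient: float = 0.0  # extra amplitude at the first stage (S9 burst)


@dataclass(frozen=True)
class StainingSimConfig:
    """Configuration of the synthetic staining generator.

    ``induction`` maps genotype -> ttf -> :class:`InductionSpec`.  Noise is
    additive Gaussian on the log-ratio scale.  ``ramp_stages`` > 0 replaces
    the step induction by a linear ramp reaching full effect after that many
    stages (for stress-testing the induction-stage caller).  Outlier volumes
    are planted at exactly ``outlier_sd_multiple`` standard deviations from
    the mean, with random sign.
    """

    induction: Mapping[str, Mapping[str, InductionSpec]]
    stages: tuple[str, ...] = DEFAULT_STAGES
    n_per_stage: int = 10
    baseline: float = 0.0
    noise_sd: float = 0.2
    volume_mean: float = 100.0
    volume_sd: float = 10.0
    outlier_fraction: float = 0.05
    outlier_sd_multiple: float = 3.0
    ramp_stages: int = 0

    def __post_init__(self):
        if self.n_per_stage < 1:
            raise ValidationError("n_per_stage must be >= 1")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        for genotype, per_ttf in self.induction.items():
            for ttf, spec in per_ttf.items():
                if spec.stage is not None and spec.stage not in self.stages:
                    raise ValidationError(
                        f"{genotype}/{ttf}: induction stage {spec.stage!r} not in stage list"
                    )


def generate_staining_dataset(
    config: StainingSimConfig,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw one synthetic staining table.

    Columns: genotype, stage, ttf, log_ratio, volume, planted_outlier.
    Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stage_index = {s: i for i, s in enumerate(config.stages)}
    rows = []
    for genotype, per_ttf in config.induction.items():
        for ttf, spec in per_ttf.items():
            ind = stage_index.get(spec.stage) if spec.stage is not None else None
            for stage in config.stages:
                si = stage_index[stage]
                level = config.baseline
                if ind is not None and si >= ind:
                    if config.ramp_stages > 0:
                        frac = min(1.0, (si - ind + 1) / config.ramp_stages)
                    else:
                        frac = 1.0
                    level += spec.effect * frac
                if si == 0:
                    level += spec.transient
                noise = rng.normal(0.0, config.noise_sd, config.n_per_stage)
                outlier = rng.random(config.n_per_stage) < config.outlier_fraction
                sign = rng.choice([-1.0, 1.0], config.n_per_stage)
                volume = rng.normal(config.volume_mean, config.volume_sd, config.n_per_stage)
                volume = np.where(
                    outlier,
                    config.volume_mean
                    + sign * config.outlier_sd_multiple * config.volume_sd,
                    volume,
                )
                for i in range(config.n_per_stage):
                    rows.append(
                        {
                            "genotype": genotype,
                            "stage": stage,
                            "ttf": ttf,
                            "log_ratio": level + noise[i],
                            "volume": volume[i],
                            "planted_outlier": bool(outlier[i]),
                        }
                    )
    return pd.DataFrame(rows)


def staining_config_from_circuit(
    params: ParameterSet,
    stage_table: StageTable,
    topology: CircuitTopology | None = None,
    effect: float = 0.6,
    noise_sd: float = 0.2,
    n_per_stage: int = 10,
) -> StainingSimConfig:
    """Ground-truth staining config from a circuit's simulated induction stages.

    Simulates the circuit under the wild type and the deletion genotypes
    used by the positioning procedure, converts each Pdm/Cas induction time
    into the stage containing it, and plants those stages as the true
    induction stages of the generated dataset.  Inductions before the table
    or never occurring map to the first stage or to "never" respectively.
    """
    from .decay_relay import induction_time

    topo = topology or build_default_topology()
    genotype_perts = {
        "wt": None,
        "hb_del": Perturbation.deletion("Hb"),
        "kr_del": Perturbation.deletion("Kr"),
        "pdm_del": Perturbation.deletion("Pdm"),
    }
    needed = {
        "wt": ("Pdm", "Cas"),
        "hb_del": ("Pdm",),
        "kr_del": ("Pdm", "Cas"),
        "pdm_del": ("Cas",),
    }
    on_thr = params.on_thresholds()
    induction: dict[str, dict[str, InductionSpec]] = {}
    for genotype, ttfs in needed.items():
        traj = simulate(params, topo, genotype_perts[genotype])
        per_ttf = {}
        for ttf in ttfs:
            t = induction_time(traj, ttf, on_thr[ttf], params.constants.sustain)
            if t is NOT_INDUCED:
                stage = None
            else:
                stage = stage_table.stage_of(t)
                if stage is None and t < stage_table.entries[0][1]:
                    stage = stage_table.stages[0]
            per_ttf[ttf] = InductionSpec(stage, effect)
        induction[genotype] = per_ttf
    return StainingSimConfig(
        induction,
        stages=stage_table.stages,
        n_per_stage=n_per_stage,
        noise_sd=noise_sd,
    )


def select_positioning_truth(
    scored_records: pd.DataFrame,
    stage_table: StageTable,
    topology: CircuitTopology | None = None,
    constants: StructuralConstants = DEFAULT_CONSTANTS,
    effect: float = 0.6,
    noise_sd: float = 0.2,
    n_per_stage: int = 10,
) -> tuple[ParameterSet, StainingSimConfig]:
    """Pick a decay-dominant circuit usable as positioning ground truth.

    The measurement protocol presumes that every compared (genotype, TTF)
    pair shows a sustained induction somewhere in the staged window: the
    wild type in a callable non-final stage, and each deletion genotype at
    some stage at all.  Candidates are scanned in descending robustness and
    the first circuit whose simulated induction stages satisfy this is
    returned together with its ground-truth staining config.
    """
    from .invivo import stageable_wild_type

    topo = topology or build_default_topology()
    stageable = scored_records.apply(
        lambda r: stageable_wild_type(r["t_wt_Pdm"], r["t_wt_Cas"], stage_table),
        axis=1,
    )
    pool = scored_records[
        stageable
        & (scored_records["decay_significance"] > scored_records["relay_significance"])
    ].sort_values("robustness_score", ascending=False)
    for _, row in pool.iterrows():
        params = ParameterSet.from_row(row, topo, constants)
        cfg = staining_config_from_circuit(
            params, stage_table, topo, effect, noise_sd, n_per_stage
        )
        if all(
            spec.stage is not None
            for per_ttf in cfg.induction.values()
            for spec in per_ttf.values()
        ):
            return params, cfg
    raise FixtureSearchError(
        f"none of {len(pool)} stageable decay-dominant circuits shows sustained "
        "inductions for every compared genotype; screen more circuits"
    )


# ---------------------------------------------------------------------------
# fixture circuits
# ---------------------------------------------------------------------------

FIXTURE_CRITERIA = ("consistent", "robust", "decay_dominant", "relay_dominant")


def find_fixture_circuits(
    ranges: ParameterRanges | None = None,
    topology: CircuitTopology | None = None,
    phenotype_table=None,
    seed: int = 0,
    criteria: Sequence[str] = FIXTURE_CRITERIA,
    max_draws: int = 100_000,
    batch: int = 5000,
    constants: StructuralConstants = DEFAULT_CONSTANTS,
    robust_cutoff: float = 80.0,
    stage_table: StageTable | None = None,
) -> dict[str, pd.Series]:
    """Search the screen for named reference circuits.

    Criteria: ``consistent`` (first consistent draw), ``robust``
    (robustness score > cutoff), ``decay_dominant`` / ``relay_dominant``
    (robust circuit whose decay/relay significance dominates within the
    ensemble screened so far).  When a ``stage_table`` is given, dominance
    fixtures are additionally required to have wild-type Pdm and Cas
    inductions inside the staged window, so they can serve the measurement
    pipeline end to end.  Returns one scored record per satisfied
    criterion; raises :class:`FixtureSearchError` with a budget report if a
    criterion is not met within ``max_draws``.
    """
    from .invivo import stageable_wild_type

    topo = topology or build_default_topology()
    found: dict[str, pd.Series] = {}
    scored_parts: list[pd.DataFrame] = []
    drawn = 0
    while drawn < max_draws and len(found) < len(criteria):
        n = min(batch, max_draws - drawn)
        df = run_screen(
            n, ranges, topo, phenotype_table, seed=seed + drawn, constants=constants
        )
        drawn += n
        cons = df[df["consistent"]].copy()
        if len(cons) == 0:
            continue
        cons = score_records(cons, topo, constants=constants)
        cons = compute_perturbation_shifts(cons, topo, constants)
        scored_parts.append(cons)
        # normalization spans the whole pool screened so far
        pool = significance_scores(pd.concat(scored_parts, ignore_index=True))
        if "consistent" in criteria and "consistent" not in found:
            found["consistent"] = pool.iloc[0]
        robust = pool[pool["robustness_score"] > robust_cutoff]
        if "robust" in criteria and "robust" not in found and len(robust):
            found["robust"] = robust.iloc[0]
        stageable = robust
        if stage_table is not None and len(robust):
            ok = robust.apply(
                lambda r: stageable_wild_type(r["t_wt_Pdm"], r["t_wt_Cas"], stage_table),
                axis=1,
            )
            stageable = robust[ok]
        if "decay_dominant" in criteria and "decay_dominant" not in found:
            cand = stageable[
                stageable["decay_significance"] > stageable["relay_significance"]
            ]
            if len(cand):
                found["decay_dominant"] = cand.iloc[0]
        if "relay_dominant" in criteria and "relay_dominant" not in found:
            cand = pool[pool["relay_significance"] > pool["decay_significance"]]
            if len(cand):
                found["relay_dominant"] = cand.iloc[0]
        log.info("fixture search: %d drawn, %d consistent, found %s",
                 drawn, len(pool), sorted(found))
    missing = [c for c in criteria if c not in found]
    if missing:
        n_cons = sum(len(p) for p in scored_parts)
        raise FixtureSearchError(
            f"criteria {missing} not met within {drawn} draws "
            f"({n_cons} consistent circuits examined)"
        )
    return found


def load_fixture(
    name: str,
    topology: CircuitTopology | None = None,
    constants: StructuralConstants = DEFAULT_CONSTANTS,
) -> ParameterSet:
    """Load one shipped fixture circuit by name as a :class:`ParameterSet`."""
    df = load_fixture_table()
    if name not in set(df["name"]):
        raise ValidationError(f"unknown fixture {name!r}; available: {sorted(df['name'])}")
    row = df[df["name"] == name].iloc[0]
    return ParameterSet.from_row(row, topology, constants, params_id=f"fixture:{name}")


def load_fixture_table() -> pd.DataFrame:
    """The shipped fixture-circuit table (parameters plus search metadata)."""
    with resources.files("ttftimer.data").joinpath("fixtures.csv").open() as fh:
        return pd.read_csv(fh)
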