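"""Random-parameter consistency screen.

Candidate circuits are generated by drawing every free kinetic parameter
log-uniformly from configured ranges (rejection sampling over parameter
space).  Each draw is simulated under the wild type and every perturbed
genotype in the phenotype table; a circuit whose on-TTF phase sequences match
the expected sequences for *all* genotypes is retained as *consistent*.  The
relative influence of the relay and decay interactions is not imposed: it
emerges from the drawn parameters, so the retained ensemble spans circuits
driven mainly by repressor decay, mainly by activator relay, and mixtures.

Regulation thresholds are sampled as a fraction (1-10% by default) of the
source TTF's maximal level, reflecting the estimate that Pdm starts
expressing when Hb has decayed to 1-10% of its peak.

Determinism: every draw has its own seed substream derived from
``(seed, draw_index)``, so the sampled ensemble is independent of chunking
and draw order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import config as _config
from .circuit import (
    BASAL_TTFS,
    CircuitTopology,
    DEFAULT_CONSTANTS,
    ParameterSet,
    StructuralConstants,
    _Batch,
    build_default_topology,
    integrate_batch,
    param_columns,
)
from .errors import ValidationError
from .phenotype import PhenotypeTable, on_intervals, phases_from_levels

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _check_bounds(name: str, lo: float, hi: float) -> None:
    if lo <= 0 or hi <= 0:
        raise ValidationError(f"{name}: bounds must be strictly positive, got ({lo}, {hi})")
    if hi < lo:
        raise ValidationError(f"{name}: high bound below low bound ({lo}, {hi})")


@dataclass(frozen=True)
class ParameterRanges:
    """Per-parameter (low, high) sampling bounds, all strictly positive.

    Thresholds are sampled either as a fraction of the source TTF's maximal
    level (``threshold_fraction``) or directly (``threshold_absolute``);
    exactly one of the two must cover each threshold-bearing interaction.
    A range collapsed to a point (low == high) always returns that value.
    """

    production: Mapping[str, tuple[float, float]]
    basal: Mapping[str, tuple[float, float]]
    degradation: Mapping[str, tuple[float, float]]
    threshold_fraction: Mapping[str, tuple[float, float]] | None = None
    threshold_absolute: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self):
        for group_name, group in (
            ("production", self.production),
            ("basal", self.basal),
            ("degradation", self.degradation),
            ("threshold_fraction", self.threshold_fraction or {}),
            ("threshold_absolute", self.threshold_absolute or {}),
        ):
            for key, (lo, hi) in group.items():
                _check_bounds(f"{group_name}[{key}]", lo, hi)

    @classmethod
    def defaults(cls, topology: CircuitTopology | None = None) -> "ParameterRanges":
        """The packaged reconstructed default ranges."""
        return cls.from_config(_config.load_ranges_config(), topology)

    @classmethod
    def from_config(cls, raw: Mapping, topology: CircuitTopology | None = None) -> "ParameterRanges":
        topo = topology or build_default_topology()
        prod = tuple(raw["production"])
        basal = tuple(raw.get("basal", raw["production"]))
        degr = tuple(raw["degradation"])
        frac = tuple(raw["threshold_fraction"])
        return cls(
            production={t: prod for t in topo.ttfs},
            basal={t: basal for t in BASAL_TTFS},
            degradation={t: degr for t in topo.ttfs},
            threshold_fraction={key: frac for key in topo.threshold_keys},
        )

    @classmethod
    def from_parameter_set(
        cls, params: ParameterSet, topology: CircuitTopology | None = None
    ) -> "ParameterRanges":
        """Ranges collapsed onto one reference circuit (every draw returns it)."""
        topo = topology or build_default_topology()
        return cls(
            production={t: (params.beta[t], params.beta[t]) for t in topo.ttfs},
            basal={t: (params.beta0[t], params.beta0[t]) for t in BASAL_TTFS},
            degradation={t: (params.alpha[t], params.alpha[t]) for t in topo.ttfs},
            threshold_absolute={
                key: (params.thresholds[key], params.thresholds[key])
                for key in topo.threshold_keys
            },
        )


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:
        return lo
    return float(np.exp(rng.uniform(math.log(lo), math.log(hi))))


def sample_parameter_set(
    ranges: ParameterRanges,
    rng: np.random.Generator,
    topology: CircuitTopology | None = None,
    constants: StructuralConstants = DEFAULT_CONSTANTS,
    params_id: str | None = None,
) -> ParameterSet:
    """Draw one candidate circuit, every free parameter log-uniform in its range."""
    topo = topology or build_default_topology()
    beta = {t: _log_uniform(rng, *ranges.production[t]) for t in topo.ttfs}
    beta0 = {t: _log_uniform(rng, *ranges.basal[t]) for t in BASAL_TTFS}
    alpha = {t: _log_uniform(rng, *ranges.degradation[t]) for t in topo.ttfs}
    thresholds: dict[str, float] = {}
    for key in topo.threshold_keys:
        if ranges.threshold_absolute and key in ranges.threshold_absolute:
            thresholds[key] = _log_uniform(rng, *ranges.threshold_absolute[key])
        elif ranges.threshold_fraction and key in ranges.threshold_fraction:
            source = topo.interaction(key).source
            max_level = (beta[source] + beta0.get(source, 0.0)) / alpha[source]
            thresholds[key] = _log_uniform(rng, *ranges.threshold_fraction[key]) * max_level
        else:
            raise ValidationError(f"no sampling range for threshold {key!r}")
    ps = ParameterSet(beta, beta0, alpha, thresholds, constants, params_id)
    ps.validate_strict(topo)
    return ps


def _draw_rng(seed: int, draw: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(draw,)))


# ---------------------------------------------------------------------------
# levels -> sequences / induction
# ---------------------------------------------------------------------------

def sequence_of(
    levels: np.ndarray,
    times: np.ndarray,
    thresholds: np.ndarray,
    ttfs: Sequence[str],
    min_phase: float,
) -> tuple[frozenset, ...]:
    """Ordered non-empty on-sets of one simulated circuit."""
    seq = phases_from_levels(levels, times, thresholds, ttfs, min_phase)
    return tuple(seq.on_sets(ignore_empty=True))


def induction_time_of(
    level: np.ndarray, times: np.ndarray, threshold: float, sustain: float
) -> float:
    """Earliest upcrossing sustained for >= ``sustain`` minutes; NaN if none."""
    for t_on, t_off in on_intervals(level, times, threshold):
        if t_off - t_on >= sustain:
            return t_on
    return math.nan


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------

def run_screen(
    n_circuits: int,
    ranges: ParameterRanges | None = None,
    topology: CircuitTopology | None = None,
    phenotype_table: PhenotypeTable | None = None,
    seed: int = 0,
    constants: StructuralConstants = DEFAULT_CONSTANTS,
    out: str | Path | None = None,
    chunk_size: int = 4000,
) -> pd.DataFrame:
    """Screen ``n_circuits`` random circuits for phenotype consistency.

    Returns one record per circuit: the 17 sampled parameters, the
    consistency flag (with the first failing genotype on mismatch) and the
    wild-type induction time of each TTF (NaN encodes NOT_INDUCED).  With
    ``out`` the records are streamed chunk-wise to CSV, keeping memory
    bounded by ``chunk_size``.  Fully reproducible from ``seed`` regardless
    of chunking.
    """
    if n_circuits < 0:
        raise ValidationError("n_circuits must be >= 0")
    topo = topology or build_default_topology()
    ranges = ranges or ParameterRanges.defaults(topo)
    table = phenotype_table or _config.load_phenotype_table()
    cols = param_columns(topo)

    expected = {g.name: tuple(g.expected) for g in table}
    mutants = [g for g in table if g.name != "wt"]

    chunks: list[pd.DataFrame] = []
    first_write = True
    for lo in range(0, n_circuits, chunk_size):
        hi = min(lo + chunk_size, n_circuits)
        draws = range(lo, hi)
        sets = [
            sample_parameter_set(ranges, _draw_rng(seed, d), topo, constants, f"s{seed}-d{d}")
            for d in draws
        ]
        chunk = _screen_chunk(sets, topo, table, expected, mutants, constants)
        chunk.insert(0, "draw", list(draws))
        chunk.insert(1, "params_id", [f"s{seed}-d{d}" for d in draws])
        if out is not None:
            mode, header = ("w", True) if first_write else ("a", False)
            chunk.to_csv(out, index=False, mode=mode, header=header)
            first_write = False
        chunks.append(chunk)
        log.info(
            "screened %d/%d circuits (%d consistent so far)",
            hi, n_circuits, int(sum(c["consistent"].sum() for c in chunks)),
        )
    if not chunks:
        df = pd.DataFrame(
            columns=["draw", "params_id", *cols, "consistent", "failed",
                     "fail_genotype", *[f"t_wt_{t}" for t in topo.ttfs]]
        )
        if out is not None:
            df.to_csv(out, index=False)
        return df
    return pd.concat(chunks, ignore_index=True)


def _screen_chunk(sets, topo, table, expected, mutants, constants) -> pd.DataFrame:
    n = len(sets)
    batch = _Batch.from_parameter_sets(sets, topo)
    on_thr = batch.on_thresholds(constants)
    times, levels, failed = integrate_batch(
        batch, topo, constants, record="levels", return_failed=True
    )

    fail_genotype = np.array([None] * n, dtype=object)
    consistent = np.zeros(n, dtype=bool)

    alive = np.zeros(n, dtype=bool)
    for i in range(n):
        if failed[i]:
            continue
        seq = sequence_of(levels[i], times, on_thr[i], topo.ttfs, constants.min_phase)
        if seq == expected["wt"]:
            alive[i] = True
        else:
            fail_genotype[i] = "wt"

    # wild-type induction times for every record
    t_wt = np.full((n, len(topo.ttfs)), np.nan)
    for j in range(len(topo.ttfs)):
        for i in range(n):
            if not failed[i]:
                t_wt[i, j] = induction_time_of(
                    levels[i, :, j], times, on_thr[i, j], constants.sustain
                )

    for spec in mutants:
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        sub, sub_topo = batch.select(idx).perturbed(topo, spec.perturbation)
        _, sub_levels, sub_failed = integrate_batch(
            sub, sub_topo, constants, record="levels", return_failed=True
        )
        for k, i in enumerate(idx):
            if sub_failed[k]:
                failed[i] = True
                alive[i] = False
                continue
            seq = sequence_of(
                sub_levels[k], times, on_thr[i], topo.ttfs, constants.min_phase
            )
            if seq != expected[spec.name]:
                alive[i] = False
                fail_genotype[i] = spec.name
    consistent[:] = alive

    frame = pd.DataFrame([p.to_row(topo) for p in sets])
    frame["consistent"] = consistent
    frame["failed"] = failed
    frame["fail_genotype"] = fail_genotype
    for j, ttf in enumerate(topo.ttfs):
        frame[f"t_wt_{ttf}"] = t_wt[:, j]
    return frame
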