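"""Statistics for staged per-neuroblast staining measurements.

The experimental readout is the log intensity ratio of a TTF stain to the
constitutively expressed Engrailed stain (controlling staining variability)
in identified NB7-1 cells, grouped by embryonic stage.  This module contains
the measurement-side half of the positioning procedure:

* volume-based outlier filtering (cells further than 2 SD from the mean
  wild-type nuclear volume are presumed dividing or misidentified),
* per-stage summaries (n, mean, SD, SEM, 1.96*SEM confidence half-width),
* induction-stage calling against a wild-type background level,
* measured induction-time shifts with worst-case error intervals, and
* translation of measured TTF-deletion shifts into link-removal shift
  ranges via the screened ensemble, yielding the in-vivo position in
  Decay-Relay space with error bars.

Stage labels are mapped to minutes on the cascade clock by a configurable
:class:`StageTable`; measured induction times are taken as the midpoint of
the called stage with half the stage duration as error margin.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

log = logging.getLogger(__name__)

DEFAULT_STAGES = ("S9", "S10E", "S10", "S11E", "S11", "S12")
#: Stages averaged to define the wild-type background expression level.
BACKGROUND_STAGES = ("S10E", "S10")


@dataclass(frozen=True)
class StageTable:
    """Ordered mapping stage label -> (start, end) minutes on the cascade clock."""

    entries: tuple[tuple[str, float, float], ...]

    def __post_init__(self):
        prev_end = None
        for name, lo, hi in self.entries:
            if hi <= lo:
                raise ValidationError(f"stage {name}: end must exceed start")
            if prev_end is not None and not math.isclose(lo, prev_end):
                raise ValidationError(f"stage {name}: stages must be contiguous")
            prev_end = hi

    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.entries)

    def span(self, stage: str) -> tuple[float, float]:
        for name, lo, hi in self.entries:
            if name == stage:
                return lo, hi
        raise ValidationError(f"unknown stage {stage!r}")

    def midpoint(self, stage: str) -> float:
        lo, hi = self.span(stage)
        return (lo + hi) / 2.0

    def half_duration(self, stage: str) -> float:
        lo, hi = self.span(stage)
        return (hi - lo) / 2.0

    def stage_of(self, t: float) -> str | None:
        """Stage containing minute ``t``; None outside the table."""
        for name, lo, hi in self.entries:
            if lo <= t < hi or (hi == self.entries[-1][2] and math.isclose(t, hi)):
                return name
        return None

    @property
    def table_hash(self) -> str:
        """Short provenance hash carried by stage-dependent outputs."""
        return hashlib.sha1(repr(self.entries).encode()).hexdigest()[:10]


@dataclass(frozen=True)
class StageSummary:
    """Per-stage summary of normalized staining intensities."""

    stage: str
    n: int
    mean: float
    sd: float

    @property
    def sem(self) -> float:
        return self.sd / math.sqrt(self.n)

    @property
    def ci_half(self) -> float:
        """Half-width of the 95% confidence interval, 1.96 * SEM."""
        return 1.96 * self.sem


# ---------------------------------------------------------------------------
# filtering and summaries
# ---------------------------------------------------------------------------

def filter_by_volume(
    measurements: pd.DataFrame,
    n_sd: float = 2.0,
    reference_genotype: str = "wt",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop cells whose nuclear volume is an outlier.

    Mean and SD are computed over the wild-type population (falling back to
    all rows if no wild-type rows exist); any measurement further than
    ``n_sd`` standard deviations from that mean, above or below, is excluded
    (assumed to be a currently dividing or misidentified cell).  Returns
    ``(kept, excluded)``; with fewer than 3 reference rows the filter is the
    identity (logged).
    """
    ref = measurements[measurements["genotype"] == reference_genotype]
    if len(ref) == 0:
        ref = measurements
    if len(ref) < 3:
        log.info("volume filter skipped: only %d reference measurements", len(ref))
        return measurements.copy(), measurements.iloc[0:0].copy()
    mean = ref["volume"].mean()
    sd = ref["volume"].std(ddof=1)
    if sd == 0:
        return measurements.copy(), measurements.iloc[0:0].copy()
    dev = (measurements["volume"] - mean).abs()
    keep = dev <= n_sd * sd
    excluded = measurements.loc[~keep].copy()
    if len(excluded):
        log.info(
            "volume filter removed %d/%d cells (>%.1f SD from WT mean volume)",
            len(excluded), len(measurements), n_sd,
        )
    return measurements.loc[keep].copy(), excluded


def stage_summaries(
    measurements: pd.DataFrame,
    value_col: str = "log_ratio",
) -> pd.DataFrame:
    """Per (genotype, ttf, stage) summary: n, mean, sd, sem, ci_half."""
    grouped = measurements.groupby(["genotype", "ttf", "stage"], sort=False)[value_col]
    summary = grouped.agg(n="count", mean="mean", sd="std").reset_index()
    summary["sd"] = summary["sd"].fillna(0.0)
    summary["sem"] = summary["sd"] / np.sqrt(summary["n"])
    summary["ci_half"] = 1.96 * summary["sem"]
    return summary


def _stage_series(summary: pd.DataFrame, genotype: str, ttf: str) -> pd.DataFrame:
    sel = summary[(summary["genotype"] == genotype) & (summary["ttf"] == ttf)]
    return sel.set_index("stage")


# ---------------------------------------------------------------------------
# induction-stage calling
# ---------------------------------------------------------------------------

def call_induction_stage(
    summaries: pd.DataFrame,
    wt_summaries: pd.DataFrame,
    genotype: str,
    ttf: str,
    stage_order: Sequence[str] = DEFAULT_STAGES,
    background_stages: Sequence[str] = BACKGROUND_STAGES,
    skip_stages: Sequence[str] = ("S9",),
) -> str | None:
    """Call the stage at which a TTF is induced, or None.

    The background is the mean of the wild-type stage means at the second
    and third stages (S10E and S10).  Scanning stages in order -- skipping
    S9, which can show an early transient induction -- the induction stage
    is the first whose mean minus 1.96*SEM exceeds the background; None if
    no stage qualifies.  The caller is invariant under adding a constant to
    every log-ratio, since the background shifts equally.
    """
    wt = _stage_series(wt_summaries, "wt", ttf)
    missing = [s for s in background_stages if s not in wt.index]
    if missing:
        raise ValidationError(f"wild-type summaries missing background stages {missing}")
    background = float(np.mean([wt.loc[s, "mean"] for s in background_stages]))
    series = _stage_series(summaries, genotype, ttf)
    for stage in stage_order:
        if stage in skip_stages or stage not in series.index:
            continue
        row = series.loc[stage]
        if row["mean"] - 1.96 * row["sem"] > background:
            return stage
    return None


# ---------------------------------------------------------------------------
# measured shifts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasuredShift:
    """Measured percent induction shift with a worst-case error interval."""

    delta_pct: float
    lo: float
    hi: float
    t_wt: float
    t_mut: float
    stage_table_hash: str = ""

    @property
    def half_range(self) -> float:
        return (self.hi - self.lo) / 2.0


def measured_delta_t(
    stage_wt: str,
    stage_mut: str,
    stage_table: StageTable,
    censored_left: bool = False,
) -> MeasuredShift:
    """Induction shift implied by the called wild-type and mutant stages.

    Induction times are taken as stage midpoints, each with half the stage
    duration as error margin; the percent-shift interval is the min/max of
    the shift over the two midpoint intervals (worst-case interval
    arithmetic, since the margins are resolution limits, not a noise
    distribution).

    ``censored_left`` handles a mutant already induced at the earliest
    scannable stage: the data then only upper-bound the onset (induction may
    have occurred any time from t = 0, including during the skipped first
    stage), so the mutant interval is extended down to zero and the shift
    interval down to -100%.
    """
    if stage_wt is None or stage_mut is None:
        raise ValidationError("both induction stages must be called before computing a shift")
    t_wt = stage_table.midpoint(stage_wt)
    t_mut = stage_table.midpoint(stage_mut)
    h_wt = stage_table.half_duration(stage_wt)
    h_mut = stage_table.half_duration(stage_mut)
    delta = 100.0 * (t_mut - t_wt) / t_wt
    mut_lo = 0.0 if censored_left else t_mut - h_mut
    corners = [
        100.0 * (tm - tw) / tw
        for tm in (mut_lo, t_mut + h_mut)
        for tw in (max(t_wt - h_wt, 1e-9), t_wt + h_wt)
    ]
    return MeasuredShift(
        delta, min(corners), max(corners), t_wt, t_mut, stage_table.table_hash
    )


def translate_deletion_to_link_range(
    scored_records: pd.DataFrame,
    measured_range: tuple[float, float],
    pair: str,
    robust_cutoff: float = 80.0,
) -> tuple[float, float]:
    """Translate a measured deletion shift range into a link-removal range.

    Places the measured deletion-shift interval on the deletion vs
    link-removal correlation plot and returns the maximal range of
    link-removal shifts reached by robust circuits (robustness score above
    the cutoff) whose deletion shift lies inside the measured interval.
    Raises if no robust circuit falls in the interval, reporting the nearest
    robust circuit's deletion shift.
    """
    from .decay_relay import CORRELATION_PAIRS

    if pair not in CORRELATION_PAIRS:
        raise ValidationError(f"unknown pair {pair!r}; known: {sorted(CORRELATION_PAIRS)}")
    xcol, ycol = CORRELATION_PAIRS[pair]
    lo, hi = min(measured_range), max(measured_range)
    robust = scored_records[
        (scored_records["robustness_score"] > robust_cutoff)
        & scored_records[xcol].notna()
        & scored_records[ycol].notna()
    ]
    if len(robust) == 0:
        raise ValidationError("no robust records available for translation")
    inside = robust[(robust[xcol] >= lo) & (robust[xcol] <= hi)]
    if len(inside) == 0:
        nearest = robust.iloc[(robust[xcol] - (lo + hi) / 2).abs().argmin()]
        raise ValidationError(
            f"no robust record with {xcol} in [{lo:.1f}, {hi:.1f}]; "
            f"nearest robust record has {xcol} = {nearest[xcol]:.1f}"
        )
    return float(inside[ycol].min()), float(inside[ycol].max())


# ---------------------------------------------------------------------------
# positioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InVivoPosition:
    """Decay/relay significance of the measured circuit with error bars."""

    decay_significance: float
    relay_significance: float
    decay_range: tuple[float, float]
    relay_range: tuple[float, float]
    link_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    stage_table_hash: str = ""

    def to_json(self) -> dict:
        return {
            "decay_significance": self.decay_significance,
            "relay_significance": self.relay_significance,
            "decay_range": list(self.decay_range),
            "relay_range": list(self.relay_range),
            "link_ranges": {k: list(v) for k, v in self.link_ranges.items()},
            "stage_table_hash": self.stage_table_hash,
        }


def invivo_normalizers(
    scored_records: pd.DataFrame,
    stage_table: StageTable,
    wt_stages: Mapping[str, str],
) -> dict[str, float]:
    """Largest experimentally observable |shift| per (TTF, link type).

    Decay removal of Pdm's repressor could at most advance Pdm induction to
    t = 0, i.e. a 100% shift.  Relay removals can at most delay induction to
    the middle of the last observed stage.  Cas decay removal cannot reach
    t = 0 (Hb still represses Cas), so it is normalized by the largest
    simulated shift in the ensemble.
    """
    last = stage_table.stages[-1]
    t_last = stage_table.midpoint(last)
    t_wt_pdm = stage_table.midpoint(wt_stages["Pdm"])
    t_wt_cas = stage_table.midpoint(wt_stages["Cas"])
    cas_decay = np.abs(scored_records["d_cas_rm_decay"].to_numpy(float))
    cas_decay_max = float(np.nanmax(cas_decay)) if np.isfinite(cas_decay).any() else 100.0
    return {
        "pdm_decay": 100.0,
        "pdm_relay": 100.0 * (t_last - t_wt_pdm) / t_wt_pdm,
        "cas_decay": cas_decay_max,
        "cas_relay": 100.0 * (t_last - t_wt_cas) / t_wt_cas,
    }


def _abs_interval(lo: float, hi: float) -> tuple[float, float]:
    if lo <= 0 <= hi:
        return 0.0, max(abs(lo), abs(hi))
    return min(abs(lo), abs(hi)), max(abs(lo), abs(hi))


def position_invivo(
    link_ranges: Mapping[str, tuple[float, float]],
    ensemble_normalizers: Mapping[str, float],
    stage_table: StageTable,
) -> InVivoPosition:
    """Combine per-TTF link-removal shift ranges into a Decay-Relay position.

    Exactly mirrors the simulated significance score: per TTF and link type
    the absolute shift is normalized by the stated maximal observable value
    (clipped to [0, 100]), and the Pdm and Cas contributions are averaged.
    Error bars propagate the range endpoints through the same arithmetic.
    """
    required = ("pdm_decay", "pdm_relay", "cas_decay", "cas_relay")
    for key in required:
        if key not in link_ranges:
            raise ValidationError(f"missing link range {key!r}")
        if key not in ensemble_normalizers:
            raise ValidationError(f"missing normalizer {key!r}")

    def contrib(key: str) -> tuple[float, float, float]:
        lo, hi = link_ranges[key]
        norm = ensemble_normalizers[key]
        if norm <= 0:
            raise ValidationError(f"normalizer {key!r} must be positive")
        a_lo, a_hi = _abs_interval(min(lo, hi), max(lo, hi))
        mid = (lo + hi) / 2.0
        scale = lambda v: min(100.0, 100.0 * v / norm)
        return scale(abs(mid)), scale(a_lo), scale(a_hi)

    pd_d, pd_d_lo, pd_d_hi = contrib("pdm_decay")
    ca_d, ca_d_lo, ca_d_hi = contrib("cas_decay")
    pd_r, pd_r_lo, pd_r_hi = contrib("pdm_relay")
    ca_r, ca_r_lo, ca_r_hi = contrib("cas_relay")
    return InVivoPosition(
        decay_significance=(pd_d + ca_d) / 2.0,
        relay_significance=(pd_r + ca_r) / 2.0,
        decay_range=((pd_d_lo + ca_d_lo) / 2.0, (pd_d_hi + ca_d_hi) / 2.0),
        relay_range=((pd_r_lo + ca_r_lo) / 2.0, (pd_r_hi + ca_r_hi) / 2.0),
        link_ranges=dict(link_ranges),
        stage_table_hash=stage_table.table_hash,
    )


def stageable_wild_type(
    t_pdm: float,
    t_cas: float,
    stage_table: StageTable,
    background_stages: Sequence[str] = BACKGROUND_STAGES,
    skip_stages: Sequence[str] = ("S9",),
) -> bool:
    """Whether a circuit's WT inductions satisfy the staging protocol's premise.

    The measurement procedure needs the wild-type background stages to
    precede Pdm induction, the induction stages to be callable (not skipped,
    not background), and a WT induction before the last stage so that the
    relay normalizer (largest observable delay) is positive.
    """
    blocked = set(background_stages) | set(skip_stages)
    last = stage_table.stages[-1]
    for t in (t_pdm, t_cas):
        stage = stage_table.stage_of(t)
        if stage is None or stage in blocked or stage == last:
            return False
    return True


#: measured (genotype, TTF) comparison backing each link-removal range.
MEASUREMENT_PAIRS: dict[str, tuple[str, str, str]] = {
    "pdm_decay": ("pdm_hb", "hb_del", "Pdm"),
    "pdm_relay": ("pdm_kr", "kr_del", "Pdm"),
    "cas_decay": ("cas_kr", "kr_del", "Cas"),
    "cas_relay": ("cas_pdm", "pdm_del", "Cas"),
}


def position_from_measurements(
    measurements: pd.DataFrame,
    scored_records: pd.DataFrame,
    stage_table: StageTable,
    robust_cutoff: float = 80.0,
    snap_to_nearest: bool = True,
) -> InVivoPosition:
    """Full measurement-side positioning procedure.

    Filters volume outliers, summarizes staining intensities per stage,
    calls wild-type and mutant induction stages for Pdm and Cas, converts
    the called stages into deletion shift intervals, translates those
    through the robust circuits of the screened ensemble into link-removal
    shift ranges, and combines them into a Decay-Relay position with error
    bars.  Raises if any required induction stage cannot be called.

    With a desk-scale ensemble the robust subset can be sparse enough that a
    measured interval contains no robust circuit at all; with
    ``snap_to_nearest`` (default) the translation then falls back on the
    robust circuit whose deletion shift is closest to the interval (logged),
    instead of failing.
    """
    filtered, _ = filter_by_volume(measurements)
    summary = stage_summaries(filtered)
    wt_summ = summary[summary["genotype"] == "wt"]

    wt_stages: dict[str, str] = {}
    for ttf in ("Pdm", "Cas"):
        stage = call_induction_stage(summary, wt_summ, "wt", ttf, stage_table.stages)
        if stage is None:
            raise ValidationError(f"wild-type {ttf} induction stage could not be called")
        wt_stages[ttf] = stage

    first_scanned = next(s for s in stage_table.stages if s != "S9")
    link_ranges: dict[str, tuple[float, float]] = {}
    for key, (pair, genotype, ttf) in MEASUREMENT_PAIRS.items():
        stage_mut = call_induction_stage(summary, wt_summ, genotype, ttf, stage_table.stages)
        if stage_mut is None:
            raise ValidationError(
                f"{genotype} {ttf} induction stage could not be called; "
                "capped-value handling must be decided by the analyst"
            )
        shift = measured_delta_t(
            wt_stages[ttf], stage_mut, stage_table,
            censored_left=(stage_mut == first_scanned),
        )
        try:
            link_ranges[key] = translate_deletion_to_link_range(
                scored_records, (shift.lo, shift.hi), pair, robust_cutoff
            )
        except ValidationError:
            if not snap_to_nearest:
                raise
            from .decay_relay import CORRELATION_PAIRS

            xcol, ycol = CORRELATION_PAIRS[pair]
            robust = scored_records[
                (scored_records["robustness_score"] > robust_cutoff)
                & scored_records[xcol].notna()
            ]
            if len(robust) == 0:
                raise
            dist = np.maximum(shift.lo - robust[xcol], robust[xcol] - shift.hi).clip(0)
            nearest = robust.iloc[int(np.argmin(dist.to_numpy()))]
            log.info(
                "%s: no robust circuit with %s in [%.1f, %.1f]; snapping to nearest "
                "(%.1f)", pair, xcol, shift.lo, shift.hi, nearest[xcol],
            )
            link_ranges[key] = (float(nearest[ycol]), float(nearest[ycol]))
    normalizers = invivo_normalizers(scored_records, stage_table, wt_stages)
    return position_invivo(link_ranges, normalizers, stage_table)
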