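"""Discretization of trajectories into on-TTF phase sequences and consistency tests.

A simulated circuit is compared with experimental observations at the level of
its *phase sequence*: the ordered list of sets of TTFs that are simultaneously
"on" (above their on-threshold).  Phase durations are deliberately ignored by
the consistency test, because the reference data (expression summaries of
wild-type, mutant and misexpression neuroblast lineages) has low temporal
resolution; only the order of expression/co-expression phases is compared.

Progeny identity bookkeeping: at each asymmetric division the neuroblast
buds off a GMC whose identity is set by the TTFs above the identity threshold
at that instant.  Adjacent phases that map to the same neuronal identity are
merged before scoring robustness -- e.g. an Hb-only phase followed by Hb+Kr
co-expression counts as a single phase because both produce the same early
fates, making the exact timing of Kr induction irrelevant to the lineage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .circuit import Perturbation, StructuralConstants, Trajectory, TTFS
from .errors import ValidationError

#: Sentinel identity for divisions at which no TTF is above threshold.
NO_IDENTITY = "none"


@dataclass(frozen=True)
class Phase:
    """A maximal time interval with a constant set of "on" TTFs."""

    on_set: frozenset[str]
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class PhaseSequence:
    """Contiguous, non-overlapping phases covering a trajectory."""

    phases: tuple[Phase, ...]

    def __post_init__(self):
        prev = None
        for ph in self.phases:
            if ph.start >= ph.end:
                raise ValidationError(f"phase has start >= end: {ph}")
            if prev is not None:
                if not np.isclose(prev.end, ph.start):
                    raise ValidationError("phases must be contiguous")
                if prev.on_set == ph.on_set:
                    raise ValidationError("adjacent phases must have different on-sets")
            prev = ph

    def on_sets(self, ignore_empty: bool = True) -> list[frozenset[str]]:
        """Ordered on-sets; empty sets (no TTF on) are dropped by default."""
        return [p.on_set for p in self.phases if p.on_set or not ignore_empty]

    def __len__(self) -> int:
        return len(self.phases)

    def __iter__(self):
        return iter(self.phases)


# ---------------------------------------------------------------------------
# phases from trajectories
# ---------------------------------------------------------------------------

def _runs_from_codes(codes: np.ndarray, times: np.ndarray) -> list[list]:
    """Maximal constant-code runs as mutable [code, start, end] triples."""
    codes = np.asarray(codes)
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(codes)]))
    # a run covering samples [i, j) spans time [t_i, t_j] on the grid: the
    # level holds its code up to the first sample of the next run
    runs = []
    for i, j in zip(starts, ends):
        end_t = times[j] if j < len(codes) else times[-1]
        runs.append([int(codes[i]), float(times[i]), float(end_t)])
    return runs


def _merge_short_runs(runs: list[list], min_phase: float) -> list[list]:
    """Absorb sub-``min_phase`` runs into the preceding run (grid-artifact guard).

    The first run, having no predecessor, is absorbed into its successor.
    Adjacent runs left with equal codes are coalesced.
    """
    runs = [list(r) for r in runs]
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for i, run in enumerate(runs):
            if run[2] - run[1] >= min_phase:
                continue
            if i > 0:
                runs[i - 1][2] = run[2]
            else:
                runs[1][1] = run[1]
            del runs[i]
            changed = True
            break
        # coalesce equal neighbors
        i = 0
        while i < len(runs) - 1:
            if runs[i][0] == runs[i + 1][0]:
                runs[i][2] = runs[i + 1][2]
                del runs[i + 1]
            else:
                i += 1
    return runs


def on_intervals(
    level: np.ndarray,
    times: np.ndarray,
    threshold: float,
) -> list[tuple[float, float]]:
    """Maximal intervals where ``level >= threshold``, with interpolated edges.

    Crossing times between grid samples are located by linear interpolation,
    so interval boundaries (hence phase durations) are not quantized to the
    output grid.  A level exactly at the threshold counts as on.
    """
    on = level >= threshold
    if not on.any():
        return []
    edges = np.diff(np.concatenate(([0], on.astype(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)  # first on-sample of each run
    ends = np.flatnonzero(edges == -1) - 1  # last on-sample of each run

    def cross(i_prev: int, i_next: int) -> float:
        x0, x1 = level[i_prev], level[i_next]
        if x1 == x0:
            return float(times[i_next])
        frac = (threshold - x0) / (x1 - x0)
        return float(times[i_prev] + frac * (times[i_next] - times[i_prev]))

    intervals = []
    for s, e in zip(starts, ends):
        t_on = float(times[0]) if s == 0 else cross(s - 1, s)
        t_off = float(times[-1]) if e == len(on) - 1 else cross(e, e + 1)
        if t_off > t_on:
            intervals.append((t_on, t_off))
    return intervals


def phases_from_levels(
    levels: np.ndarray,
    times: np.ndarray,
    thresholds: np.ndarray,
    ttfs: Sequence[str] = TTFS,
    min_phase: float = 2.0,
) -> PhaseSequence:
    """Phase sequence of a levels array (n_t, n_ttf) with interpolated boundaries."""
    if levels.shape[0] == 0:
        raise ValidationError("empty trajectory")
    per_ttf = [on_intervals(levels[:, j], times, thresholds[j]) for j in range(len(ttfs))]
    bounds = {float(times[0]), float(times[-1])}
    for intervals in per_ttf:
        for t_on, t_off in intervals:
            bounds.add(t_on)
            bounds.add(t_off)
    cuts = sorted(bounds)
    runs: list[list] = []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        mid = (lo + hi) / 2.0
        code = 0
        for j, intervals in enumerate(per_ttf):
            if any(a <= mid < b for a, b in intervals):
                code |= 1 << j
        if runs and runs[-1][0] == code:
            runs[-1][2] = hi
        else:
            runs.append([code, lo, hi])
    runs = _merge_short_runs(runs, min_phase)
    phases = tuple(
        Phase(frozenset(t for j, t in enumerate(ttfs) if code >> j & 1), s, e)
        for code, s, e in runs
        if e > s
    )
    return PhaseSequence(phases)


def phases_from_codes(
    codes: np.ndarray,
    times: np.ndarray,
    ttfs: Sequence[str] = TTFS,
    min_phase: float = 2.0,
) -> PhaseSequence:
    """Decode a bitmask time series (bit j = ``ttfs[j]`` on) into phases."""
    if len(codes) == 0:
        raise ValidationError("empty trajectory")
    runs = _merge_short_runs(_runs_from_codes(codes, times), min_phase)
    phases = tuple(
        Phase(frozenset(t for j, t in enumerate(ttfs) if code >> j & 1), s, e)
        for code, s, e in runs
        if e > s
    )
    return PhaseSequence(phases)


def trajectory_to_phases(
    traj: Trajectory,
    on_thresholds: Mapping[str, float],
    min_phase: float = 2.0,
) -> PhaseSequence:
    """Call "on" phases of a trajectory.

    A TTF is on wherever its level is at or above its threshold (ties count
    as on).  Phases shorter than ``min_phase`` minutes are merged into the
    preceding phase to suppress grid artifacts.
    """
    if traj.levels.shape[0] == 0:
        raise ValidationError("empty trajectory")
    for ttf in traj.ttfs:
        if on_thresholds.get(ttf, 0.0) <= 0:
            raise ValidationError(f"on_threshold[{ttf}] must be positive")
    thr = np.array([on_thresholds[t] for t in traj.ttfs])
    return phases_from_levels(traj.levels, traj.times, thr, traj.ttfs, min_phase)


# ---------------------------------------------------------------------------
# identities
# ---------------------------------------------------------------------------

def _set_key(on_set: Iterable[str]) -> str:
    """Canonical text key for an on-set, e.g. ``"Hb+Kr"`` (TTF order)."""
    members = set(on_set)
    return "+".join(t for t in TTFS if t in members) or ""


@dataclass(frozen=True)
class IdentityMap:
    """Maps on-sets to neuronal identity labels.

    ``mapping`` is keyed by canonical set keys (``"Hb"``, ``"Hb+Kr"`` ...).
    With ``strict`` identity lookup, an unmapped on-set raises; otherwise the
    canonical set key itself is used as the label, which keeps distinct
    unexpected co-expression states distinct.
    """

    mapping: Mapping[str, str]

    def identity(self, on_set: Iterable[str], strict: bool = True) -> str:
        key = _set_key(on_set)
        if key in self.mapping:
            return self.mapping[key]
        if key == "":
            return NO_IDENTITY
        if strict:
            raise ValidationError(f"no identity mapped for on-set {{{key}}}")
        return key


@dataclass(frozen=True)
class IdentityPhase:
    """A phase after identity merging; ``on_set`` is the first constituent's."""

    identity: str
    on_set: frozenset[str]
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


def merge_identity_phases(
    seq: PhaseSequence | Sequence[Phase],
    identity_map: IdentityMap,
    strict: bool = True,
) -> tuple[IdentityPhase, ...]:
    """Merge adjacent phases that lead to the same neuronal identity.

    Durations are summed; the operation is idempotent.  With ``strict``
    (default) an on-set missing from the identity map raises a
    :class:`ValidationError` naming the set.
    """
    phases = list(seq.phases if isinstance(seq, PhaseSequence) else seq)
    merged: list[IdentityPhase] = []
    for ph in phases:
        label = identity_map.identity(ph.on_set, strict=strict)
        if merged and merged[-1].identity == label:
            prev = merged[-1]
            merged[-1] = IdentityPhase(label, prev.on_set, prev.start, ph.end)
        else:
            merged.append(IdentityPhase(label, ph.on_set, ph.start, ph.end))
    return tuple(merged)


def progeny_identities(
    traj: Trajectory,
    division_times: Sequence[float] | None,
    identity_map: IdentityMap,
    identity_thresholds: Mapping[str, float],
    constants: StructuralConstants | None = None,
) -> list[str]:
    """Identity of the GMC budded off at each division time.

    The identity is determined by the set of TTFs whose (linearly
    interpolated) level is at or above the identity threshold at the instant
    of division; an empty set records the explicit ``"none"`` identity.
    With ``division_times=None``, divisions are placed every
    ``constants.division_period`` minutes starting one period in.
    """
    horizon = float(traj.times[-1])
    if division_times is None:
        period = (constants or StructuralConstants()).division_period
        division_times = np.arange(period, horizon + 1e-9, period)
    identities = []
    for t in division_times:
        if not 0 <= t <= horizon:
            raise ValidationError(f"division time {t} outside [0, {horizon}]")
        levels = np.array(
            [np.interp(t, traj.times, traj.level(ttf)) for ttf in traj.ttfs]
        )
        thr = np.array([identity_thresholds[ttf] for ttf in traj.ttfs])
        on = {ttf for ttf, lv, th in zip(traj.ttfs, levels, thr) if lv >= th}
        identities.append(identity_map.identity(on) if on else NO_IDENTITY)
    return identities


# ---------------------------------------------------------------------------
# phenotype tables and consistency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeSpec:
    """One genotype: the perturbation producing it and its expected sequence."""

    name: str
    perturbation: Perturbation
    expected: tuple[frozenset[str], ...]


@dataclass(frozen=True)
class PhenotypeTable:
    """Expected on-set sequences per genotype (wild type plus perturbations)."""

    genotypes: tuple[GenotypeSpec, ...]

    def __post_init__(self):
        names = [g.name for g in self.genotypes]
        if "wt" not in names:
            raise ValidationError("phenotype table must contain a 'wt' entry")
        if len(set(names)) != len(names):
            raise ValidationError("duplicate genotype names in phenotype table")
        for g in self.genotypes:
            for on_set in g.expected:
                unknown = set(on_set) - set(TTFS)
                if unknown:
                    raise ValidationError(f"{g.name}: unknown TTFs {sorted(unknown)}")

    def __iter__(self):
        return iter(self.genotypes)

    def __getitem__(self, name: str) -> GenotypeSpec:
        for g in self.genotypes:
            if g.name == name:
                return g
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.genotypes]


def phase_sequences_to_frame(seqs: Mapping[str, PhaseSequence]):
    """Export phase sequences as a tidy table.

    Columns: genotype, phase_index, on_set (canonical ``"Hb+Kr"`` key),
    start, end (minutes).
    """
    import pandas as pd

    rows = []
    for genotype, seq in seqs.items():
        for i, ph in enumerate(seq):
            rows.append(
                {
                    "genotype": genotype,
                    "phase_index": i,
                    "on_set": _set_key(ph.on_set),
                    "start": ph.start,
                    "end": ph.end,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConsistencyResult:
    consistent: bool
    genotype: str | None = None  # first failing genotype
    position: int | None = None  # index of the first mismatching phase

    def __bool__(self) -> bool:
        return self.consistent


def _sequences_match(
    observed: Sequence[frozenset[str]], expected: Sequence[frozenset[str]]
) -> int | None:
    """Index of the first mismatch under exact list equality, or None."""
    for i in range(max(len(observed), len(expected))):
        if i >= len(observed) or i >= len(expected) or observed[i] != expected[i]:
            return i
    return None


def check_consistency(
    phase_seqs_by_genotype: Mapping[str, PhaseSequence],
    phenotype_table: PhenotypeTable,
    ignore_empty: bool = True,
) -> ConsistencyResult:
    """Test whether simulated phase sequences reproduce every genotype's phenotype.

    A circuit is consistent iff, for each genotype in the table, the ordered
    list of on-sets equals the expected list exactly (durations are never
    compared).  Phases with an empty on-set are dropped before comparison by
    default, since every simulation starts from zero levels.  Returns the
    first failing genotype and phase position on mismatch; a mismatch is a
    result, not an error.
    """
    for spec in phenotype_table:
        if spec.name not in phase_seqs_by_genotype:
            raise ValidationError(f"missing phase sequence for genotype {spec.name!r}")
        observed = phase_seqs_by_genotype[spec.name].on_sets(ignore_empty=ignore_empty)
        pos = _sequences_match(observed, spec.expected)
        if pos is not None:
            return ConsistencyResult(False, spec.name, pos)
    return ConsistencyResult(True)
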