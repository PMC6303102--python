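"""Positioning circuits in Decay-Relay timer space.

The last two TTFs of the cascade, Pdm and Cas, each receive both an
activator-relay input (Kr->Pdm, Pdm->Cas) and a repressor-decay input
(Hb-|Pdm, Kr-|Cas).  How much a circuit's Pdm/Cas induction times shift when
one of these links is specifically removed measures how strongly that link
drives the timer.  Normalizing the absolute shifts by the largest shift seen
across the whole ensemble (per TTF and link type) and averaging the Pdm and
Cas contributions yields a *decay significance* and *relay significance*
coordinate in [0, 100] for every consistent circuit.

TTF deletions are the experimentally accessible analogues of link removal;
this module also computes deletion-induced shifts (the Hb-Kr sensitivity
coordinates of Pdm induction) and the deletion-vs-link-removal correlations
that justify reading link strengths off mutant phenotypes.  Kr induction is
never scored: in vivo it is driven by an input external to the cascade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats as _stats

from .circuit import (
    CircuitTopology,
    DEFAULT_CONSTANTS,
    Perturbation,
    StructuralConstants,
    Trajectory,
    _Batch,
    build_default_topology,
    integrate_batch,
)
from .errors import ValidationError
from .screen import induction_time_of


class _NotInduced:
    """Sentinel: the TTF never shows a sustained upcrossing before the horizon."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "NOT_INDUCED"

    def __bool__(self):
        return False


NOT_INDUCED = _NotInduced()


#: The link-removal and deletion perturbations whose induction shifts are
#: scored, keyed by record column suffix.  For Cas decay only the immediate
#: repressor Kr is removed; the Hb-|Cas repression stays intact because Hb
#: has normally decayed by the time Cas is induced.
SHIFT_PERTURBATIONS: dict[str, tuple[str, Perturbation]] = {
    "pdm_rm_decay": ("Pdm", Perturbation.remove_link("Hb-|Pdm")),
    "pdm_rm_relay": ("Pdm", Perturbation.remove_link("Kr->Pdm")),
    "cas_rm_decay": ("Cas", Perturbation.remove_link("Kr-|Cas")),
    "cas_rm_relay": ("Cas", Perturbation.remove_link("Pdm->Cas")),
    "pdm_del_hb": ("Pdm", Perturbation.deletion("Hb")),
    "pdm_del_kr": ("Pdm", Perturbation.deletion("Kr")),
    "cas_del_kr": ("Cas", Perturbation.deletion("Kr")),
    "cas_del_pdm": ("Cas", Perturbation.deletion("Pdm")),
}

#: Deletion / link-removal column pairs for the correlation analysis.
CORRELATION_PAIRS: dict[str, tuple[str, str]] = {
    "pdm_hb": ("d_pdm_del_hb", "d_pdm_rm_decay"),
    "pdm_kr": ("d_pdm_del_kr", "d_pdm_rm_relay"),
    "cas_kr": ("d_cas_del_kr", "d_cas_rm_decay"),
    "cas_pdm": ("d_cas_del_pdm", "d_cas_rm_relay"),
}


# ---------------------------------------------------------------------------
# induction times and shifts
# ---------------------------------------------------------------------------

def induction_time(
    traj: Trajectory,
    ttf: str,
    on_threshold: float,
    sustain: float = 10.0,
):
    """Earliest sustained upcrossing of ``on_threshold``, in minutes.

    The level must stay at or above the threshold for at least ``sustain``
    minutes after the crossing; shorter excursions (early transient bursts)
    are ignored.  Returns :data:`NOT_INDUCED` if no such crossing occurs
    before the horizon.
    """
    t = induction_time_of(traj.level(ttf), traj.times, on_threshold, sustain)
    return NOT_INDUCED if math.isnan(t) else t


@dataclass(frozen=True)
class InductionShift:
    """Signed percent change of an induction time under a perturbation."""

    ttf: str
    perturbation: str
    delta_pct: float
    capped: bool = False


def delta_t_ind(t_pert, t_wt, horizon: float | None = None) -> float:
    """Percent induction-time shift 100 * (t_pert - t_wt) / t_wt.

    A perturbed TTF that is never induced is capped at the horizon (the
    caller should track the cap flag separately); a wild type that is never
    induced is an error -- such a circuit cannot have been consistent.
    """
    if t_wt is NOT_INDUCED or (isinstance(t_wt, float) and math.isnan(t_wt)):
        raise ValidationError("wild-type induction time is NOT_INDUCED; circuit inconsistent")
    if t_wt <= 0:
        raise ValidationError("wild-type induction time must be positive")
    if t_pert is NOT_INDUCED or (isinstance(t_pert, float) and math.isnan(t_pert)):
        if horizon is None:
            raise ValidationError("capping a NOT_INDUCED shift requires the horizon")
        t_pert = horizon
    return 100.0 * (t_pert - t_wt) / t_wt


def compute_perturbation_shifts(
    records: pd.DataFrame,
    topology: CircuitTopology | None = None,
    constants: StructuralConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Simulate all scored perturbations and add induction/shift columns.

    For every consistent record and every perturbation in
    :data:`SHIFT_PERTURBATIONS`, adds ``t_<name>`` (perturbed induction time,
    minutes; NaN = never induced), ``d_<name>`` (signed percent shift, capped
    at the horizon when never induced) and ``capped_<name>``.  Thresholds are
    always the unperturbed circuit's on-thresholds.
    """
    topo = topology or build_default_topology()
    out = records.copy()
    mask = out["consistent"].to_numpy(bool) if "consistent" in out else np.ones(len(out), bool)
    idx = np.flatnonzero(mask)
    sub_records = out.iloc[idx]
    batch = _Batch.from_dataframe(sub_records, topo)
    on_thr = batch.on_thresholds(constants)

    for name, (ttf, pert) in SHIFT_PERTURBATIONS.items():
        out[f"t_{name}"] = np.nan
        out[f"d_{name}"] = np.nan
        out[f"capped_{name}"] = False
        if idx.size == 0:
            continue
        pb, ptopo = batch.perturbed(topo, pert)
        times, levels, failed = integrate_batch(
            pb, ptopo, constants, record="levels", return_failed=True
        )
        j = topo.index(ttf)
        t_pert = np.array(
            [induction_time_of(levels[k, :, j], times, on_thr[k, j], constants.sustain)
             for k in range(len(idx))]
        )
        t_wt = sub_records[f"t_wt_{ttf}"].to_numpy(float)
        capped = np.isnan(t_pert)
        t_eff = np.where(capped, constants.horizon, t_pert)
        delta = 100.0 * (t_eff - t_wt) / t_wt
        delta[failed] = np.nan
        out.loc[out.index[idx], f"t_{name}"] = t_pert
        out.loc[out.index[idx], f"d_{name}"] = delta
        out.loc[out.index[idx], f"capped_{name}"] = capped
    return out


# ---------------------------------------------------------------------------
# significance coordinates
# ---------------------------------------------------------------------------

def significance_scores(
    records: pd.DataFrame,
    exclude_capped: bool = False,
) -> pd.DataFrame:
    """Decay/relay significance coordinates in [0, 100] for each record.

    Per TTF and link type, the absolute percent shift is normalized to the
    maximal absolute shift observed across the ensemble (so the largest
    shift maps to 100 exactly), then the Pdm and Cas contributions are
    averaged.  Shift signs are kept in the raw ``d_*`` columns.  With
    ``exclude_capped`` records whose shift was capped at the horizon are
    dropped first.
    """
    if len(records) == 0:
        raise ValidationError("significance_scores requires at least one record")
    out = records.copy()
    if exclude_capped:
        capped_cols = [c for c in out.columns if c.startswith("capped_") and "rm" in c]
        keep = ~out[capped_cols].any(axis=1)
        out = out.loc[keep].copy()
        if len(out) == 0:
            raise ValidationError("all records capped; nothing to score")
    norms: dict[str, np.ndarray] = {}
    for name in ("pdm_rm_decay", "pdm_rm_relay", "cas_rm_decay", "cas_rm_relay"):
        shift = np.abs(out[f"d_{name}"].to_numpy(float))
        top = np.nanmax(shift) if np.isfinite(shift).any() else 0.0
        norms[name] = 100.0 * shift / top if top > 0 else np.zeros_like(shift)
        out[f"n_{name}"] = norms[name]
    out["decay_significance"] = (norms["pdm_rm_decay"] + norms["cas_rm_decay"]) / 2.0
    out["relay_significance"] = (norms["pdm_rm_relay"] + norms["cas_rm_relay"]) / 2.0
    return out


def deletion_sensitivity(records: pd.DataFrame) -> pd.DataFrame:
    """Hb/Kr deletion sensitivity of Pdm induction (signed percent shifts)."""
    out = records.copy()
    out["hb_deletion_shift"] = out["d_pdm_del_hb"]
    out["kr_deletion_shift"] = out["d_pdm_del_kr"]
    return out


def classify_regime(
    decay: np.ndarray | pd.Series,
    relay: np.ndarray | pd.Series,
    band: float = 100.0 / 3.0,
) -> np.ndarray:
    """Label circuits decay-dominant / mixed / relay-dominant.

    The Decay-Relay plane is split by the signed difference
    ``decay_significance - relay_significance``: above ``+band`` is the
    decay-dominant third, below ``-band`` the relay-dominant third.
    """
    diff = np.asarray(decay, float) - np.asarray(relay, float)
    labels = np.where(diff > band, "decay", np.where(diff < -band, "relay", "mixed"))
    return labels


@dataclass(frozen=True)
class CorrelationResult:
    pair: str
    r_all: float
    n_all: int
    r_robust: float
    n_robust: int


def deletion_vs_link_correlation(
    records: pd.DataFrame,
    robust_cutoff: float = 80.0,
    exclude_capped: bool = True,
) -> dict[str, CorrelationResult]:
    """Pearson correlations between deletion and link-removal shifts.

    One coefficient per pair in :data:`CORRELATION_PAIRS`, over all records
    and over robust records (robustness_score > cutoff) separately.
    Records whose shift was capped at the horizon (the TTF was never
    induced, so the shift magnitude is a floor, not a measurement) are
    excluded per pair by default.  Degenerate variance yields NaN.
    """
    all_cols = [c for cols in CORRELATION_PAIRS.values() for c in cols]
    rows = records.dropna(subset=[c for c in all_cols if c in records])
    if len(rows) < 10:
        raise ValidationError(f"need >= 10 records with shifts, got {len(rows)}")
    results = {}
    for pair, (xcol, ycol) in CORRELATION_PAIRS.items():
        sel = rows
        if exclude_capped:
            for col in (xcol, ycol):
                flag = "capped_" + col[2:]
                if flag in sel:
                    sel = sel[~sel[flag].astype(bool)]
        robust = (
            sel[sel["robustness_score"] > robust_cutoff]
            if "robustness_score" in sel
            else sel.iloc[:0]
        )
        results[pair] = CorrelationResult(
            pair,
            _pearson(sel[xcol], sel[ycol]),
            len(sel),
            _pearson(robust[xcol], robust[ycol]),
            len(robust),
        )
    return results


def _pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return math.nan
    return float(_stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# density maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DensityMap:
    """2D binned counts (and optional bin-mean values) over coordinate space.

    ``counts`` is integer per bin; ``mean`` is NaN where a bin is empty
    (absent, not zero).
    """

    counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    mean: np.ndarray | None = None

    def to_json(self) -> dict:
        mean = None
        if self.mean is not None:
            mean = [[None if math.isnan(v) else v for v in row] for row in self.mean]
        return {
            "counts": self.counts.astype(int).tolist(),
            "x_edges": self.x_edges.tolist(),
            "y_edges": self.y_edges.tolist(),
            "mean": mean,
        }


def density_map(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    bins: int = 20,
    extent: tuple[float, float] = (0.0, 100.0),
    values: np.ndarray | pd.Series | None = None,
) -> DensityMap:
    """Bin circuit coordinates into a ``bins`` x ``bins`` map over ``extent``.

    With ``values`` (e.g. robustness scores) also returns the per-bin mean,
    NaN in empty bins.  The total count equals the number of records.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    edges = np.linspace(extent[0], extent[1], bins + 1)
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=[edges, edges])
    mean = None
    if values is not None:
        values = np.asarray(values, float)
        sums, _, _ = np.histogram2d(x, y, bins=[edges, edges], weights=values)
        with np.errstate(invalid="ignore"):
            mean = np.where(counts > 0, sums / counts, np.nan)
    return DensityMap(counts, x_edges, y_edges, mean)
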