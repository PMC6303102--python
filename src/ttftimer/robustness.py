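"""Robustness scoring of consistent circuits against production-rate noise.

A circuit buffers developmental noise well if moderate changes in TTF
production rates leave the *durations* of its expression phases nearly
unchanged -- the property needed to keep the timer synchronized with the
cell-division cycle.  Each circuit is re-simulated under every combinatorial
pattern of +/-20% applied to its six production parameters (regulated
production of Hb, Kr, Pdm, Cas and basal production of Pdm and Cas), giving
2^6 = 64 noise combinations.  A combination is "close" when every
identity-merged phase duration stays within 10% of the unperturbed duration
(and the phase order is unchanged); the robustness score is the percentage of
close combinations.

Degradation rates are left untouched: they set the overall time scale of the
timer and would rescale all circuits alike.  Fluctuations in thresholds need
no separate treatment because the dynamics depend only on level/threshold
ratios, which production noise already perturbs.
"""

from __future__ import annotations

import itertools
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .circuit import (
    CircuitTopology,
    DEFAULT_CONSTANTS,
    ParameterSet,
    StructuralConstants,
    _Batch,
    build_default_topology,
    integrate_batch,
)
from .errors import ValidationError
from .phenotype import IdentityMap, IdentityPhase, merge_identity_phases, phases_from_levels

log = logging.getLogger(__name__)

#: Order in which noise multipliers are applied to production parameters.
PRODUCTION_PARAMS = ("beta_Hb", "beta_Kr", "beta_Pdm", "beta_Cas", "beta0_Pdm", "beta0_Cas")


def noise_combinations(p: int = 6, eps: float = 0.2) -> np.ndarray:
    """All 2^p sign patterns of +/-``eps`` production noise.

    Returns an array of multipliers in {1-eps, 1+eps}, one row per
    combination, in lexicographic order (all-minus first), deterministic.
    """
    if p < 1:
        raise ValidationError("p must be >= 1")
    lo, hi = 1.0 - eps, 1.0 + eps
    return np.array(list(itertools.product((lo, hi), repeat=p)))


def is_close(
    perturbed: Sequence[IdentityPhase],
    original: Sequence[IdentityPhase],
    tol: float = 0.10,
    compare_final: bool = False,
) -> bool:
    """Whether a perturbed phase sequence is 'close' to the original.

    Both sequences must already be identity-merged.  Close means: identical
    identity order, and every corresponding duration within ``tol`` relative
    distance of the original duration.  Any change in phase order (including
    extra or missing phases) is not close.

    The last phase is open-ended -- it is truncated by the simulation
    horizon, not terminated by the circuit -- so its "duration" measures the
    horizon and would let an arbitrary structural constant dominate the
    score.  By default it participates in the order check but not in the
    duration comparison; pass ``compare_final=True`` to compare it too.
    """
    if len(perturbed) != len(original):
        return False
    last = len(original) - 1
    for i, (ph_p, ph_o) in enumerate(zip(perturbed, original)):
        if ph_p.identity != ph_o.identity:
            return False
        if i == last and not compare_final:
            continue
        if ph_o.duration <= 0 or abs(ph_p.duration - ph_o.duration) > tol * ph_o.duration:
            return False
    return True


def _identity_phases(levels, times, thresholds, ttfs, identity_map, min_phase):
    seq = phases_from_levels(levels, times, thresholds, ttfs, min_phase)
    nonempty = [ph for ph in seq if ph.on_set]
    return merge_identity_phases(nonempty, identity_map, strict=False)


def robustness_scores(
    records: pd.DataFrame,
    topology: CircuitTopology | None = None,
    identity_map: IdentityMap | None = None,
    constants: StructuralConstants = DEFAULT_CONSTANTS,
    tol: float = 0.10,
    eps: float = 0.2,
    group_size: int = 100,
) -> np.ndarray:
    """Robustness score for every circuit in ``records`` (parameter columns).

    Circuits are expanded into (1 original + 2^6 noisy) variants and
    integrated in vectorized groups; phase sequences of the noisy variants
    are called against the *original* on-thresholds, so the score measures
    genuine changes in dynamics rather than a moving goalpost.
    """
    topo = topology or build_default_topology()
    if identity_map is None:
        from .config import load_identity_map

        identity_map = load_identity_map()
    combos = noise_combinations(len(PRODUCTION_PARAMS), eps)
    n_combo = combos.shape[0]
    batch = _Batch.from_dataframe(records, topo)
    n = batch.n
    scores = np.full(n, np.nan)

    # multiplier layout per variant row: first the original, then each combo
    mult_beta = np.vstack([np.ones(4), combos[:, :4]])  # (n_combo+1, 4)
    mult_beta0 = np.ones((n_combo + 1, 4))
    mult_beta0[1:, 2] = combos[:, 4]  # Pdm basal
    mult_beta0[1:, 3] = combos[:, 5]  # Cas basal

    rows_per = n_combo + 1
    for lo in range(0, n, group_size):
        hi = min(lo + group_size, n)
        g = hi - lo
        sub = batch.select(slice(lo, hi))
        beta = np.repeat(sub.beta, rows_per, axis=0) * np.tile(mult_beta, (g, 1))
        beta0 = np.repeat(sub.beta0, rows_per, axis=0) * np.tile(mult_beta0, (g, 1))
        alpha = np.repeat(sub.alpha, rows_per, axis=0)
        thr = {k: np.repeat(v, rows_per) for k, v in sub.thr.items()}
        expanded = _Batch(beta, beta0, alpha, thr)
        on_thr = np.repeat(sub.on_thresholds(constants), rows_per, axis=0)
        times, levels, failed = integrate_batch(
            expanded, topo, constants, record="levels", return_failed=True
        )
        for i in range(g):
            base = i * rows_per
            if failed[base]:
                continue
            original = _identity_phases(
                levels[base], times, on_thr[base], topo.ttfs,
                identity_map, constants.min_phase,
            )
            close = 0
            for c in range(1, rows_per):
                if failed[base + c]:
                    log.debug("noise combination failed to integrate; counted not close")
                    continue
                perturbed = _identity_phases(
                    levels[base + c], times, on_thr[base + c], topo.ttfs,
                    identity_map, constants.min_phase,
                )
                if is_close(perturbed, original, tol):
                    close += 1
            scores[lo + i] = 100.0 * close / n_combo
    return scores


def robustness_score(
    params: ParameterSet,
    topology: CircuitTopology | None = None,
    identity_map: IdentityMap | None = None,
    constants: StructuralConstants | None = None,
    tol: float = 0.10,
    eps: float = 0.2,
) -> float:
    """Robustness score (percent of close noise combinations) of one circuit."""
    topo = topology or build_default_topology()
    records = pd.DataFrame([params.to_row(topo)])
    return float(
        robustness_scores(
            records, topo, identity_map, constants or params.constants, tol, eps
        )[0]
    )


def score_records(
    records: pd.DataFrame,
    topology: CircuitTopology | None = None,
    identity_map: IdentityMap | None = None,
    constants: StructuralConstants = DEFAULT_CONSTANTS,
    tol: float = 0.10,
    eps: float = 0.2,
) -> pd.DataFrame:
    """Add a ``robustness_score`` column (consistent circuits only, else NaN)."""
    out = records.copy()
    out["robustness_score"] = np.nan
    mask = out["consistent"].to_numpy(bool) if "consistent" in out else np.ones(len(out), bool)
    if mask.any():
        out.loc[mask, "robustness_score"] = robustness_scores(
            out.loc[mask], topology, identity_map, constants, tol, eps
        )
    return out
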