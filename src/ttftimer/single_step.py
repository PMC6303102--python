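"""Closed-form one-step timers: activator accumulation versus repressor decay.

A single timing step can be encoded in two ways.  An *accumulation* timer
starts producing an activator at t = 0 (production beta, degradation k) and
fires when the level crosses a threshold Tr from below:

    t_delay = -(1/k) * ln(1 - Tr * k / beta),        requires Tr < beta / k.

A *decay* timer stops producing a repressor at t = 0, which then decays from
its initial level P0 and fires when it crosses Tr from above:

    t_delay = (1/k) * ln(P0 / Tr).

The decay timer's delay depends only logarithmically on the production that
set P0: a fold-change f in production shifts the delay by ln(f)/k regardless
of the threshold.  The accumulation timer approaches its steady state
beta/k, so for thresholds near the ceiling the same fold-change produces
arbitrarily large shifts -- the analytic core of why repressor-decay timers
are the more robust design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


class _Never:
    """Sentinel: the timer never reaches its threshold."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "NEVER"


NEVER = _Never()

ACCUMULATION = "accumulation"
DECAY = "decay"


@dataclass(frozen=True)
class OneStepTimer:
    """A one-step timer.

    kind
        ``"accumulation"`` (needs ``production``) or ``"decay"``
        (needs ``initial``).
    k
        degradation rate, 1/min.
    threshold
        readout threshold Tr, concentration units.
    """

    kind: str
    k: float
    threshold: float
    production: float | None = None  # beta, accumulation only
    initial: float | None = None  # P0, decay only

    def __post_init__(self):
        if self.kind not in (ACCUMULATION, DECAY):
            raise ValidationError(f"unknown timer kind {self.kind!r}")
        if self.k <= 0 or self.threshold <= 0:
            raise ValidationError("k and threshold must be strictly positive")
        if self.kind == ACCUMULATION and (self.production is None or self.production <= 0):
            raise ValidationError("accumulation timer requires positive production")
        if self.kind == DECAY and (self.initial is None or self.initial <= 0):
            raise ValidationError("decay timer requires positive initial level")

    def with_production_fold(self, fold: float) -> "OneStepTimer":
        """Rescale production by ``fold`` (for decay, P0 scales with production)."""
        if fold <= 0:
            raise ValidationError("fold must be positive")
        if self.kind == ACCUMULATION:
            return OneStepTimer(self.kind, self.k, self.threshold, self.production * fold)
        return OneStepTimer(self.kind, self.k, self.threshold, initial=self.initial * fold)


def delay(timer: OneStepTimer):
    """Time from onset until the regulator reaches the threshold, minutes.

    An accumulation timer whose threshold is at or above its steady state
    beta/k never fires and returns :data:`NEVER`.
    """
    if timer.kind == ACCUMULATION:
        ceiling = timer.production / timer.k
        if timer.threshold >= ceiling:
            return NEVER
        return -math.log(1.0 - timer.threshold / ceiling) / timer.k
    return math.log(timer.initial / timer.threshold) / timer.k


def delay_shift_under_production_change(timer: OneStepTimer, fold: float):
    """Change in delay (minutes) after a ``fold`` change in production rate.

    For a decay timer this equals ln(fold)/k exactly, independent of the
    threshold; for an accumulation timer it grows without bound as the
    (perturbed) threshold approaches the steady state, returning
    :data:`NEVER` when the perturbed timer cannot fire.
    """
    base = delay(timer)
    if base is NEVER:
        return NEVER
    shifted = delay(timer.with_production_fold(fold))
    if shifted is NEVER:
        return NEVER
    return shifted - base


def delay_curve(
    kind: str,
    k: float,
    thresholds: np.ndarray,
    fold: float = 0.5,
    production: float = 1.0,
    initial: float = 1.0,
):
    """Delay and delay-shift across a threshold grid (the sensitivity curve).

    Returns ``(delays, shifts)`` arrays with NaN where the timer (or its
    perturbed version) never fires.
    """
    delays = np.full(len(thresholds), np.nan)
    shifts = np.full(len(thresholds), np.nan)
    for i, tr in enumerate(np.asarray(thresholds, float)):
        timer = (
            OneStepTimer(kind, k, tr, production=production)
            if kind == ACCUMULATION
            else OneStepTimer(kind, k, tr, initial=initial)
        )
        d = delay(timer)
        if d is NEVER:
            continue
        delays[i] = d
        s = delay_shift_under_production_change(timer, fold)
        if s is not NEVER:
            shifts[i] = s
    return delays, shifts
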