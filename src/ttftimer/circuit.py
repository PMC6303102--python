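"""Regulatory circuit model of the neuroblast temporal transcription factor (TTF) timer.

The embryonic *Drosophila* neuroblast expresses four TTFs -- Hunchback (Hb),
Krüppel (Kr), Pdm and Castor (Cas) -- in a stereotyped temporal sequence.  The
cross-regulation between them combines *activator-relay* interactions (each TTF
activates the next one), *repressor-decay* interactions (an upstream TTF
represses a downstream one, which is induced only once the repressor has
decayed) and *backward* repression of upstream TTFs by downstream ones.

This module defines the regulatory graph (:class:`CircuitTopology`), the free
kinetic parameters of one candidate circuit (:class:`ParameterSet`), in-silico
perturbations (TTF deletion, constitutive expression, removal of a single
regulatory link) and the ODE dynamics.  For each TTF ``X`` the model reads

    dX/dt = [beta_X * prod(A(Y; T)) + beta0_X] * prod(R(Z; T)) - alpha_X * X

with Hill-type regulation terms ``A(Y;T) = (Y/T)^n / (1 + (Y/T)^n)`` and
``R(Z;T) = 1 / (1 + (Z/T)^n)``.  Hb has no upstream activator; its production
is gated by an external input active on ``[0, t_off)``.  Basal production
(Pdm and Cas only) is subject to repression but not activation, which is what
produces the early transient expression bursts seen before the repressors have
accumulated.  All regulation terms are dimensionless and depend only on the
ratio of a TTF level to its threshold, so production rates and thresholds are
meaningful only relative to each other.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import PerturbationError, SolverError, ValidationError

TTFS: tuple[str, ...] = ("Hb", "Kr", "Pdm", "Cas")
#: TTFs that carry a basal (activator-independent) production term.
BASAL_TTFS: tuple[str, ...] = ("Pdm", "Cas")

ACTIVATION = "activation"
REPRESSION = "repression"

_NEG_CLIP = 1e-9  # tolerance for clipping tiny negative solver noise


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interaction:
    """One directed regulatory edge of the TTF circuit.

    ``klass`` records the edge's role in the timer: ``forward-relay``
    (activation of the next TTF), ``forward-decay`` (repression of a
    downstream TTF by an upstream one) or ``backward`` (repression of an
    upstream TTF by a downstream one).
    """

    source: str
    target: str
    sign: str  # "activation" | "repression"
    klass: str  # "forward-relay" | "forward-decay" | "backward"
    has_threshold: bool = True

    @property
    def key(self) -> str:
        """Stable identifier, e.g. ``"Hb->Kr"`` or ``"Hb-|Pdm"``."""
        arrow = "->" if self.sign == ACTIVATION else "-|"
        return f"{self.source}{arrow}{self.target}"

    @property
    def threshold_name(self) -> str:
        """Parameter column name for this edge's threshold, e.g. ``T_HbKr``."""
        return f"T_{self.source}{self.target}"


@dataclass(frozen=True)
class Perturbation:
    """A single in-silico perturbation applied to a circuit.

    kinds
        ``none``
            identity.
        ``deletion``
            the target TTF's production rates (regulated and basal) are set
            to zero; mimics a null mutant.
        ``constitutive``
            every regulation term on the target's production, including the
            external-input gate for Hb, is fixed at 1; mimics uniform
            misexpression.
        ``remove_link``
            only the named interaction is abolished, leaving every other
            edge intact.  Removing a repression edge fixes its regulation
            term at 1 (the target is no longer repressed and can only be
            induced earlier); removing an activation edge abolishes the
            activation input, so the target's regulated production term
            vanishes and only basal production remains (induction can only
            be delayed), exactly mirroring what deletion of the activator
            does to this one target.
    """

    kind: str = "none"
    target: str | None = None

    KINDS = ("none", "deletion", "constitutive", "remove_link")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise PerturbationError(f"unknown perturbation kind {self.kind!r}")
        if self.kind != "none" and self.target is None:
            raise PerturbationError(f"perturbation {self.kind!r} requires a target")

    @classmethod
    def none(cls) -> "Perturbation":
        return cls("none")

    @classmethod
    def deletion(cls, ttf: str) -> "Perturbation":
        return cls("deletion", ttf)

    @classmethod
    def constitutive(cls, ttf: str) -> "Perturbation":
        return cls("constitutive", ttf)

    @classmethod
    def remove_link(cls, key: str) -> "Perturbation":
        return cls("remove_link", key)


@dataclass(frozen=True)
class CircuitTopology:
    """The TTF regulatory graph plus a record of any applied perturbation."""

    ttfs: tuple[str, ...] = TTFS
    interactions: tuple[Interaction, ...] = ()
    applied_perturbation: Perturbation | None = None

    def __post_init__(self):
        names = set(self.ttfs)
        seen: set[str] = set()
        for ia in self.interactions:
            if ia.source not in names or ia.target not in names:
                raise ValidationError(
                    f"interaction {ia.key}: unknown TTF (known: {sorted(names)})"
                )
            if ia.source == ia.target:
                raise ValidationError(f"self-edge not allowed: {ia.key}")
            if ia.key in seen:
                raise ValidationError(f"duplicate interaction {ia.key}")
            seen.add(ia.key)

    # -- lookups ----------------------------------------------------------
    def index(self, ttf: str) -> int:
        try:
            return self.ttfs.index(ttf)
        except ValueError:
            raise ValidationError(f"unknown TTF {ttf!r}") from None

    def interaction(self, key: str) -> Interaction:
        for ia in self.interactions:
            if ia.key == key:
                return ia
        raise ValidationError(f"no interaction {key!r} in topology")

    @property
    def threshold_keys(self) -> tuple[str, ...]:
        return tuple(ia.key for ia in self.interactions if ia.has_threshold)

    def regulators(self, target: str, sign: str) -> tuple[Interaction, ...]:
        return tuple(
            ia for ia in self.interactions if ia.target == target and ia.sign == sign
        )

    @property
    def n_free_parameters(self) -> int:
        """Threshold-bearing edges + production + basal + degradation rates."""
        n_thr = sum(1 for ia in self.interactions if ia.has_threshold)
        return n_thr + len(self.ttfs) + len(BASAL_TTFS) + len(self.ttfs)


_DEFAULT_EDGES = (
    Interaction("Hb", "Kr", ACTIVATION, "forward-relay"),
    Interaction("Kr", "Pdm", ACTIVATION, "forward-relay"),
    Interaction("Hb", "Pdm", REPRESSION, "forward-decay"),
    Interaction("Pdm", "Cas", ACTIVATION, "forward-relay"),
    Interaction("Kr", "Cas", REPRESSION, "forward-decay"),
    Interaction("Hb", "Cas", REPRESSION, "forward-decay"),
    Interaction("Cas", "Pdm", REPRESSION, "backward"),
)


def build_default_topology() -> CircuitTopology:
    """The experimentally described TTF circuit.

    Six forward edges (three relay activations, three decay repressions) plus
    one backward repression Cas-|Pdm, all threshold-bearing: 7 thresholds,
    which together with 6 production/basal and 4 degradation rates gives the
    17 free parameters of the default model.
    """
    return CircuitTopology(TTFS, _DEFAULT_EDGES)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructuralConstants:
    """Fixed structural constants of the model (not free parameters).

    hill_n
        Hill steepness of every regulation term; ``None`` selects sharp
        (step-function) regulation.
    t_off
        end of the external input driving Hb production, minutes.  Hb is
        transcribed for roughly one ~45 min neuroblast cell cycle.
    horizon
        total simulated time, minutes; long enough for the full cascade.
    dt / grid_step
        integrator step and trajectory output step, minutes.
    on_fraction
        a TTF counts as "on" where its level exceeds this fraction of its
        maximal steady-state level (beta + beta0) / alpha.
    identity_fraction
        like ``on_fraction`` but for calling progeny identity at division.
    min_phase
        phases shorter than this (minutes) are treated as grid artifacts
        and merged into their neighbor.
    sustain
        minutes a level must stay above threshold for an upcrossing to
        count as induction (discounts early transient bursts).
    division_period
        interval between asymmetric neuroblast divisions, minutes.
    """

    hill_n: int | None = 4
    t_off: float = 45.0
    horizon: float = 400.0
    dt: float = 0.125
    grid_step: float = 1.0
    on_fraction: float = 0.05
    identity_fraction: float = 0.05
    min_phase: float = 2.0
    sustain: float = 10.0
    division_period: float = 45.0


DEFAULT_CONSTANTS = StructuralConstants()


def param_columns(topology: CircuitTopology | None = None) -> list[str]:
    """Stable CSV column order for the free parameters.

    ``beta_Hb..beta_Cas, beta0_Pdm, beta0_Cas, alpha_Hb..alpha_Cas,
    T_HbKr, T_KrPdm, T_HbPdm, T_PdmCas, T_KrCas, T_HbCas, T_CasPdm``
    for the default topology.
    """
    topo = topology or build_default_topology()
    cols = [f"beta_{t}" for t in topo.ttfs]
    cols += [f"beta0_{t}" for t in BASAL_TTFS]
    cols += [f"alpha_{t}" for t in topo.ttfs]
    cols += [ia.threshold_name for ia in topo.interactions if ia.has_threshold]
    return cols


@dataclass(frozen=True)
class ParameterSet:
    """The free kinetic parameters of one candidate circuit.

    beta / beta0
        production rates (concentration/min); ``beta0`` holds basal rates
        for Pdm and Cas only.
    alpha
        first-order degradation rates (1/min).
    thresholds
        regulation threshold (concentration) per threshold-bearing
        interaction, keyed by interaction key (``"Hb->Kr"`` ...).
    """

    beta: Mapping[str, float]
    beta0: Mapping[str, float]
    alpha: Mapping[str, float]
    thresholds: Mapping[str, float]
    constants: StructuralConstants = DEFAULT_CONSTANTS
    params_id: str | None = None

    def __post_init__(self):
        for name, mapping in (("beta", self.beta), ("beta0", self.beta0),
                              ("alpha", self.alpha), ("thresholds", self.thresholds)):
            for key, value in mapping.items():
                if not np.isfinite(value) or value < 0:
                    raise ValidationError(f"{name}[{key}] = {value!r} must be >= 0 and finite")
        for key, value in self.alpha.items():
            if value <= 0:
                raise ValidationError(f"alpha[{key}] must be strictly positive")

    def validate_strict(self, topology: CircuitTopology) -> None:
        """Full invariant check for unperturbed parameter sets.

        All rates and thresholds strictly positive, every threshold-bearing
        interaction covered, free-parameter count as implied by the topology
        (17 for the default circuit).
        """
        for ttf in topology.ttfs:
            if self.beta.get(ttf, 0.0) <= 0:
                raise ValidationError(f"beta[{ttf}] must be strictly positive")
            if self.alpha.get(ttf, 0.0) <= 0:
                raise ValidationError(f"alpha[{ttf}] must be strictly positive")
        for ttf in BASAL_TTFS:
            if self.beta0.get(ttf, 0.0) <= 0:
                raise ValidationError(f"beta0[{ttf}] must be strictly positive")
        for key in topology.threshold_keys:
            if self.thresholds.get(key, 0.0) <= 0:
                raise ValidationError(f"thresholds[{key}] must be strictly positive")
        if self.n_free != topology.n_free_parameters:
            raise ValidationError(
                f"{self.n_free} free parameters, topology implies {topology.n_free_parameters}"
            )

    @property
    def n_free(self) -> int:
        return len(self.beta) + len(self.beta0) + len(self.alpha) + len(self.thresholds)

    def max_level(self, ttf: str) -> float:
        """Steady-state ceiling (beta + beta0) / alpha for one TTF."""
        return (self.beta.get(ttf, 0.0) + self.beta0.get(ttf, 0.0)) / self.alpha[ttf]

    def on_thresholds(self) -> dict[str, float]:
        """Per-TTF "on" thresholds used for phase calling."""
        return {t: self.constants.on_fraction * self.max_level(t) for t in self.beta}

    def identity_thresholds(self) -> dict[str, float]:
        return {t: self.constants.identity_fraction * self.max_level(t) for t in self.beta}

    def scaled(self, factor: float) -> "ParameterSet":
        """Multiply all production rates and thresholds by ``factor``.

        The dynamics depend only on level/threshold ratios, so this leaves
        phase sequences and induction times unchanged.
        """
        return replace(
            self,
            beta={k: v * factor for k, v in self.beta.items()},
            beta0={k: v * factor for k, v in self.beta0.items()},
            thresholds={k: v * factor for k, v in self.thresholds.items()},
        )

    # -- serialization -----------------------------------------------------
    def to_row(self, topology: CircuitTopology | None = None) -> dict[str, float]:
        topo = topology or build_default_topology()
        row: dict[str, float] = {}
        for ttf in topo.ttfs:
            row[f"beta_{ttf}"] = self.beta.get(ttf, 0.0)
        for ttf in BASAL_TTFS:
            row[f"beta0_{ttf}"] = self.beta0.get(ttf, 0.0)
        for ttf in topo.ttfs:
            row[f"alpha_{ttf}"] = self.alpha[ttf]
        for ia in topo.interactions:
            if ia.has_threshold:
                row[ia.threshold_name] = self.thresholds[ia.key]
        return row

    @classmethod
    def from_row(
        cls,
        row: Mapping[str, float],
        topology: CircuitTopology | None = None,
        constants: StructuralConstants = DEFAULT_CONSTANTS,
        params_id: str | None = None,
    ) -> "ParameterSet":
        topo = topology or build_default_topology()
        beta = {t: float(row[f"beta_{t}"]) for t in topo.ttfs}
        beta0 = {t: float(row[f"beta0_{t}"]) for t in BASAL_TTFS}
        alpha = {t: float(row[f"alpha_{t}"]) for t in topo.ttfs}
        thresholds = {
            ia.key: float(row[ia.threshold_name])
            for ia in topo.interactions
            if ia.has_threshold
        }
        return cls(beta, beta0, alpha, thresholds, constants, params_id)


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

def apply_perturbation(
    params: ParameterSet,
    topology: CircuitTopology,
    perturbation: Perturbation | None,
) -> tuple[ParameterSet, CircuitTopology]:
    """Return a perturbed copy of ``(params, topology)``.

    Only one perturbation may be applied to a circuit; applying a second one
    raises :class:`PerturbationError`.  The original inputs are never
    modified.  Deleted TTFs get zero production; constitutive expression and
    link removal are represented by dropping the corresponding regulation
    edges (an absent edge contributes a factor of 1 to the production term).
    """
    if perturbation is None or perturbation.kind == "none":
        return params, topology
    if topology.applied_perturbation is not None:
        raise PerturbationError(
            f"circuit already carries perturbation "
            f"{topology.applied_perturbation.kind}:{topology.applied_perturbation.target}; "
            "one perturbation at a time"
        )
    kind, target = perturbation.kind, perturbation.target
    if kind == "deletion":
        topology.index(target)  # validates the TTF name
        beta = dict(params.beta)
        beta[target] = 0.0
        beta0 = {k: (0.0 if k == target else v) for k, v in params.beta0.items()}
        new_params = replace(params, beta=beta, beta0=beta0)
        new_topo = replace(topology, applied_perturbation=perturbation)
        return new_params, new_topo
    if kind == "constitutive":
        topology.index(target)
        kept = tuple(ia for ia in topology.interactions if ia.target != target)
        new_topo = replace(topology, interactions=kept, applied_perturbation=perturbation)
        return params, new_topo
    if kind == "remove_link":
        edge = topology.interaction(target)  # validates existence
        kept = tuple(ia for ia in topology.interactions if ia.key != target)
        new_topo = replace(topology, interactions=kept, applied_perturbation=perturbation)
        new_params = params
        if edge.sign == ACTIVATION:
            # losing the activation input abolishes the regulated production
            beta = dict(params.beta)
            beta[edge.target] = 0.0
            new_params = replace(params, beta=beta)
        return new_params, new_topo
    raise PerturbationError(f"unknown perturbation kind {kind!r}")


def _gate_disabled(topology: CircuitTopology) -> bool:
    pert = topology.applied_perturbation
    return pert is not None and pert.kind == "constitutive" and pert.target == "Hb"


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def _regulation(level: np.ndarray, threshold, hill_n: int | None, activation: bool):
    """Dimensionless Hill regulation term in [0, 1]."""
    if hill_n is None:  # sharp-threshold (step) regulation
        on = level >= threshold
        return on.astype(float) if activation else (~on).astype(float)
    ratio = level / threshold
    if hill_n == 4:
        w = ratio * ratio
        w = w * w
    else:
        w = ratio ** hill_n
    return w / (1.0 + w) if activation else 1.0 / (1.0 + w)


def _batch_rhs(t, X, beta, beta0, alpha, thr, topology, constants):
    """Right-hand side for a batch of circuits; X has shape (n, 4)."""
    ttfs = topology.ttfs
    dX = np.empty_like(X)
    gate_off = _gate_disabled(topology)
    for j, ttf in enumerate(ttfs):
        prod = beta[:, j]
        for ia in topology.interactions:
            if ia.target != ttf or ia.sign != ACTIVATION:
                continue
            si = topology.index(ia.source)
            prod = prod * _regulation(X[:, si], thr[ia.key], constants.hill_n, True)
        if ttf == "Hb" and not gate_off and t >= constants.t_off:
            prod = np.zeros_like(beta[:, j])
        prod = prod + beta0[:, j]
        for ia in topology.interactions:
            if ia.target != ttf or ia.sign != REPRESSION:
                continue
            si = topology.index(ia.source)
            prod = prod * _regulation(X[:, si], thr[ia.key], constants.hill_n, False)
        dX[:, j] = prod - alpha[:, j] * X[:, j]
    return dX


def rhs(
    levels: Sequence[float] | np.ndarray,
    t: float,
    params: ParameterSet,
    topology: CircuitTopology | None = None,
    perturbation: Perturbation | None = None,
) -> np.ndarray:
    """Level derivatives d[levels]/dt at time ``t`` for a single circuit."""
    topo = topology or build_default_topology()
    p, topo = apply_perturbation(params, topo, perturbation)
    levels = np.asarray(levels, dtype=float)
    if np.any(levels < 0):
        raise ValidationError("levels must be non-negative")
    beta = np.array([[p.beta.get(t_, 0.0) for t_ in topo.ttfs]])
    beta0 = np.array([[p.beta0.get(t_, 0.0) for t_ in topo.ttfs]])
    alpha = np.array([[p.alpha[t_] for t_ in topo.ttfs]])
    thr = {ia.key: np.array([p.thresholds[ia.key]]) for ia in topo.interactions}
    return _batch_rhs(t, levels[None, :], beta, beta0, alpha, thr, topo, p.constants)[0]


@dataclass(frozen=True)
class Trajectory:
    """Simulated TTF concentration time-courses on a uniform grid."""

    times: np.ndarray  # (n_t,) minutes, strictly increasing
    levels: np.ndarray  # (n_t, n_ttf) concentrations, >= 0
    ttfs: tuple[str, ...] = TTFS
    params_id: str | None = None

    def level(self, ttf: str) -> np.ndarray:
        return self.levels[:, self.ttfs.index(ttf)]


class _Batch:
    """Array-of-circuits parameter container for the vectorized integrator."""

    __slots__ = ("beta", "beta0", "alpha", "thr", "n")

    def __init__(self, beta, beta0, alpha, thr):
        self.beta = beta
        self.beta0 = beta0
        self.alpha = alpha
        self.thr = thr
        self.n = beta.shape[0]

    @classmethod
    def from_parameter_sets(cls, sets: Iterable[ParameterSet], topology: CircuitTopology):
        sets = list(sets)
        ttfs = topology.ttfs
        beta = np.array([[p.beta.get(t, 0.0) for t in ttfs] for p in sets])
        beta0 = np.array([[p.beta0.get(t, 0.0) for t in ttfs] for p in sets])
        alpha = np.array([[p.alpha[t] for t in ttfs] for p in sets])
        thr = {
            key: np.array([p.thresholds[key] for p in sets])
            for key in topology.threshold_keys
        }
        return cls(beta, beta0, alpha, thr)

    @classmethod
    def from_dataframe(cls, df, topology: CircuitTopology):
        ttfs = topology.ttfs
        beta = np.column_stack([df[f"beta_{t}"].to_numpy(float) for t in ttfs])
        beta0 = np.column_stack(
            [
                df[f"beta0_{t}"].to_numpy(float) if f"beta0_{t}" in df else np.zeros(len(df))
                for t in ttfs
            ]
        )
        alpha = np.column_stack([df[f"alpha_{t}"].to_numpy(float) for t in ttfs])
        thr = {
            ia.key: df[ia.threshold_name].to_numpy(float)
            for ia in topology.interactions
            if ia.has_threshold
        }
        return cls(beta, beta0, alpha, thr)

    def copy(self) -> "_Batch":
        return _Batch(
            self.beta.copy(), self.beta0.copy(), self.alpha.copy(),
            {k: v.copy() for k, v in self.thr.items()},
        )

    def select(self, idx) -> "_Batch":
        return _Batch(
            self.beta[idx], self.beta0[idx], self.alpha[idx],
            {k: v[idx] for k, v in self.thr.items()},
        )

    def max_levels(self) -> np.ndarray:
        return (self.beta + self.beta0) / self.alpha

    def on_thresholds(self, constants: StructuralConstants) -> np.ndarray:
        return constants.on_fraction * self.max_levels()

    def perturbed(self, topology: CircuitTopology, perturbation: Perturbation | None):
        """Batch analogue of :func:`apply_perturbation`."""
        if perturbation is None or perturbation.kind == "none":
            return self, topology
        if perturbation.kind == "deletion":
            j = topology.index(perturbation.target)
            out = self.copy()
            out.beta[:, j] = 0.0
            out.beta0[:, j] = 0.0
            return out, replace(topology, applied_perturbation=perturbation)
        if perturbation.kind == "constitutive":
            topology.index(perturbation.target)
            kept = tuple(ia for ia in topology.interactions if ia.target != perturbation.target)
            return self, replace(topology, interactions=kept, applied_perturbation=perturbation)
        if perturbation.kind == "remove_link":
            edge = topology.interaction(perturbation.target)
            kept = tuple(ia for ia in topology.interactions if ia.key != perturbation.target)
            out = self
            if edge.sign == ACTIVATION:
                out = self.copy()
                out.beta[:, topology.index(edge.target)] = 0.0
            return out, replace(topology, interactions=kept, applied_perturbation=perturbation)
        raise PerturbationError(f"unknown perturbation kind {perturbation.kind!r}")


def integrate_batch(
    batch: _Batch,
    topology: CircuitTopology,
    constants: StructuralConstants = DEFAULT_CONSTANTS,
    *,
    record: str = "levels",
    on_thresholds: np.ndarray | None = None,
    return_failed: bool = False,
):
    """Integrate a batch of circuits with a fixed-step classic Runge-Kutta scheme.

    All circuits start from zero levels and share the structural constants.
    With ``record="levels"`` returns ``(times, levels)`` where levels has
    shape ``(n, n_t, n_ttf)``; with ``record="codes"`` returns
    ``(times, codes)`` where ``codes[i, k]`` is a bitmask of the TTFs whose
    level is at or above ``on_thresholds[i, :]`` at output point ``k``
    (bit j corresponds to ``topology.ttfs[j]``).
    """
    dt = constants.dt
    n_steps = int(round(constants.horizon / dt))
    per_out = max(1, int(round(constants.grid_step / dt)))
    n_out = n_steps // per_out
    times = np.arange(n_out + 1) * (dt * per_out)
    n, m = batch.n, len(topology.ttfs)

    if record == "codes":
        if on_thresholds is None:
            raise ValueError("record='codes' requires on_thresholds")
        out = np.zeros((n, n_out + 1), dtype=np.uint8)
        bits = (1 << np.arange(m)).astype(np.uint8)
    elif record == "levels":
        out = np.zeros((n, n_out + 1, m))
    else:
        raise ValueError(f"unknown record mode {record!r}")

    X = np.zeros((n, m))
    args = (batch.beta, batch.beta0, batch.alpha, batch.thr, topology, constants)

    def store(k, X):
        if record == "codes":
            out[:, k] = ((X >= on_thresholds) * bits).sum(axis=1).astype(np.uint8)
        else:
            out[:, k, :] = X

    store(0, X)
    t = 0.0
    half = dt / 2.0
    sixth = dt / 6.0
    for step in range(1, n_steps + 1):
        k1 = _batch_rhs(t, X, *args)
        k2 = _batch_rhs(t + half, X + half * k1, *args)
        k3 = _batch_rhs(t + half, X + half * k2, *args)
        k4 = _batch_rhs(t + dt, X + dt * k3, *args)
        X = X + sixth * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        np.maximum(X, 0.0, out=X)
        t = step * dt
        if step % per_out == 0:
            store(step // per_out, X)

    failed = ~np.isfinite(X).all(axis=1)
    if return_failed:
        return times, out, failed
    if failed.any():
        raise SolverError("non-finite levels during integration")
    return times, out


def simulate(
    params: ParameterSet,
    topology: CircuitTopology | None = None,
    perturbation: Perturbation | None = None,
) -> Trajectory:
    """Simulate one circuit from zero initial conditions over the full horizon.

    Tiny negative solver noise (below 1e-9) is clipped to zero; the output
    grid step is ``constants.grid_step`` (1 min by default).
    """
    topo = topology or build_default_topology()
    p, topo = apply_perturbation(params, topo, perturbation)
    b = _Batch.from_parameter_sets([p], topo)
    try:
        times, levels = integrate_batch(b, topo, p.constants, record="levels")
    except SolverError as exc:
        raise SolverError(str(exc), params_id=params.params_id) from None
    lv = levels[0]
    lv[(lv < 0) & (lv > -_NEG_CLIP)] = 0.0
    return Trajectory(times, lv, topo.ttfs, params.params_id)
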