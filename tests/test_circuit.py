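"""Circuit model: topology, dynamics, perturbations, integrator accuracy."""

import numpy as np
import pytest

from ttftimer import (
    DEFAULT_CONSTANTS,
    Interaction,
    ParameterSet,
    PerturbationError,
    Perturbation,
    StructuralConstants,
    ValidationError,
    apply_perturbation,
    build_default_topology,
    load_topology,
    param_columns,
    rhs,
    simulate,
)
from ttftimer.circuit import CircuitTopology, TTFS
from ttftimer.screen import ParameterRanges, sample_parameter_set, _draw_rng
from ttftimer.phenotype import trajectory_to_phases


def make_params(beta=1.0, beta0=0.1, alpha=0.05, thr=1.0, **const):
    topo = build_default_topology()
    constants = StructuralConstants(**const) if const else DEFAULT_CONSTANTS
    return ParameterSet(
        beta={t: beta for t in TTFS},
        beta0={"Pdm": beta0, "Cas": beta0},
        alpha={t: alpha for t in TTFS},
        thresholds={k: thr for k in topo.threshold_keys},
        constants=constants,
    )


class TestTopology:
    def test_default_contents(self, topology):
        keys = {ia.key for ia in topology.interactions}
        assert "Kr->Pdm" in keys  # activator-relay input of Pdm
        assert "Hb-|Pdm" in keys  # repressor-decay input of Pdm
        assert "Kr-|Cas" in keys and "Pdm->Cas" in keys and "Hb-|Cas" in keys
        assert "Cas-|Pdm" in keys  # backward repression
        assert len(topology.threshold_keys) == 7
        assert topology.n_free_parameters == 17

    def test_config_file_matches_builtin(self, topology):
        loaded, constants = load_topology()
        assert loaded.ttfs == topology.ttfs
        assert loaded.interactions == topology.interactions
        assert constants == DEFAULT_CONSTANTS

    def test_self_edge_rejected(self):
        with pytest.raises(ValidationError, match="self-edge"):
            CircuitTopology(TTFS, (Interaction("Hb", "Hb", "activation", "backward"),))

    def test_unknown_ttf_rejected(self):
        with pytest.raises(ValidationError, match="unknown TTF"):
            CircuitTopology(TTFS, (Interaction("Hb", "Svp", "repression", "backward"),))

    def test_parameter_row_roundtrip(self, topology):
        ps = make_params()
        row = ps.to_row(topology)
        assert list(row) == param_columns(topology)
        back = ParameterSet.from_row(row, topology)
        assert back.beta == ps.beta and back.thresholds == ps.thresholds


class TestRhs:
    def test_pure_decay(self):
        ps = make_params(beta=0.0, beta0=0.0, alpha=0.1)
        levels = np.array([2.0, 3.0, 4.0, 5.0])
        # with all production off only first-order decay remains
        assert np.allclose(rhs(levels, 10.0, ps), -0.1 * levels)

    def test_half_saturation_at_threshold(self):
        ps = make_params(beta=2.0, alpha=0.05, thr=1.0)
        # Hb sits exactly at the Kr-activation threshold -> term = 1/2
        deriv = rhs([1.0, 0.0, 0.0, 0.0], 0.0, ps)
        assert deriv[TTFS.index("Kr")] == pytest.approx(0.5 * 2.0)

    def test_hb_steady_state_under_external_input(self):
        ps = make_params(beta=1.0, alpha=0.05)
        deriv = rhs([1.0 / 0.05, 0.0, 0.0, 0.0], 10.0, ps)  # t < t_off
        assert deriv[0] == pytest.approx(0.0)

    def test_hb_production_stops_after_t_off(self):
        ps = make_params(beta=1.0, alpha=0.05)
        deriv = rhs([1.0, 0.0, 0.0, 0.0], ps.constants.t_off + 1.0, ps)
        assert deriv[0] == pytest.approx(-0.05)

    def test_negative_levels_rejected(self):
        with pytest.raises(ValidationError):
            rhs([-1.0, 0.0, 0.0, 0.0], 0.0, make_params())

    def test_negative_parameter_rejected(self):
        with pytest.raises(ValidationError):
            make_params(alpha=-0.1)


class TestSimulate:
    @pytest.mark.parametrize("alpha", [0.05, 0.5])
    def test_matches_closed_form(self, alpha):
        """Single-species accumulation follows beta/alpha (1 - exp(-alpha t))."""
        ps = make_params(beta=1.0, beta0=0.0, alpha=alpha, t_off=1e9)
        traj = simulate(ps)
        hb = traj.level("Hb")
        exact = (1.0 / alpha) * (1.0 - np.exp(-alpha * traj.times))
        assert np.abs(hb - exact).max() / (1.0 / alpha) < 1e-6

    def test_deletion_gives_zero_trajectory(self):
        traj = simulate(make_params(), perturbation=Perturbation.deletion("Hb"))
        assert np.all(traj.level("Hb") == 0.0)

    def test_constitutive_relaxes_to_ceiling(self):
        ps = make_params(beta=1.0, alpha=0.05)
        traj = simulate(ps, perturbation=Perturbation.constitutive("Hb"))
        hb = traj.level("Hb")
        assert np.all(np.diff(hb) >= -1e-9)  # monotone rise
        assert hb[-1] == pytest.approx(1.0 / 0.05, rel=1e-4)

    def test_trajectory_nonnegative_on_random_draws(self, topology):
        ranges = ParameterRanges.defaults(topology)
        for draw in range(15):
            ps = sample_parameter_set(ranges, _draw_rng(99, draw), topology)
            traj = simulate(ps, topology)
            assert traj.levels.min() >= 0.0
            assert np.all(np.diff(traj.times) > 0)

    def test_scale_invariance(self, topology, constants):
        """Production rates and thresholds matter only as ratios."""
        ranges = ParameterRanges.defaults(topology)
        for draw in range(5):
            ps = sample_parameter_set(ranges, _draw_rng(7, draw), topology)
            scaled = ps.scaled(37.0)
            seq_a = trajectory_to_phases(simulate(ps, topology), ps.on_thresholds())
            seq_b = trajectory_to_phases(simulate(scaled, topology), scaled.on_thresholds())
            assert seq_a.on_sets() == seq_b.on_sets()


class TestPerturbations:
    def test_none_is_identity(self, topology):
        ps = make_params()
        p2, t2 = apply_perturbation(ps, topology, Perturbation.none())
        assert p2 is ps and t2 is topology

    def test_remove_repression_link_decouples(self, topology):
        ps = make_params(beta=1.0, beta0=0.2, thr=1.0)
        p2, t2 = apply_perturbation(ps, topology, Perturbation.remove_link("Hb-|Pdm"))
        j = TTFS.index("Pdm")
        lo = rhs([0.5, 1.0, 0.0, 0.0], 0.0, p2, t2)[j]
        hi = rhs([50.0, 1.0, 0.0, 0.0], 0.0, p2, t2)[j]
        assert lo == pytest.approx(hi)  # Pdm derivative independent of Hb

    def test_remove_activation_link_leaves_basal(self, topology):
        ps = make_params(beta=1.0, beta0=0.2, thr=1.0)
        p2, t2 = apply_perturbation(ps, topology, Perturbation.remove_link("Kr->Pdm"))
        j = TTFS.index("Pdm")
        # regulated production is gone; only basal remains, Kr level irrelevant
        for kr in (0.0, 100.0):
            assert rhs([0.0, kr, 0.0, 0.0], 0.0, p2, t2)[j] == pytest.approx(0.2)

    def test_stacked_perturbations_rejected(self, topology):
        ps = make_params()
        p2, t2 = apply_perturbation(ps, topology, Perturbation.deletion("Kr"))
        with pytest.raises(PerturbationError, match="one perturbation"):
            apply_perturbation(p2, t2, Perturbation.constitutive("Kr"))

    def test_unknown_targets_rejected(self, topology):
        with pytest.raises(ValidationError):
            apply_perturbation(make_params(), topology, Perturbation.deletion("Svp"))
        with pytest.raises(ValidationError):
            apply_perturbation(make_params(), topology, Perturbation.remove_link("Kr->Hb"))

    def test_inputs_unmodified(self, topology):
        ps = make_params()
        before = dict(ps.beta)
        apply_perturbation(ps, topology, Perturbation.deletion("Hb"))
        assert ps.beta == before
        assert len(topology.interactions) == 7
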