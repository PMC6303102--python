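"""Phase calling, identity merging, consistency checks, progeny identities."""

import numpy as np
import pytest

from ttftimer import (
    IdentityMap,
    Trajectory,
    ValidationError,
    check_consistency,
    merge_identity_phases,
    progeny_identities,
    simulate,
    trajectory_to_phases,
)
from ttftimer.phenotype import (
    Phase,
    PhaseSequence,
    phases_from_levels,
)

from conftest import square_trajectory

THR = {t: 1.0 for t in ("Hb", "Kr", "Pdm", "Cas")}


class TestPhaseCalling:
    def test_square_wave(self, toy_trajectory):
        seq = trajectory_to_phases(toy_trajectory, THR)
        assert seq.on_sets() == [frozenset({"Hb"}), frozenset({"Kr"})]

    def test_all_below_threshold_single_empty_phase(self):
        traj = square_trajectory({}, horizon=50.0)
        seq = trajectory_to_phases(traj, THR)
        assert len(seq) == 1 and seq.phases[0].on_set == frozenset()

    def test_short_blip_merged(self):
        traj = square_trajectory({"Hb": (0, 40), "Kr": (40, 41)}, horizon=100.0)
        seq = trajectory_to_phases(traj, THR, min_phase=2.0)
        assert frozenset({"Kr"}) not in seq.on_sets()

    def test_interpolated_boundary(self):
        times = np.arange(0.0, 21.0)
        levels = np.zeros((len(times), 4))
        levels[:, 0] = times * 0.2  # Hb ramp crossing 1.0 at t = 5.0
        traj = Trajectory(times, levels)
        seq = trajectory_to_phases(traj, THR)
        hb_phase = [p for p in seq if p.on_set == frozenset({"Hb"})][0]
        assert hb_phase.start == pytest.approx(5.0, abs=1e-9)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            phases_from_levels(np.zeros((0, 4)), np.zeros(0), np.ones(4))

    def test_reference_circuit_wild_type_sequence(self, reference_params, phenotype_table):
        traj = simulate(reference_params)
        seq = trajectory_to_phases(traj, reference_params.on_thresholds())
        assert seq.on_sets() == list(phenotype_table["wt"].expected)
        assert seq.on_sets()[-1] == frozenset({"Cas"})


class TestIdentityMerging:
    def test_hb_and_hbkr_lead_to_same_fates(self, identity_map):
        seq = [
            Phase(frozenset({"Hb"}), 0, 40),
            Phase(frozenset({"Hb", "Kr"}), 40, 60),
        ]
        merged = merge_identity_phases(seq, identity_map)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (0, 60)

    def test_distinct_identities_untouched(self, identity_map):
        seq = [Phase(frozenset({"Kr"}), 0, 30), Phase(frozenset({"Pdm"}), 30, 60)]
        assert len(merge_identity_phases(seq, identity_map)) == 2

    def test_three_same_identity_phases_merge(self):
        imap = IdentityMap({"Hb": "x", "Kr": "x", "Pdm": "x"})
        seq = [
            Phase(frozenset({"Hb"}), 0, 10),
            Phase(frozenset({"Kr"}), 10, 30),
            Phase(frozenset({"Pdm"}), 30, 35),
        ]
        merged = merge_identity_phases(seq, imap)
        assert len(merged) == 1 and merged[0].duration == 35

    def test_idempotent(self, identity_map):
        seq = PhaseSequence(
            (
                Phase(frozenset({"Hb"}), 0, 40),
                Phase(frozenset({"Hb", "Kr"}), 40, 60),
                Phase(frozenset({"Kr"}), 60, 90),
            )
        )
        once = merge_identity_phases(seq, identity_map)
        twice = merge_identity_phases(once, identity_map)
        assert once == twice

    def test_unmapped_set_raises_naming_it(self, identity_map):
        seq = [Phase(frozenset({"Hb", "Cas"}), 0, 10)]
        with pytest.raises(ValidationError, match="Hb\\+Cas"):
            merge_identity_phases(seq, identity_map)


class TestConsistency:
    def _seqs_from_table(self, table, scale=1.0):
        seqs = {}
        for g in table:
            t = 0.0
            phases = []
            for on_set in g.expected:
                phases.append(Phase(on_set, t, t + 10 * scale))
                t += 10 * scale
            seqs[g.name] = PhaseSequence(tuple(phases))
        return seqs

    def test_sequences_copied_from_table_are_consistent(self, phenotype_table):
        res = check_consistency(self._seqs_from_table(phenotype_table), phenotype_table)
        assert res.consistent

    def test_durations_ignored(self, phenotype_table):
        res = check_consistency(
            self._seqs_from_table(phenotype_table, scale=3.0), phenotype_table
        )
        assert res.consistent

    def test_missing_phase_reported(self, phenotype_table):
        seqs = self._seqs_from_table(phenotype_table)
        wt = list(seqs["wt"].phases)
        dropped = [p for p in wt if p.on_set != frozenset({"Pdm", "Cas"})]
        fixed = []
        t = 0.0
        for p in dropped:
            fixed.append(Phase(p.on_set, t, t + 10))
            t += 10
        seqs["wt"] = PhaseSequence(tuple(fixed))
        res = check_consistency(seqs, phenotype_table)
        assert not res.consistent
        assert res.genotype == "wt" and res.position == 5

    def test_export_as_table(self, phenotype_table):
        from ttftimer import phase_sequences_to_frame

        seqs = self._seqs_from_table(phenotype_table)
        frame = phase_sequences_to_frame(seqs)
        assert list(frame.columns) == ["genotype", "phase_index", "on_set", "start", "end"]
        wt = frame[frame["genotype"] == "wt"]
        assert wt["on_set"].tolist()[0] == "Hb"
        assert len(wt) == len(phenotype_table["wt"].expected)

    def test_missing_genotype_raises(self, phenotype_table):
        with pytest.raises(ValidationError, match="missing phase sequence"):
            check_consistency({}, phenotype_table)


class TestProgenyIdentities:
    def test_square_wave_fates(self, toy_trajectory, identity_map):
        fates = progeny_identities(toy_trajectory, [20, 65], identity_map, THR)
        assert fates == ["fate-1/2", "fate-3"]

    def test_level_at_threshold_counts_as_on(self, identity_map):
        times = np.arange(0.0, 11.0)
        levels = np.zeros((len(times), 4))
        levels[:, 0] = 1.0  # exactly at threshold
        traj = Trajectory(times, levels)
        assert progeny_identities(traj, [5.0], identity_map, THR) == ["fate-1/2"]

    def test_no_ttf_above_threshold_records_none(self, identity_map):
        traj = square_trajectory({}, horizon=50.0)
        assert progeny_identities(traj, [25.0], identity_map, THR) == ["none"]

    def test_four_gmcs_in_180_min_pdm_window(self, identity_map):
        """45-min divisions across a 180-min Pdm window inherit Pdm 4 times."""
        traj = square_trajectory({"Pdm": (90, 270)}, horizon=400.0)
        fates = progeny_identities(traj, None, identity_map, THR)
        assert sum(f == "fate-5/6" for f in fates) == 4

    def test_division_outside_horizon_rejected(self, toy_trajectory, identity_map):
        with pytest.raises(ValidationError):
            progeny_identities(toy_trajectory, [500.0], identity_map, THR)
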