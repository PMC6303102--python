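"""Measurement-side statistics: filtering, stage calling, positioning."""

import numpy as np
import pandas as pd
import pytest

from ttftimer import (
    StageTable,
    ValidationError,
    call_induction_stage,
    filter_by_volume,
    measured_delta_t,
    position_invivo,
    stage_summaries,
    translate_deletion_to_link_range,
)
from ttftimer.invivo import stageable_wild_type


def measurements(volumes, genotype="wt", ttf="Pdm", stage="S10"):
    return pd.DataFrame(
        {
            "genotype": genotype,
            "stage": stage,
            "ttf": ttf,
            "log_ratio": 0.0,
            "volume": volumes,
        }
    )


def summary_table(means, ns=10, sd=0.1, genotype="wt", ttf="Pdm",
                  stages=("S9", "S10E", "S10", "S11E", "S11", "S12")):
    rows = []
    for stage, mean in zip(stages, means):
        rows.append(
            {"genotype": genotype, "ttf": ttf, "stage": stage, "n": ns,
             "mean": mean, "sd": sd, "sem": sd / np.sqrt(ns),
             "ci_half": 1.96 * sd / np.sqrt(ns)}
        )
    return pd.DataFrame(rows)


class TestStageTable:
    def test_lookup(self, stage_table):
        assert stage_table.stage_of(0.0) == "S9"
        assert stage_table.stage_of(stage_table.midpoint("S11")) == "S11"
        assert stage_table.stage_of(10_000.0) is None

    def test_non_contiguous_rejected(self):
        with pytest.raises(ValidationError, match="contiguous"):
            StageTable((("A", 0.0, 10.0), ("B", 12.0, 20.0)))

    def test_hash_tracks_content(self, stage_table):
        other = StageTable((("A", 0.0, 10.0), ("B", 10.0, 20.0)))
        assert stage_table.table_hash != other.table_hash


class TestVolumeFilter:
    def test_identical_volumes_kept(self):
        kept, excluded = filter_by_volume(measurements([5.0] * 10))
        assert len(kept) == 10 and len(excluded) == 0

    def test_planted_outlier_removed(self):
        vols = [100.0, 101, 99, 100, 102, 98, 100, 101, 99, 104.5]
        df = measurements(vols)
        mean, sd = np.mean(vols), np.std(vols, ddof=1)
        assert abs(104.5 - mean) > 2 * sd  # sanity: planted beyond the cut
        kept, excluded = filter_by_volume(df)
        assert excluded["volume"].tolist() == [104.5]

    def test_tiny_dataset_untouched(self):
        kept, excluded = filter_by_volume(measurements([1.0, 100.0]))
        assert len(kept) == 2 and len(excluded) == 0

    def test_statistics_from_wild_type_population(self):
        wt = measurements([100.0, 101, 99, 100, 102, 98, 100, 101, 99, 100])
        mut = measurements([130.0], genotype="kr_del")
        kept, excluded = filter_by_volume(pd.concat([wt, mut], ignore_index=True))
        assert excluded["genotype"].tolist() == ["kr_del"]


class TestSummaries:
    def test_sem_and_ci(self):
        rng = np.random.default_rng(0)
        df = measurements(np.ones(16))
        df["log_ratio"] = rng.normal(1.0, 0.3, 16)
        summ = stage_summaries(df)
        row = summ.iloc[0]
        assert row["n"] == 16
        assert row["sem"] == pytest.approx(row["sd"] / 4.0)
        assert row["ci_half"] == pytest.approx(1.96 * row["sem"])


class TestInductionCalling:
    def test_flat_profile_returns_none(self, stage_table):
        summ = summary_table([0, 0, 0, 0, 0, 0])
        assert call_induction_stage(summ, summ, "wt", "Pdm", stage_table.stages) is None

    def test_planted_induction_called(self, stage_table):
        summ = summary_table([0, 0, 0, 1.0, 1.0, 1.0])
        assert call_induction_stage(summ, summ, "wt", "Pdm", stage_table.stages) == "S11E"

    def test_first_stage_skipped_for_transients(self, stage_table):
        summ = summary_table([2.0, 0, 0, 0, 0, 0])  # S9 burst only
        assert call_induction_stage(summ, summ, "wt", "Pdm", stage_table.stages) is None

    def test_invariant_under_constant_offset(self, stage_table):
        base = summary_table([0, 0.02, -0.01, 0.9, 1.0, 1.0])
        shifted = base.copy()
        shifted["mean"] = shifted["mean"] + 7.5
        call = lambda s: call_induction_stage(s, s, "wt", "Pdm", stage_table.stages)
        assert call(base) == call(shifted) == "S11E"

    def test_missing_background_stage_rejected(self, stage_table):
        summ = summary_table([0, 1.0], stages=("S9", "S11"))
        with pytest.raises(ValidationError, match="background"):
            call_induction_stage(summ, summ, "wt", "Pdm", stage_table.stages)


class TestMeasuredShift:
    def test_same_stage_interval_contains_zero(self, stage_table):
        shift = measured_delta_t("S11", "S11", stage_table)
        assert shift.delta_pct == 0.0
        assert shift.lo < 0 < shift.hi

    def test_halved_midpoint_is_minus_fifty(self):
        table = StageTable((("A", 75.0, 125.0), ("B", 125.0, 275.0)))
        shift = measured_delta_t("B", "A", table)
        assert shift.delta_pct == pytest.approx(-50.0)

    def test_two_cell_cycle_advance(self):
        """A 90-min advance from a 200-min induction is a ~45% advance."""
        table = StageTable((("early", 87.5, 132.5), ("mid", 132.5, 177.5),
                            ("late", 177.5, 222.5)))
        shift = measured_delta_t("late", "early", table)
        assert shift.delta_pct == pytest.approx(-45.0)

    def test_left_censoring_reaches_full_advance(self, stage_table):
        shift = measured_delta_t("S11", "S10E", stage_table, censored_left=True)
        assert shift.lo == pytest.approx(-100.0)

    def test_uncalled_stage_rejected(self, stage_table):
        with pytest.raises(ValidationError):
            measured_delta_t(None, "S11", stage_table)


def scored(xs, ys, scores=None):
    df = pd.DataFrame({"d_pdm_del_hb": xs, "d_pdm_rm_decay": ys})
    df["robustness_score"] = 90.0 if scores is None else scores
    return df


class TestTranslation:
    def test_full_range_returned(self):
        df = scored([-80, -60, -40], [-90, -70, -50])
        assert translate_deletion_to_link_range(df, (-100, 0), "pdm_hb") == (-90, -50)

    def test_degenerate_range_single_record(self):
        df = scored([-80, -60, -40], [-90, -70, -50])
        lo, hi = translate_deletion_to_link_range(df, (-61, -59), "pdm_hb")
        assert lo == hi == -70

    def test_widening_measured_range_never_narrows_output(self):
        rng = np.random.default_rng(5)
        xs = -100 * rng.random(40)
        df = scored(xs, xs + rng.normal(0, 3, 40))
        prev = (np.inf, -np.inf)
        for half in (5, 15, 30, 60):
            lo, hi = translate_deletion_to_link_range(df, (-50 - half, -50 + half), "pdm_hb")
            assert lo <= prev[0] and hi >= prev[1]
            prev = (lo, hi)

    def test_no_robust_record_in_range_reports_nearest(self):
        df = scored([-95, -90], [-95, -90])
        with pytest.raises(ValidationError, match="nearest"):
            translate_deletion_to_link_range(df, (-20, -10), "pdm_hb")

    def test_low_scores_excluded(self):
        df = scored([-60, -60], [-70, -10], scores=[90.0, 10.0])
        assert translate_deletion_to_link_range(df, (-70, -50), "pdm_hb") == (-70, -70)


class TestPositioning:
    def norms(self):
        return {"pdm_decay": 100.0, "pdm_relay": 200.0,
                "cas_decay": 80.0, "cas_relay": 150.0}

    def test_zero_ranges_at_origin(self, stage_table):
        ranges = {k: (0.0, 0.0) for k in self.norms()}
        pos = position_invivo(ranges, self.norms(), stage_table)
        assert pos.decay_significance == 0.0 and pos.relay_significance == 0.0

    def test_pdm_full_advance_contributes_its_maximum(self, stage_table):
        ranges = {"pdm_decay": (-100.0, -100.0), "pdm_relay": (0.0, 0.0),
                  "cas_decay": (0.0, 0.0), "cas_relay": (0.0, 0.0)}
        pos = position_invivo(ranges, self.norms(), stage_table)
        assert pos.decay_significance == pytest.approx(50.0)  # (100 + 0) / 2

    def test_error_bars_from_range_endpoints(self, stage_table):
        ranges = {"pdm_decay": (-80.0, -40.0), "pdm_relay": (0.0, 0.0),
                  "cas_decay": (-40.0, -40.0), "cas_relay": (0.0, 0.0)}
        pos = position_invivo(ranges, self.norms(), stage_table)
        assert pos.decay_range[0] == pytest.approx((40.0 + 50.0) / 2)
        assert pos.decay_range[1] == pytest.approx((80.0 + 50.0) / 2)

    def test_missing_normalizer_rejected(self, stage_table):
        ranges = {k: (0.0, 0.0) for k in self.norms()}
        with pytest.raises(ValidationError, match="cas_relay"):
            position_invivo(ranges, {"pdm_decay": 100.0, "pdm_relay": 1.0,
                                     "cas_decay": 1.0}, stage_table)


class TestStageableWildType:
    def test_background_stage_induction_not_stageable(self, stage_table):
        assert not stageable_wild_type(45.0, 150.0, stage_table)  # Pdm in S10

    def test_callable_wild_type(self, stage_table):
        assert stageable_wild_type(70.0, 150.0, stage_table)

    def test_last_stage_not_stageable(self, stage_table):
        assert not stageable_wild_type(70.0, 300.0, stage_table)  # Cas in S12
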