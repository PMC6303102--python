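"""Induction shifts, Decay-Relay significance coordinates, correlations, maps."""

import numpy as np
import pandas as pd
import pytest

from ttftimer import (
    NOT_INDUCED,
    Perturbation,
    ValidationError,
    compute_perturbation_shifts,
    delta_t_ind,
    deletion_sensitivity,
    deletion_vs_link_correlation,
    density_map,
    induction_time,
    significance_scores,
    simulate,
)
from ttftimer.decay_relay import classify_regime

from conftest import square_trajectory

THR = 1.0


class TestInductionTime:
    def test_monotone_rise(self):
        from ttftimer import Trajectory

        times = np.arange(0.0, 401.0)
        levels = np.zeros((len(times), 4))
        levels[:, 2] = np.maximum(times - 100.0, 0.0) * 0.05  # crosses 1.0 at t=120
        traj = Trajectory(times, levels)
        assert induction_time(traj, "Pdm", THR) == pytest.approx(120.0)

    def test_short_transient_discounted(self):
        traj = square_trajectory({"Pdm": (10, 15)})
        t2 = square_trajectory({"Pdm": (150, 400)})
        both = traj.levels + t2.levels
        from ttftimer import Trajectory

        merged = Trajectory(traj.times, both)
        assert induction_time(merged, "Pdm", THR, sustain=10.0) == pytest.approx(150.0, abs=1.0)

    def test_flat_zero_not_induced(self):
        traj = square_trajectory({})
        assert induction_time(traj, "Pdm", THR) is NOT_INDUCED


class TestDeltaTInd:
    def test_formula(self):
        assert delta_t_ind(100.0, 200.0) == pytest.approx(-50.0)

    def test_no_change(self):
        assert delta_t_ind(130.0, 130.0) == 0.0

    def test_capped_at_horizon(self):
        assert delta_t_ind(NOT_INDUCED, 100.0, horizon=400.0) == pytest.approx(300.0)

    def test_uninduced_wild_type_rejected(self):
        with pytest.raises(ValidationError):
            delta_t_ind(100.0, NOT_INDUCED)


class TestFixtureShifts:
    def test_link_removal_shift_signs(self, reference_params, topology):
        """Losing the repressor-decay input advances Pdm; losing the
        activator-relay input can only delay it."""
        on = reference_params.on_thresholds()
        sustain = reference_params.constants.sustain
        t_wt = induction_time(simulate(reference_params, topology), "Pdm", on["Pdm"], sustain)
        t_decay = induction_time(
            simulate(reference_params, topology, Perturbation.remove_link("Hb-|Pdm")),
            "Pdm", on["Pdm"], sustain,
        )
        t_relay = induction_time(
            simulate(reference_params, topology, Perturbation.remove_link("Kr->Pdm")),
            "Pdm", on["Pdm"], sustain,
        )
        assert delta_t_ind(t_decay, t_wt) < 0
        assert delta_t_ind(t_relay, t_wt, horizon=400.0) >= 0


def synthetic_records(n=12, seed=0):
    """Hand-built shift records with known structure."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "d_pdm_rm_decay": -90 + 10 * rng.random(n),
            "d_pdm_rm_relay": 5 * rng.random(n),
            "d_cas_rm_decay": -60 + 30 * rng.random(n),
            "d_cas_rm_relay": 20 * rng.random(n),
        }
    )
    for c in list(df.columns):
        df["capped_" + c[2:]] = False
    return df


class TestSignificance:
    def test_ensemble_max_normalizes_to_hundred(self):
        df = significance_scores(synthetic_records())
        for col in ("n_pdm_rm_decay", "n_pdm_rm_relay", "n_cas_rm_decay", "n_cas_rm_relay"):
            assert df[col].max() == pytest.approx(100.0)
            assert df[col].min() >= 0.0

    def test_zero_shift_gives_zero_decay_significance(self):
        df = synthetic_records()
        df.loc[0, ["d_pdm_rm_decay", "d_cas_rm_decay"]] = 0.0
        out = significance_scores(df)
        assert out.loc[0, "decay_significance"] == pytest.approx(0.0)

    def test_record_at_both_maxima_scores_hundred(self):
        df = synthetic_records()
        df.loc[1, "d_pdm_rm_decay"] = df["d_pdm_rm_decay"].min() - 5
        df.loc[1, "d_cas_rm_decay"] = df["d_cas_rm_decay"].min() - 5
        out = significance_scores(df)
        assert out.loc[1, "decay_significance"] == pytest.approx(100.0)

    def test_empty_records_rejected(self):
        with pytest.raises(ValidationError):
            significance_scores(pd.DataFrame())

    def test_no_crosstalk_between_links_and_deletions(self):
        df = synthetic_records()
        df["d_pdm_del_hb"] = -50.0
        df["d_pdm_del_kr"] = 5.0
        base = significance_scores(df)
        mutated = df.copy()
        mutated["d_pdm_del_hb"] = 99.0  # deletion shifts must not move significance
        assert significance_scores(mutated)["decay_significance"].equals(
            base["decay_significance"]
        )
        sens = deletion_sensitivity(df)
        mutated2 = df.copy()
        mutated2["d_pdm_rm_decay"] = 0.0  # link shifts must not move deletion axes
        assert deletion_sensitivity(mutated2)["hb_deletion_shift"].equals(
            sens["hb_deletion_shift"]
        )

    def test_regime_classification_bands(self):
        labels = classify_regime(np.array([90.0, 50.0, 5.0]), np.array([5.0, 50.0, 90.0]))
        assert labels.tolist() == ["decay", "mixed", "relay"]


class TestCorrelations:
    def test_perfectly_coupled_shifts(self):
        df = synthetic_records(n=15)
        df["d_pdm_del_hb"] = df["d_pdm_rm_decay"]
        df["d_pdm_del_kr"] = df["d_pdm_rm_relay"]
        df["d_cas_del_kr"] = df["d_cas_rm_decay"]
        df["d_cas_del_pdm"] = df["d_cas_rm_relay"]
        for c in ("capped_pdm_del_hb", "capped_pdm_del_kr",
                  "capped_cas_del_kr", "capped_cas_del_pdm"):
            df[c] = False
        res = deletion_vs_link_correlation(df)
        for pair in res.values():
            assert pair.r_all == pytest.approx(1.0)

    def test_degenerate_variance_is_nan(self):
        df = synthetic_records(n=15)
        for col in ("d_pdm_del_hb", "d_pdm_del_kr", "d_cas_del_kr", "d_cas_del_pdm"):
            df[col] = 1.0
            df["capped_" + col[2:]] = False
        res = deletion_vs_link_correlation(df)
        assert np.isnan(res["pdm_hb"].r_all)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValidationError):
            deletion_vs_link_correlation(synthetic_records(n=5))


class TestDensityMap:
    def test_single_record(self):
        dm = density_map(np.array([37.0]), np.array([61.0]))
        assert dm.counts.sum() == 1

    def test_counts_conserved(self):
        rng = np.random.default_rng(1)
        x, y = 100 * rng.random(250), 100 * rng.random(250)
        dm = density_map(x, y, values=rng.random(250))
        assert dm.counts.sum() == 250

    def test_empty_bins_absent_in_mean(self):
        dm = density_map(np.array([7.0]), np.array([7.0]), values=np.array([42.0]))
        assert np.isnan(dm.mean).sum() == dm.mean.size - 1
        js = dm.to_json()
        flat = [v for row in js["mean"] for v in row if v is not None]
        assert flat == [pytest.approx(42.0)]


class TestPerturbationShiftPipeline:
    def test_adds_shift_columns_for_consistent_rows(self, reference_params, topology):
        row = reference_params.to_row(topology)
        row["consistent"] = True
        df = pd.DataFrame([row])
        on = reference_params.on_thresholds()
        traj = simulate(reference_params, topology)
        for ttf in topology.ttfs:
            t = induction_time(traj, ttf, on[ttf], reference_params.constants.sustain)
            df[f"t_wt_{ttf}"] = np.nan if t is NOT_INDUCED else t
        out = compute_perturbation_shifts(df, topology)
        assert out.loc[0, "d_pdm_rm_decay"] < 0
        assert out.loc[0, "d_pdm_rm_relay"] >= 0
        assert not out.loc[0, "capped_pdm_rm_decay"]
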