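"""Generator determinism, structural validity, and analytic ground truth."""

import numpy as np
import pandas as pd
import pytest

from teamsync import event_model, synthetic
from teamsync.errors import ConfigError, PairingError
from teamsync.synthetic import (
    MatchSimConfig,
    StroopSimConfig,
    analytic_relative_connectivity,
    female14,
    ground_truth_report,
    male16,
    male_stroop_preset,
    simulate_experiment,
    simulate_stroop,
)


class TestMatchSimConfig:
    def test_position_counts_must_sum_to_matches(self):
        with pytest.raises(ConfigError):
            MatchSimConfig(n_matches=10, wR_position_counts=(6, 6, 4))

    def test_out_of_range_probability_clipped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="teamsync.synthetic"):
            cfg = MatchSimConfig(n_matches=16, base_pass_success=0.9, effect_Sy=0.2)
        assert cfg.pass_success("Sy") == 1.0
        assert any("clipped" in rec.message for rec in caplog.records)

    def test_presets_inject_reported_magnitudes(self):
        cfg = male16()
        assert analytic_relative_connectivity(cfg, "Sy") == pytest.approx(0.04)
        assert analytic_relative_connectivity(cfg, "nS") == pytest.approx(-0.08)
        null = female14()
        assert analytic_relative_connectivity(null, "Sy") == 0.0


class TestSimulateExperiment:
    def test_deterministic_from_seed(self):
        a = simulate_experiment(male16(seed=42))
        b = simulate_experiment(male16(seed=42))
        pd.testing.assert_frame_equal(a.possessions, b.possessions)
        assert [s.thirds for s in a.schedules] == [s.thirds for s in b.schedules]

    def test_generated_tables_pass_validation(self, tmp_path, male_sim):
        path = tmp_path / "sim.csv"
        event_model.write_possession_table(male_sim.possessions, path)
        records = event_model.read_possession_table(path)
        assert len(records) == len(male_sim.possessions)

    def test_each_team_match_has_one_third_per_condition(self, male_sim):
        summaries = event_model.summarize_thirds(male_sim.possessions)
        counts = summaries.groupby(["match_id", "team_id"])["condition"].agg(
            lambda c: sorted(c)
        )
        assert len(counts) == 32
        assert all(c == ["Sy", "nS", "wR"] for c in counts)

    def test_wr_positions_honored_exactly(self, male_sim):
        slots = [s.thirds.index("wR") for s in male_sim.schedules]
        assert sorted(np.bincount(slots, minlength=3)) == sorted((6, 6, 4))
        assert np.bincount(slots, minlength=3).sum() == 16

    def test_ns_third_uses_the_five_personal_tempi(self, male_sim):
        for schedule in male_sim.schedules:
            assert tuple(sorted(schedule.ns_tempi.values())) == event_model.NS_TEMPI

    def test_opposing_team_mirrors_cras_conditions(self, male_sim):
        frame = male_sim.possessions
        for match_id, sub in frame.groupby("match_id"):
            pivot = sub.groupby(["order_index"]).first()  # same third ordering
            teams = sub["team_id"].unique()
            conds = {
                t: set(sub[sub.team_id == t]["condition"].unique()) for t in teams
            }
            assert all(c == {"wR", "Sy", "nS"} for c in conds.values())


class TestGeometricPossessionModel:
    def test_connectivity_converges_to_pass_success(self):
        cfg = MatchSimConfig(
            n_matches=30, wR_position_counts=(10, 10, 10), possession_rate=8.0, seed=3
        )
        sim = simulate_experiment(cfg)
        summaries = event_model.summarize_thirds(sim.possessions)
        c_hat = summaries["n_p"].sum() / summaries["n_c"].sum()
        assert c_hat == pytest.approx(cfg.base_pass_success, abs=0.01)

    def test_mean_passes_per_possession_is_geometric(self):
        cfg = MatchSimConfig(
            n_matches=30, wR_position_counts=(10, 10, 10), possession_rate=8.0, seed=4
        )
        sim = simulate_experiment(cfg)
        q = cfg.base_pass_success
        mean_passes = sim.possessions["n_passes"].mean()
        assert mean_passes == pytest.approx(q / (1 - q), rel=0.03)

    def test_contacts_exceed_passes_by_one(self, male_sim):
        frame = male_sim.possessions
        assert ((frame["n_contacts"] - frame["n_passes"]) == 1).all()


class TestSimulateStroop:
    def test_deterministic_from_seed(self):
        a = simulate_stroop(male_stroop_preset(seed=9))
        b = simulate_stroop(male_stroop_preset(seed=9))
        pd.testing.assert_frame_equal(a.trials, b.trials)

    def test_study_group_sizes_reproduced_exactly(self, stroop_sim):
        trials = stroop_sim.trials
        for (gender, phase), sizes in synthetic.TABLE1_GROUP_SIZES.items():
            label = phase if phase is not None else "not_applicable"
            for tempo, n in sizes.items():
                sub = trials[
                    (trials.gender == gender)
                    & (trials.phase == label)
                    & (trials.tempo_bpm == tempo)
                ]
                assert sub["participant_id"].nunique() == n

    def test_block_run_trial_structure(self, stroop_sim):
        per = stroop_sim.trials.groupby(["participant_id", "block", "run"]).agg(
            n=("rt_s", "size"), congruent=("congruent", "sum")
        )
        assert (per["n"] == 48).all() and (per["congruent"] == 24).all()

    def test_tempo_only_in_music_block(self, stroop_sim):
        trials = stroop_sim.trials
        assert trials.loc[trials.block != 2, "tempo_bpm"].isna().all()
        assert trials.loc[trials.block == 2, "tempo_bpm"].notna().all()

    def test_round_trip_through_csv(self, tmp_path):
        sim = simulate_stroop(male_stroop_preset(seed=5))
        path = tmp_path / "stroop.csv"
        event_model.write_stroop_table(sim.trials, path)
        records = event_model.read_stroop_table(path)
        assert len(records) == len(sim.trials)

    def test_true_median_matches_large_sample(self):
        cfg = StroopSimConfig(
            group_sizes={("male", None): {140: 60}},
            tempo_effects={("male", None): {140: -0.065}},
            seed=6,
        )
        sim = simulate_stroop(cfg)
        from teamsync.stroop import select_trials

        selected = select_trials(sim.trials)
        empirical = selected["rt_s"].median()
        assert empirical == pytest.approx(cfg.true_median("male", None, 140), rel=0.02)

    def test_negative_unit_effect_rejected(self):
        with pytest.raises(ConfigError):
            StroopSimConfig(tempo_effects={("male", None): {140: -1.0}})


class TestGroundTruthReport:
    def test_pairing_error_on_mismatched_runs(self, male_sim):
        with pytest.raises(PairingError):
            ground_truth_report(
                male_sim.ground_truth, {"run_id": "other", "values": {}}
            )

    def test_recovery_table_columns(self, male_sim):
        report = ground_truth_report(
            male_sim.ground_truth,
            {
                "run_id": male_sim.ground_truth["run_id"],
                "values": {"Sy": 0.041, "nS": -0.079},
                "errors": {"Sy": 0.01, "nS": 0.01},
            },
        )
        assert len(report) == 2
        assert report.set_index("quantity").loc["Sy", "injected"] == pytest.approx(0.04)
        assert "difference" in report.columns

    def test_single_replicate_single_row(self, male_sim):
        report = ground_truth_report(
            male_sim.ground_truth,
            {"run_id": male_sim.ground_truth["run_id"], "values": {"Sy": 0.04}},
        )
        assert len(report) == 1
        assert report["difference"].iloc[0] == pytest.approx(0.0)
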