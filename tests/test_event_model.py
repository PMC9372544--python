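"""Possession/Stroop record validation, CSV round-trips, aggregation."""

import pandas as pd
import pytest

from teamsync import event_model
from teamsync.errors import SchemaError, ValidationError
from teamsync.event_model import (
    ConditionSchedule,
    Possession,
    StroopTrial,
    possessions_to_frame,
    rate_normalize,
    read_possession_table,
    read_stroop_table,
    summarize_thirds,
    write_possession_table,
    write_stroop_table,
)


class TestPossessionInvariants:
    def test_more_passes_than_contacts_rejected(self):
        with pytest.raises(ValidationError, match="exceeds"):
            Possession("M1", "T1", "wR", 0, 4, 3, False)

    def test_zero_contacts_rejected(self):
        with pytest.raises(ValidationError, match="contact"):
            Possession("M1", "T1", "wR", 0, 0, 0, False)

    def test_one_touch_play_is_legal(self):
        # reception simultaneously is the pass: n_passes == n_contacts
        p = Possession("M1", "T1", "Sy", 0, 4, 4, False)
        assert p.n_passes == p.n_contacts

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValidationError, match="condition"):
            Possession("M1", "T1", "XX", 0, 1, 2, False)

    def test_goal_without_pass_is_legal(self):
        assert Possession("M1", "T1", "nS", 0, 0, 1, True).goal


class TestConditionSchedule:
    def test_each_condition_once(self):
        with pytest.raises(ValidationError):
            ConditionSchedule("M1", ("Sy", "Sy", "wR"), {})

    def test_five_player_tempo_set_enforced(self):
        tempi = {f"p{i}": t for i, t in enumerate([119, 133, 147, 154, 161])}
        sched = ConditionSchedule("M1", ("wR", "Sy", "nS"), tempi)
        assert sched.mirrored().thirds == ("wR", "nS", "Sy")
        bad = dict(tempi, p0=140)
        with pytest.raises(ValidationError, match="tempo"):
            ConditionSchedule("M1", ("wR", "Sy", "nS"), bad)


class TestPossessionIO:
    def test_three_row_file_round_trip(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text(
            "match_id,team_id,condition,order_index,n_passes,n_contacts,goal\n"
            "M1,T1,wR,0,3,5,1\nM1,T1,Sy,0,2,2,0\nM1,T2,nS,0,0,1,0\n"
        )
        records = read_possession_table(path)
        assert len(records) == 3
        assert records[0].goal and not records[1].goal
        out = tmp_path / "q.csv"
        write_possession_table(records, out)
        assert out.read_bytes() == path.read_bytes()

    def test_invalid_row_reports_row_number(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text(
            "match_id,team_id,condition,order_index,n_passes,n_contacts,goal\n"
            "M1,T1,wR,0,1,2,0\nM1,T1,wR,1,4,3,0\n"
        )
        with pytest.raises(ValidationError, match="row 2"):
            read_possession_table(path)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("match_id,team_id,condition,order_index,n_passes,goal\nM1,T1,wR,0,1,0\n")
        with pytest.raises(SchemaError, match="n_contacts"):
            read_possession_table(path)

    def test_simulated_table_round_trips_identically(self, tmp_path, male_sim):
        path = tmp_path / "sim.csv"
        write_possession_table(male_sim.possessions, path)
        records = read_possession_table(path)
        path2 = tmp_path / "sim2.csv"
        write_possession_table(records, path2)
        assert path.read_bytes() == path2.read_bytes()
        pd.testing.assert_frame_equal(
            possessions_to_frame(records),
            possessions_to_frame(male_sim.possessions).astype(
                possessions_to_frame(records).dtypes.to_dict()
            ),
        )


class TestSummarizeThirds:
    def test_hand_summed_totals(self, tiny_possessions):
        summary = summarize_thirds(tiny_possessions).iloc[0]
        assert (summary.n_p, summary.n_c, summary.goals, summary.N0) == (3, 7, 1, 1)

    def test_all_zero_pass_possessions(self):
        poss = [Possession("M1", "T1", "wR", i, 0, 1, False) for i in range(4)]
        summary = summarize_thirds(poss).iloc[0]
        assert summary.n_p == 0 and summary.N0 == 4

    def test_empty_input_gives_empty_output(self):
        assert summarize_thirds([]).empty

    def test_additive_over_partitions(self, male_sim):
        frame = possessions_to_frame(male_sim.possessions)
        whole = summarize_thirds(frame).set_index(["match_id", "team_id", "condition"])
        part = pd.concat(
            [summarize_thirds(frame.iloc[::2]), summarize_thirds(frame.iloc[1::2])]
        )
        recombined = (
            part.groupby(["match_id", "team_id", "condition"])[["n_p", "n_c", "goals", "N0"]]
            .sum()
        )
        pd.testing.assert_frame_equal(
            whole[["n_p", "n_c", "goals", "N0"]].sort_index(), recombined.sort_index()
        )

    def test_matches_simulator_tallies(self, male_sim):
        merged = summarize_thirds(male_sim.possessions).merge(
            male_sim.tallies, on=["match_id", "team_id", "condition"], suffixes=("", "_sim")
        )
        for col in ("n_p", "n_c", "goals", "N0"):
            assert (merged[col] == merged[col + "_sim"]).all()


class TestRateNormalize:
    def test_per_minute_rates(self):
        frame = pd.DataFrame(
            dict(match_id=["M1"], team_id=["T1"], condition=["wR"],
                 n_p=[60], n_c=[80], goals=[0], N0=[5], duration_min=[10.0])
        )
        rates = rate_normalize(frame, 10.0)
        assert rates.loc[0, "n_p_per_min"] == 6.0
        assert rates.loc[0, "goals_per_min"] == 0.0

    def test_non_positive_duration_rejected(self):
        with pytest.raises(ValueError):
            rate_normalize(pd.DataFrame(), 0.0)

    def test_rates_comparable_across_experiment_sizes(self, male_sim, null_sim):
        # totals normalized by playing time must not scale with match count
        for sim, n_matches in ((male_sim, 16), (null_sim, 14)):
            summaries = summarize_thirds(sim.possessions)
            total_minutes = 10.0 * 3 * 2 * n_matches
            rate = rate_normalize(
                summaries[["n_p", "n_c", "goals", "N0"]].sum().to_frame().T.assign(
                    match_id="all", team_id="all", condition="wR", duration_min=1.0
                ),
                total_minutes,
            )["n_p_per_min"].iloc[0]
            # per-minute pass rate of one team is rate * ... sanity band only
            assert 1.0 < rate < 20.0


class TestStroopIO:
    def _rows(self):
        return [
            StroopTrial("P1", "male", "not_applicable", None, 1, "neutral", True, 0.9),
            StroopTrial("P1", "male", "not_applicable", 140, 2, "stroop", False, 1.4),
            StroopTrial("P1", "male", "not_applicable", None, 3, "stroop", False, 1.2),
        ]

    def test_round_trip(self, tmp_path):
        path = tmp_path / "s.csv"
        write_stroop_table(self._rows(), path)
        records = read_stroop_table(path)
        assert [t.tempo_bpm for t in records] == [None, 140, None]
        path2 = tmp_path / "s2.csv"
        write_stroop_table(records, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_tempo_outside_music_block_rejected(self):
        with pytest.raises(ValidationError, match="block 2"):
            StroopTrial("P1", "male", "not_applicable", 140, 1, "neutral", True, 0.9)

    def test_two_tempi_per_participant_rejected(self, tmp_path):
        rows = self._rows() + [
            StroopTrial("P1", "male", "not_applicable", 180, 2, "stroop", False, 1.0)
        ]
        path = tmp_path / "s.csv"
        write_stroop_table(rows, path)
        with pytest.raises(ValidationError, match="one tempo"):
            read_stroop_table(path)

    def test_non_positive_rt_rejected(self):
        with pytest.raises(ValidationError, match="rt"):
            StroopTrial("P1", "male", "not_applicable", None, 1, "neutral", True, 0.0)
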