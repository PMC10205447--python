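"""Activity generation: participation, durations, sequences, schedules."""

import numpy as np
import pandas as pd
import pytest

from mobisynth import activities as act
from mobisynth.activities import (anchor_and_build_schedule, diary_features,
                                  durations_satisfy, match_sequences,
                                  sample_durations)


@pytest.fixture(scope="module")
def survey_features(small_world):
    return diary_features(small_world.survey_persons, small_world.survey_diary)


class TestParticipation:
    def test_always_contains_home(self, survey_features, rng):
        model = act.ParticipationModel(survey_features)
        for _ in range(500):
            assert "H" in model.sample(rng.integers(2), rng.integers(2), rng)

    def test_degenerate_distribution(self, rng):
        feats = pd.DataFrame({"participation": ["H"] * 10,
                              "employment": [0] * 10, "studenthood": [0] * 10})
        model = act.ParticipationModel(feats)
        assert model.sample(0, 0, rng) == "H"

    def test_workers_likelier_to_work(self, survey_features, rng):
        model = act.ParticipationModel(survey_features)
        freq = {e: np.mean([("W" in model.sample(e, 0, rng)) for _ in range(2000)])
                for e in (0, 1)}
        assert freq[1] > freq[0] + 0.3


class TestDurationConstraint:
    def test_sum_inside_band_accepted(self):
        # travel class (1, 2]: activity total must fall in [22, 23)
        assert durations_satisfy({"H": 14, "W": 8, "S": 0, "O": 0}, (1.0, 2.0))

    def test_upper_bound_strict(self):
        assert not durations_satisfy({"H": 15, "W": 8}, (1.0, 2.0))  # sum 23

    def test_lower_bound_inclusive(self):
        assert durations_satisfy({"H": 22.0}, (1.0, 2.0))

    def test_point_masses_inside_band_accepted_first_try(self, rng):
        class PointMass:
            def sample(self, purpose, cls, rng):
                return {"H": 14.0, "W": 8.5}[purpose]
        draw, flagged = sample_durations("HW", {"H": "moderate", "W": "moderate"},
                                         (1.0, 2.0), PointMass(), rng)
        assert draw == {"H": 14.0, "W": 8.5}
        assert not flagged

    def test_fallback_rescales_to_band_midpoint(self, rng):
        class Impossible:
            def sample(self, purpose, cls, rng):
                return 20.0  # sum always 40, never feasible
        draw, flagged = sample_durations("HW", {"H": "high", "W": "high"},
                                         (1.0, 2.0), Impossible(), rng, max_tries=5)
        assert flagged
        assert sum(draw.values()) == pytest.approx(22.5)  # midpoint of [22, 23)

    def test_home_only_day_fills_24h(self, rng):
        draw, flagged = sample_durations("H", {"H": "low"}, (0.0, 0.5), None, rng)
        assert draw == {"H": 24.0} and not flagged


class TestMatchSequence:
    def _agents(self, rows):
        return pd.DataFrame(rows, columns=["PId", "participation", "gender",
                                           "age", "employment", "studenthood"])

    def _donors(self, rows):
        return pd.DataFrame(rows, columns=["respondent_id", "participation",
                                           "gender", "age", "employment",
                                           "studenthood", "t_H", "t_W", "t_S",
                                           "t_O", "sequence"])

    def test_single_matching_donor_wins(self):
        donors = self._donors([(1, "HW", "Male", 40, 1, 0, 14, 8, 0, 0,
                                ["H", "W", "H"])])
        agents = self._agents([(1, "HW", "Female", 30, 1, 0)])
        durs = pd.DataFrame({"t_H": [15.0], "t_W": [7.0], "t_S": [0.0], "t_O": [0.0]})
        seqs, fb = match_sequences(agents, durs, donors)
        assert seqs.iloc[0] == ["H", "W", "H"]
        assert not fb.iloc[0]

    def test_euclidean_distance_decides(self):
        # agent (13,8,0,3): sqrt(61) to donor 1, sqrt(2) to donor 2
        donors = self._donors([
            (1, "HOW", "Male", 40, 1, 0, 8, 8, 0, 8, ["H", "W", "O", "H"]),
            (2, "HOW", "Male", 40, 1, 0, 14, 8, 0, 2, ["H", "O", "W", "H"])])
        agents = self._agents([(1, "HOW", "Male", 40, 1, 0)])
        durs = pd.DataFrame({"t_H": [13.0], "t_W": [8.0], "t_S": [0.0], "t_O": [3.0]})
        seqs, _ = match_sequences(agents, durs, donors)
        assert seqs.iloc[0] == ["H", "O", "W", "H"]

    def test_tie_broken_by_lower_respondent_id(self):
        donors = self._donors([
            (7, "HW", "Male", 40, 1, 0, 14, 8, 0, 0, ["H", "W", "H"]),
            (2, "HW", "Male", 40, 1, 0, 16, 8, 0, 0, ["H", "W", "O", "H"])])
        agents = self._agents([(1, "HW", "Male", 40, 1, 0)])
        durs = pd.DataFrame({"t_H": [15.0], "t_W": [8.0], "t_S": [0.0], "t_O": [0.0]})
        seqs, _ = match_sequences(agents, durs, donors)
        assert seqs.iloc[0] == ["H", "W", "O", "H"]  # rid 2 wins the tie

    def test_no_donor_falls_back_to_canonical(self):
        donors = self._donors([(1, "HW", "Male", 40, 1, 0, 14, 8, 0, 0,
                                ["H", "W", "H"])])
        agents = self._agents([(1, "HOS", "Male", 12, 0, 1)])
        durs = pd.DataFrame({"t_H": [14.0], "t_W": [0.0], "t_S": [6.0], "t_O": [2.0]})
        seqs, fb = match_sequences(agents, durs, donors)
        assert seqs.iloc[0] == ["H", "S", "O", "H"]
        assert fb.iloc[0]

    def test_equals_brute_force_nearest_neighbour(self, survey_features, rng):
        """Grouped matcher equals exhaustive per-agent search (<=500 donors)."""
        assert_matches_brute_force(survey_features.head(500), rng)


def assert_matches_brute_force(donors, rng, n_q=100):
    """Check match_sequences against an exhaustive per-agent search."""
    assert len(donors) <= 500
    parts = donors["participation"].unique()
    agents = pd.DataFrame({
        "PId": np.arange(n_q),
        "participation": rng.choice(parts, n_q),
        "gender": rng.choice(["Male", "Female"], n_q),
        "age": rng.integers(6, 85, n_q),
        "employment": rng.integers(0, 2, n_q),
        "studenthood": rng.integers(0, 2, n_q),
    })
    durs = pd.DataFrame({
        f"t_{p}": np.where([p in s for s in agents["participation"]],
                           rng.uniform(0.5, 16, n_q), 0.0)
        for p in "HWSO"})
    seqs, _ = match_sequences(agents, durs, donors)

    from mobisynth import vocab
    d2 = donors.copy()
    d2["age_band"] = d2["age"].map(vocab.age_to_band)
    for i in range(n_q):
        pool = d2[d2["participation"] == agents.at[i, "participation"]]
        keyvals = {"gender": agents.at[i, "gender"],
                   "age_band": vocab.age_to_band(int(agents.at[i, "age"])),
                   "employment": agents.at[i, "employment"],
                   "studenthood": agents.at[i, "studenthood"]}
        attrs = ["gender", "age_band", "employment", "studenthood"]
        cand = None
        for k in range(len(attrs), -1, -1):
            m = np.ones(len(pool), dtype=bool)
            for a in attrs[:k]:
                m &= (pool[a] == keyvals[a]).to_numpy()
            if m.any():
                cand = pool[m]
                break
        x = durs.loc[i, ["t_H", "t_W", "t_S", "t_O"]].to_numpy(float)
        dist = np.sqrt(((cand[["t_H", "t_W", "t_S", "t_O"]].to_numpy(float)
                         - x) ** 2).sum(axis=1))
        best = np.lexsort((cand["respondent_id"].to_numpy(), dist))[0]
        assert seqs.iloc[i] == list(cand["sequence"].iloc[best])


class TestSchedule:
    def test_worked_example_h_w_h(self):
        # t_W=8, t_H=14.5, travel 1.5 -> H 3.00-10.25, W 11.00-19.00, H 19.75-3.00
        s = anchor_and_build_schedule(1, ["H", "W", "H"], {"H": 14.5, "W": 8.0},
                                      (1.0, 2.0))
        eps = s.episodes
        assert [e["purpose"] for e in eps] == ["H", "W", "H"]
        assert eps[0]["end_rel"] == pytest.approx(7.25)    # clock 10.25
        assert eps[1]["start_rel"] == pytest.approx(8.0)   # clock 11.00
        assert eps[1]["end_rel"] == pytest.approx(16.0)    # clock 19.00
        assert eps[2]["start_rel"] == pytest.approx(16.75)  # clock 19.75
        assert s.gaps() == pytest.approx([0.75, 0.75])

    def test_repeated_work_instances_split_equally(self):
        s = anchor_and_build_schedule(1, ["H", "W", "O", "W", "H"],
                                      {"H": 12.0, "W": 8.0, "O": 2.0}, (1.0, 2.0))
        w_eps = [e for e in s.episodes if e["purpose"] == "W"]
        durations = [e["end_rel"] - e["start_rel"] for e in w_eps]
        assert durations == pytest.approx([4.0, 4.0])

    def test_day_tiles_24_hours(self, midscale_result):
        for s in midscale_result.schedules:
            ep_time = sum(e["end_rel"] - e["start_rel"] for e in s.episodes)
            assert ep_time + sum(s.gaps()) == pytest.approx(24.0, abs=1e-6)

    def test_anchor_sampled_end_clamped(self):
        s = anchor_and_build_schedule(1, ["H", "W", "H"], {"H": 10.0, "W": 12.0},
                                      (1.0, 2.0), anchor_end_rel=50.0)
        assert s.episodes[0]["end_rel"] == pytest.approx(9.5)  # 0.95 * 10

    def test_time_budget_holds_for_every_agent(self, midscale_result):
        for s in midscale_result.schedules:
            if len(s.episodes) == 1:
                assert s.durations.get("H") == pytest.approx(24.0)
                continue
            lo, hi = s.tt_class
            total = sum(s.durations.values())
            assert 24.0 - hi - 1e-9 <= total < 24.0 - lo + 1e-9
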