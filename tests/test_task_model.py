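"""Task model: schedules, adjacency constraint, behavior simulation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from srpsearch import (
    BehaviorParams,
    ExperimentConfig,
    TrialSchedule,
    behavioral_metrics,
    generate_schedule,
    math_task_schedule,
    simulate_behavior,
    validate_adjacency,
)
from srpsearch.task_model import (
    BehavioralOutcome,
    default_serial_position_curve,
    outcome_table,
)


def brute_force_adjacent(a, b):
    """Independent statement of the constraint: at most two steps in one
    grid direction combined with at most one in the other."""
    dr, dc = abs(a[0] - b[0]), abs(a[1] - b[1])
    return (dr <= 1 and dc <= 2) or (dr <= 2 and dc <= 1)


class TestValidateAdjacency:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ([(0, 0), (1, 2)], True),
            ([(0, 0), (0, 0)], True),
            ([(0, 0), (2, 2)], False),
            ([(1, 1)], True),
        ],
    )
    def test_examples(self, seq, expected):
        assert validate_adjacency(seq) is expected

    def test_matches_enumeration_of_all_pairs(self):
        locations = list(itertools.product(range(3), range(5)))
        for a, b in itertools.product(locations, repeat=2):
            assert validate_adjacency([a, b]) == brute_force_adjacent(a, b)

    def test_rejects_off_grid_coordinates(self):
        with pytest.raises(ValueError):
            validate_adjacency([(0, 0), (3, 0)])
        with pytest.raises(ValueError):
            validate_adjacency([(-1, 0)])

    @given(
        st.lists(
            st.tuples(st.integers(0, 2), st.integers(0, 4)), min_size=2, max_size=15
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_agrees_with_pairwise_oracle(self, seq):
        expected = all(brute_force_adjacent(a, b) for a, b in zip(seq, seq[1:]))
        assert validate_adjacency(seq) == expected


class TestGenerateSchedule:
    def test_every_trial_is_an_admissible_permutation(self):
        config = ExperimentConfig(n_blocks_per_load=1, n_trials_per_block=20)
        schedule = generate_schedule(config, "high", 3)
        for _, trial in schedule.events.groupby("trial"):
            locs = list(zip(trial["row"], trial["col"]))
            assert len(set(locs)) == 15
            assert validate_adjacency(locs)
            onsets = trial["onset_s"].to_numpy()
            assert np.allclose(np.diff(onsets), config.highlight_duration)

    def test_deterministic_given_seed(self):
        config = ExperimentConfig(n_blocks_per_load=1, n_trials_per_block=5)
        a = generate_schedule(config, "low", 42)
        b = generate_schedule(config, "low", 42)
        pd.testing.assert_frame_equal(a.events, b.events)

    def test_target_count_uniform_over_choices(self):
        # 10,000 trials; each count in {2,3,4} should fall inside the
        # 99% normal interval around 1/3 (half-width 2.576*sqrt(p(1-p)/n))
        config = ExperimentConfig(n_blocks_per_load=10, n_trials_per_block=1000)
        schedule = generate_schedule(config, "high", 11)
        counts = schedule.events.groupby("trial")["is_target"].sum()
        n = len(counts)
        assert n == 10_000
        half = 2.576 * np.sqrt((1 / 3) * (2 / 3) / n)
        for k in (2, 3, 4):
            assert abs((counts == k).mean() - 1 / 3) < half

    def test_tsv_round_trip(self, tmp_path):
        config = ExperimentConfig(n_blocks_per_load=1, n_trials_per_block=2)
        schedule = generate_schedule(config, "high", 0)
        path = tmp_path / "events.tsv"
        schedule.to_tsv(path)
        back = TrialSchedule.from_tsv(path, "high", config)
        pd.testing.assert_frame_equal(
            schedule.events, back.events, check_dtype=False
        )


class TestSimulateBehavior:
    def test_zero_miss_probability_means_all_hits(self, small_config):
        schedule = generate_schedule(small_config, "high", 5)
        params = BehaviorParams(base_miss_prob_low=0.0, base_miss_prob_high=0.0)
        outcomes = simulate_behavior(schedule, params, 6)
        assert all(all(o.hits.values()) for o in outcomes)
        assert all(not o.false_alarm_locations for o in outcomes)

    def test_high_load_hit_rate_matches_configured_expectation(self):
        # >= 5000 simulated targets; default params anchor the mean to 0.73
        config = ExperimentConfig(n_blocks_per_load=2, n_trials_per_block=900)
        schedule = generate_schedule(config, "high", 1)
        outcomes = simulate_behavior(schedule, BehaviorParams(), 2)
        table = outcome_table(schedule, outcomes)
        targets = table[table["is_target"]]
        assert len(targets) >= 5000
        assert abs(targets["is_hit"].mean() - 0.73) < 0.02

    def test_flat_curve_gives_equal_per_position_hit_rates(self):
        config = ExperimentConfig(n_blocks_per_load=2, n_trials_per_block=900)
        schedule = generate_schedule(config, "high", 3)
        params = BehaviorParams(serial_position_curve=np.ones(15))
        outcomes = simulate_behavior(schedule, params, 4)
        table = outcome_table(schedule, outcomes)
        targets = table[table["is_target"]]
        obs = targets.groupby("serial_pos")["is_hit"].agg(["sum", "count"])
        # chi-square against a common hit probability
        p_hat = targets["is_hit"].mean()
        expected_hits = obs["count"] * p_hat
        chi2 = (
            (obs["sum"] - expected_hits) ** 2 / expected_hits
            + ((obs["count"] - obs["sum"]) - obs["count"] * (1 - p_hat)) ** 2
            / (obs["count"] * (1 - p_hat))
        ).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=14)

    def test_u_shaped_curve_yields_primacy_and_recency(self):
        config = ExperimentConfig(n_blocks_per_load=2, n_trials_per_block=400)
        schedule = generate_schedule(config, "high", 7)
        outcomes = simulate_behavior(schedule, BehaviorParams(), 8)
        table = outcome_table(schedule, outcomes)
        targets = table[table["is_target"]]
        per_pos = targets.groupby("serial_pos")["is_hit"].mean()
        edge = (per_pos.loc[1] + per_pos.loc[15]) / 2
        middle = per_pos.loc[7:9].mean()
        assert edge > middle

    def test_deterministic_given_seed(self, small_config):
        schedule = generate_schedule(small_config, "high", 5)
        a = simulate_behavior(schedule, BehaviorParams(), 9)
        b = simulate_behavior(schedule, BehaviorParams(), 9)
        assert all(
            x.reported_locations == y.reported_locations for x, y in zip(a, b)
        )


class TestMathSchedule:
    def test_onsets_match_task_timing(self):
        onsets = math_task_schedule(ExperimentConfig())
        assert onsets[0] == pytest.approx(1.0)
        assert onsets[5] == pytest.approx(14.3)
        assert len(onsets) == 6

    def test_single_number(self):
        onsets = math_task_schedule(ExperimentConfig(math_n_numbers=1))
        assert list(onsets) == [1.0]


class TestBehavioralMetrics:
    def _manual_outcome(self, schedule):
        """Trial 0: one target missed with a false alarm, rest hit."""
        outcomes = []
        for trial, ev in schedule.events.groupby("trial"):
            tlocs = [
                (int(r.row), int(r.col)) for r in ev.itertuples() if r.is_target
            ]
            nontarget = next(
                (int(r.row), int(r.col)) for r in ev.itertuples() if not r.is_target
            )
            if trial == 0:
                hits = {loc: i > 0 for i, loc in enumerate(tlocs)}
                reported = {loc for loc, h in hits.items() if h} | {nontarget}
                outcomes.append(BehavioralOutcome(trial, reported, hits, {nontarget}))
            else:
                hits = {loc: True for loc in tlocs}
                outcomes.append(BehavioralOutcome(trial, set(tlocs), hits, set()))
        return outcomes

    def test_hand_counted_example(self, small_config):
        schedule = generate_schedule(small_config, "high", 13)
        outcomes = self._manual_outcome(schedule)
        m = behavioral_metrics(schedule, outcomes)
        assert m["n_hits"] == m["n_targets"] - 1
        assert m["hit_rate"] == pytest.approx((m["n_targets"] - 1) / m["n_targets"])
        assert m["false_alarms"] == 1
        assert m["under_report"] == 0  # one miss offset by one false alarm

    def test_all_hits_rate_one_everywhere(self, small_config):
        schedule = generate_schedule(small_config, "high", 5)
        params = BehaviorParams(base_miss_prob_high=0.0)
        outcomes = simulate_behavior(schedule, params, 6)
        m = behavioral_metrics(schedule, outcomes)
        assert m["hit_rate"] == 1.0
        assert all(v == 1.0 for v in m["hit_rate_per_block"].values())
        assert all(v == 1.0 for v in m["hit_rate_per_serial_pos"].values())

    def test_block_rates_aggregate_to_overall(self):
        config = ExperimentConfig(n_blocks_per_load=3, n_trials_per_block=10)
        schedule = generate_schedule(config, "high", 1)
        outcomes = simulate_behavior(schedule, BehaviorParams(), 2)
        m = behavioral_metrics(schedule, outcomes)
        weighted = sum(
            m["hit_rate_per_block"][b] * m["targets_per_block"][b]
            for b in m["hit_rate_per_block"]
        ) / sum(m["targets_per_block"].values())
        assert weighted == pytest.approx(m["hit_rate"])

    def test_empty_input_rejected(self, small_config):
        schedule = generate_schedule(small_config, "high", 5)
        with pytest.raises(ValueError):
            behavioral_metrics(schedule, [])


class TestParams:
    def test_default_curve_is_u_shaped_mean_one(self):
        curve = default_serial_position_curve()
        assert curve.mean() == pytest.approx(1.0)
        assert curve[0] < curve[7] and curve[-1] < curve[7]

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            BehaviorParams(base_miss_prob_high=1.5)

    def test_inverted_curve_rejected(self):
        with pytest.raises(ValueError):
            BehaviorParams(serial_position_curve=2.0 - default_serial_position_curve())

    def test_config_invariants(self):
        assert ExperimentConfig().n_positions_per_trial == 15
        with pytest.raises(ValueError):
            ExperimentConfig(n_rows=0)
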