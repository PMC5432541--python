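"""Structured visual-search task: schedules, behavior model, behavioral metrics.

The monitoring task presents 15 "systems" arranged in 3 rows x 5 columns.
Within a trial every grid location is highlighted exactly once, in a
pseudo-random order constrained so that two successively highlighted
locations are never further apart than two steps in one grid direction
combined with one step in the orthogonal direction.  Each trial contains
2, 3 or 4 targets (failure strings) at random locations; all other
highlights are non-targets.  After the highlight sweep the participant
reports the target locations; a concurrent auditory arithmetic task is
performed in the high-load condition only.

The stochastic behavior model misses each target independently with a
load-dependent base probability modulated by a U-shaped serial-position
curve (primacy/recency: targets at the start and end of a trial are
remembered better), optionally spawning a false alarm for a missed target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExperimentConfig",
    "TrialSchedule",
    "BehavioralOutcome",
    "BehaviorParams",
    "generate_schedule",
    "validate_adjacency",
    "simulate_behavior",
    "math_task_schedule",
    "behavioral_metrics",
    "default_serial_position_curve",
    "outcome_table",
]

SCHEDULE_COLUMNS = ["trial", "serial_pos", "row", "col", "onset_s", "is_target"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Geometry and timing of one session of the monitoring + math task.

    Durations are in seconds.  ``intertrial_gap`` stands in for the
    (unmodelled) reporting phase between highlight sweeps; ``lead_in`` and
    ``tail`` pad the continuous recording so that epochs never run off the
    ends.
    """

    n_rows: int = 3
    n_cols: int = 5
    highlight_duration: float = 1.027
    n_targets_choices: tuple[int, ...] = (2, 3, 4)
    n_blocks_per_load: int = 8
    n_trials_per_block: int = 11
    math_first_onset: float = 1.0
    math_interval: float = 2.66
    math_n_numbers: int = 6
    math_correct_prob: float = 0.62
    intertrial_gap: float = 20.0
    lead_in: float = 2.0
    tail: float = 3.0

    @property
    def n_positions_per_trial(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_trials(self) -> int:
        return self.n_blocks_per_load * self.n_trials_per_block

    @property
    def trial_duration(self) -> float:
        return self.n_positions_per_trial * self.highlight_duration

    def __post_init__(self) -> None:
        for name in (
            "n_rows",
            "n_cols",
            "n_blocks_per_load",
            "n_trials_per_block",
            "math_n_numbers",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.n_targets_choices:
            raise ValueError("n_targets_choices must be non-empty")
        if max(self.n_targets_choices) > self.n_positions_per_trial:
            raise ValueError("more targets than grid positions")


@dataclass
class TrialSchedule:
    """Highlight sequence for one session under one load condition.

    ``events`` has one row per highlight with columns
    ``trial, serial_pos, row, col, onset_s, is_target`` (serial_pos is
    1-based; grid coordinates are 0-based with row 0 the top row).
    """

    events: pd.DataFrame
    load: str
    config: ExperimentConfig = field(default_factory=ExperimentConfig)

    def __post_init__(self) -> None:
        if self.load not in ("low", "high"):
            raise ValueError("load must be 'low' or 'high'")
        missing = set(SCHEDULE_COLUMNS) - set(self.events.columns)
        if missing:
            raise ValueError(f"schedule missing columns: {sorted(missing)}")

    @property
    def n_trials(self) -> int:
        return self.events["trial"].nunique()

    def trial_events(self, trial: int) -> pd.DataFrame:
        return self.events[self.events["trial"] == trial]

    def to_tsv(self, path: str | Path) -> None:
        self.events.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, load: str, config: ExperimentConfig | None = None
    ) -> "TrialSchedule":
        events = pd.read_csv(path, sep="\t")
        return cls(events=events, load=load, config=config or ExperimentConfig())


@dataclass
class BehavioralOutcome:
    """Reported locations for one trial.

    ``hits`` maps each target location to whether it was reported;
    ``false_alarm_locations`` are reported locations that held no target.
    """

    trial_id: int
    reported_locations: set[tuple[int, int]]
    hits: dict[tuple[int, int], bool]
    false_alarm_locations: set[tuple[int, int]]

    def __post_init__(self) -> None:
        for loc, hit in self.hits.items():
            if hit != (loc in self.reported_locations):
                raise ValueError("hit flag inconsistent with reported locations")
        if self.false_alarm_locations & set(self.hits):
            raise ValueError("false alarm at a target location")


def default_serial_position_curve(n_positions: int = 15) -> np.ndarray:
    """Multiplicative miss-probability modifiers over serial position.

    Raised-cosine bump: low at the trial ends (primacy/recency), high in
    the middle, normalised to mean 1 so that the expected miss rate over
    uniformly placed targets equals the base miss probability.
    """
    k = np.arange(n_positions)
    raw = 0.35 + 1.3 * 0.5 * (1.0 - np.cos(2.0 * np.pi * k / (n_positions - 1)))
    return raw / raw.mean()


@dataclass
class BehaviorParams:
    """Parameters of the stochastic hit/miss/false-alarm model.

    Base miss probabilities are anchored so that mean hit rates match the
    study conditions (0.96 low load, 0.73 high load); the serial-position
    curve multiplies the base probability and averages to 1.
    """

    base_miss_prob_low: float = 0.04
    base_miss_prob_high: float = 0.27
    serial_position_curve: np.ndarray = field(
        default_factory=default_serial_position_curve
    )
    false_alarm_prob_per_miss: float = 0.35

    def __post_init__(self) -> None:
        self.serial_position_curve = np.asarray(self.serial_position_curve, float)
        for p in (
            self.base_miss_prob_low,
            self.base_miss_prob_high,
            self.false_alarm_prob_per_miss,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        curve = self.serial_position_curve
        if curve.ndim != 1 or (curve < 0).any():
            raise ValueError("serial_position_curve must be a non-negative vector")
        ends = max(curve[0], curve[-1])
        mid = curve[len(curve) // 2]
        if ends > mid:
            raise ValueError("serial_position_curve must be U-shaped (ends <= middle)")

    def base_miss_prob(self, load: str) -> float:
        return self.base_miss_prob_high if load == "high" else self.base_miss_prob_low

    @classmethod
    def null(cls) -> "BehaviorParams":
        """Flat curve, equal loads — for null-calibration studies."""
        return cls(
            base_miss_prob_low=0.27,
            base_miss_prob_high=0.27,
            serial_position_curve=np.ones(15),
        )


def validate_adjacency(
    sequence: Sequence[tuple[int, int]],
    n_rows: int = 3,
    n_cols: int = 5,
) -> bool:
    """True iff every consecutive pair of grid locations is "adjacent".

    Two locations are adjacent when they differ by at most two steps in one
    grid direction and at most one in the other:
    (|dcol| <= 2 and |drow| <= 1) or (|drow| <= 2 and |dcol| <= 1).
    Raises ValueError on coordinates outside the grid.
    """
    for r, c in sequence:
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise ValueError(f"location ({r}, {c}) outside {n_rows}x{n_cols} grid")
    return all(
        _adjacent(a, b) for a, b in zip(sequence, sequence[1:])
    )


def _adjacent(a: tuple[int, int], b: tuple[int, int]) -> bool:
    dr, dc = abs(a[0] - b[0]), abs(a[1] - b[1])
    return (dc <= 2 and dr <= 1) or (dr <= 2 and dc <= 1)


def _sample_trial_order(
    rng: np.random.Generator,
    locations: list[tuple[int, int]],
    n_rejection: int = 50,
    n_greedy: int = 1000,
) -> list[tuple[int, int]]:
    """One admissible permutation of all grid locations.

    Rejection sampling of unconstrained permutations first (cheap when it
    hits), then a greedy walk — pick a uniformly random unvisited adjacent
    location, restarting on dead ends.
    """
    n = len(locations)
    for _ in range(n_rejection):
        perm = [locations[i] for i in rng.permutation(n)]
        if all(_adjacent(a, b) for a, b in zip(perm, perm[1:])):
            return perm
    for _ in range(n_greedy):
        remaining = set(locations)
        current = locations[rng.integers(n)]
        order = [current]
        remaining.discard(current)
        while remaining:
            options = sorted(loc for loc in remaining if _adjacent(current, loc))
            if not options:
                break
            current = options[rng.integers(len(options))]
            order.append(current)
            remaining.discard(current)
        if not remaining:
            return order
    raise RuntimeError("could not sample an admissible highlight order")


def generate_schedule(
    config: ExperimentConfig,
    load: str,
    seed: int | np.random.Generator,
) -> TrialSchedule:
    """Generate the highlight schedule for one session.

    Per trial: an admissible permutation of all grid locations, a target
    count drawn uniformly from ``config.n_targets_choices`` and target
    locations drawn uniformly without replacement.  Onsets are spaced by
    ``highlight_duration`` within a trial; trials are separated by
    ``intertrial_gap``. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    locations = [
        (r, c) for r in range(config.n_rows) for c in range(config.n_cols)
    ]
    choices = np.asarray(config.n_targets_choices)
    rows = []
    t = config.lead_in
    for trial in range(config.n_trials):
        order = _sample_trial_order(rng, locations)
        n_targets = int(choices[rng.integers(len(choices))])
        target_idx = set(
            rng.choice(len(order), size=n_targets, replace=False).tolist()
        )
        for k, (r, c) in enumerate(order):
            rows.append(
                (trial, k + 1, r, c, t + k * config.highlight_duration, k in target_idx)
            )
        t += config.trial_duration + config.intertrial_gap
    events = pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)
    return TrialSchedule(events=events, load=load, config=config)


def simulate_behavior(
    schedule: TrialSchedule,
    params: BehaviorParams,
    seed: int | np.random.Generator,
    load: str | None = None,
) -> list[BehavioralOutcome]:
    """Simulate reported locations for every trial of a schedule.

    Each target is missed independently with probability
    ``base_miss_prob(load) * serial_position_curve[serial_pos - 1]``
    (clipped to [0, 1]); each miss spawns a false alarm at a uniformly
    random non-target, not-yet-reported location with probability
    ``false_alarm_prob_per_miss``.
    """
    rng = np.random.default_rng(seed)
    load = load or schedule.load
    base = params.base_miss_prob(load)
    curve = params.serial_position_curve
    outcomes: list[BehavioralOutcome] = []
    all_locations = [
        (r, c)
        for r in range(schedule.config.n_rows)
        for c in range(schedule.config.n_cols)
    ]
    for trial, ev in schedule.events.groupby("trial", sort=True):
        hits: dict[tuple[int, int], bool] = {}
        reported: set[tuple[int, int]] = set()
        n_false_alarms = 0
        for _, row in ev.iterrows():
            if not row["is_target"]:
                continue
            p_miss = float(np.clip(base * curve[int(row["serial_pos"]) - 1], 0.0, 1.0))
            loc = (int(row["row"]), int(row["col"]))
            missed = rng.random() < p_miss
            hits[loc] = not missed
            if not missed:
                reported.add(loc)
            elif rng.random() < params.false_alarm_prob_per_miss:
                n_false_alarms += 1
        target_locs = set(hits)
        fa_locs: set[tuple[int, int]] = set()
        candidates = [loc for loc in all_locations if loc not in target_locs]
        if n_false_alarms:
            picks = rng.choice(
                len(candidates), size=min(n_false_alarms, len(candidates)), replace=False
            )
            fa_locs = {candidates[i] for i in picks}
            reported |= fa_locs
        outcomes.append(
            BehavioralOutcome(
                trial_id=int(trial),
                reported_locations=reported,
                hits=hits,
                false_alarm_locations=fa_locs,
            )
        )
    return outcomes


def math_task_schedule(config: ExperimentConfig) -> np.ndarray:
    """Onset times (s, trial-relative) of the aurally presented numbers."""
    k = np.arange(config.math_n_numbers)
    return config.math_first_onset + k * config.math_interval


def outcome_table(
    schedule: TrialSchedule, outcomes: Iterable[BehavioralOutcome]
) -> pd.DataFrame:
    """Event-level table joining the schedule with hit/miss labels.

    Adds ``is_hit`` (boolean, meaningful for targets only; False for
    non-targets) and ``condition`` in {hit, miss, nontarget}.
    """
    by_trial = {o.trial_id: o for o in outcomes}
    if set(by_trial) != set(schedule.events["trial"].unique()):
        raise ValueError("outcomes do not cover all trials of the schedule")
    events = schedule.events.copy()
    is_hit = []
    for _, row in events.iterrows():
        if row["is_target"]:
            is_hit.append(by_trial[int(row["trial"])].hits[(int(row["row"]), int(row["col"]))])
        else:
            is_hit.append(False)
    events["is_hit"] = is_hit
    events["condition"] = np.where(
        events["is_target"], np.where(events["is_hit"], "hit", "miss"), "nontarget"
    )
    return events


def behavioral_metrics(
    schedule: TrialSchedule, outcomes: Iterable[BehavioralOutcome]
) -> dict:
    """Summary of behavioral performance for one session.

    Returns overall hit rate, hit rate per block and per serial position,
    false-alarm count, and the under-report count (targets presented minus
    locations reported; negative when false alarms outnumber misses).
    """
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("no outcomes supplied")
    events = outcome_table(schedule, outcomes)
    targets = events[events["is_target"]]
    if targets.empty:
        raise ValueError("schedule contains no targets")
    cfg = schedule.config
    targets = targets.assign(block=targets["trial"] // cfg.n_trials_per_block)
    per_block = targets.groupby("block")["is_hit"].agg(["mean", "count"])
    per_pos = targets.groupby("serial_pos")["is_hit"].agg(["mean", "count"])
    n_false_alarms = sum(len(o.false_alarm_locations) for o in outcomes)
    n_reported = sum(len(o.reported_locations) for o in outcomes)
    return {
        "hit_rate": float(targets["is_hit"].mean()),
        "n_targets": int(len(targets)),
        "n_hits": int(targets["is_hit"].sum()),
        "hit_rate_per_block": per_block["mean"].to_dict(),
        "targets_per_block": per_block["count"].to_dict(),
        "hit_rate_per_serial_pos": per_pos["mean"].to_dict(),
        "targets_per_serial_pos": per_pos["count"].to_dict(),
        "false_alarms": int(n_false_alarms),
        "under_report": int(len(targets) - n_reported),
    }


def simulate_math_scores(
    config: ExperimentConfig, n_trials: int, seed: int | np.random.Generator
) -> float:
    """Fraction of math trials answered correctly (fixed per-trial probability)."""
    rng = np.random.default_rng(seed)
    return float(np.mean(rng.random(n_trials) < config.math_correct_prob))
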