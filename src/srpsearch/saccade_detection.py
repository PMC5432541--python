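"""Candidate saccade detection and selection of the saccade of interest.

Candidate saccades are supra-threshold excursions of the EOG velocity
trace (|v| above ``candidate_k`` times the trace SD).  For every stimulus
highlight, the saccade of interest is the first candidate between 100 and
800 ms after highlight onset whose sign matches the direction of the
stimulus-to-stimulus transition, searched first on the horizontal channel
and, failing that (or for purely vertical transitions), on the vertical
channel.

Sign conventions (shared with the synthetic generator): HEOG positive for
rightward gaze, VEOG positive for upward gaze; grid row index grows
downward, so the expected vertical sign is ``-sign(delta_row)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from srpsearch.eog_pipeline import PipelineParams, _merge_runs, _runs_from_mask

__all__ = [
    "CandidateSaccade",
    "SaccadeOfInterest",
    "find_candidate_saccades",
    "select_saccade_of_interest",
    "select_session_saccades",
    "compute_saccade_latencies",
]


@dataclass(frozen=True)
class CandidateSaccade:
    peak_time: float          # seconds
    peak_velocity: float      # signed, velocity-trace units
    channel: str              # "H" | "V"


@dataclass(frozen=True)
class SaccadeOfInterest:
    event_id: int
    peak_time: float
    latency_ms: float
    matched_channel: str
    direction_sign: int


def find_candidate_saccades(
    velocity: np.ndarray,
    fs: float,
    k: float = 4.0,
    channel: str = "H",
    merge_gap_ms: float = 20.0,
) -> list[CandidateSaccade]:
    """Supra-threshold runs of |velocity|, merged across short gaps.

    Each merged run yields one candidate at its sample of maximum absolute
    velocity, with that sample's sign.
    """
    v = np.asarray(velocity, float)
    if not np.isfinite(v).all():
        raise ValueError("velocity trace contains non-finite values")
    sd = v.std()
    if sd == 0:
        return []
    mask = np.abs(v) > k * sd
    runs = _merge_runs(_runs_from_mask(mask), int(round(merge_gap_ms / 1000.0 * fs)))
    out = []
    for s, e in runs:
        i = s + int(np.argmax(np.abs(v[s:e])))
        out.append(CandidateSaccade(i / fs, float(v[i]), channel))
    return out


def _first_matching(
    candidates: list[CandidateSaccade],
    onset_s: float,
    window_ms: tuple[float, float],
    wanted_sign: int,
) -> CandidateSaccade | None:
    lo, hi = window_ms
    for c in candidates:
        lat = (c.peak_time - onset_s) * 1000.0
        if lat < lo:
            continue
        if lat > hi:
            return None
        if np.sign(c.peak_velocity) == wanted_sign:
            return c
    return None


def select_saccade_of_interest(
    candidates_h: list[CandidateSaccade],
    candidates_v: list[CandidateSaccade],
    event_id: int,
    onset_s: float,
    delta_col: int,
    delta_row: int,
    window_ms: tuple[float, float] = (100.0, 800.0),
) -> SaccadeOfInterest | None:
    """Select the saccade of interest for one highlight.

    ``delta_col``/``delta_row`` describe the grid transition from the
    previously fixated location to the currently highlighted one.  The
    horizontal channel is searched first for a candidate whose sign
    matches ``sign(delta_col)``; if the transition is purely vertical or
    no horizontal match exists, the vertical channel is searched for
    ``-sign(delta_row)`` (VEOG positive upward, rows grow downward).
    Returns None when no candidate matches - a valid, counted outcome.
    """
    h_sign = int(np.sign(delta_col))
    v_sign = int(-np.sign(delta_row))
    if h_sign != 0:
        c = _first_matching(candidates_h, onset_s, window_ms, h_sign)
        if c is not None:
            return SaccadeOfInterest(
                event_id, c.peak_time, (c.peak_time - onset_s) * 1000.0, "H", h_sign
            )
    if v_sign != 0:
        c = _first_matching(candidates_v, onset_s, window_ms, v_sign)
        if c is not None:
            return SaccadeOfInterest(
                event_id, c.peak_time, (c.peak_time - onset_s) * 1000.0, "V", v_sign
            )
    return None


def select_session_saccades(
    velocity_h: np.ndarray,
    velocity_v: np.ndarray,
    fs: float,
    events: pd.DataFrame,
    params: PipelineParams | None = None,
) -> pd.DataFrame:
    """Saccades of interest for every highlight of a session.

    ``events`` must carry ``trial, serial_pos, row, col, onset_s`` (the
    labelled schedule table).  The previous location for the first
    highlight of a trial is taken as the grid centre (gaze rests at the
    screen centre between trials).  Returns one row per event with
    ``matched`` flag, peak time, latency and channel.
    """
    p = params or PipelineParams()
    cands_h = find_candidate_saccades(velocity_h, fs, p.candidate_k, "H",
                                      p.candidate_merge_gap_ms)
    cands_v = find_candidate_saccades(velocity_v, fs, p.candidate_k, "V",
                                      p.candidate_merge_gap_ms)
    n_rows = int(events["row"].max()) + 1
    n_cols = int(events["col"].max()) + 1
    centre = ((n_rows - 1) / 2.0, (n_cols - 1) / 2.0)
    rows = []
    ev = events.reset_index(drop=True)
    for i, e in ev.iterrows():
        if int(e["serial_pos"]) == 1:
            prev = centre
        else:
            prev = (float(ev["row"].iloc[i - 1]), float(ev["col"].iloc[i - 1]))
        dcol = int(np.sign(float(e["col"]) - prev[1]) * np.ceil(abs(float(e["col"]) - prev[1])))
        drow = int(np.sign(float(e["row"]) - prev[0]) * np.ceil(abs(float(e["row"]) - prev[0])))
        soi = select_saccade_of_interest(
            cands_h, cands_v, int(i), float(e["onset_s"]), dcol, drow,
            p.saccade_window_ms,
        )
        rows.append(
            {
                "event_id": int(i),
                "matched": soi is not None,
                "peak_time_s": soi.peak_time if soi else np.nan,
                "latency_ms": soi.latency_ms if soi else np.nan,
                "channel": soi.matched_channel if soi else "",
                "sign": soi.direction_sign if soi else 0,
            }
        )
    return pd.DataFrame(rows)


def compute_saccade_latencies(
    saccades: pd.DataFrame,
    events: pd.DataFrame,
    participant: str | int | None = None,
    load: str | None = None,
) -> pd.DataFrame:
    """Mean and SD of saccade latency per condition for one session.

    Joins selected saccades to the labelled event table (``condition`` in
    {hit, miss, nontarget}) and summarises matched events.  The ``target``
    condition is the union of hits and misses.  Conditions without any
    observation are flagged missing (NaN mean, n = 0), never reported as
    zero.
    """
    ev = events.reset_index(drop=True).copy()
    ev["event_id"] = np.arange(len(ev))
    joined = saccades.merge(
        ev[["event_id", "condition", "is_target"]], on="event_id", how="left"
    )
    matched = joined[joined["matched"]]
    rows = []
    groups = {
        "target": matched[matched["is_target"]],
        "nontarget": matched[matched["condition"] == "nontarget"],
        "hit": matched[matched["condition"] == "hit"],
        "miss": matched[matched["condition"] == "miss"],
    }
    for name, g in groups.items():
        rows.append(
            {
                "participant": participant,
                "load": load,
                "condition": name,
                "mean_ms": float(g["latency_ms"].mean()) if len(g) else np.nan,
                "sd_ms": float(g["latency_ms"].std(ddof=1)) if len(g) > 1 else np.nan,
                "n": int(len(g)),
            }
        )
    return pd.DataFrame(rows)
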