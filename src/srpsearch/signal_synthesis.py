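"""Render a trial schedule into synchronized synthetic EEG/EOG/gaze/pupil.

The generator emulates the statistical structure the analysis chain
assumes, with ground truth returned alongside every stream:

* per highlight, a saccade toward the stimulus at a condition-dependent
  latency (hit / miss / non-target means and SDs anchored to the study's
  saccade-latency table); eye position follows a logistic sigmoid with a
  40 ms rise whose midpoint defines the true peak-velocity time;
* HEOG/VEOG proportional to the horizontal / vertical gaze angle
  (positive rightward / upward), plus noise, spikes and blinks;
* EEG = 1/f^alpha background + white noise + an additive P300-like
  half-cosine bump 0.5 s after each saccade peak, larger for targets than
  non-targets, spatially weighted toward parieto-central channels;
* gaze at 60 Hz with fixation scatter and invalid samples; pupil =
  load-dependent baseline + slow drift + an increment during fixations of
  subsequently missed targets + noise.

Condition-dependent fixation dwell is produced by a slow (sub-saccadic)
drift off the stimulus once the dwell has elapsed, so fixation-duration
features can be controlled independently of the saccade chain.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.special import expit

from srpsearch.task_model import (
    BehavioralOutcome,
    TrialSchedule,
    outcome_table,
)

__all__ = [
    "EEG_CHANNELS",
    "PARIETO_CENTRAL",
    "ScreenGeometry",
    "SignalParams",
    "ContinuousRecording",
    "px_to_physical",
    "stimulus_centers_px",
    "synthesize_recording",
    "inject_blinks",
    "write_recording",
    "read_recording",
]

# BioSemi 32-channel cap, 10-20 names.
EEG_CHANNELS = (
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "Pz", "PO3", "O1", "Oz",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
)

PARIETO_CENTRAL = ("CP1", "P3", "Pz", "PO3", "PO4", "P4", "CP2")

# Fixed P300 topography: maximal over the parieto-central set, reduced on
# their neighbours, small elsewhere.
_NEIGHBOURS = ("CP5", "CP6", "P7", "P8", "O1", "Oz", "O2", "C3", "Cz", "C4")
DEFAULT_P300_WEIGHTS = {
    ch: 1.0 if ch in PARIETO_CENTRAL else (0.5 if ch in _NEIGHBOURS else 0.15)
    for ch in EEG_CHANNELS
}

# saccadic main sequence: movement duration grows with amplitude
# (duration_ms ~ 21 + 2.2 * amplitude_deg); used as the sigmoid rise time
MAIN_SEQUENCE_INTERCEPT_MS = 21.0
MAIN_SEQUENCE_SLOPE_MS_PER_DEG = 2.2
DRIFT_DURATION_S = 0.400  # slow off-stimulus drift (sub-saccadic velocity)


def saccade_rise_s(amplitude_deg: float) -> float:
    """Sigmoid rise time (s) of a saccade of the given angular amplitude."""
    return (MAIN_SEQUENCE_INTERCEPT_MS
            + MAIN_SEQUENCE_SLOPE_MS_PER_DEG * abs(amplitude_deg)) / 1000.0


@dataclass(frozen=True)
class ScreenGeometry:
    """Display geometry: 19-inch panel viewed from ~40 cm."""

    width_px: int = 1280
    height_px: int = 1024
    width_cm: float = 37.5
    height_cm: float = 30.0
    eye_distance_cm: float = 40.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")


def px_to_physical(pixels: float, geometry: ScreenGeometry) -> tuple[float, float]:
    """Convert a horizontal extent in pixels to (cm, degrees of visual angle)."""
    cm = pixels * geometry.width_cm / geometry.width_px
    deg = np.degrees(2.0 * np.arctan(cm / (2.0 * geometry.eye_distance_cm)))
    return float(cm), float(deg)


def stimulus_centers_px(
    n_rows: int, n_cols: int, geometry: ScreenGeometry
) -> dict[tuple[int, int], tuple[float, float]]:
    """Pixel centers of the grid cells; row 0 is the top row."""
    return {
        (r, c): (
            geometry.width_px * (c + 0.5) / n_cols,
            geometry.height_px * (r + 0.5) / n_rows,
        )
        for r in range(n_rows)
        for c in range(n_cols)
    }


def _latency_table() -> dict[tuple[str, str], tuple[float, float]]:
    # (load, condition) -> (mean_ms, sd_ms), from the study's latency table
    return {
        ("low", "hit"): (154.0, 38.0),
        ("low", "miss"): (267.0, 245.0),
        ("low", "nontarget"): (165.0, 45.0),
        ("high", "hit"): (199.0, 43.0),
        ("high", "miss"): (284.0, 97.0),
        ("high", "nontarget"): (229.0, 53.0),
    }


def _dwell_table() -> dict[str, float]:
    # mean on-stimulus dwell (ms) by condition: hits > non-targets > misses
    return {"hit": 950.0, "miss": 800.0, "nontarget": 870.0}


@dataclass
class SignalParams:
    """All tunable knobs of the synthetic recording.

    Voltages are microvolts, pupil sizes millimetres, times seconds unless
    a field name says otherwise.  ``saccade_latency_ms`` maps
    (load, condition) to (mean, SD) of the stimulus-to-saccade-peak
    latency; draws are truncated to [105, 795] ms so true saccades stay
    inside the detector's search window.
    """

    eeg_fs: float = 512.0
    eye_fs: float = 60.0
    eeg_noise_sd: float = 9.0          # 1/f^alpha background, per channel
    eeg_white_noise_sd: float = 3.0
    pink_noise_exponent: float = 1.0
    p300_amplitude_target: float = 5.0
    p300_amplitude_nontarget: float = 1.0
    p300_amplitude_miss: float | None = None   # None -> same as target
    p300_latency: float = 0.5
    p300_width: float = 0.3
    p300_channel_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_P300_WEIGHTS)
    )
    saccade_latency_ms: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=_latency_table
    )
    latency_bounds_ms: tuple[float, float] = (105.0, 795.0)
    fixation_dwell_ms: dict[str, float] = field(default_factory=_dwell_table)
    fixation_dwell_sd_ms: float = 110.0
    fixation_scatter_px: float = 8.0
    gaze_jitter_px: float = 6.0
    pupil_baseline_low: float = 4.3
    pupil_baseline_high: float = 4.7
    pupil_miss_increment: float = 0.15
    pupil_drift_sd: float = 0.2
    pupil_drift_timescale_s: float = 5.0
    pupil_noise_sd: float = 0.1
    blink_rate_per_min: float = 15.0
    blink_amplitude: float = 400.0
    blink_width_range_ms: tuple[float, float] = (150.0, 400.0)
    eog_gain: float = 12.0             # microvolts per degree of gaze angle
    eog_noise_sd: float = 3.0
    eog_spike_rate_per_min: float = 2.0
    eog_spike_amplitude: float = 1200.0
    invalid_sample_prob: float = 0.02
    gaze_scale: float = 1.0            # miscalibration applied to recorded gaze
    gaze_offset_px: tuple[float, float] = (0.0, 0.0)
    bad_channel: str | None = None     # channel rendered with 10x noise
    bad_channel_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.p300_amplitude_target < self.p300_amplitude_nontarget:
            raise ValueError("target P300 amplitude below non-target amplitude")
        for name in (
            "eeg_noise_sd", "eeg_white_noise_sd", "pupil_noise_sd",
            "blink_rate_per_min", "eog_noise_sd", "invalid_sample_prob",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def miss_amplitude(self) -> float:
        if self.p300_amplitude_miss is None:
            return self.p300_amplitude_target
        return self.p300_amplitude_miss

    @classmethod
    def null(cls) -> "SignalParams":
        """All condition effects removed: identical latency, dwell, P300
        amplitude, pupil baseline and no miss-related pupil increment."""
        lat = {k: (220.0, 60.0) for k in _latency_table()}
        dwell = {k: 870.0 for k in _dwell_table()}
        return cls(
            p300_amplitude_target=2.0,
            p300_amplitude_nontarget=2.0,
            p300_amplitude_miss=2.0,
            saccade_latency_ms=lat,
            fixation_dwell_ms=dwell,
            pupil_baseline_low=4.5,
            pupil_baseline_high=4.5,
            pupil_miss_increment=0.0,
        )


@dataclass
class ContinuousRecording:
    """Synchronized multichannel EEG/EOG plus gaze/pupil with shared t=0.

    ``eeg`` is channels x samples (microvolts) at ``eeg_fs``; ``heog`` and
    ``veog`` share that clock.  Eye streams are sampled at ``eye_fs``.
    ``events`` carries the labelled stimulus table; ``truth`` the
    generator's ground-truth annotations (empty for real or reloaded data
    without them); ``blink_intervals`` are (start_s, end_s) pairs.
    """

    eeg: np.ndarray
    channel_names: tuple[str, ...]
    heog: np.ndarray
    veog: np.ndarray
    eeg_fs: float
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    pupil: np.ndarray
    validity: np.ndarray
    eye_fs: float
    events: pd.DataFrame
    load: str
    truth: pd.DataFrame | None = None
    blink_intervals: list[tuple[float, float]] = field(default_factory=list)
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)

    def __post_init__(self) -> None:
        n = self.eeg.shape[1]
        if len(self.heog) != n or len(self.veog) != n:
            raise ValueError("EEG-rate streams must have equal length")
        m = len(self.gaze_x)
        if any(len(v) != m for v in (self.gaze_y, self.pupil, self.validity)):
            raise ValueError("eye-rate streams must have equal length")
        if len(self.channel_names) != self.eeg.shape[0]:
            raise ValueError("channel name count mismatch")
        if len(self.events) and self.events["onset_s"].max() > self.duration:
            raise ValueError("event onset beyond recording duration")

    @property
    def duration(self) -> float:
        return self.eeg.shape[1] / self.eeg_fs

    @property
    def eye_times(self) -> np.ndarray:
        return np.arange(len(self.gaze_x)) / self.eye_fs

    def copy(self) -> "ContinuousRecording":
        return dataclasses.replace(
            self,
            eeg=self.eeg.copy(),
            heog=self.heog.copy(),
            veog=self.veog.copy(),
            gaze_x=self.gaze_x.copy(),
            gaze_y=self.gaze_y.copy(),
            pupil=self.pupil.copy(),
            validity=self.validity.copy(),
            events=self.events.copy(),
        )


def _pink_noise(rng: np.random.Generator, n: int, exponent: float, sd: float) -> np.ndarray:
    white = rng.standard_normal(n)
    if sd == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n)
    s = out.std()
    return out * (sd / s) if s > 0 else out


def inject_blinks(
    veog: np.ndarray,
    fs: float,
    rate_per_min: float,
    seed: int | np.random.Generator,
    amplitude: float = 400.0,
    width_range_ms: tuple[float, float] = (150.0, 400.0),
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Add positive blink deflections at Poisson times.

    Each blink is a raised-cosine bump of random width; returns the
    modified copy and ground-truth (start_s, end_s) intervals.
    """
    if rate_per_min < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    out = veog.copy()
    duration = len(veog) / fs
    n_blinks = rng.poisson(rate_per_min * duration / 60.0)
    intervals: list[tuple[float, float]] = []
    for _ in range(n_blinks):
        width_s = rng.uniform(*width_range_ms) / 1000.0
        t0 = rng.uniform(0.0, max(duration - width_s, 0.0))
        amp = amplitude * rng.uniform(0.8, 1.2)
        i0 = int(round(t0 * fs))
        n = max(int(round(width_s * fs)), 3)
        i1 = min(i0 + n, len(out))
        phase = np.linspace(0.0, 1.0, i1 - i0)
        out[i0:i1] += amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
        intervals.append((i0 / fs, i1 / fs))
    intervals.sort()
    return out, intervals


def _gaze_angles_deg(
    x_px: np.ndarray, y_px: np.ndarray, geom: ScreenGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal (rightward-positive) and vertical (upward-positive) gaze
    angles relative to the screen centre."""
    cx, cy = geom.width_px / 2.0, geom.height_px / 2.0
    x_cm = (np.asarray(x_px) - cx) * geom.width_cm / geom.width_px
    y_cm = (cy - np.asarray(y_px)) * geom.height_cm / geom.height_px
    ax = np.degrees(np.arctan(x_cm / geom.eye_distance_cm))
    ay = np.degrees(np.arctan(y_cm / geom.eye_distance_cm))
    return ax, ay


@dataclass
class _Transition:
    t: float                     # midpoint (saccades) / start (drifts), s
    from_xy: tuple[float, float]
    to_xy: tuple[float, float]
    kind: str                    # "saccade" | "drift"
    duration: float = DRIFT_DURATION_S   # drifts: ramp length; saccades: rise time


def _eval_gaze(transitions: list[_Transition], times: np.ndarray,
               start_xy: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the piecewise gaze trajectory at arbitrary timestamps.

    Saccades follow a logistic sigmoid (midpoint = peak velocity) whose
    rise time follows the saccadic main sequence; drifts are linear
    ramps.  Transitions are assumed non-overlapping and time-sorted.
    """
    x = np.full(len(times), start_xy[0])
    y = np.full(len(times), start_xy[1])
    # baseline: value after each completed transition
    ends = np.array([tr.t + (2.5 * tr.duration if tr.kind == "saccade" else tr.duration)
                     for tr in transitions])
    idx = np.searchsorted(ends, times)
    finals_x = np.array([start_xy[0]] + [tr.to_xy[0] for tr in transitions])
    finals_y = np.array([start_xy[1]] + [tr.to_xy[1] for tr in transitions])
    x[:] = finals_x[idx]
    y[:] = finals_y[idx]
    for tr in transitions:
        if tr.kind == "saccade":
            scale = tr.duration / (2.0 * np.log(9.0))
            lo, hi = tr.t - 2.5 * tr.duration, tr.t + 2.5 * tr.duration
            i0, i1 = np.searchsorted(times, (lo, hi))
            if i1 > i0:
                w = expit((times[i0:i1] - tr.t) / scale)
                x[i0:i1] = tr.from_xy[0] + (tr.to_xy[0] - tr.from_xy[0]) * w
                y[i0:i1] = tr.from_xy[1] + (tr.to_xy[1] - tr.from_xy[1]) * w
        else:
            lo, hi = tr.t, tr.t + tr.duration
            i0, i1 = np.searchsorted(times, (lo, hi))
            if i1 > i0:
                w = (times[i0:i1] - lo) / tr.duration
                x[i0:i1] = tr.from_xy[0] + (tr.to_xy[0] - tr.from_xy[0]) * w
                y[i0:i1] = tr.from_xy[1] + (tr.to_xy[1] - tr.from_xy[1]) * w
    return x, y


def _rise_for(a: tuple[float, float], b: tuple[float, float],
              geom: ScreenGeometry) -> float:
    ax, ay = _gaze_angles_deg(np.array([a[0], b[0]]), np.array([a[1], b[1]]), geom)
    amp = float(np.hypot(ax[1] - ax[0], ay[1] - ay[0]))
    return saccade_rise_s(amp)


def _park_position(
    fix: tuple[float, float], nxt: tuple[float, float], geom: ScreenGeometry,
    distance: float = 190.0,
) -> tuple[float, float]:
    """Off-stimulus resting point: perpendicular to the upcoming transition
    so it stays outside the fixation radius of both stimuli.

    The perpendicular sign is chosen so the subsequent saccade's dominant
    component grows rather than shrinks (the rest position never shadows
    the direction of the upcoming transition).
    """
    dx, dy = nxt[0] - fix[0], nxt[1] - fix[1]
    norm = float(np.hypot(dx, dy))
    if norm < 1e-9:
        px, py = fix[0], fix[1] + distance
    else:
        # park at fix + s*(-dy, dx)*d/norm; next saccade x-component is
        # dx + s*dy*d/norm, so s = sign(dx*dy) enlarges |dx| (any s works
        # when dx or dy is 0)
        s = 1.0 if dx * dy >= 0 else -1.0
        px = fix[0] - s * dy / norm * distance
        py = fix[1] + s * dx / norm * distance
    px = float(np.clip(px, 10.0, geom.width_px - 10.0))
    py = float(np.clip(py, 10.0, geom.height_px - 10.0))
    return px, py


def synthesize_recording(
    schedule: TrialSchedule,
    outcomes: Sequence[BehavioralOutcome],
    params: SignalParams,
    geometry: ScreenGeometry | None = None,
    seed: int | np.random.Generator = 0,
) -> ContinuousRecording:
    """Render one session (one load condition) into continuous streams.

    Deterministic given (schedule, outcomes, params, seed).  The returned
    recording carries a ``truth`` table with, per stimulus event, the true
    saccade peak-velocity time, latency, injected P300 amplitude and
    condition label, plus ground-truth blink intervals.
    """
    geom = geometry or ScreenGeometry()
    rng = np.random.default_rng(seed)
    cfg = schedule.config
    events = outcome_table(schedule, outcomes)
    centers = stimulus_centers_px(cfg.n_rows, cfg.n_cols, geom)
    center_screen = (geom.width_px / 2.0, geom.height_px / 2.0)

    duration = float(events["onset_s"].max()) + cfg.highlight_duration + cfg.tail
    n_eeg = int(np.ceil(duration * params.eeg_fs))
    n_eye = int(np.ceil(duration * params.eye_fs))
    t_eeg = np.arange(n_eeg) / params.eeg_fs
    t_eye = np.arange(n_eye) / params.eye_fs

    # --- per-event saccade latencies and dwell times -------------------
    lo_ms, hi_ms = params.latency_bounds_ms
    latencies = np.empty(len(events))
    dwells = np.empty(len(events))
    for i, (_, ev) in enumerate(events.iterrows()):
        mean, sd = params.saccade_latency_ms[(schedule.load, ev["condition"])]
        a, b = (lo_ms - mean) / sd, (hi_ms - mean) / sd
        latencies[i] = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)
        dwells[i] = max(
            rng.normal(params.fixation_dwell_ms[ev["condition"]],
                       params.fixation_dwell_sd_ms),
            150.0,
        )

    # --- build the gaze transition chain -------------------------------
    transitions: list[_Transition] = []
    truth_rows = []
    pos = center_screen
    ev_list = events.reset_index(drop=True)
    t_sacc = ev_list["onset_s"].to_numpy() + latencies / 1000.0
    for i, ev in ev_list.iterrows():
        loc = (int(ev["row"]), int(ev["col"]))
        scatter = rng.normal(0.0, params.fixation_scatter_px, 2)
        fix = (centers[loc][0] + scatter[0], centers[loc][1] + scatter[1])
        transitions.append(
            _Transition(float(t_sacc[i]), pos, fix, "saccade",
                        duration=_rise_for(pos, fix, geom))
        )
        pos = fix
        last_of_trial = (
            i + 1 >= len(ev_list) or ev_list["trial"].iloc[i + 1] != ev["trial"]
        )
        nxt_center = (
            centers[(int(ev_list["row"].iloc[i + 1]), int(ev_list["col"].iloc[i + 1]))]
            if not last_of_trial
            else center_screen
        )
        t_drift = float(t_sacc[i]) + dwells[i] / 1000.0
        t_limit = (
            float(t_sacc[i + 1]) - 0.06
            if not last_of_trial
            else float(ev["onset_s"]) + cfg.highlight_duration + 1.0 - 0.06
        )
        if t_drift + DRIFT_DURATION_S < t_limit:
            park = _park_position(fix, nxt_center, geom)
            transitions.append(_Transition(t_drift, pos, park, "drift"))
            pos = park
        if last_of_trial:
            t_return = float(ev["onset_s"]) + cfg.highlight_duration + 1.0
            transitions.append(
                _Transition(t_return, pos, center_screen, "drift", duration=1.5)
            )
            pos = center_screen
        truth_rows.append(
            {
                "event_id": i,
                "trial": int(ev["trial"]),
                "serial_pos": int(ev["serial_pos"]),
                "row": loc[0],
                "col": loc[1],
                "onset_s": float(ev["onset_s"]),
                "is_target": bool(ev["is_target"]),
                "is_hit": bool(ev["is_hit"]),
                "condition": ev["condition"],
                "t_peak_true": float(t_sacc[i]),
                "latency_true_ms": float(latencies[i]),
                "dwell_true_ms": float(dwells[i]),
            }
        )
    truth = pd.DataFrame(truth_rows)

    # --- EOG at EEG rate ------------------------------------------------
    gx_eeg, gy_eeg = _eval_gaze(transitions, t_eeg, center_screen)
    ax, ay = _gaze_angles_deg(gx_eeg, gy_eeg, geom)
    heog = params.eog_gain * ax + rng.normal(0.0, params.eog_noise_sd, n_eeg)
    veog = params.eog_gain * ay + rng.normal(0.0, params.eog_noise_sd, n_eeg)

    # noise spikes (short, large)
    n_spikes = rng.poisson(params.eog_spike_rate_per_min * duration / 60.0 * 2)
    for _ in range(n_spikes):
        ch = rng.integers(2)
        i0 = rng.integers(0, n_eeg - 4)
        sgn = rng.choice([-1.0, 1.0])
        target = heog if ch == 0 else veog
        target[i0:i0 + 3] += sgn * params.eog_spike_amplitude

    veog, blink_intervals = inject_blinks(
        veog, params.eeg_fs, params.blink_rate_per_min, rng,
        amplitude=params.blink_amplitude,
        width_range_ms=params.blink_width_range_ms,
    )

    # --- EEG -------------------------------------------------------------
    eeg = np.empty((len(EEG_CHANNELS), n_eeg))
    for c in range(len(EEG_CHANNELS)):
        eeg[c] = _pink_noise(rng, n_eeg, params.pink_noise_exponent, params.eeg_noise_sd)
        eeg[c] += rng.normal(0.0, params.eeg_white_noise_sd, n_eeg)
    if params.bad_channel is not None:
        bi = EEG_CHANNELS.index(params.bad_channel)
        eeg[bi] *= params.bad_channel_factor

    # P300-like bump per event
    amps = np.where(
        truth["is_target"],
        np.where(truth["is_hit"], params.p300_amplitude_target, params.miss_amplitude),
        params.p300_amplitude_nontarget,
    ).astype(float)
    truth["p300_amp"] = amps
    weights = np.array([params.p300_channel_weights.get(ch, 0.0) for ch in EEG_CHANNELS])
    half = params.p300_width / 2.0
    for i in range(len(truth)):
        c0 = truth["t_peak_true"].iloc[i] + params.p300_latency
        i0 = max(int((c0 - half) * params.eeg_fs), 0)
        i1 = min(int((c0 + half) * params.eeg_fs) + 1, n_eeg)
        if i1 <= i0:
            continue
        tt = t_eeg[i0:i1]
        bump = amps[i] * np.cos(np.pi * (tt - c0) / params.p300_width) ** 2
        bump[np.abs(tt - c0) > half] = 0.0
        eeg[:, i0:i1] += weights[:, None] * bump[None, :]

    # --- eye streams -----------------------------------------------------
    gx, gy = _eval_gaze(transitions, t_eye, center_screen)
    gx = gx + rng.normal(0.0, params.gaze_jitter_px, n_eye)
    gy = gy + rng.normal(0.0, params.gaze_jitter_px, n_eye)
    # recorded gaze carries the (mis)calibration the analysis must undo
    gx = params.gaze_scale * gx + params.gaze_offset_px[0]
    gy = params.gaze_scale * gy + params.gaze_offset_px[1]

    baseline = params.pupil_baseline_high if schedule.load == "high" else params.pupil_baseline_low
    drift = ndimage.gaussian_filter1d(
        rng.standard_normal(n_eye), params.pupil_drift_timescale_s * params.eye_fs,
        mode="reflect",
    )
    s = drift.std()
    if s > 0:
        drift *= params.pupil_drift_sd / s
    pupil = baseline + drift + rng.normal(0.0, params.pupil_noise_sd, n_eye)
    for _, ev in truth[truth["condition"] == "miss"].iterrows():
        i0 = int(ev["onset_s"] * params.eye_fs)
        i1 = min(int((ev["onset_s"] + 2.0) * params.eye_fs), n_eye)
        pupil[i0:i1] += params.pupil_miss_increment

    validity = rng.random(n_eye) >= params.invalid_sample_prob
    for b0, b1 in blink_intervals:
        validity[int(b0 * params.eye_fs): int(np.ceil(b1 * params.eye_fs)) + 1] = False

    return ContinuousRecording(
        eeg=eeg,
        channel_names=EEG_CHANNELS,
        heog=heog,
        veog=veog,
        eeg_fs=params.eeg_fs,
        gaze_x=gx,
        gaze_y=gy,
        pupil=pupil,
        validity=validity,
        eye_fs=params.eye_fs,
        events=events,
        load=schedule.load,
        truth=truth,
        blink_intervals=blink_intervals,
        geometry=geom,
    )


# ----------------------------------------------------------------------
# Recording I/O: a session directory with 16-bit-quantized signals (HDF5)
# plus plain-text event / gaze / truth tables.
# ----------------------------------------------------------------------

_QUANT_BITS = 16


def _quantize(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        hi = lo + 1.0
    step = (hi - lo) / (2 ** _QUANT_BITS - 1)
    digital = np.round((x - lo) / step).astype(np.uint16)
    return digital, lo, step


def write_recording(rec: ContinuousRecording, path: str | Path) -> Path:
    """Write a session directory: signals.h5 (16-bit quantized EEG/EOG),
    gaze.tsv, events.tsv, truth.tsv, meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / "signals.h5", "w") as f:
        for name, data in [("eeg", rec.eeg), ("heog", rec.heog), ("veog", rec.veog)]:
            digital, lo, step = _quantize(np.asarray(data))
            ds = f.create_dataset(name, data=digital, compression="gzip")
            ds.attrs["offset"] = lo
            ds.attrs["step"] = step
        f.attrs["eeg_fs"] = rec.eeg_fs
        f.attrs["channel_names"] = list(rec.channel_names)
    gaze = pd.DataFrame(
        {
            "time_s": rec.eye_times,
            "x_px": rec.gaze_x,
            "y_px": rec.gaze_y,
            "pupil_mm": rec.pupil,
            "valid": rec.validity.astype(int),
        }
    )
    gaze.to_csv(path / "gaze.tsv", sep="\t", index=False, float_format="%.6f")
    rec.events.to_csv(path / "events.tsv", sep="\t", index=False)
    if rec.truth is not None:
        rec.truth.to_csv(path / "truth.tsv", sep="\t", index=False)
    meta = {
        "eye_fs": rec.eye_fs,
        "load": rec.load,
        "blink_intervals": rec.blink_intervals,
        "geometry": dataclasses.asdict(rec.geometry),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_recording(path: str | Path) -> ContinuousRecording:
    """Read a session directory written by :func:`write_recording`.

    Raises FileNotFoundError / KeyError naming the missing piece on
    malformed input.
    """
    path = Path(path)
    sig = path / "signals.h5"
    if not sig.exists():
        raise FileNotFoundError(f"missing signal file: {sig}")
    with h5py.File(sig, "r") as f:
        for required in ("eeg", "heog", "veog"):
            if required not in f:
                raise KeyError(f"signal file missing required channel group '{required}'")
        def load(name: str) -> np.ndarray:
            ds = f[name]
            return ds[()].astype(float) * ds.attrs["step"] + ds.attrs["offset"]
        eeg = load("eeg")
        heog = load("heog")
        veog = load("veog")
        eeg_fs = float(f.attrs["eeg_fs"])
        channels = tuple(
            n.decode() if isinstance(n, bytes) else str(n)
            for n in f.attrs["channel_names"]
        )
    gaze = pd.read_csv(path / "gaze.tsv", sep="\t")
    events = pd.read_csv(path / "events.tsv", sep="\t")
    truth_path = path / "truth.tsv"
    truth = pd.read_csv(truth_path, sep="\t") if truth_path.exists() else None
    meta = json.loads((path / "meta.json").read_text())
    return ContinuousRecording(
        eeg=eeg,
        channel_names=channels,
        heog=heog,
        veog=veog,
        eeg_fs=eeg_fs,
        gaze_x=gaze["x_px"].to_numpy(),
        gaze_y=gaze["y_px"].to_numpy(),
        pupil=gaze["pupil_mm"].to_numpy(),
        validity=gaze["valid"].to_numpy().astype(bool),
        eye_fs=float(meta["eye_fs"]),
        events=events,
        load=meta["load"],
        truth=truth,
        blink_intervals=[tuple(b) for b in meta["blink_intervals"]],
        geometry=ScreenGeometry(**meta["geometry"]),
    )
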