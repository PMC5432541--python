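"""EOG conditioning: despiking, blink removal, and the velocity trace.

The cleaning chain mirrors the saccade-extraction procedure used for
EOG-based saccade detection: (A) noise spikes are values exceeding a
multiple of the channel's standard deviation, cut out and linearly
interpolated; (B) blinks are supra-threshold peaks of a 2-100 Hz
bandpassed copy of the vertical EOG, cut out of the original signal and
interpolated; (C) the saccade velocity trace is the convolution of the
cleaned EOG with a derivative-of-Gaussian kernel (sigma = 8 samples at
256 Hz, about 31 ms), normalised so that a unit-slope ramp maps to its
slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "PipelineParams",
    "despike",
    "detect_and_remove_blinks",
    "gaussian_derivative_filter",
    "clean_eog",
]


@dataclass
class PipelineParams:
    """Every numeric threshold of the analysis chain, in one place.

    SD multipliers are unitless; spans in the units their names state.
    ``velocity_sigma`` is in samples at the working rate (8 samples at
    256 Hz ~ 31 ms).
    """

    working_fs: float = 256.0
    spike_k: float = 5.0
    spike_pad_ms: float = 50.0
    blink_k: float = 3.0
    blink_band: tuple[float, float] = (2.0, 100.0)
    blink_merge_gap_ms: float = 100.0
    blink_pad_ms: float = 100.0
    blink_min_width_ms: float = 30.0
    velocity_sigma: float = 8.0
    candidate_k: float = 4.0
    candidate_merge_gap_ms: float = 20.0
    saccade_window_ms: tuple[float, float] = (100.0, 800.0)
    badchan_k: float = 5.0
    eeg_band: tuple[float, float] = (0.5, 32.0)
    epoch_span_s: tuple[float, float] = (0.0, 1.0)
    baseline_span_s: float = 0.1
    outlier_k: float = 50.0
    svm_interval_ms: tuple[float, float] = (250.0, 1000.0)
    fixation_radius_px: float = 150.0
    fixation_window_s: tuple[float, float] = (0.0, 2.0)
    cv_folds: int = 5
    alpha: float = 0.05
    min_misses: int = 10
    svm_c: float = 1.0

    def __post_init__(self) -> None:
        for name in ("spike_k", "blink_k", "candidate_k", "badchan_k", "outlier_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("blink_band", "saccade_window_ms", "eeg_band",
                     "epoch_span_s", "svm_interval_ms", "fixation_window_s"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be well-ordered")


def _runs_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index ranges of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, len(mask)]
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < max_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _pad_runs(runs: list[tuple[int, int]], pad: int, n: int) -> list[tuple[int, int]]:
    padded = [(max(s - pad, 0), min(e + pad, n)) for s, e in runs]
    return _merge_runs(padded, 1)


def _cut_and_interpolate(x: np.ndarray, runs: list[tuple[int, int]]) -> np.ndarray:
    """Replace flagged runs by linear interpolation between flanking clean
    samples; endpoints are held at the nearest clean value."""
    out = x.astype(float).copy()
    bad = np.zeros(len(x), bool)
    for s, e in runs:
        bad[s:e] = True
    if not bad.any():
        return out
    if bad.all():
        raise ValueError("entire signal flagged; nothing to interpolate from")
    good = np.flatnonzero(~bad)
    out[bad] = np.interp(np.flatnonzero(bad), good, out[good])
    return out


def despike(
    x: np.ndarray, k: float = 5.0, fs: float = 256.0, pad_ms: float = 50.0
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Remove large-amplitude noise spikes from an EOG channel.

    Samples deviating from the channel mean by more than ``k`` times the
    channel SD (computed over the whole channel) are flagged; flagged runs
    are padded by ``pad_ms`` on both sides, cut out and linearly
    interpolated.  Returns the cleaned copy and the removed [start, end)
    sample intervals.
    """
    x = np.asarray(x, float)
    if len(x) < 3:
        raise ValueError("signal too short")
    if not np.isfinite(x).all():
        raise ValueError("signal contains non-finite values")
    sd = x.std()
    if sd == 0:
        return x.copy(), []
    mask = np.abs(x - x.mean()) > k * sd
    runs = _pad_runs(_runs_from_mask(mask), int(round(pad_ms / 1000.0 * fs)), len(x))
    return _cut_and_interpolate(x, runs), runs


def detect_and_remove_blinks(
    veog: np.ndarray, fs: float, params: PipelineParams | None = None
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Detect blinks on a bandpassed copy of the vertical EOG and
    interpolate them out of the original signal.

    Detection: bandpass (2-100 Hz, clipped below Nyquist), flag samples
    whose filtered value exceeds ``blink_k`` times the filtered channel's
    SD (one-sided: blinks are positive VEOG deflections, and a signed
    threshold spares the transients of downward saccade steps), merge
    runs closer than ``blink_merge_gap_ms``, drop runs shorter than
    ``blink_min_width_ms`` (a physiological blink lasts >= ~100 ms;
    isolated supra-threshold noise samples are not blinks) and pad the
    survivors by ``blink_pad_ms``.  The cut-and-interpolate step runs on
    the ORIGINAL signal.
    """
    p = params or PipelineParams()
    veog = np.asarray(veog, float)
    if not np.isfinite(veog).all():
        raise ValueError("signal contains non-finite values")
    lo, hi = p.blink_band
    hi = min(hi, 0.95 * fs / 2.0)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, veog)
    sd = filt.std()
    if sd == 0:
        return veog.copy(), []
    mask = filt > p.blink_k * sd
    runs = _merge_runs(_runs_from_mask(mask), int(round(p.blink_merge_gap_ms / 1000.0 * fs)))
    min_len = int(round(p.blink_min_width_ms / 1000.0 * fs))
    runs = [(s, e) for s, e in runs if e - s >= min_len]
    runs = _pad_runs(runs, int(round(p.blink_pad_ms / 1000.0 * fs)), len(veog))
    return _cut_and_interpolate(veog, runs), runs


def gaussian_derivative_filter(x: np.ndarray, sigma: float = 8.0) -> np.ndarray:
    """Velocity trace: convolution with a derivative-of-Gaussian kernel.

    The kernel is truncated at +/-4 sigma and normalised so that a
    unit-slope ramp maps to a constant 1 (output units: signal units per
    sample).  Positive output for a rising signal.  Edges use reflected
    padding; output length equals input length.
    """
    x = np.asarray(x, float)
    if sigma < 1:
        raise ValueError("sigma must be >= 1 sample")
    half = int(np.ceil(4 * sigma))
    if len(x) <= 2 * half:
        raise ValueError("signal shorter than the filter kernel")
    t = np.arange(-half, half + 1, dtype=float)
    kernel = t * np.exp(-0.5 * (t / sigma) ** 2)
    # normalise so a unit-slope ramp maps to 1: sum_t t * kernel[t] = 1
    kernel /= np.sum(t * kernel)
    padded = np.pad(x, half, mode="reflect")
    # correlation: y[n] = sum_t kernel[t] x[n+t]; positive for rising x
    return np.correlate(padded, kernel, mode="valid")


def clean_eog(
    heog: np.ndarray, veog: np.ndarray, fs: float, params: PipelineParams | None = None
) -> dict:
    """Full EOG chain: despike both channels, deblink VEOG, velocity traces.

    Returns a dict with cleaned channels, removed intervals and the
    horizontal/vertical velocity traces.
    """
    p = params or PipelineParams()
    h_clean, h_spikes = despike(heog, p.spike_k, fs, p.spike_pad_ms)
    v_desp, v_spikes = despike(veog, p.spike_k, fs, p.spike_pad_ms)
    v_clean, blinks = detect_and_remove_blinks(v_desp, fs, p)
    return {
        "heog": h_clean,
        "veog": v_clean,
        "spike_intervals_h": h_spikes,
        "spike_intervals_v": v_spikes,
        "blink_intervals": blinks,
        "velocity_h": gaussian_derivative_filter(h_clean, p.velocity_sigma),
        "velocity_v": gaussian_derivative_filter(v_clean, p.velocity_sigma),
    }
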