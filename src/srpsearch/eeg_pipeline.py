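"""EEG conditioning and saccade-locked epoch extraction.

Fixed processing order: resample to 256 Hz -> bad-channel detection (on a
0.5-32 Hz bandpassed copy) -> interpolation of bad channels (on the
unfiltered data) -> average re-reference over good channels (unfiltered)
-> 0.5-32 Hz bandpass -> epoch extraction [peak velocity, +1 s) ->
baseline over the first 100 ms of the epoch -> variance-based outlier
rejection.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from srpsearch.eog_pipeline import PipelineParams
from srpsearch.signal_synthesis import ContinuousRecording

__all__ = [
    "EpochSet",
    "resample_recording",
    "detect_bad_channels",
    "interpolate_bad_channels",
    "rereference_average",
    "bandpass_eeg",
    "extract_epochs",
    "reject_outlier_epochs",
    "preprocess_eeg",
    "channel_positions",
]

_MONTAGE_CACHE: dict[str, np.ndarray] = {}


def channel_positions(names: tuple[str, ...]) -> np.ndarray:
    """3D scalp positions (metres) from the standard 10-20 montage."""
    key = "|".join(names)
    if key not in _MONTAGE_CACHE:
        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            montage = mne.channels.make_standard_montage("standard_1005")
        pos = montage.get_positions()["ch_pos"]
        missing = [n for n in names if n not in pos]
        if missing:
            raise ValueError(f"channels not in 10-20 montage: {missing}")
        _MONTAGE_CACHE[key] = np.array([pos[n] for n in names])
    return _MONTAGE_CACHE[key]


@dataclass
class EpochSet:
    """Saccade-locked voltage epochs with condition labels.

    ``data`` is epochs x channels x samples at ``fs``; t = 0 is the
    saccade peak-velocity time and the time axis runs over [0, 1 s).
    ``labels`` has one row per retained epoch (event_id, condition,
    is_target, is_hit, ...).  ``rejected_epoch_ids`` holds event ids
    dropped by outlier rejection; ``n_skipped`` counts saccades too close
    to the recording end to epoch.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    fs: float
    labels: pd.DataFrame
    load: str
    participant: str | int | None = None
    rejected_epoch_ids: list[int] = field(default_factory=list)
    n_skipped: int = 0

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[2]) / self.fs

    def pick(self, channels: tuple[str, ...] | list[str]) -> np.ndarray:
        idx = [self.channel_names.index(c) for c in channels]
        return self.data[:, idx, :]

    def condition_mask(self, condition: str) -> np.ndarray:
        if condition == "target":
            return self.labels["is_target"].to_numpy(bool)
        if condition == "nontarget":
            return ~self.labels["is_target"].to_numpy(bool)
        return (self.labels["condition"] == condition).to_numpy()


def resample_recording(rec: ContinuousRecording, target_fs: float) -> ContinuousRecording:
    """Polyphase anti-aliased resampling of all EEG-rate channels.

    Event times are in seconds and are unchanged; eye streams keep their
    own clock.  Upsampling requests are rejected.  The resampled length is
    ``ceil(n * target_fs / native_fs)`` (the resampler's contract).
    """
    if target_fs > rec.eeg_fs:
        raise ValueError("upsampling not supported")
    if target_fs == rec.eeg_fs:
        return rec.copy()
    frac = Fraction(target_fs / rec.eeg_fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator

    def rs(x: np.ndarray) -> np.ndarray:
        return sps.resample_poly(x, up, down, axis=-1)

    return dataclasses.replace(
        rec,
        eeg=rs(rec.eeg),
        heog=rs(rec.heog),
        veog=rs(rec.veog),
        eeg_fs=float(target_fs),
        events=rec.events.copy(),
    )


def bandpass_eeg(
    eeg: np.ndarray, fs: float, low: float = 0.5, high: float = 32.0
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth bandpass (forward-backward)."""
    if not 0.0 < low < high < fs / 2.0:
        raise ValueError("invalid band edges")
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.atleast_2d(eeg), axis=-1).reshape(np.shape(eeg))


def detect_bad_channels(
    eeg: np.ndarray,
    fs: float,
    channel_names: tuple[str, ...],
    params: PipelineParams | None = None,
) -> list[str]:
    """Channels whose bandpassed SD exceeds ``badchan_k`` times the median
    bandpassed SD over all channels.  The input data are untouched."""
    p = params or PipelineParams()
    if eeg.shape[0] < 3:
        raise ValueError("need at least 3 channels")
    filt = bandpass_eeg(eeg, fs, *p.eeg_band)
    sds = filt.std(axis=1)
    threshold = p.badchan_k * np.median(sds)
    return [channel_names[i] for i in np.flatnonzero(sds > threshold)]


def interpolate_bad_channels(
    eeg: np.ndarray,
    channel_names: tuple[str, ...],
    bads: list[str],
    k_neighbors: int = 4,
) -> np.ndarray:
    """Replace each bad channel by an inverse-distance-weighted average of
    its ``k_neighbors`` nearest good channels (weights sum to 1).

    Operates on the unfiltered data; positions come from the standard
    10-20 montage.
    """
    unknown = set(bads) - set(channel_names)
    if unknown:
        raise ValueError(f"bad channels not in recording: {sorted(unknown)}")
    good = [c for c in channel_names if c not in bads]
    if not good:
        raise ValueError("all channels bad; cannot interpolate")
    if not bads:
        return eeg.copy()
    pos = channel_positions(channel_names)
    out = eeg.copy()
    good_idx = np.array([channel_names.index(c) for c in good])
    for b in bads:
        bi = channel_names.index(b)
        d = np.linalg.norm(pos[good_idx] - pos[bi], axis=1)
        order = np.argsort(d)[: min(k_neighbors, len(good_idx))]
        w = 1.0 / np.maximum(d[order], 1e-12)
        w /= w.sum()
        out[bi] = w @ eeg[good_idx[order]]
    return out


def rereference_average(
    eeg: np.ndarray, channel_names: tuple[str, ...], bads: list[str] | None = None
) -> np.ndarray:
    """Subtract, at every sample, the mean over good channels from all
    channels; afterwards the good-channel mean is zero everywhere."""
    bads = bads or []
    good_idx = [i for i, c in enumerate(channel_names) if c not in bads]
    if len(good_idx) < 2:
        raise ValueError("need at least 2 good channels to re-reference")
    ref = eeg[good_idx].mean(axis=0, keepdims=True)
    return eeg - ref


def extract_epochs(
    eeg: np.ndarray,
    fs: float,
    channel_names: tuple[str, ...],
    saccades: pd.DataFrame,
    events: pd.DataFrame,
    load: str,
    participant: str | int | None = None,
    params: PipelineParams | None = None,
) -> EpochSet:
    """Cut saccade-locked epochs [t0, t0 + 1 s) and baseline them.

    ``saccades`` is the table from
    :func:`srpsearch.saccade_detection.select_session_saccades`; only
    matched events are epoched.  Per channel, the mean of the first
    ``floor(0.1 * fs)`` samples is subtracted.  Saccades whose epoch would
    run past the end of the recording are skipped (counted, warned).
    """
    p = params or PipelineParams()
    span = p.epoch_span_s[1] - p.epoch_span_s[0]
    n_samp = int(round(span * fs))
    n_base = int(np.floor(p.baseline_span_s * fs))
    ev = events.reset_index(drop=True).copy()
    ev["event_id"] = np.arange(len(ev))
    matched = saccades[saccades["matched"]]
    epochs, labels, skipped = [], [], 0
    for _, s in matched.iterrows():
        i0 = int(round((s["peak_time_s"] + p.epoch_span_s[0]) * fs))
        if i0 < 0 or i0 + n_samp > eeg.shape[1]:
            skipped += 1
            continue
        seg = eeg[:, i0:i0 + n_samp].astype(float).copy()
        seg -= seg[:, :n_base].mean(axis=1, keepdims=True)
        epochs.append(seg)
        lab = ev.iloc[int(s["event_id"])].to_dict()
        lab.update(peak_time_s=float(s["peak_time_s"]), latency_ms=float(s["latency_ms"]))
        labels.append(lab)
    if skipped:
        warnings.warn(f"skipped {skipped} saccades too close to the recording end")
    data = np.array(epochs) if epochs else np.empty((0, eeg.shape[0], n_samp))
    return EpochSet(
        data=data,
        channel_names=tuple(channel_names),
        fs=fs,
        labels=pd.DataFrame(labels),
        load=load,
        participant=participant,
        n_skipped=skipped,
    )


def reject_outlier_epochs(epochs: EpochSet, k: float = 50.0) -> EpochSet:
    """Drop epochs with extreme variance.

    An epoch is discarded iff, on any channel, its within-epoch SD exceeds
    ``k`` times the median within-epoch SD of that channel across epochs.
    """
    if epochs.data.shape[0] < 2:
        return epochs
    sds = epochs.data.std(axis=2)              # epochs x channels
    med = np.median(sds, axis=0, keepdims=True)
    bad = (sds > k * med).any(axis=1)
    rejected = epochs.labels.loc[bad, "event_id"].astype(int).tolist()
    return dataclasses.replace(
        epochs,
        data=epochs.data[~bad],
        labels=epochs.labels.loc[~bad].reset_index(drop=True),
        rejected_epoch_ids=list(epochs.rejected_epoch_ids) + rejected,
    )


def preprocess_eeg(
    rec: ContinuousRecording,
    params: PipelineParams | None = None,
) -> tuple[ContinuousRecording, list[str]]:
    """Condition a (resampled) recording: bad channels -> interpolation ->
    average reference -> bandpass.  Returns the processed recording and
    the bad-channel list."""
    p = params or PipelineParams()
    bads = detect_bad_channels(rec.eeg, rec.eeg_fs, rec.channel_names, p)
    eeg = interpolate_bad_channels(rec.eeg, rec.channel_names, bads)
    eeg = rereference_average(eeg, rec.channel_names, bads)
    eeg = bandpass_eeg(eeg, rec.eeg_fs, *p.eeg_band)
    return dataclasses.replace(rec, eeg=eeg, events=rec.events.copy()), bads
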