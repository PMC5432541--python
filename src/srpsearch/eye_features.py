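"""Gaze recalibration and per-highlight fixation / pupil features.

Gaze is recalibrated against the 15 known stimulus positions: the median
gaze during the settled part of each highlight is mapped onto the true
stimulus centre by a global least-squares affine transform.  Per
highlight, fixation duration is the cumulative time that valid gaze
samples lie within the fixation radius (150 px) of the stimulus centre
during the 2 s post-onset window, and pupil size is the mean (or,
optionally, median) pupil over those same samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from srpsearch.eog_pipeline import PipelineParams
from srpsearch.signal_synthesis import ContinuousRecording, stimulus_centers_px

__all__ = ["recalibrate_gaze", "fixation_features", "session_eye_features"]

# settled-fixation window (s after highlight onset) used for recalibration;
# the first 300 ms are excluded to avoid pre-saccade gaze
RECAL_WINDOW_S = (0.3, 1.0)


def recalibrate_gaze(
    gaze_x: np.ndarray,
    gaze_y: np.ndarray,
    times: np.ndarray,
    events: pd.DataFrame,
    centers: dict[tuple[int, int], tuple[float, float]],
    validity: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit and apply a global 2D affine transform to the gaze stream.

    For every highlight, the median valid gaze position over
    ``RECAL_WINDOW_S`` after onset is paired with the true stimulus
    centre; a least-squares affine map (6 parameters) from measured to
    true positions is fitted and applied to the whole stream.  Degenerate
    geometry (fewer than 3 non-collinear anchor points) falls back to a
    translation-only fit with a warning.

    Returns (x', y', A) where A is the 3x2 affine matrix acting on
    ``[x, y, 1]`` row vectors.
    """
    gaze_x = np.asarray(gaze_x, float)
    gaze_y = np.asarray(gaze_y, float)
    valid = (
        np.ones(len(gaze_x), bool) if validity is None else np.asarray(validity, bool)
    )
    measured, true = [], []
    for _, ev in events.iterrows():
        t0 = ev["onset_s"] + RECAL_WINDOW_S[0]
        t1 = ev["onset_s"] + RECAL_WINDOW_S[1]
        m = (times >= t0) & (times < t1) & valid
        if m.sum() < 3:
            continue
        measured.append((np.median(gaze_x[m]), np.median(gaze_y[m])))
        true.append(centers[(int(ev["row"]), int(ev["col"]))])
    if len({(int(r), int(c)) for r, c in (t for t in true)}) < 2:
        raise ValueError("need gaze anchors at >= 2 distinct stimulus locations")
    M = np.asarray(measured)
    T = np.asarray(true)
    X = np.column_stack([M, np.ones(len(M))])
    # collinearity check on the measured anchors
    rank = np.linalg.matrix_rank(X - X.mean(axis=0), tol=1e-6 * max(X.std(), 1.0))
    if rank < 2 or len(M) < 3:
        warnings.warn("degenerate anchor geometry; translation-only recalibration")
        shift = (T - M).mean(axis=0)
        A = np.vstack([np.eye(2), shift])
    else:
        A, *_ = np.linalg.lstsq(X, T, rcond=None)
    pts = np.column_stack([gaze_x, gaze_y, np.ones(len(gaze_x))])
    out = pts @ A
    return out[:, 0], out[:, 1], A


def fixation_features(
    gaze_x: np.ndarray,
    gaze_y: np.ndarray,
    pupil: np.ndarray,
    validity: np.ndarray,
    times: np.ndarray,
    eye_fs: float,
    onset_s: float,
    center: tuple[float, float],
    params: PipelineParams | None = None,
    pupil_statistic: str = "mean",
) -> dict:
    """Fixation duration and pupil size for one highlight.

    Valid samples in ``[onset, onset + 2 s)`` count as on-stimulus when
    their Euclidean distance to the stimulus centre is at most the
    fixation radius.  Duration is the on-stimulus sample count divided by
    the eye rate; pupil is the mean (default) or median over those same
    samples.  With zero valid samples the feature is missing (NaN), not
    zero.
    """
    p = params or PipelineParams()
    if pupil_statistic not in ("mean", "median"):
        raise ValueError("pupil_statistic must be 'mean' or 'median'")
    w0, w1 = p.fixation_window_s
    m = (times >= onset_s + w0) & (times < onset_s + w1)
    valid = m & np.asarray(validity, bool)
    n_window = int(m.sum())
    if valid.sum() == 0:
        return {
            "fixation_duration_ms": np.nan,
            "pupil_mm": np.nan,
            "valid_fraction": 0.0,
            "missing": True,
        }
    d = np.hypot(gaze_x[valid] - center[0], gaze_y[valid] - center[1])
    on = d <= p.fixation_radius_px
    pupil_on = pupil[valid][on]
    stat = np.mean if pupil_statistic == "mean" else np.median
    return {
        "fixation_duration_ms": float(on.sum() / eye_fs * 1000.0),
        "pupil_mm": float(stat(pupil_on)) if on.any() else np.nan,
        "valid_fraction": float(valid.sum() / n_window) if n_window else 0.0,
        "missing": False,
    }


def session_eye_features(
    rec: ContinuousRecording,
    params: PipelineParams | None = None,
    recalibrate: bool = True,
    pupil_statistic: str = "mean",
) -> pd.DataFrame:
    """Per-event fixation/pupil feature table for a session recording."""
    p = params or PipelineParams()
    events = rec.events.reset_index(drop=True)
    n_rows = int(events["row"].max()) + 1
    n_cols = int(events["col"].max()) + 1
    centers = stimulus_centers_px(n_rows, n_cols, rec.geometry)
    times = rec.eye_times
    gx, gy = rec.gaze_x, rec.gaze_y
    if recalibrate:
        gx, gy, _ = recalibrate_gaze(gx, gy, times, events, centers, rec.validity)
    rows = []
    for i, ev in events.iterrows():
        feats = fixation_features(
            gx, gy, rec.pupil, rec.validity, times, rec.eye_fs,
            float(ev["onset_s"]), centers[(int(ev["row"]), int(ev["col"]))],
            p, pupil_statistic,
        )
        feats["event_id"] = int(i)
        rows.append(feats)
    out = pd.DataFrame(rows)
    return out[["event_id", "fixation_duration_ms", "pupil_mm", "valid_fraction", "missing"]]
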