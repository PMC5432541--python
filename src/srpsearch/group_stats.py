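"""Group-level statistics: grand-average SRPs, pointwise paired t-tests
with Benjamini-Hochberg correction, scalar paired tests, correlations.

The SRP summary follows the study design: per participant, epochs are
averaged within condition and over the parieto-central channel set
(CP1, P3, Pz, PO3, PO4, P4, CP2); the grand average is the unweighted
mean over participants.  Pointwise two-sided paired t-tests across
participants are run at every time sample and corrected with the
Benjamini-Hochberg step-up over the whole epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


from srpsearch.signal_synthesis import PARIETO_CENTRAL

__all__ = [
    "PointwiseTestResult",
    "average_srp",
    "pointwise_paired_ttest",
    "bh_correct",
    "paired_feature_test",
    "correlate_performance",
]


@dataclass
class PointwiseTestResult:
    """Pointwise paired-test outcome along the epoch time axis."""

    times: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    sig_uncorrected: np.ndarray
    sig_bh: np.ndarray
    conditions: tuple[str, str]
    alpha: float
    n_participants: int
    zero_variance_samples: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        for arr in (self.t_values, self.p_values, self.sig_uncorrected, self.sig_bh):
            if len(arr) != n:
                raise ValueError("result arrays must match the time axis")
        if (self.sig_bh & ~self.sig_uncorrected).any():
            raise AssertionError("BH mask must be a subset of the uncorrected mask")


def average_srp(
    epoch_sets: dict,
    conditions: tuple[str, ...] = ("target", "nontarget", "hit", "miss"),
    channels: tuple[str, ...] = PARIETO_CENTRAL,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Per-participant condition-mean traces and grand averages.

    ``epoch_sets`` maps participant id -> :class:`EpochSet`.  Per
    participant and condition: mean over epochs, then over the channel
    set.  Participants without any epoch in a condition are excluded from
    that condition's average (logged via the returned table's NaN rows).

    Returns a long-format table (participant, condition, time_s, mean)
    and a dict condition -> grand-average trace.
    """
    if not channels:
        raise ValueError("empty channel set")
    rows = []
    traces: dict[str, list[np.ndarray]] = {c: [] for c in conditions}
    times = None
    for pid, es in epoch_sets.items():
        if es.data.shape[0] == 0:
            continue
        times = es.times
        sub = es.pick(channels)
        for cond in conditions:
            mask = es.condition_mask(cond)
            if not mask.any():
                continue
            trace = sub[mask].mean(axis=0).mean(axis=0)
            traces[cond].append(trace)
            rows.append(
                pd.DataFrame(
                    {"participant": pid, "condition": cond, "time_s": times, "mean": trace}
                )
            )
    grand = {
        c: (np.mean(t, axis=0) if t else np.full(len(times or []), np.nan))
        for c, t in traces.items()
    }
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["participant", "condition", "time_s", "mean"]
    )
    return table, grand


def participant_traces(
    epoch_sets: dict,
    condition: str,
    channels: tuple[str, ...] = PARIETO_CENTRAL,
) -> tuple[list, np.ndarray]:
    """Participant ids and stacked per-participant mean traces for one
    condition (participants with zero epochs in the condition excluded)."""
    ids, traces = [], []
    for pid, es in epoch_sets.items():
        if es.data.shape[0] == 0:
            continue
        mask = es.condition_mask(condition)
        if not mask.any():
            continue
        ids.append(pid)
        traces.append(es.pick(channels)[mask].mean(axis=0).mean(axis=0))
    return ids, np.array(traces)


def pointwise_paired_ttest(
    traces_a: np.ndarray,
    traces_b: np.ndarray,
    times: np.ndarray,
    conditions: tuple[str, str] = ("A", "B"),
    alpha: float = 0.05,
) -> PointwiseTestResult:
    """Two-sided paired t-test across participants at every time sample.

    ``traces_a`` / ``traces_b`` are participants x samples arrays with
    matching participant order.  Samples with zero difference variance get
    p = 1 and are flagged.  The BH mask is computed over all samples of
    the epoch.
    """
    a = np.asarray(traces_a, float)
    b = np.asarray(traces_b, float)
    if a.shape != b.shape:
        raise ValueError("condition trace arrays must have identical shape")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 participants")
    d = a - b
    sd = d.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_rel(a, b, axis=0)
    t = np.where(zero_var, 0.0, t)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    sig = p < alpha
    bh = bh_correct(p, alpha)
    return PointwiseTestResult(
        times=np.asarray(times, float),
        t_values=t,
        p_values=p,
        sig_uncorrected=sig,
        sig_bh=bh,
        conditions=conditions,
        alpha=alpha,
        n_participants=a.shape[0],
        zero_variance_samples=zero_var,
    )


def bh_correct(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask, in the input order."""
    p = np.asarray(p_values, float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, bool)
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def paired_feature_test(values_a: np.ndarray, values_b: np.ndarray) -> dict:
    """Two-sided paired t-test on per-participant scalar means.

    Returns t, df (= n - 1) and p; zero-variance differences are flagged
    (t = 0, p = 1).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors required")
    if len(a) < 3:
        raise ValueError("need at least 3 paired observations")
    d = a - b
    if d.std(ddof=1) == 0:
        return {"t": 0.0, "df": len(a) - 1, "p": 1.0, "zero_variance": True}
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "df": len(a) - 1, "p": float(p), "zero_variance": False}


def correlate_performance(x: np.ndarray, y: np.ndarray) -> dict:
    """Pearson correlation with two-sided t-based p-value.

    Used for the math-score vs monitoring-hit-rate association across
    participants.  Zero variance in either vector is flagged undefined.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("paired vectors of length >= 3 required")
    if x.std() == 0 or y.std() == 0:
        return {"r": np.nan, "p": np.nan, "undefined": True}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "undefined": False}
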