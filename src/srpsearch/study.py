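"""End-to-end synthetic study: simulate -> synthesize -> preprocess ->
detect saccades -> epoch -> eye features -> group stats -> classify.

``run_study`` simulates ``n_participants`` independent participants, each
with one session per load condition, runs the full analysis chain on each
session, and aggregates group statistics and the classification grid.
Everything is deterministic given the seed; result tables are written as
TSV/CSV with fixed float formatting so identical seeds give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from srpsearch.task_model import (
    BehaviorParams,
    ExperimentConfig,
    behavioral_metrics,
    generate_schedule,
    simulate_behavior,
)
from srpsearch.signal_synthesis import (
    PARIETO_CENTRAL,
    ContinuousRecording,
    ScreenGeometry,
    SignalParams,
    synthesize_recording,
)
from srpsearch.eog_pipeline import PipelineParams, clean_eog
from srpsearch.saccade_detection import (
    compute_saccade_latencies,
    select_session_saccades,
)
from srpsearch.eeg_pipeline import (
    EpochSet,
    extract_epochs,
    preprocess_eeg,
    reject_outlier_epochs,
    resample_recording,
)
from srpsearch.eye_features import session_eye_features
from srpsearch.group_stats import (
    correlate_performance,
    paired_feature_test,
    pointwise_paired_ttest,
)
from srpsearch.single_trial_classification import FEATURE_SETS, comparison_grid

__all__ = ["SessionAnalysis", "StudyResult", "analyse_session", "run_study",
           "default_scaled_config"]


def default_scaled_config() -> ExperimentConfig:
    """Session size used for simulation studies: 2 blocks x 8 trials per
    load (240 highlights, ~48 targets), enough for stable condition means
    and a workable miss count per participant while keeping a simulated
    participant cheap."""
    return ExperimentConfig(n_blocks_per_load=2, n_trials_per_block=8)


@dataclass
class SessionAnalysis:
    """Everything the pipeline derives from one session recording."""

    load: str
    participant: str | int | None
    recording: ContinuousRecording
    saccades: pd.DataFrame
    epochs: EpochSet
    eye_features: pd.DataFrame
    latency_table: pd.DataFrame
    behavioral: dict
    bad_channels: list[str]
    unmatched_fraction: float

    def eye_condition_means(self) -> dict[str, dict[str, float]]:
        """Per-condition mean fixation duration / pupil size (matched
        events with non-missing features)."""
        ev = self.recording.events.reset_index(drop=True).copy()
        ev["event_id"] = np.arange(len(ev))
        feats = self.eye_features.merge(
            ev[["event_id", "condition", "is_target"]], on="event_id"
        )
        feats = feats[~feats["missing"]]
        out: dict[str, dict[str, float]] = {}
        groups = {
            "target": feats[feats["is_target"]],
            "nontarget": feats[~feats["is_target"]],
            "hit": feats[feats["condition"] == "hit"],
            "miss": feats[feats["condition"] == "miss"],
        }
        for name, g in groups.items():
            out[name] = {
                "fixation_duration_ms": float(g["fixation_duration_ms"].mean())
                if len(g) else np.nan,
                "pupil_mm": float(g["pupil_mm"].mean()) if len(g) else np.nan,
                "n": int(len(g)),
            }
        return out


def analyse_session(
    rec: ContinuousRecording,
    params: PipelineParams | None = None,
    participant: str | int | None = None,
    behavioral: dict | None = None,
) -> SessionAnalysis:
    """Run the full single-session analysis chain on a recording."""
    p = params or PipelineParams()
    rec256 = resample_recording(rec, p.working_fs)
    eog = clean_eog(rec256.heog, rec256.veog, rec256.eeg_fs, p)
    saccades = select_session_saccades(
        eog["velocity_h"], eog["velocity_v"], rec256.eeg_fs, rec256.events, p
    )
    processed, bads = preprocess_eeg(rec256, p)
    combined = np.vstack([processed.eeg, eog["heog"][None, :], eog["veog"][None, :]])
    channels = tuple(processed.channel_names) + ("HEOG", "VEOG")
    epochs = extract_epochs(
        combined, rec256.eeg_fs, channels, saccades, rec256.events,
        rec.load, participant, p,
    )
    epochs = reject_outlier_epochs(epochs, p.outlier_k)
    eye = session_eye_features(rec, p)
    latency = compute_saccade_latencies(saccades, rec256.events, participant, rec.load)
    return SessionAnalysis(
        load=rec.load,
        participant=participant,
        recording=rec,
        saccades=saccades,
        epochs=epochs,
        eye_features=eye,
        latency_table=latency,
        behavioral=behavioral or {},
        bad_channels=bads,
        unmatched_fraction=float(1.0 - saccades["matched"].mean()),
    )


@dataclass
class StudyResult:
    """Aggregated outputs of a multi-participant simulation study."""

    n_participants: int
    seed: int
    behavioral: pd.DataFrame          # participant x load hit rates etc.
    latency: pd.DataFrame             # participant x load x condition
    latency_group: pd.DataFrame       # across-participant means
    srp_tests: dict                   # (load, contrast) -> PointwiseTestResult
    srp_traces: dict                  # (load, condition) -> grand-average trace
    srp_times: np.ndarray
    eye_tests: pd.DataFrame           # scalar paired tests
    eye_means: pd.DataFrame           # participant x load x condition means
    classification: pd.DataFrame      # per participant x cell
    classification_summary: pd.DataFrame
    math_correlation: dict
    unmatched_fraction: float

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fmt = "%.6g"
        self.behavioral.to_csv(outdir / "behavior.tsv", sep="\t", index=False,
                               float_format=fmt)
        self.latency.to_csv(outdir / "latency.tsv", sep="\t", index=False,
                            float_format=fmt)
        self.latency_group.to_csv(outdir / "latency_group.tsv", sep="\t",
                                  index=False, float_format=fmt)
        self.eye_tests.to_csv(outdir / "eye_tests.tsv", sep="\t", index=False,
                              float_format=fmt)
        self.eye_means.to_csv(outdir / "eye_means.tsv", sep="\t", index=False,
                              float_format=fmt)
        self.classification.to_csv(outdir / "classification.csv", index=False,
                                   float_format=fmt)
        self.classification_summary.to_csv(
            outdir / "classification_summary.csv", index=False, float_format=fmt
        )
        traces = pd.DataFrame(
            {f"{load}:{cond}": trace for (load, cond), trace in self.srp_traces.items()}
        )
        traces.insert(0, "time_s", self.srp_times)
        traces.to_csv(outdir / "srp_grand_average.tsv", sep="\t", index=False,
                      float_format=fmt)
        tests = []
        for (load, contrast), res in self.srp_tests.items():
            tests.append(
                pd.DataFrame(
                    {
                        "load": load,
                        "contrast": contrast,
                        "time_s": res.times,
                        "t": res.t_values,
                        "p": res.p_values,
                        "sig": res.sig_uncorrected.astype(int),
                        "sig_bh": res.sig_bh.astype(int),
                    }
                )
            )
        test_table = (
            pd.concat(tests, ignore_index=True)
            if tests
            else pd.DataFrame(
                columns=["load", "contrast", "time_s", "t", "p", "sig", "sig_bh"]
            )
        )
        test_table.to_csv(
            outdir / "srp_pointwise_tests.tsv", sep="\t", index=False, float_format=fmt
        )
        summary = {
            "n_participants": self.n_participants,
            "seed": self.seed,
            "unmatched_fraction": round(self.unmatched_fraction, 6),
            "math_correlation": {
                k: (round(v, 6) if isinstance(v, float) and np.isfinite(v) else v)
                for k, v in self.math_correlation.items()
            },
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        return outdir


_CONDITIONS = ("target", "nontarget", "hit", "miss")


def _condition_traces(epochs, channels=PARIETO_CENTRAL) -> dict[str, np.ndarray]:
    """Per-condition mean parieto-central trace for one session."""
    out = {}
    if epochs.data.shape[0] == 0:
        return out
    sub = epochs.pick(channels)
    for cond in _CONDITIONS:
        mask = epochs.condition_mask(cond)
        if mask.any():
            out[cond] = sub[mask].mean(axis=0).mean(axis=0)
    return out


def _simulate_participant(
    pid: int,
    config: ExperimentConfig,
    behavior: BehaviorParams,
    signal: SignalParams,
    geometry: ScreenGeometry,
    rng: np.random.Generator,
    pipeline: PipelineParams,
) -> tuple[dict[str, SessionAnalysis], dict]:
    sessions: dict[str, SessionAnalysis] = {}
    beh_rows: dict = {"participant": pid}
    for load in ("high", "low"):
        schedule = generate_schedule(config, load, int(rng.integers(2**31 - 1)))
        outcomes = simulate_behavior(schedule, behavior, int(rng.integers(2**31 - 1)))
        metrics = behavioral_metrics(schedule, outcomes)
        rec = synthesize_recording(
            schedule, outcomes, signal, geometry, int(rng.integers(2**31 - 1))
        )
        sessions[load] = analyse_session(rec, pipeline, pid, metrics)
        beh_rows[f"hit_rate_{load}"] = metrics["hit_rate"]
        beh_rows[f"false_alarms_{load}"] = metrics["false_alarms"]
        beh_rows[f"misses_{load}"] = metrics["n_targets"] - metrics["n_hits"]
    beh_rows["math_score"] = float(
        np.mean(rng.random(config.n_trials) < config.math_correct_prob)
    )
    return sessions, beh_rows


def run_study(
    n_participants: int = 20,
    seed: int = 0,
    config: ExperimentConfig | None = None,
    behavior: BehaviorParams | None = None,
    signal: SignalParams | None = None,
    geometry: ScreenGeometry | None = None,
    pipeline: PipelineParams | None = None,
    feature_sets: tuple[str, ...] = FEATURE_SETS,
    outdir: str | Path | None = None,
) -> StudyResult:
    """Simulate and analyse a complete multi-participant study.

    Each participant gets an independent high-load and low-load session.
    Group statistics follow the study design: pointwise paired t-tests on
    parieto-central SRP traces (target vs non-target per load; hit vs miss
    in the high-load condition), scalar paired tests on fixation duration
    and pupil size, the saccade-latency table, and the classification
    grid.  Participants lacking a condition are excluded pairwise per
    contrast.
    """
    config = config or default_scaled_config()
    behavior = behavior or BehaviorParams()
    signal = signal or SignalParams()
    geometry = geometry or ScreenGeometry()
    pipeline = pipeline or PipelineParams()
    rng = np.random.default_rng(seed)

    beh_rows = []
    cls_results = []
    latency_tables = []
    traces_by: dict = {}          # (load, cond) -> {pid: trace}
    eye_rows = []
    unmatched_list = []
    times = None
    for pid in range(n_participants):
        sessions, beh = _simulate_participant(
            pid, config, behavior, signal, geometry, rng, pipeline
        )
        beh_rows.append(beh)
        cls_results.extend(
            comparison_grid(
                {load: s.epochs for load, s in sessions.items()},
                {load: s.eye_features for load, s in sessions.items()},
                seed=int(rng.integers(2**31 - 1)),
                participant=pid,
                feature_sets=feature_sets,
                params=pipeline,
            )
        )
        # keep only lightweight summaries; the raw session is dropped here
        for load, sess in sessions.items():
            latency_tables.append(sess.latency_table)
            unmatched_list.append(sess.unmatched_fraction)
            if sess.epochs.data.shape[0]:
                times = sess.epochs.times
            for cond, trace in _condition_traces(sess.epochs).items():
                traces_by.setdefault((load, cond), {})[pid] = trace
            for cond, vals in sess.eye_condition_means().items():
                eye_rows.append(
                    {"participant": pid, "load": load, "condition": cond, **vals}
                )
        del sessions

    behavioral = pd.DataFrame(beh_rows)
    latency = pd.concat(latency_tables, ignore_index=True)
    latency_group = (
        latency.dropna(subset=["mean_ms"])
        .groupby(["load", "condition"], as_index=False)
        .agg(mean_ms=("mean_ms", "mean"), sd_ms=("mean_ms", "std"),
             n_participants=("mean_ms", "count"))
    )

    # --- SRP group statistics -----------------------------------------
    srp_tests: dict = {}
    srp_traces: dict = {}
    contrasts = [
        ("low", ("target", "nontarget")),
        ("high", ("target", "nontarget")),
        ("high", ("hit", "miss")),
    ]
    for key, by_pid in traces_by.items():
        srp_traces[key] = np.mean(list(by_pid.values()), axis=0)
    for load, (ca, cb) in contrasts:
        da = traces_by.get((load, ca), {})
        db = traces_by.get((load, cb), {})
        common = [i for i in da if i in db]
        if len(common) < 3:
            continue
        a = np.array([da[i] for i in common])
        b = np.array([db[i] for i in common])
        srp_tests[(load, f"{ca}_vs_{cb}")] = pointwise_paired_ttest(
            a, b, times, (ca, cb), pipeline.alpha
        )

    # --- eye-feature scalar tests --------------------------------------
    eye_means = pd.DataFrame(eye_rows)

    def _paired(metric: str, load: str, ca: str, cb: str) -> dict:
        sub = eye_means[eye_means["load"] == load].pivot_table(
            index="participant", columns="condition", values=metric
        )
        ok = sub[[ca, cb]].dropna()
        if len(ok) < 3:
            return {"t": np.nan, "df": 0, "p": np.nan, "n": len(ok)}
        res = paired_feature_test(ok[ca].to_numpy(), ok[cb].to_numpy())
        res["n"] = len(ok)
        return res

    eye_tests = []
    for metric in ("fixation_duration_ms", "pupil_mm"):
        for load in ("low", "high"):
            for ca, cb in (("target", "nontarget"), ("hit", "miss")):
                r = _paired(metric, load, ca, cb)
                eye_tests.append(
                    {"metric": metric, "load": load, "contrast": f"{ca}_vs_{cb}", **r}
                )
    # high vs low load (pupil and fixation duration, all events)
    for metric in ("fixation_duration_ms", "pupil_mm"):
        piv = eye_means[eye_means["condition"].isin(["target", "nontarget"])]
        piv = piv.groupby(["participant", "load"])[metric].mean().unstack("load")
        ok = piv.dropna()
        if len(ok) >= 3:
            r = paired_feature_test(ok["high"].to_numpy(), ok["low"].to_numpy())
            r["n"] = len(ok)
        else:
            r = {"t": np.nan, "df": 0, "p": np.nan, "n": len(ok)}
        eye_tests.append(
            {"metric": metric, "load": "both", "contrast": "high_vs_low", **r}
        )
    eye_tests = pd.DataFrame(eye_tests)

    # --- classification summary ----------------------------------------
    classification = pd.DataFrame([dataclasses.asdict(r) for r in cls_results])
    if len(classification):
        classification = classification.drop(columns=["fold_accuracies"])
        classification_summary = (
            classification.groupby(["load", "contrast", "feature_set"], as_index=False)
            .agg(
                mean_accuracy=("accuracy", "mean"),
                sem_accuracy=("accuracy", "sem"),
                n_participants=("accuracy", "count"),
                n_above_chance=("above_chance", "sum"),
            )
        )
    else:
        classification_summary = pd.DataFrame()

    math_corr = correlate_performance(
        behavioral["math_score"].to_numpy(), behavioral["hit_rate_high"].to_numpy()
    ) if len(behavioral) >= 3 else {"r": np.nan, "p": np.nan, "undefined": True}

    unmatched = float(np.mean(unmatched_list))

    result = StudyResult(
        n_participants=n_participants,
        seed=seed,
        behavioral=behavioral,
        latency=latency,
        latency_group=latency_group,
        srp_tests=srp_tests,
        srp_traces=srp_traces,
        srp_times=times if times is not None else np.array([]),
        eye_tests=eye_tests,
        eye_means=eye_means,
        classification=classification,
        classification_summary=classification_summary,
        math_correlation=math_corr,
        unmatched_fraction=unmatched,
    )
    if outdir is not None:
        result.write(outdir)
    return result
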