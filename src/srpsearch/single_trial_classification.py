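"""Single-fixation classification: feature assembly, balanced linear-SVM
cross-validation, and exact binomial above-chance testing.

Feature sets mirror the study's model comparison: SRP voltages (all EEG
channels, 250-1000 ms after saccade peak velocity), EOG voltages over the
same interval, fixation duration, pupil size, their combinations.  Per
participant / load / contrast, a linear SVM is evaluated with stratified
5-fold cross-validation; features are standardized with training-fold
statistics only, and the majority class is randomly subsampled in the
training folds to balance the classes.  Above-chance performance is
judged with an exact one-sided binomial test against 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from srpsearch.eeg_pipeline import EpochSet
from srpsearch.eog_pipeline import PipelineParams

__all__ = [
    "FEATURE_SETS",
    "FeatureSetSpec",
    "ClassificationResult",
    "build_feature_matrix",
    "subsample_majority",
    "train_eval_svm_cv",
    "binomial_above_chance",
    "comparison_grid",
]

FEATURE_SETS = ("SRP", "EOG", "FIXDUR", "PUPIL", "EYE_COMBINED", "ALL", "SRP+EOG")

# which concatenated blocks each feature-set id selects
_BLOCKS = {
    "SRP": ("srp",),
    "EOG": ("eog",),
    "FIXDUR": ("fixdur",),
    "PUPIL": ("pupil",),
    "EYE_COMBINED": ("fixdur", "pupil"),
    "ALL": ("srp", "fixdur", "pupil"),
    "SRP+EOG": ("srp", "eog"),
}


@dataclass(frozen=True)
class FeatureSetSpec:
    """One of the study's feature combinations.

    ``srp_interval_ms`` is the post-peak-velocity voltage window; SRP
    blocks take all EEG channels, EOG blocks the HEOG/VEOG pair.
    """

    id: str = "SRP"
    srp_interval_ms: tuple[float, float] = (250.0, 1000.0)

    def __post_init__(self) -> None:
        if self.id not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.id!r}")

    @property
    def blocks(self) -> tuple[str, ...]:
        return _BLOCKS[self.id]

    @property
    def needs_eye(self) -> bool:
        return "fixdur" in self.blocks or "pupil" in self.blocks


@dataclass
class ClassificationResult:
    """Cross-validated accuracy for one participant x condition cell."""

    participant: str | int | None
    load: str
    contrast: str
    feature_set: str
    accuracy: float                 # pooled over test folds
    accuracy_fold_mean: float       # unweighted mean of fold accuracies
    n_test: int
    n_correct: int
    fold_accuracies: list[float]
    n_folds_used: int
    binomial_p: float
    above_chance: bool
    alpha: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy out of [0, 1]")


def build_feature_matrix(
    epochs: EpochSet,
    eye_features: pd.DataFrame | None,
    spec: FeatureSetSpec,
    eog_channels: tuple[str, str] = ("HEOG", "VEOG"),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Assemble the observations x features matrix for one feature set.

    SRP block: per retained epoch, voltages of all EEG channels over the
    configured interval, concatenated channel-major.  EOG block: the same
    interval over the HEOG/VEOG epoch channels.  Scalar blocks append
    fixation duration / pupil size joined on event id; rows with missing
    eye features are dropped when the spec needs them.

    Returns the matrix and the matching label rows.
    """
    labels = epochs.labels.reset_index(drop=True)
    if len(labels) == 0:
        raise ValueError("no epochs to build features from")
    fs = epochs.fs
    i0 = int(round(spec.srp_interval_ms[0] / 1000.0 * fs))
    i1 = int(round(spec.srp_interval_ms[1] / 1000.0 * fs))
    blocks: list[np.ndarray] = []
    keep = np.ones(len(labels), bool)
    eye = None
    if spec.needs_eye:
        if eye_features is None:
            raise ValueError(f"feature set {spec.id} needs eye features")
        eye = labels[["event_id"]].merge(eye_features, on="event_id", how="left")
        keep &= ~eye["missing"].fillna(True).to_numpy(bool)
        keep &= np.isfinite(eye["fixation_duration_ms"].to_numpy(float))
        keep &= np.isfinite(eye["pupil_mm"].to_numpy(float))
    for name in spec.blocks:
        if name == "srp":
            eeg_idx = [
                i for i, c in enumerate(epochs.channel_names) if c not in eog_channels
            ]
            blocks.append(
                epochs.data[:, eeg_idx, i0:i1].reshape(len(labels), -1)
            )
        elif name == "eog":
            idx = [epochs.channel_names.index(c) for c in eog_channels]
            blocks.append(epochs.data[:, idx, i0:i1].reshape(len(labels), -1))
        elif name == "fixdur":
            blocks.append(eye["fixation_duration_ms"].to_numpy(float)[:, None])
        elif name == "pupil":
            blocks.append(eye["pupil_mm"].to_numpy(float)[:, None])
    X = np.hstack(blocks)
    if not keep.all():
        X = X[keep]
        labels = labels.loc[keep].reset_index(drop=True)
    if len(labels) == 0:
        raise ValueError("no observations left after dropping missing eye features")
    return X, labels


def subsample_majority(
    labels: np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """Training indices balancing the two classes.

    The majority class is randomly subsampled without replacement to the
    minority count; order is sorted for determinism.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    n_min = counts.min()
    keep: list[np.ndarray] = []
    for cls, cnt in zip(classes, counts):
        idx = np.flatnonzero(labels == cls)
        if cnt > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    safe = np.where(sd == 0, 1.0, sd)
    ztr = (train - mu) / safe
    zte = (test - mu) / safe
    ztr[:, sd == 0] = 0.0
    zte[:, sd == 0] = 0.0
    return ztr, zte


def binomial_above_chance(
    n_correct: int, n_total: int, alpha: float = 0.05
) -> tuple[float, bool]:
    """Exact one-sided binomial tail P(X >= n_correct | p = 0.5)."""
    if not 0 <= n_correct <= n_total:
        raise ValueError("need 0 <= n_correct <= n_total")
    p = float(stats.binom.sf(n_correct - 1, n_total, 0.5)) if n_total else 1.0
    return p, p < alpha


def train_eval_svm_cv(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    folds: int = 5,
    c: float = 1.0,
    alpha: float = 0.05,
    participant: str | int | None = None,
    load: str = "",
    contrast: str = "",
    feature_set: str = "",
) -> ClassificationResult:
    """Balanced linear-SVM stratified cross-validation.

    Per fold: standardize with training statistics, subsample the
    training majority class, fit a linear SVM (C = ``c``), score the
    untouched test fold.  Degenerate folds (a class absent from training)
    are skipped and reflected in ``n_folds_used``.  Accuracy is pooled
    correct / pooled tested; the unweighted fold mean is reported too.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    if counts.min() < folds:
        raise ValueError("need at least `folds` observations per class")
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(rng.integers(2**31 - 1)))
    n_correct = n_test = 0
    fold_accs: list[float] = []
    for train_idx, test_idx in skf.split(X, y):
        y_tr = y[train_idx]
        if len(np.unique(y_tr)) < 2:
            continue
        bal = subsample_majority(y_tr, rng)
        Xtr, Xte = _standardize(X[train_idx][bal], X[test_idx])
        clf = SVC(kernel="linear", C=c)
        clf.fit(Xtr, y_tr[bal])
        pred = clf.predict(Xte)
        correct = int((pred == y[test_idx]).sum())
        n_correct += correct
        n_test += len(test_idx)
        fold_accs.append(correct / len(test_idx))
    if n_test == 0:
        raise ValueError("no evaluable folds")
    p, flag = binomial_above_chance(n_correct, n_test, alpha)
    return ClassificationResult(
        participant=participant,
        load=load,
        contrast=contrast,
        feature_set=feature_set,
        accuracy=n_correct / n_test,
        accuracy_fold_mean=float(np.mean(fold_accs)),
        n_test=n_test,
        n_correct=n_correct,
        fold_accuracies=fold_accs,
        n_folds_used=len(fold_accs),
        binomial_p=p,
        above_chance=flag,
        alpha=alpha,
        seed=seed,
    )


def comparison_grid(
    epochs_by_load: dict[str, EpochSet],
    eye_by_load: dict[str, pd.DataFrame],
    seed: int,
    participant: str | int | None = None,
    feature_sets: tuple[str, ...] = FEATURE_SETS,
    params: PipelineParams | None = None,
) -> list[ClassificationResult]:
    """Classification over contrasts x feature sets x loads for one
    participant.

    Target vs non-target is evaluated for both loads; hit vs miss only
    where the miss count reaches ``params.min_misses`` (the low-load
    condition rarely qualifies, matching the study design).  Cells that
    cannot be evaluated are omitted rather than reported as zero.
    """
    p = params or PipelineParams()
    rng = np.random.default_rng(seed)
    results: list[ClassificationResult] = []
    for load, epochs in epochs_by_load.items():
        eye = eye_by_load.get(load)
        labels = epochs.labels
        cells: list[tuple[str, np.ndarray]] = [
            ("target_vs_nontarget", labels["is_target"].to_numpy(bool).astype(int))
        ]
        target_mask = labels["is_target"].to_numpy(bool)
        n_miss = int((labels.loc[target_mask, "condition"] == "miss").sum())
        if n_miss >= p.min_misses:
            cells.append(("hit_vs_miss", None))  # built per feature set below
        for fs_id in feature_sets:
            spec = FeatureSetSpec(fs_id, p.svm_interval_ms)
            try:
                X_all, lab_all = build_feature_matrix(epochs, eye, spec)
            except ValueError:
                continue
            for contrast, _ in cells:
                if contrast == "target_vs_nontarget":
                    Xc = X_all
                    yc = lab_all["is_target"].to_numpy(bool).astype(int)
                else:
                    m = lab_all["is_target"].to_numpy(bool)
                    Xc = X_all[m]
                    yc = (lab_all.loc[m, "condition"] == "hit").to_numpy().astype(int)
                try:
                    results.append(
                        train_eval_svm_cv(
                            Xc, yc, seed=int(rng.integers(2**31 - 1)),
                            folds=p.cv_folds, c=p.svm_c, alpha=p.alpha,
                            participant=participant, load=load,
                            contrast=contrast, feature_set=fs_id,
                        )
                    )
                except ValueError:
                    continue
    return results
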