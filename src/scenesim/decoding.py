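"""Multi-voxel pattern analysis: per-volume linear SVM with leave-one-run-out CV.

The procedure mirrors the standard block-design MVPA pipeline: each run is
(optionally) normalized to its temporal mean, the eight volumes of every 16 s
block are extracted with a 4 s hemodynamic shift, a linear-kernel SVM
(C = 0.02, one-vs-rest) is trained on every volume of five runs, and each
held-out block is labeled by majority vote over its eight per-volume
predictions, with ties broken by the largest summed SVM decision value.
Accuracy is the fraction of blocks predicted correctly; errors are summarized
in a true-category x predicted-category confusion matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.svm import LinearSVC

from .neural_sim import ScanRun

logger = logging.getLogger(__name__)

DEFAULT_C = 0.02
DEFAULT_SHIFT = 4.0  # seconds; approximates the BOLD delay
VOLUMES_PER_BLOCK = 8  # 16 s block / 2 s TR


@dataclass(frozen=True)
class BlockSample:
    """The eight shifted volumes of one presentation block, with its label."""

    volumes: np.ndarray  # (8, V)
    label: str
    run_id: int
    condition: str = "good"

    def __post_init__(self) -> None:
        vols = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "volumes", vols)
        if vols.ndim != 2 or vols.shape[0] != VOLUMES_PER_BLOCK:
            raise ValueError(f"a block sample must hold exactly {VOLUMES_PER_BLOCK} volumes")


@dataclass
class DecodingResult:
    """Block-level predictions, overall accuracy, and the confusion matrix."""

    categories: list[str]
    true_labels: list[str]
    predicted_labels: list[str]
    run_ids: list[int]
    accuracy: float
    confusion: np.ndarray  # (6, 6) counts, rows = true, cols = predicted

    def to_dict(self) -> dict:
        return {
            "categories": self.categories,
            "accuracy": self.accuracy,
            "true_labels": self.true_labels,
            "predicted_labels": self.predicted_labels,
            "run_ids": self.run_ids,
            "confusion": self.confusion.tolist(),
        }


def normalize_run(run: ScanRun, eps: float = 1e-12) -> ScanRun:
    """Divide each voxel's series by its within-run temporal mean.

    Voxels whose temporal mean is (numerically) zero cannot be normalized;
    they are set to a constant 1.0 series and logged.
    """
    means = run.data.mean(axis=0)
    degenerate = np.abs(means) < eps
    safe = np.where(degenerate, 1.0, means)
    data = run.data / safe
    if degenerate.any():
        idx = np.flatnonzero(degenerate)
        logger.warning("normalize_run: %d zero-mean voxel(s) set to constant 1.0: %s",
                       len(idx), idx.tolist())
        data[:, degenerate] = 1.0
    return replace(run, data=data)


def extract_block_samples(run: ScanRun, shift_seconds: float = DEFAULT_SHIFT) -> list[BlockSample]:
    """The eight consecutive volumes of each block, starting at onset + shift.

    The shift must be an integer multiple of the TR (non-integer shifts are
    rejected rather than interpolated).
    """
    ratio = shift_seconds / run.tr
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"shift of {shift_seconds} s is not an integer multiple of TR {run.tr} s")
    samples = []
    for onset, duration, label in zip(run.onsets, run.durations, run.labels):
        n_vol = int(round(duration / run.tr))
        start_f = (onset + shift_seconds) / run.tr
        if abs(start_f - round(start_f)) > 1e-9:
            raise ValueError(f"block at {onset} s does not align to the TR grid after the shift")
        start = int(round(start_f))
        stop = start + n_vol
        if stop > run.n_volumes:
            raise ValueError(
                f"block at onset {onset} s (shifted window {start}:{stop}) exceeds the run "
                f"length of {run.n_volumes} volumes"
            )
        samples.append(BlockSample(run.data[start:stop], label, run.run_id, run.condition))
    return samples


def train_category_classifier(volumes: np.ndarray, labels: Sequence[str], C: float = DEFAULT_C) -> LinearSVC:
    """Fit the one-vs-rest linear-kernel SVM (C = 0.02 by default) on volumes."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    clf = LinearSVC(C=C, max_iter=20000)
    clf.fit(np.asarray(volumes, dtype=float), y)
    return clf


def _decision_matrix(clf: LinearSVC, X: np.ndarray) -> np.ndarray:
    """Per-category decision values as an (n_samples, n_classes) matrix."""
    d = clf.decision_function(X)
    if d.ndim == 1:  # binary: one margin, positive favors classes_[1]
        return np.column_stack([-d, d])
    return d


def predict_block(clf: LinearSVC, block: BlockSample) -> str:
    """Majority vote over the block's eight per-volume predictions.

    If several categories tie for the most votes, the tied category with the
    largest decision value summed over the eight volumes wins; an exact tie in
    summed decision values (probability zero in floating point, but possible)
    falls back to the classifier's fixed class order and is logged.
    """
    preds = clf.predict(block.volumes)
    classes = list(clf.classes_)
    votes = np.array([np.sum(preds == c) for c in classes])
    top = votes.max()
    tied = np.flatnonzero(votes == top)
    if len(tied) == 1:
        return classes[tied[0]]
    summed = _decision_matrix(clf, block.volumes).sum(axis=0)
    tied_scores = summed[tied]
    best = tied[int(np.argmax(tied_scores))]
    if np.sum(tied_scores == tied_scores.max()) > 1:
        logger.warning("predict_block: exact decision-value tie; using fixed class order")
    return classes[best]


def _result_from_predictions(
    categories: list[str], true: list[str], pred: list[str], run_ids: list[int]
) -> DecodingResult:
    cat_index = {c: i for i, c in enumerate(categories)}
    confusion = np.zeros((len(categories), len(categories)), dtype=int)
    for t, p in zip(true, pred):
        confusion[cat_index[t], cat_index[p]] += 1
    accuracy = float(np.mean([t == p for t, p in zip(true, pred)]))
    return DecodingResult(categories, true, pred, run_ids, accuracy, confusion)


def loro_cross_validate(
    runs: Sequence[ScanRun],
    C: float = DEFAULT_C,
    shift_seconds: float = DEFAULT_SHIFT,
) -> DecodingResult:
    """Leave-one-run-out decoding of block-design runs.

    For each fold, every volume of every block in the five training runs is an
    independent training sample labeled with its block's category; each block
    of the held-out run is then predicted with ``predict_block``.  Results are
    aggregated over all folds.
    """
    if len(runs) < 2:
        raise ValueError("LORO cross-validation needs at least 2 runs")
    n_vox = {r.n_voxels for r in runs}
    if len(n_vox) != 1:
        raise ValueError(f"runs have inconsistent voxel counts: {sorted(n_vox)}")
    per_run_samples = [extract_block_samples(r, shift_seconds) for r in runs]
    categories = sorted({s.label for samples in per_run_samples for s in samples})

    true: list[str] = []
    pred: list[str] = []
    run_ids: list[int] = []
    for held_out in range(len(runs)):
        train = [s for i, samples in enumerate(per_run_samples) if i != held_out for s in samples]
        X = np.vstack([s.volumes for s in train])
        y = np.repeat([s.label for s in train], VOLUMES_PER_BLOCK)
        clf = train_category_classifier(X, y, C=C)
        for s in per_run_samples[held_out]:
            true.append(s.label)
            pred.append(predict_block(clf, s))
            run_ids.append(s.run_id)
    return _result_from_predictions(categories, true, pred, run_ids)


def loro_cross_validate_patterns(
    per_run_patterns: Sequence[np.ndarray],
    per_run_labels: Sequence[Sequence[str]],
    C: float = DEFAULT_C,
) -> DecodingResult:
    """Leave-one-run-out decoding of per-run pattern sets (e.g. beta patterns).

    Used for the event-related pathway, where each run contributes one beta
    pattern per category; held-out patterns are predicted directly (no
    within-block voting applies).
    """
    if len(per_run_patterns) < 2:
        raise ValueError("LORO cross-validation needs at least 2 runs")
    if len(per_run_patterns) != len(per_run_labels):
        raise ValueError("per_run_patterns and per_run_labels must align")
    categories = sorted({lab for labs in per_run_labels for lab in labs})
    true: list[str] = []
    pred: list[str] = []
    run_ids: list[int] = []
    for held_out in range(len(per_run_patterns)):
        X_train = np.vstack([p for i, p in enumerate(per_run_patterns) if i != held_out])
        y_train = [lab for i, labs in enumerate(per_run_labels) if i != held_out for lab in labs]
        clf = train_category_classifier(X_train, y_train, C=C)
        preds = clf.predict(np.asarray(per_run_patterns[held_out], dtype=float))
        true.extend(per_run_labels[held_out])
        pred.extend(preds.tolist())
        run_ids.extend([held_out] * len(preds))
    return _result_from_predictions(categories, true, pred, run_ids)


@dataclass
class ConditionComparison:
    """Paired good-vs-bad accuracy comparison plus per-condition tests vs chance."""

    mean_good: float
    mean_bad: float
    mean_difference: float
    t_statistic: float
    p_value: float
    df: int
    degenerate: bool
    vs_chance_good: tuple[float, float]  # (t, one-tailed p) against 1/6
    vs_chance_bad: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "mean_good": self.mean_good,
            "mean_bad": self.mean_bad,
            "mean_difference": self.mean_difference,
            "t": self.t_statistic,
            "p": self.p_value,
            "df": self.df,
            "degenerate": self.degenerate,
            "vs_chance_good": list(self.vs_chance_good),
            "vs_chance_bad": list(self.vs_chance_bad),
        }


def compare_conditions(
    acc_good: Sequence[float], acc_bad: Sequence[float], chance: float = 1.0 / 6.0
) -> ConditionComparison:
    """Two-tailed paired t-test between conditions, with tests against chance.

    Each element of ``acc_good``/``acc_bad`` is one subject's mean accuracy.
    Degenerate zero-variance differences are flagged: identical samples give
    t = 0, p = 1; a constant nonzero difference gives t = +/-inf, p = 0.
    """
    g = np.asarray(acc_good, dtype=float)
    b = np.asarray(acc_bad, dtype=float)
    if g.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = len(g)
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    diffs = g - b
    sd = diffs.std(ddof=1)
    degenerate = bool(sd < 1e-15)
    if degenerate:
        if abs(diffs.mean()) < 1e-15:
            t_stat, p_val = 0.0, 1.0
        else:
            t_stat = float(np.inf) if diffs.mean() > 0 else float(-np.inf)
            p_val = 0.0
    else:
        t_stat, p_val = stats.ttest_rel(g, b)
        t_stat, p_val = float(t_stat), float(p_val)

    def _vs_chance(acc: np.ndarray) -> tuple[float, float]:
        if acc.std(ddof=1) < 1e-15:
            if abs(acc.mean() - chance) < 1e-15:
                return 0.0, 1.0
            return (float(np.inf) if acc.mean() > chance else float(-np.inf),
                    0.0 if acc.mean() > chance else 1.0)
        t, p = stats.ttest_1samp(acc, chance, alternative="greater")
        return float(t), float(p)

    return ConditionComparison(
        mean_good=float(g.mean()),
        mean_bad=float(b.mean()),
        mean_difference=float(diffs.mean()),
        t_statistic=t_stat,
        p_value=p_val,
        df=n - 1,
        degenerate=degenerate,
        vs_chance_good=_vs_chance(g),
        vs_chance_bad=_vs_chance(b),
    )
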