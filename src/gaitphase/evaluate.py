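"""Multi-class classifier evaluation.

Confusion matrix, one-vs-rest per-class metrics (sensitivity,
specificity, precision, F-score, Matthews correlation coefficient),
instance-weighted averages, stratified k-fold cross-validation and the
pooled-CV report used to compare the raw classifier against the
TSVC-corrected stream.

Per class ``i`` (one-vs-rest): TP = cm[i][i], FN = row_i - TP,
FP = col_i - TP, TN = total - TP - FN - FP, with

    sens = TP/(TP+FN)              spec = TN/(TN+FP)
    prec = TP/(TP+FP)              FS = 2*prec*sens/(prec+sens)
    MCC  = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A ratio with a zero denominator is reported as 0 and flagged, so the
weighted averages ``W_m = sum(m_i * I_i) / sum(I_i)`` (weights = true
instance counts per class) always remain computable.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .features import FEATURE_NAMES
from .preprocess import PHASE_ORDER, ConfigurationError, InputError
from .tsvc import tsvc_correct

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "per_class_metrics",
    "weighted_average",
    "stratified_kfold",
    "crossval_report",
    "resubstitution_report",
    "inject_isolated_outliers",
]

METRIC_NAMES = ("sensitivity", "specificity", "precision", "f_score", "mcc")


@dataclasses.dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_order: tuple[str, ...] = PHASE_ORDER

    def __post_init__(self) -> None:
        k = len(self.class_order)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (k, k) or (self.counts < 0).any():
            raise InputError("confusion matrix must be KxK with nonnegative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.class_order), columns=list(self.class_order)
        )


@dataclasses.dataclass
class MetricsReport:
    """Per-class and instance-weighted classification metrics."""

    cm: ConfusionMatrix
    per_class: pd.DataFrame  # rows = classes, columns = METRIC_NAMES
    weighted: dict[str, float]
    accuracy: float
    instance_counts: np.ndarray
    undefined_flags: pd.DataFrame  # True where a ratio had zero denominator

    def to_frame(self) -> pd.DataFrame:
        """Flat condition x class x metric table."""
        rows = []
        for cls in self.per_class.index:
            for m in METRIC_NAMES:
                rows.append({"class": cls, "metric": m, "value": self.per_class.loc[cls, m]})
        for m in METRIC_NAMES:
            rows.append({"class": "weighted", "metric": m, "value": self.weighted[m]})
        rows.append({"class": "overall", "metric": "accuracy", "value": self.accuracy})
        return pd.DataFrame(rows)


def confusion(
    true: Sequence, pred: Sequence, class_order: tuple[str, ...] = PHASE_ORDER
) -> ConfusionMatrix:
    """Count matrix ``counts[i][j] = #(true == i and pred == j)``."""
    true = np.asarray([str(x) for x in true], dtype=object)
    pred = np.asarray([str(x) for x in pred], dtype=object)
    if true.shape != pred.shape:
        raise InputError("true and predicted label vectors differ in length")
    index = {c: i for i, c in enumerate(class_order)}
    k = len(class_order)
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(true, pred):
        if t not in index or p not in index:
            raise InputError(f"unknown label in pair ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, class_order)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest metrics per class, weighted averages and accuracy."""
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise InputError("empty confusion matrix")
    k = len(cm.class_order)
    values = np.zeros((k, len(METRIC_NAMES)))
    flags = np.zeros((k, len(METRIC_NAMES)), dtype=bool)
    for i in range(k):
        tp = float(counts[i, i])
        fn = float(counts[i, :].sum() - tp)
        fp = float(counts[:, i].sum() - tp)
        tn = float(total - tp - fn - fp)
        sens, f_sens = _safe_div(tp, tp + fn)
        spec, f_spec = _safe_div(tn, tn + fp)
        prec, f_prec = _safe_div(tp, tp + fp)
        fs, f_fs = _safe_div(2 * prec * sens, prec + sens)
        mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc, f_mcc = _safe_div(tp * tn - fp * fn, mcc_den)
        values[i] = (sens, spec, prec, fs, mcc)
        flags[i] = (f_sens, f_spec, f_prec, f_fs, f_mcc)

    instance_counts = counts.sum(axis=1)
    weighted = {
        m: weighted_average(values[:, j], instance_counts)
        for j, m in enumerate(METRIC_NAMES)
    }
    per_class = pd.DataFrame(values, index=list(cm.class_order), columns=list(METRIC_NAMES))
    flag_df = pd.DataFrame(flags, index=list(cm.class_order), columns=list(METRIC_NAMES))
    return MetricsReport(
        cm=cm,
        per_class=per_class,
        weighted=weighted,
        accuracy=float(np.trace(counts)) / total,
        instance_counts=instance_counts,
        undefined_flags=flag_df,
    )


def weighted_average(values: Sequence[float], counts: Sequence[int]) -> float:
    """Instance-weighted mean ``sum(m_i * I_i) / sum(I_i)``."""
    values = np.asarray(values, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if values.shape != counts.shape:
        raise InputError("values and counts differ in length")
    if counts.sum() <= 0:
        raise InputError("weighted_average needs a positive total count")
    return float((values * counts).sum() / counts.sum())


def stratified_kfold(
    labels: Sequence, k: int = 5, seed: int = 0
) -> list[np.ndarray]:
    """Class-stratified fold assignment; returns k test-index arrays."""
    y = np.asarray([str(x) for x in labels], dtype=object)
    classes, cls_counts = np.unique(y, return_counts=True)
    if (cls_counts < k).any():
        bad = classes[cls_counts < k]
        raise ConfigurationError(
            f"class(es) {list(bad)} have fewer than k={k} instances"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(y)), y)]


def inject_isolated_outliers(
    labels: Sequence, rate: float, seed: int = 0
) -> list[str]:
    """Corrupt a label stream with isolated single-instance outliers.

    Flips ~``rate`` of the eligible positions, restricted to positions
    whose three predecessors and one successor all share the position's
    label (i.e. away from phase boundaries), so each corruption is an
    isolated outlier that TSVC can provably restore.
    """
    rng = np.random.default_rng(seed)
    out = [str(x) for x in labels]
    n = len(out)
    eligible = [
        i
        for i in range(3, n - 1)
        if len({out[i - 3], out[i - 2], out[i - 1], out[i], out[i + 1]}) == 1
    ]
    n_flip = int(round(rate * len(eligible)))
    if n_flip == 0:
        return out
    picks = rng.choice(len(eligible), size=n_flip, replace=False)
    # avoid adjacent corruptions, which would not be isolated
    chosen: list[int] = []
    taken: set[int] = set()
    for p in sorted(eligible[int(i)] for i in picks):
        if all(abs(p - q) > 4 for q in taken):
            chosen.append(p)
            taken.add(p)
    for i in chosen:
        others = [c for c in PHASE_ORDER if c != out[i]]
        out[i] = str(rng.choice(others))
    return out


def _apply_tsvc_per_recording(df: pd.DataFrame, pred: np.ndarray) -> np.ndarray:
    """TSVC per contiguous recording, never across recording boundaries."""
    corrected = pred.astype(object).copy()
    frame = df.reset_index(drop=True)
    for _, grp in frame.groupby("recording_id", sort=False):
        idx = grp.sort_values("end_index").index.to_numpy()
        corrected[idx] = tsvc_correct(pred[idx])
    return corrected


def crossval_report(
    df: pd.DataFrame,
    k: int = 5,
    config=None,
    with_tsvc: bool = True,
    seed: int = 0,
) -> dict[str, MetricsReport]:
    """Pooled stratified k-fold cross-validation of the LMT classifier.

    Trains on k-1 folds, predicts the held-out fold in window order,
    optionally applies TSVC per contiguous recording, pools all fold
    predictions and reports metrics for ``"lmt"`` and (when requested)
    ``"lmt_tsvc"``.
    """
    from .lmt import LMTTrainConfig, predict_batch, train_lmt

    config = config or LMTTrainConfig(seed=seed)
    X = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = df["label"].to_numpy(dtype=object)
    folds = stratified_kfold(y, k=k, seed=seed)

    pooled_pred = np.empty(len(df), dtype=object)
    for fold_idx, test in enumerate(folds):
        mask = np.ones(len(df), dtype=bool)
        mask[test] = False
        model = train_lmt(
            X[mask],
            y[mask],
            dataclasses.replace(config, seed=config.seed + fold_idx),
        )
        pooled_pred[test] = predict_batch(model, X[test])

    reports = {"lmt": per_class_metrics(confusion(y, pooled_pred))}
    if with_tsvc:
        corrected = _apply_tsvc_per_recording(df, pooled_pred)
        reports["lmt_tsvc"] = per_class_metrics(confusion(y, corrected))
    return reports


def resubstitution_report(
    df: pd.DataFrame, model, with_tsvc: bool = True
) -> dict[str, MetricsReport]:
    """Metrics from re-predicting the supplied training set itself."""
    from .lmt import predict_batch

    X = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = df["label"].to_numpy(dtype=object)
    pred = predict_batch(model, X)
    reports = {"lmt": per_class_metrics(confusion(y, pred))}
    if with_tsvc:
        corrected = _apply_tsvc_per_recording(df, pred)
        reports["lmt_tsvc"] = per_class_metrics(confusion(y, corrected))
    return reports
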