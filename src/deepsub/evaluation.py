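"""Confusion accounting, macro metrics, the 8:2 split and k-fold CV.

Metrics follow the one-vs-rest macro convention: for each class i the
counts TP_i, TN_i, FP_i, FN_i are taken against the rest, and

    mACC       = mean_i (TP_i + TN_i) / total
    mPrecision = mean_i TP_i / (TP_i + FP_i)
    mRecall    = mean_i TP_i / (TP_i + FN_i)
    mF1        = 2 * mPrecision * mRecall / (mPrecision + mRecall)

Per-class terms with a zero denominator contribute 0 and stay in the
macro average — a class the model never predicts correctly (e.g. a
heptamer class with a handful of samples) must drag the average down
rather than silently drop out. A secondary mF1 variant, the macro
average of per-class F1 scores, is also reported because the two
conventions differ whenever per-class precision/recall are imbalanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from deepsub.model import NS_LABELS, DeepSubConfig, TrainedModel, predict_batch, train


@dataclass
class ConfusionCounts:
    """One-vs-rest counts per class over a fixed label map."""

    labels: tuple[int, ...]
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    total: int

    def __post_init__(self) -> None:
        for arr in (self.tp, self.tn, self.fp, self.fn):
            if np.any(arr < 0):
                raise ValueError("confusion counts must be non-negative")
        sums = self.tp + self.tn + self.fp + self.fn
        if not np.all(sums == self.total):
            raise ValueError("TP+TN+FP+FN must equal the sample total for every class")

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    @property
    def accuracy(self) -> float:
        """Plain (micro) accuracy: fraction of correct predictions."""
        return float(self.tp.sum()) / self.total


def confusion(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    labels: Sequence[int] = NS_LABELS,
) -> ConfusionCounts:
    """One-vs-rest confusion counts for a multi-class prediction."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    label_set = set(labels)
    unknown = (set(y_true.tolist()) | set(y_pred.tolist())) - label_set
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}; expected subset of {tuple(labels)}")
    total = len(y_true)
    tp = np.array([int(np.sum((y_true == c) & (y_pred == c))) for c in labels])
    fp = np.array([int(np.sum((y_true != c) & (y_pred == c))) for c in labels])
    fn = np.array([int(np.sum((y_true == c) & (y_pred != c))) for c in labels])
    tn = total - tp - fp - fn
    return ConfusionCounts(tuple(labels), tp, tn, fp, fn, total)


@dataclass
class MetricsReport:
    mACC: float
    mPrecision: float
    mRecall: float
    mF1: float
    #: secondary convention: macro average of the per-class F1 scores
    mF1_per_class: float
    per_class: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        for name in ("mACC", "mPrecision", "mRecall", "mF1", "mF1_per_class"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def harmonic_f1(precision: float, recall: float) -> float:
    """2 P R / (P + R); 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def macro_metrics(counts: ConfusionCounts) -> MetricsReport:
    """The four macro metrics from one-vs-rest confusion counts.

    Zero-denominator per-class precision or recall contributes 0 to the
    macro mean (the class stays in the average).
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics for zero samples")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    acc_i = (tp + tn) / counts.total
    with np.errstate(divide="ignore", invalid="ignore"):
        prec_i = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        rec_i = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
    f1_i = np.array([harmonic_f1(p, r) for p, r in zip(prec_i, rec_i)])
    m_prec = float(prec_i.mean())
    m_rec = float(rec_i.mean())
    per_class = pd.DataFrame(
        {
            "label": counts.labels,
            "TP": tp, "TN": tn, "FP": fp, "FN": fn,
            "precision": prec_i, "recall": rec_i, "F1": f1_i,
        }
    )
    return MetricsReport(
        mACC=float(acc_i.mean()),
        mPrecision=m_prec,
        mRecall=m_rec,
        mF1=harmonic_f1(m_prec, m_rec),
        mF1_per_class=float(f1_i.mean()),
        per_class=per_class,
    )


def split(
    dataset: Sequence | tuple[np.ndarray, np.ndarray],
    ratio: float = 0.8,
    seed: int = 0,
) -> tuple:
    """Disjoint, exhaustive train/test split at the given ratio.

    Sizes are within one sample of the exact ratio; the partition is a
    pure function of the seed.
    """
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio must lie strictly between 0 and 1")
    if isinstance(dataset, tuple) and len(dataset) == 2:
        n = len(dataset[1])
    else:
        n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.Generator(np.random.PCG64(seed))
    order = rng.permutation(n)
    n_train = int(round(ratio * n))
    n_train = min(max(n_train, 1), n - 1)
    train_idx, test_idx = np.sort(order[:n_train]), np.sort(order[n_train:])
    if isinstance(dataset, tuple) and len(dataset) == 2:
        X, y = dataset
        X = np.asarray(X)
        y = np.asarray(y)
        return (X[train_idx], y[train_idx]), (X[test_idx], y[test_idx])
    return [dataset[i] for i in train_idx], [dataset[i] for i in test_idx]


@dataclass
class FoldResult:
    fold: int  # 1-based
    metrics: MetricsReport
    train_idx: np.ndarray
    test_idx: np.ndarray


def evaluate(
    model: TrainedModel, X: np.ndarray, y: Sequence[int]
) -> MetricsReport:
    """Score a trained model on pooled embeddings X against NS labels y."""
    y_pred = predict_batch(X, model)
    return macro_metrics(confusion(np.asarray(y), y_pred, model.label_map))


def cross_validate(
    X: np.ndarray,
    y: Sequence[int],
    k: int = 10,
    config: DeepSubConfig | None = None,
    seed: int = 0,
    stratified: bool = False,
    label_map: Sequence[int] = NS_LABELS,
) -> tuple[list[FoldResult], pd.DataFrame]:
    """k-fold cross-validation: the data are randomly divided into k
    parts; each round trains on k-1 parts and tests on the held-out part.

    Returns per-fold results and a summary table in the shape
    fold x (mPrecision, mRecall, mACC, mF1) with an ``Average`` row of
    arithmetic means +/- sample standard deviations (ddof=1).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if k > len(y):
        raise ValueError(f"k={k} exceeds the number of samples {len(y)}")
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < k):
        import warnings

        warnings.warn(
            f"classes {classes[counts < k].tolist()} have fewer than k={k} samples; "
            "some folds will lack them",
            stacklevel=2,
        )
    config = config or DeepSubConfig()
    splitter = (
        StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        if stratified
        else KFold(n_splits=k, shuffle=True, random_state=seed)
    )
    results: list[FoldResult] = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y), start=1):
        model = train((X[train_idx], y[train_idx]), config, label_map=label_map)
        metrics = evaluate(model, X[test_idx], y[test_idx])
        results.append(FoldResult(fold, metrics, train_idx, test_idx))
    summary = summarize_folds(results)
    return results, summary


def summarize_folds(results: list[FoldResult]) -> pd.DataFrame:
    """Per-fold metric table plus an Average row (mean, sample SD)."""
    rows = {
        r.fold: [r.metrics.mPrecision, r.metrics.mRecall, r.metrics.mACC, r.metrics.mF1]
        for r in results
    }
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["mPrecision", "mRecall", "mACC", "mF1"]
    )
    df.index.name = "Fold"
    means = df.mean(axis=0)
    sds = df.std(axis=0, ddof=1)
    df.loc["Average"] = means
    df.attrs["sd"] = sds.to_dict()
    return df


def format_summary(df: pd.DataFrame, decimals: int = 3) -> str:
    """TSV rendering with the Average row shown as ``mean ± sd``."""
    lines = ["Fold\t" + "\t".join(df.columns)]
    sd = df.attrs.get("sd", {})
    for idx, row in df.iterrows():
        if idx == "Average":
            cells = [
                f"{row[c]:.{decimals}f} ± {sd.get(c, float('nan')):.{decimals}f}"
                for c in df.columns
            ]
        else:
            cells = [f"{row[c]:.{decimals}f}" for c in df.columns]
        lines.append(f"{idx}\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"
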