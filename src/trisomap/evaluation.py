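"""Repeated random-split evaluation protocol and the six-metric report.

The protocol: ten parallel experiments, each on a fresh uniform random 75/25
train/test split of the cohort, training the model from scratch every time.
Per run the 2x2 confusion table (DS = positive class) yields accuracy,
precision, recall, F-score, false-positive rate and false-negative rate; the
report carries per-run metrics, their mean +- standard deviation, and the
confusion counts pooled across all runs. Because published screening tables
sometimes report an F-score that coincides with accuracy (consistent with a
support-weighted average over both classes), the report includes both the
positive-class F1 (``f_score``) and the support-weighted variant
(``f_score_weighted``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .io_formats import CONTROL_LABEL, DS_LABEL

METRIC_NAMES = (
    "accuracy",
    "precision",
    "recall",
    "f_score",
    "f_score_weighted",
    "fp_rate",
    "fn_rate",
)


def split_indices(
    n: int,
    train_fraction: float = 0.75,
    seed: int = 0,
    stratify_labels: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random train/test split; train size = floor(train_fraction * n).

    Unstratified by default (samples drawn uniformly without regard to class);
    pass the label vector as ``stratify_labels`` to split each class in the
    same proportion instead. Returns sorted, disjoint, exhaustive index arrays.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(np.floor(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError("split would leave one side empty")
    rng = np.random.default_rng(seed)
    if stratify_labels is None:
        perm = rng.permutation(n)
        train = perm[:n_train]
    else:
        labels = np.asarray(stratify_labels)
        train_parts = []
        for cls in sorted(set(labels)):
            idx = np.flatnonzero(labels == cls)
            k = int(np.floor(train_fraction * len(idx)))
            train_parts.append(rng.permutation(idx)[:k])
        train = np.concatenate(train_parts)
    mask = np.zeros(n, dtype=bool)
    mask[train] = True
    return np.sort(train), np.flatnonzero(~mask)


def confusion(
    labels_true: Sequence[str], labels_pred: Sequence[str], positive: str = DS_LABEL
) -> tuple[int, int, int, int]:
    """Standard 2x2 confusion counts (TP, FP, FN, TN) with DS positive by default."""
    yt = np.asarray(labels_true)
    yp = np.asarray(labels_pred)
    if yt.shape != yp.shape:
        raise ValueError("label vectors must have equal length")
    known = {DS_LABEL, CONTROL_LABEL}
    if unknown := (set(yt) | set(yp)) - known:
        raise ValueError(f"unknown label values {sorted(unknown)}")
    tp = int(np.sum((yt == positive) & (yp == positive)))
    fp = int(np.sum((yt != positive) & (yp == positive)))
    fn = int(np.sum((yt == positive) & (yp != positive)))
    tn = int(np.sum((yt != positive) & (yp != positive)))
    return tp, fp, fn, tn


@dataclass(frozen=True)
class ExperimentMetrics:
    """Confusion counts and derived metrics for one train/test run."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f_score: float
    f_score_weighted: float
    fp_rate: float
    fn_rate: float
    undefined: tuple[str, ...] = ()  # metrics whose denominator was zero

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            **{m: getattr(self, m) for m in METRIC_NAMES},
            "undefined": list(self.undefined),
        }


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def compute_metrics(tp: int, fp: int, fn: int, tn: int) -> ExperimentMetrics:
    """Derive the six evaluation metrics from 2x2 confusion counts.

    accuracy = (TP+TN)/n, precision = TP/(TP+FP), recall = TP/(TP+FN),
    F = 2PR/(P+R), fp_rate = FP/(FP+TN), fn_rate = FN/(FN+TP). A ratio with a
    zero denominator is reported as 0 and flagged in ``undefined``. The
    weighted F-score averages the two per-class F1 values by class support.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("confusion counts are all zero")
    undefined: list[str] = []
    precision = _ratio(tp, tp + fp, "precision", undefined)
    recall = _ratio(tp, tp + fn, "recall", undefined)
    f_score = _ratio(2 * precision * recall, precision + recall, "f_score", undefined)
    # Negative-class F1 for the support-weighted variant (control as "positive").
    npv = _ratio(tn, tn + fn, "npv", [])
    specificity = _ratio(tn, tn + fp, "specificity", [])
    f_neg = _ratio(2 * npv * specificity, npv + specificity, "f_neg", [])
    pos_support, neg_support = tp + fn, tn + fp
    f_weighted = (f_score * pos_support + f_neg * neg_support) / n
    return ExperimentMetrics(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        accuracy=(tp + tn) / n,
        precision=precision,
        recall=recall,
        f_score=f_score,
        f_score_weighted=f_weighted,
        fp_rate=_ratio(fp, fp + tn, "fp_rate", undefined),
        fn_rate=_ratio(fn, fn + tp, "fn_rate", undefined),
        undefined=tuple(undefined),
    )


@dataclass
class MetricsReport:
    """Per-run metrics plus cross-run aggregates and pooled confusion counts."""

    runs: list[ExperimentMetrics]
    mean: dict[str, float] = field(init=False)
    std: dict[str, float] = field(init=False)
    pooled: ExperimentMetrics = field(init=False)

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("report needs at least one run")
        self.mean = {
            m: float(np.mean([getattr(r, m) for r in self.runs])) for m in METRIC_NAMES
        }
        self.std = {
            m: float(np.std([getattr(r, m) for r in self.runs])) for m in METRIC_NAMES
        }
        self.pooled = compute_metrics(
            sum(r.tp for r in self.runs),
            sum(r.fp for r in self.runs),
            sum(r.fn for r in self.runs),
            sum(r.tn for r in self.runs),
        )

    def as_dict(self) -> dict:
        return {
            "n_runs": len(self.runs),
            "runs": [r.as_dict() for r in self.runs],
            "mean": self.mean,
            "std": self.std,
            "pooled": self.pooled.as_dict(),
        }


FitPredict = Callable[[np.ndarray, np.ndarray, int], np.ndarray]


def run_protocol(
    fit_predict: FitPredict,
    labels: Sequence[str],
    n_repeats: int = 10,
    seed: int = 0,
    train_fraction: float = 0.75,
    stratified: bool = False,
) -> MetricsReport:
    """Run the repeated random-split protocol.

    ``fit_predict(train_idx, test_idx, run_seed)`` must train a model from
    scratch on the training indices and return predicted labels for the test
    indices. Repeat r uses split seed ``seed + r`` (and passes the same value
    as the run seed), so the whole protocol is reproducible from ``seed``.
    """
    labels = np.asarray(labels)
    if len(set(labels)) < 2:
        raise ValueError("dataset must contain both classes")
    runs = []
    for r in range(n_repeats):
        train_idx, test_idx = split_indices(
            len(labels),
            train_fraction,
            seed=seed + r,
            stratify_labels=labels if stratified else None,
        )
        predicted = fit_predict(train_idx, test_idx, seed + r)
        runs.append(compute_metrics(*confusion(labels[test_idx], predicted)))
    return MetricsReport(runs=runs)
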