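"""Train/test protocol, confusion-matrix metrics, ROC/AUC, comparison.

The confusion matrix is oriented as rows = predicted, columns =
measured: tp = predicted-positive & measured-positive, fp = predicted-
positive & measured-negative, fn = predicted-negative & measured-
positive, tn = predicted-negative & measured-negative.  Metrics follow
the standard definitions; ratios with a zero denominator are reported
as ``None`` (absent), never coerced to 0, so a degenerate predictor is
distinguishable from a bad one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

from .classifiers import (
    FittedClassifier,
    predict,
    train_kdb,
    train_nb,
    train_tan,
)
from .exceptions import DataError

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "split",
    "confusion",
    "metrics",
    "auc",
    "evaluate_model",
    "compare_models",
    "parse_model_spec",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Derived classification metrics; ``None`` marks an undefined ratio.

    ``sensitivity`` is an alias of ``recall`` and ``ppv`` of
    ``precision`` — both are reported for clinical readability.
    """

    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    auc: float | None = None


def split(
    table: pd.DataFrame,
    ratio: float = 0.7,
    seed: int = 0,
    stratify: bool = True,
    outcome: str = "np",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row-disjoint train/test partition with train fraction = ratio."""
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1); got {ratio}")
    strata = table[outcome] if stratify else None
    train, test = train_test_split(
        table,
        train_size=ratio,
        random_state=seed,
        shuffle=True,
        stratify=strata,
    )
    if stratify:
        for part, name in ((train, "train"), (test, "test")):
            if part[outcome].nunique() < table[outcome].nunique():
                raise DataError(f"a class is absent from the {name} split")
    return train.reset_index(drop=True), test.reset_index(drop=True)


def confusion(
    predicted: Sequence[str], measured: Sequence[str], positive: str
) -> ConfusionMatrix:
    """Tally a confusion matrix from paired label lists."""
    if len(predicted) != len(measured):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs "
            f"{len(measured)} measurements"
        )
    tp = fp = fn = tn = 0
    for p, m in zip(predicted, measured):
        if p == positive:
            if m == positive:
                tp += 1
            else:
                fp += 1
        else:
            if m == positive:
                fn += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(cm: ConfusionMatrix, auc: float | None = None) -> MetricsReport:
    """Standard metric battery from a confusion matrix.

    accuracy = (tp+tn)/total, precision = ppv = tp/(tp+fp),
    recall = sensitivity = tp/(tp+fn), specificity = tn/(tn+fp),
    npv = tn/(tn+fn), f1 = harmonic mean of precision and recall.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
    return MetricsReport(
        accuracy=(cm.tp + cm.tn) / cm.total,
        precision=precision,
        recall=recall,
        f1=f1,
        sensitivity=recall,
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=precision,
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        auc=auc,
    )


def auc(scores: Sequence[float], labels: Sequence[str], positive: str) -> float:
    """Probability-of-concordance AUC with 0.5 credit for tied scores.

    Equivalent to the Mann-Whitney U statistic of the positive-class
    scores divided by n_pos * n_neg (midrank tie handling).
    """
    if len(scores) != len(labels):
        raise ValueError("scores and labels differ in length")
    scores = np.asarray(scores, dtype=float)
    is_pos = np.asarray([lab == positive for lab in labels])
    n_pos = int(is_pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("both classes must be present to compute AUC")
    ranks = stats.rankdata(scores)  # midranks
    u = ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


_TRAINERS = {"nb": train_nb, "tan": train_tan}


def parse_model_spec(spec: str) -> tuple[str, dict]:
    """Parse a model id: ``nb``, ``tan`` or ``kdb:<k>`` (e.g. ``kdb:2``)."""
    if spec in _TRAINERS:
        return spec, {}
    if spec.startswith("kdb"):
        _, _, k = spec.partition(":")
        return "kdb", {"k": int(k) if k else 2}
    raise ValueError(f"unknown model spec {spec!r}")


def _train(
    name: str,
    kwargs: dict,
    table: pd.DataFrame,
    class_var: str,
    attributes: Sequence[str],
    smoothing: float,
) -> FittedClassifier:
    if name == "kdb":
        return train_kdb(
            table, class_var, attributes, smoothing=smoothing, **kwargs
        )
    return _TRAINERS[name](table, class_var, attributes, smoothing=smoothing)


def evaluate_model(
    model: FittedClassifier,
    test: pd.DataFrame,
    positive: str = "1",
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Predict the test set and report confusion counts plus metrics.

    AUC uses the posterior probability of the positive class as score.
    """
    predicted, scores = [], []
    records = test[list(model.attributes)].astype(str).to_dict("records")
    for record in records:
        pred = predict(model, record)
        predicted.append(pred.predicted_class)
        scores.append(pred.posterior.get(positive, 0.0))
    measured = test[model.class_var].astype(str).tolist()
    cm = confusion(predicted, measured, positive)
    try:
        area = auc(scores, measured, positive)
    except DataError:
        area = None
    return cm, metrics(cm, auc=area)


def compare_models(
    table: pd.DataFrame,
    model_specs: Sequence[str],
    ratio: float = 0.7,
    seed: int = 0,
    class_var: str = "np",
    attributes: Sequence[str] | None = None,
    positive: str = "1",
    smoothing: float = 1.0,
) -> list[tuple[str, ConfusionMatrix, MetricsReport]]:
    """Train each requested model on one shared split and evaluate it."""
    if len(model_specs) < 1:
        raise ValueError("at least one model spec is required")
    if attributes is None:
        attributes = [c for c in table.columns if c != class_var]
    train, test = split(table, ratio=ratio, seed=seed, outcome=class_var)
    reports = []
    for spec in model_specs:
        name, kwargs = parse_model_spec(spec)
        model = _train(name, kwargs, train, class_var, attributes, smoothing)
        cm, report = evaluate_model(model, test, positive=positive)
        reports.append((spec, cm, report))
    return reports
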