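"""Diagnostic metrics and k-fold cross-validated evaluation.

The positive class is ictal (label 1) throughout.  All five metrics derive
from the confusion matrix:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    sensitivity = recall = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 TP / (2 TP + FP + FN)

Metrics are percentages; formatted output rounds to one decimal
(round-half-up), full precision is retained internally.  A metric whose
denominator is zero is reported as undefined (None), never silently as 0.

Cross-validation is stratified; normalization statistics are fitted on
each training split only and applied to the held-out fold, so no
information leaks across the fold boundary.  Headline numbers are the
unweighted mean of per-fold metrics; the pooled confusion matrix over all
folds is also reported.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError
from .models import ModelConfig, build_model
from .preprocess import SegmentSet, minmax_scale, zscore
from .training import TrainConfig, train

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "FoldResult",
    "CVResult",
    "confusion",
    "metrics_from_confusion",
    "round_half_up",
    "kfold_split",
    "cross_validate",
    "render_report",
]

METRIC_NAMES = ("accuracy", "sensitivity", "precision", "specificity", "f1")


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (2.25 -> 2.3 at one decimal)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts; positive = ictal."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")
        if self.total < 1:
            raise ValueError("confusion matrix must count at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricSet:
    """The five diagnostic metrics as percentages (None = undefined)."""

    accuracy: float | None
    sensitivity: float | None
    precision: float | None
    specificity: float | None
    f1: float | None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def rounded(self, decimals: int = 1) -> dict:
        """One-decimal round-half-up presentation values."""
        return {
            k: (None if v is None else round_half_up(v, decimals))
            for k, v in self.as_dict().items()
        }

    def undefined(self) -> list[str]:
        return [k for k, v in self.as_dict().items() if v is None]


def confusion(labels, predictions) -> ConfusionMatrix:
    """Tally binary predictions against binary labels (1 = ictal)."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if y.shape != p.shape:
        raise ValueError(
            f"labels and predictions differ in length: {y.shape} vs {p.shape}"
        )
    return ConfusionMatrix(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricSet:
    """All five metrics from counts; zero-denominator metrics are None."""
    return MetricSet(
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        precision=_ratio(cm.tp, cm.tp + cm.fp),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        f1=_ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn),
    )


def kfold_split(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment: array of fold indices in [0, k).

    Per-class fold sizes differ by at most one; deterministic under seed.
    """
    y = np.asarray(labels).astype(int)
    if len(y) < k:
        raise ConfigurationError(f"{len(y)} segments cannot fill {k} folds")
    counts = np.bincount(y)
    if np.any(counts[counts > 0] < k):
        raise ConfigurationError(
            f"smallest class has {counts[counts > 0].min()} members, fewer "
            f"than k={k}; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = fold
    return assignment


@dataclass
class FoldResult:
    fold: int
    confusion: ConfusionMatrix
    metrics: MetricSet
    history_final_loss: float | None = None


@dataclass
class CVResult:
    """Per-fold results plus pooled confusion matrix and mean metrics."""

    folds: list[FoldResult]
    pooled: ConfusionMatrix
    k: int
    seed: int
    config_fingerprint: str = ""
    failures: list[dict] = field(default_factory=list)

    @property
    def mean_metrics(self) -> MetricSet:
        """Unweighted mean of fold metrics (None if undefined anywhere)."""
        values = {}
        for name in METRIC_NAMES:
            per_fold = [getattr(f.metrics, name) for f in self.folds]
            values[name] = (
                None if any(v is None for v in per_fold)
                else float(np.mean(per_fold))
            )
        return MetricSet(**values)

    @property
    def pooled_metrics(self) -> MetricSet:
        return metrics_from_confusion(self.pooled)


def _fingerprint(*configs) -> str:
    blob = json.dumps(
        [dataclasses.asdict(c) for c in configs], sort_keys=True, default=str
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def cross_validate(
    model_config: ModelConfig,
    segments: SegmentSet,
    train_config: TrainConfig,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation of a model on a segment set.

    Each fold fits normalization (z-score + min-max) on its training split
    only, trains a freshly initialized model, and evaluates on the held-out
    fold.  A fold whose training fails is recorded in ``failures`` and the
    remaining folds still run.
    """
    assignment = kfold_split(segments.labels, k=k, seed=seed)
    folds: list[FoldResult] = []
    failures: list[dict] = []
    pooled: ConfusionMatrix | None = None
    for fold in range(k):
        test_mask = assignment == fold
        train_split = segments.subset(~test_mask)
        test_split = segments.subset(test_mask)
        try:
            norm_train, params = zscore(train_split)
            norm_train, params = minmax_scale(norm_train, params)
            norm_test, _ = zscore(test_split, params)
            norm_test, _ = minmax_scale(norm_test, params)

            fold_model_cfg = dataclasses.replace(
                model_config, seed=model_config.seed + fold
            )
            fold_train_cfg = dataclasses.replace(
                train_config, seed=train_config.seed + fold
            )
            descriptor = build_model(
                fold_model_cfg,
                (segments.n_channels, segments.segment_samples),
            )
            model, history = train(descriptor, norm_train, None, fold_train_cfg)
            from .preprocess import reshape_for_model

            probs = model.predict_proba(reshape_for_model(norm_test))
            preds = probs.argmax(axis=1)
            cm = confusion(norm_test.labels, preds)
            folds.append(
                FoldResult(
                    fold=fold,
                    confusion=cm,
                    metrics=metrics_from_confusion(cm),
                    history_final_loss=history.loss[-1] if len(history) else None,
                )
            )
            pooled = cm if pooled is None else pooled + cm
        except Exception as exc:  # noqa: BLE001 - fold failure is data
            failures.append({"fold": fold, "error": f"{type(exc).__name__}: {exc}"})
    if pooled is None:
        raise RuntimeError(f"all {k} folds failed: {failures}")
    return CVResult(
        folds=folds,
        pooled=pooled,
        k=k,
        seed=seed,
        config_fingerprint=_fingerprint(model_config, train_config),
        failures=failures,
    )


def render_report(result: CVResult | MetricSet, seed: int | None = None) -> dict:
    """Machine-readable report dict plus a one-decimal text table.

    Returns ``{"json": <dict>, "table": <str>, "csv": <str>}``; the JSON
    part keeps full precision, the table and CSV round to one decimal.
    """
    if isinstance(result, MetricSet):
        payload = {"metrics": result.as_dict(), "rounded": result.rounded()}
        header = "metric," + ",".join(METRIC_NAMES)
        row = "value," + ",".join(
            "NA" if v is None else f"{v}" for v in result.rounded().values()
        )
        table = _format_table(
            ["metric"] + list(METRIC_NAMES),
            [["value"] + [_cell(v) for v in result.rounded().values()]],
        )
        return {"json": payload, "table": table, "csv": header + "\n" + row}

    rows = []
    csv_lines = ["fold," + ",".join(METRIC_NAMES) + ",tp,tn,fp,fn"]
    for f in result.folds:
        r = f.metrics.rounded()
        rows.append([str(f.fold)] + [_cell(r[m]) for m in METRIC_NAMES])
        csv_lines.append(
            f"{f.fold},"
            + ",".join("NA" if r[m] is None else str(r[m]) for m in METRIC_NAMES)
            + f",{f.confusion.tp},{f.confusion.tn},{f.confusion.fp},{f.confusion.fn}"
        )
    mean = result.mean_metrics.rounded()
    rows.append(["mean"] + [_cell(mean[m]) for m in METRIC_NAMES])
    csv_lines.append(
        "mean," + ",".join("NA" if mean[m] is None else str(mean[m])
                           for m in METRIC_NAMES) + ",,,,"
    )
    payload = {
        "k": result.k,
        "seed": seed if seed is not None else result.seed,
        "config_fingerprint": result.config_fingerprint,
        "folds": [
            {
                "fold": f.fold,
                "confusion": dataclasses.asdict(f.confusion),
                "metrics": f.metrics.as_dict(),
            }
            for f in result.folds
        ],
        "pooled_confusion": dataclasses.asdict(result.pooled),
        "pooled_metrics": result.pooled_metrics.as_dict(),
        "mean_metrics": result.mean_metrics.as_dict(),
        "failures": result.failures,
    }
    table = _format_table(["fold"] + list(METRIC_NAMES), rows)
    return {"json": payload, "table": table, "csv": "\n".join(csv_lines)}


def _cell(v) -> str:
    return "NA" if v is None else f"{v:.1f}"


def _format_table(header: list[str], rows: list[list[str]]) -> str:
    widths = [
        max(len(header[i]), *(len(r[i]) for r in rows)) for i in range(len(header))
    ]
    fmt = "  ".join(f"{{:>{w}}}" for w in widths)
    lines = [fmt.format(*header), fmt.format(*["-" * w for w in widths])]
    lines += [fmt.format(*r) for r in rows]
    return "\n".join(lines)
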