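"""Classification performance statistics.

Confusion matrices over {malignant, benign, fat}, one-vs-rest sensitivity /
specificity / accuracy with exact (Clopper-Pearson) binomial confidence
intervals, Pearson correlation, and two-sample t-tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import CLASS_LABELS

__all__ = [
    "PerformanceReport",
    "confusion_matrix",
    "class_metrics",
    "clopper_pearson",
    "pearson_correlation",
    "two_sample_ttest",
    "performance_report",
]


def confusion_matrix(
    true_classes: Sequence[str],
    predicted_classes: Sequence[str],
    labels: Sequence[str] = CLASS_LABELS,
) -> np.ndarray:
    """counts[i, j] = number of items with true class i predicted as class j."""
    true_classes = list(true_classes)
    predicted_classes = list(predicted_classes)
    if len(true_classes) != len(predicted_classes):
        raise ValueError("label sequences must have equal length")
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(true_classes, predicted_classes):
        if t not in index or p not in index:
            raise ValueError(f"unknown class label: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return counts


def class_metrics(
    confusion: np.ndarray, class_index: int
) -> tuple[float | None, float | None, float | None]:
    """One-vs-rest (sensitivity, specificity, accuracy) for one class.

    A metric whose denominator is zero is returned as None (undefined), never
    coerced to 0.
    """
    confusion = np.asarray(confusion)
    total = int(confusion.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    i = class_index
    tp = int(confusion[i, i])
    fn = int(confusion[i, :].sum()) - tp
    fp = int(confusion[:, i].sum()) - tp
    tn = total - tp - fn - fp
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    specificity = tn / (tn + fp) if (tn + fp) > 0 else None
    accuracy = (tp + tn) / total
    return sensitivity, specificity, accuracy


def clopper_pearson(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact binomial confidence interval from beta-distribution quantiles.

    lower = BetaInv(alpha/2; x, n-x+1) (0 when x = 0) and
    upper = BetaInv(1-alpha/2; x+1, n-x) (1 when x = n).
    """
    if trials <= 0 or not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials and trials > 0")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    x, n = successes, trials
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return lower, upper


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p-value from the t distribution.

    t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom; |r| = 1 gives
    p = 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(np.sqrt(np.sum(dx**2)))
    sy = float(np.sqrt(np.sum(dy**2)))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.sum(dx * dy) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, p


def two_sample_ttest(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided two-sample t-test; pooled-variance Student's t by default.

    Welch's correction is available via ``equal_var=False``. Identical
    degenerate groups (zero pooled variance, equal means) return (0, 1);
    zero pooled variance with unequal means is an error.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    ma, mb = a.mean(), b.mean()
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        if sp2 == 0:
            if ma == mb:
                return 0.0, 1.0
            raise ValueError("zero pooled variance with unequal means")
        se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    else:
        if va == 0 and vb == 0:
            if ma == mb:
                return 0.0, 1.0
            raise ValueError("zero variance with unequal means")
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t = float((ma - mb) / se)
    p = 2.0 * float(stats.t.sf(abs(t), df=df))
    return t, p


@dataclass
class PerformanceReport:
    """Confusion matrix plus per-class metrics with binomial CIs."""

    confusion: np.ndarray
    labels: tuple[str, ...]
    per_class: dict[str, dict[str, object]]
    overall_accuracy: float
    overall_accuracy_ci: tuple[float, float]
    level: float
    unit: str  # "specimen" or "pixel"

    @property
    def total(self) -> int:
        return int(np.asarray(self.confusion).sum())

    def row_fractions(self) -> np.ndarray:
        """Per-true-class row-normalized confusion fractions."""
        counts = np.asarray(self.confusion, float)
        sums = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            return np.where(sums > 0, counts / sums, np.nan)

    def to_dict(self) -> dict:
        return {
            "unit": self.unit,
            "level": self.level,
            "labels": list(self.labels),
            "confusion": np.asarray(self.confusion).tolist(),
            "per_class": self.per_class,
            "overall_accuracy": self.overall_accuracy,
            "overall_accuracy_ci": list(self.overall_accuracy_ci),
            "n": self.total,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_table(self) -> pd.DataFrame:
        """Long-format metric table (metric, class, estimate, CI, n)."""
        rows = []
        for lab in self.labels:
            for metric in ("sensitivity", "specificity", "accuracy"):
                entry = self.per_class[lab][metric]
                est, ci = entry["estimate"], entry["ci"]
                rows.append(
                    {
                        "class": lab,
                        "metric": metric,
                        "estimate": est,
                        "ci_lower": None if ci is None else ci[0],
                        "ci_upper": None if ci is None else ci[1],
                        "n": entry["n"],
                    }
                )
        rows.append(
            {
                "class": "overall",
                "metric": "accuracy",
                "estimate": self.overall_accuracy,
                "ci_lower": self.overall_accuracy_ci[0],
                "ci_upper": self.overall_accuracy_ci[1],
                "n": self.total,
            }
        )
        return pd.DataFrame(rows)


def performance_report(
    true_classes: Sequence[str],
    predicted_classes: Sequence[str],
    level: float = 0.95,
    unit: str = "specimen",
    labels: Sequence[str] = CLASS_LABELS,
) -> PerformanceReport:
    """Full classification report with Clopper-Pearson CIs at ``level``."""
    counts = confusion_matrix(true_classes, predicted_classes, labels)
    total = int(counts.sum())
    per_class: dict[str, dict[str, object]] = {}
    for i, lab in enumerate(labels):
        tp = int(counts[i, i])
        fn = int(counts[i, :].sum()) - tp
        fp = int(counts[:, i].sum()) - tp
        tn = total - tp - fn - fp
        sens, spec, acc = class_metrics(counts, i)
        per_class[lab] = {
            "sensitivity": _metric_entry(sens, tp, tp + fn, level),
            "specificity": _metric_entry(spec, tn, tn + fp, level),
            "accuracy": _metric_entry(acc, tp + tn, total, level),
        }
    correct = int(np.trace(counts))
    return PerformanceReport(
        confusion=counts,
        labels=tuple(labels),
        per_class=per_class,
        overall_accuracy=correct / total,
        overall_accuracy_ci=clopper_pearson(correct, total, level),
        level=level,
        unit=unit,
    )


def _metric_entry(estimate, successes: int, trials: int, level: float) -> dict:
    if estimate is None or trials == 0:
        return {"estimate": None, "ci": None, "n": trials}
    return {
        "estimate": estimate,
        "ci": list(clopper_pearson(successes, trials, level)),
        "n": trials,
    }
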