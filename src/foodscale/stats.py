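"""Validation statistics for the estimation pipeline.

Paired t-test, Pearson correlation, one-sample t-test of paired
differences, and per-class accuracy aggregation — the suite used to
compare machine-recognised against physically measured quantities.

All tests are two-sided.  Zero-variance inputs yield an explicitly
flagged degenerate result instead of infinities: identical paired
vectors report t = 0, p = 1 (no evidence of any difference), while a
constant nonzero difference is flagged with undefined t/p.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatsError

__all__ = [
    "PairedSample",
    "OneSampleResult",
    "PearsonResult",
    "ValidationReport",
    "ClassAccuracyTable",
    "paired_t",
    "pearson",
    "one_sample_t",
    "class_accuracy",
    "validate_pairs",
]


@dataclass(frozen=True)
class PairedSample:
    """Two matched numeric vectors (e.g. estimated vs measured weight)."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
            raise StatsError("paired sample needs two equal-length 1-D vectors")
        if len(x) < 3:
            raise StatsError(f"paired sample needs n >= 3, got {len(x)}")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise StatsError("paired sample contains non-finite values")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return len(self.x)

    def differences(self) -> np.ndarray:
        return self.x - self.y


class OneSampleResult(NamedTuple):
    """One-sample t-test summary: mean and SD of the data, Student t
    against mu0 with df = n - 1, two-sided p.  ``degenerate`` marks
    zero-variance input (t/p are 0/1 when the mean equals mu0, NaN
    otherwise)."""

    mean: float
    sd: float
    statistic: float
    pvalue: float
    n: int
    degenerate: bool = False


class PearsonResult(NamedTuple):
    r: float
    r_squared: float
    pvalue: float
    n: int


def one_sample_t(values: Sequence[float], mu0: float = 0.0) -> OneSampleResult:
    """Two-sided one-sample Student t-test of ``values`` against ``mu0``."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 3:
        raise StatsError(f"one-sample t needs n >= 3 values, got shape {v.shape}")
    if not np.isfinite(v).all():
        raise StatsError("non-finite values in sample")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    n = len(v)
    if sd == 0.0:
        if mean == mu0:
            return OneSampleResult(mean, 0.0, 0.0, 1.0, n, degenerate=True)
        return OneSampleResult(mean, 0.0, float("nan"), float("nan"), n, degenerate=True)
    res = sps.ttest_1samp(v, popmean=mu0)
    return OneSampleResult(mean, sd, float(res.statistic), float(res.pvalue), n)


def paired_t(sample: PairedSample) -> OneSampleResult:
    """Two-sided paired Student t-test: by definition the one-sample t
    of the differences x - y against zero (df = n - 1)."""
    return one_sample_t(sample.differences(), mu0=0.0)


def pearson(sample: PairedSample) -> PearsonResult:
    """Product-moment correlation of the paired vectors, with r^2."""
    if sample.x.std() == 0.0 or sample.y.std() == 0.0:
        raise StatsError("Pearson correlation undefined for a zero-variance vector")
    r, p = sps.pearsonr(sample.x, sample.y)
    return PearsonResult(float(r), float(r) ** 2, float(p), sample.n)


@dataclass(frozen=True)
class ValidationReport:
    """Full comparison of estimated against measured values: paired t,
    Pearson correlation, and the one-sample t of the differences."""

    n: int
    mean_diff: float
    sd_diff: float
    t_statistic: float
    p_value: float
    pearson_r: float
    pearson_r_squared: float
    pearson_p: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def validate_pairs(estimated: Sequence[float], measured: Sequence[float]) -> ValidationReport:
    """Run the full validation suite on estimated vs measured values.

    The paired t on (estimated, measured) and the one-sample t on their
    differences are the same test; the report carries it once, alongside
    the Pearson correlation of the two vectors.
    """
    sample = PairedSample(np.asarray(estimated, float), np.asarray(measured, float))
    t_res = paired_t(sample)
    try:
        p_res = pearson(sample)
        r, r2, pp = p_res.r, p_res.r_squared, p_res.pvalue
    except StatsError:
        r = r2 = pp = float("nan")
    return ValidationReport(
        n=sample.n,
        mean_diff=t_res.mean,
        sd_diff=t_res.sd,
        t_statistic=t_res.statistic,
        p_value=t_res.pvalue,
        pearson_r=r,
        pearson_r_squared=r2,
        pearson_p=pp,
        degenerate=t_res.degenerate,
    )


@dataclass(frozen=True)
class ClassAccuracyTable:
    """Per-class recognition accuracy: class -> (sample size, percent
    correct), plus the overall row."""

    per_class: dict
    overall_n: int
    overall_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"class": "Overall", "n": self.overall_n, "accuracy_pct": round(self.overall_accuracy, 2)}]
        for cls, (n, acc) in self.per_class.items():
            rows.append({"class": cls, "n": n, "accuracy_pct": round(acc, 2)})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def class_accuracy(
    labels_true: Sequence,
    labels_pred: Sequence,
    class_map: Optional[Mapping] = None,
) -> ClassAccuracyTable:
    """Percent of correct predictions per class and overall.

    ``class_map`` maps a true label to its aggregation class (e.g. a
    dish name to a food category); without it each distinct true label
    is its own class.  Accuracies are percentages in [0, 100].
    """
    t = list(labels_true)
    p = list(labels_pred)
    if len(t) != len(p):
        raise StatsError("label vectors must have equal length")
    if len(t) == 0:
        raise StatsError("empty label vectors")
    per: dict = {}
    for lt, lp in zip(t, p):
        cls = class_map[lt] if class_map is not None else lt
        n, k = per.get(cls, (0, 0))
        per[cls] = (n + 1, k + (1 if lt == lp else 0))
    table = {cls: (n, 100.0 * k / n) for cls, (n, k) in per.items()}
    total_n = len(t)
    total_k = sum(1 for lt, lp in zip(t, p) if lt == lp)
    return ClassAccuracyTable(
        per_class=table, overall_n=total_n, overall_accuracy=100.0 * total_k / total_n
    )
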