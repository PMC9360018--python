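"""Cross-assay concordance statistics.

Paired measurements (e.g. log10 EC50 by imaging versus by an endpoint
viability assay) are compared with the Pearson correlation (two-sided p),
Lin's concordance correlation coefficient

    CCC = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2),

which penalizes location/scale shifts in addition to scatter (|CCC| <= |r|),
a percentile bootstrap confidence interval (default 10,000 paired
resamples, middle 95%), and a response/no-response confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "ConcordanceResult",
    "pearson_with_p",
    "lins_concordance",
    "bootstrap_ci",
    "response_confusion_matrix",
    "concordance_report",
]


@dataclass
class PairedMeasurements:
    x: np.ndarray
    y: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D and of equal length")
        if len(self.x) < 3:
            raise ValueError("need at least 3 pairs")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("non-finite values in paired measurements")


@dataclass
class ConcordanceResult:
    pearson_r: float
    pearson_p: float
    lin_ccc: float
    ccc_ci_low: float
    ccc_ci_high: float
    n: int
    n_boot: int


def pearson_with_p(pairs: PairedMeasurements) -> tuple[float, float]:
    """Product-moment correlation with two-sided p (t-transform, n-2 dof)."""
    if np.std(pairs.x) == 0 or np.std(pairs.y) == 0:
        raise ValueError("zero variance in one variable")
    r, p = stats.pearsonr(pairs.x, pairs.y)
    return float(r), float(p)


def lins_concordance(pairs: PairedMeasurements) -> float:
    x, y = pairs.x, pairs.y
    sxy = np.cov(x, y, ddof=1)[0, 1]
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    denom = vx + vy + (x.mean() - y.mean()) ** 2
    if denom == 0:
        raise ValueError("degenerate data: zero denominator in CCC")
    return float(2.0 * sxy / denom)


def bootstrap_ci(
    pairs: PairedMeasurements,
    statistic: Callable[[PairedMeasurements], float],
    n_boot: int = 10_000,
    seed: int | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap interval of a paired statistic.

    Resamples pairs with replacement; degenerate resamples (statistic
    raises) are skipped with a reported count.  Deterministic per seed.
    """
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap resamples")
    rng = np.random.default_rng(seed)
    n = len(pairs.x)
    vals = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            vals.append(statistic(PairedMeasurements(pairs.x[idx], pairs.y[idx])))
        except ValueError:
            skipped += 1
    if skipped:
        warnings.warn(f"{skipped} degenerate bootstrap resamples skipped", stacklevel=2)
    lo, hi = np.percentile(vals, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi)


def response_confusion_matrix(
    calls_a: Sequence[bool], calls_b: Sequence[bool]
) -> tuple[np.ndarray, float]:
    """2x2 counts [[RR, RN], [NR, NN]] (a = rows, b = columns) and agreement."""
    a = np.asarray(calls_a, dtype=bool)
    b = np.asarray(calls_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("call vectors differ in length")
    counts = np.array(
        [[int((a & b).sum()), int((a & ~b).sum())],
         [int((~a & b).sum()), int((~a & ~b).sum())]]
    )
    agreement = float(np.trace(counts) / counts.sum())
    return counts, agreement


def concordance_report(
    pairs: PairedMeasurements, n_boot: int = 10_000, seed: int | None = None
) -> ConcordanceResult:
    r, p = pearson_with_p(pairs)
    ccc = lins_concordance(pairs)
    lo, hi = bootstrap_ci(pairs, lins_concordance, n_boot=n_boot, seed=seed)
    return ConcordanceResult(r, p, ccc, lo, hi, len(pairs.x), n_boot)
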