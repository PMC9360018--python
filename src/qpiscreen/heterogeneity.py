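"""Growth heterogeneity metrics and in-silico resistant-cell mixing.

Heterogeneity is summarized by the standard deviation of single-cell SGR
at the tested concentration nearest the EC50 (SD at EC50).  The detection
limit for resistant subpopulations is probed in silico: control
(resistant-like) cells are mixed into a drug-treated population at a known
ratio, cells are called resistant when their SGR exceeds a threshold swept
over a fixed grid, and performance is summarized by the area under the
precision-recall curve normalized by the area above the no-skill line
(the positive-class prevalence):

    nAUPRC = (AUPRC - prevalence) / (1 - prevalence)

so a no-skill classifier scores ~0 and a perfect one scores 1.  Mixing is
repeated (default 100x) and the median normalized AUPRC reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MixingDesign",
    "PRResult",
    "LabeledPool",
    "sd_at_ec50",
    "simulate_mixture",
    "precision_recall_curve",
    "replicate_mixing",
]

DEFAULT_MIXING_RATIOS = (0.5, 0.25, 0.1, 0.05, 0.02, 0.01, 0.001, 0.0001)


def _default_threshold_grid() -> np.ndarray:
    # -0.1 to 0.15 1/h in 0.005 steps (51 thresholds)
    return np.round(np.arange(-0.1, 0.15 + 1e-9, 0.005), 10)


@dataclass
class MixingDesign:
    mixing_ratios: tuple[float, ...] = DEFAULT_MIXING_RATIOS
    threshold_grid: np.ndarray = field(default_factory=_default_threshold_grid)
    n_repeats: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not (0 < r < 1) for r in self.mixing_ratios):
            raise ValueError("mixing ratios must lie in (0, 1)")
        self.threshold_grid = np.asarray(self.threshold_grid, dtype=float)
        if not (np.diff(self.threshold_grid) > 0).all():
            raise ValueError("threshold grid must be strictly increasing")
        if self.n_repeats < 1:
            raise ValueError("need at least one repeat")


@dataclass
class PRResult:
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auprc: float
    no_skill: float
    normalized_auprc: float


@dataclass
class LabeledPool:
    """Pooled SGR values with resistant labels (True = spiked-in control cell)."""

    sgr: np.ndarray
    is_resistant: np.ndarray

    def __post_init__(self) -> None:
        self.sgr = np.asarray(self.sgr, dtype=float)
        self.is_resistant = np.asarray(self.is_resistant, dtype=bool)
        if self.sgr.shape != self.is_resistant.shape:
            raise ValueError("value/label length mismatch")
        if self.sgr.size == 0:
            raise ValueError("empty pool")


# --------------------------------------------------------------------------
# SD at EC50
# --------------------------------------------------------------------------

def sd_at_ec50(
    sgr_by_concentration: dict[float, np.ndarray], ec50_uM: float
) -> tuple[float, float]:
    """(concentration, SD of single-cell SGR) at the tested concentration
    nearest the EC50 in absolute log-distance."""
    conc = np.array(sorted(c for c in sgr_by_concentration if c > 0), dtype=float)
    if conc.size == 0:
        raise ValueError("no positive tested concentrations")
    nearest = float(conc[np.argmin(np.abs(np.log(conc) - np.log(ec50_uM)))])
    vals = np.asarray(sgr_by_concentration[nearest], dtype=float)
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return nearest, sd


# --------------------------------------------------------------------------
# mixing simulation
# --------------------------------------------------------------------------

def simulate_mixture(
    control_sgr: np.ndarray,
    treated_sgr: np.ndarray,
    ratio: float,
    seed: int | None = None,
) -> LabeledPool:
    """Spike control cells into the treated pool so positives make up ``ratio``.

    The number of controls added is round(ratio * n_treated / (1 - ratio)),
    at least 1; sampling is without replacement when the control pool
    allows, with replacement (and a warning) otherwise.  Deterministic per
    seed.
    """
    import warnings

    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    control = np.asarray(control_sgr, dtype=float)
    treated = np.asarray(treated_sgr, dtype=float)
    if control.size == 0 or treated.size == 0:
        raise ValueError("empty control or treated pool")
    n_add = max(int(round(ratio * treated.size / (1.0 - ratio))), 1)
    rng = np.random.default_rng(seed)
    replace = n_add > control.size
    if replace:
        warnings.warn("control pool smaller than spike; sampling with replacement",
                      stacklevel=2)
    spiked = rng.choice(control, size=n_add, replace=replace)
    return LabeledPool(
        np.concatenate([treated, spiked]),
        np.concatenate([np.zeros(treated.size, bool), np.ones(n_add, bool)]),
    )


def precision_recall_curve(pool: LabeledPool, threshold_grid: np.ndarray | None = None) -> PRResult:
    """Precision/recall over a fixed SGR threshold grid and normalized AUPRC.

    A cell is called resistant when its SGR strictly exceeds the threshold.
    Precision with no predicted positives is defined as the no-skill level
    (positive prevalence).  The AUPRC is the trapezoid over recall after
    sorting by recall, on the attainable frontier: ties in recall keep the
    best precision, and the recall -> 0 end is anchored at the precision of
    the smallest positive recall (the usual PR-curve convention, so a
    perfectly separating threshold grid integrates to 1).
    """
    thresholds = _default_threshold_grid() if threshold_grid is None else np.asarray(threshold_grid)
    y, lab = pool.sgr, pool.is_resistant
    n_pos = int(lab.sum())
    if n_pos == 0 or n_pos == lab.size:
        raise ValueError("pool contains a single class")
    prevalence = n_pos / lab.size
    precision = np.empty(len(thresholds))
    recall = np.empty(len(thresholds))
    for i, th in enumerate(thresholds):
        pred = y > th
        tp = int((pred & lab).sum())
        fp = int((pred & ~lab).sum())
        precision[i] = tp / (tp + fp) if (tp + fp) > 0 else prevalence
        recall[i] = tp / n_pos
    # attainable frontier: unique recalls with their best precision
    uniq = np.unique(recall)
    frontier = np.array([precision[recall == r].max() for r in uniq])
    if uniq[0] == 0.0:
        frontier[0] = frontier[1] if len(uniq) > 1 else prevalence
    auprc = float(np.trapezoid(frontier, uniq))
    if uniq[-1] < 1.0:  # grid never reaches full recall: extend flat
        auprc += float(frontier[-1] * (1.0 - uniq[-1]))
    normalized = (auprc - prevalence) / (1.0 - prevalence)
    return PRResult(thresholds, precision, recall, auprc, prevalence, float(normalized))


def replicate_mixing(
    design: MixingDesign,
    control_sgr: np.ndarray,
    treated_sgr: np.ndarray,
) -> dict[float, dict]:
    """Seeded repeats of the mixing analysis per ratio.

    Returns, per mixing ratio: the normalized AUPRC of every repeat, the
    median normalized AUPRC, and the PR curve of the median-AUPRC repeat.
    """
    out: dict[float, dict] = {}
    ss = np.random.SeedSequence(design.seed)
    for ratio in design.mixing_ratios:
        seeds = ss.spawn(1)[0].generate_state(design.n_repeats) % (2**31)
        results = [
            precision_recall_curve(
                simulate_mixture(control_sgr, treated_sgr, ratio, int(s)),
                design.threshold_grid,
            )
            for s in seeds
        ]
        scores = np.array([r.normalized_auprc for r in results])
        med_idx = int(np.argsort(scores, kind="stable")[len(scores) // 2])
        out[ratio] = {
            "normalized_auprc": scores,
            "median_normalized_auprc": float(np.median(scores)),
            "median_repeat": results[med_idx],
        }
    return out
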