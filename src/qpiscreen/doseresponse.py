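"""Four-parameter Hill dose-response fitting and response classification.

The response model relates mean specific growth rate to drug concentration:

    SGR(C) = Emax + (E0 - Emax) / (1 + (C / EC50)^HS)

with E0 the low-concentration asymptote, Emax the high-concentration
asymptote, EC50 the inflection point, and HS the Hill slope.  A condition
responds when the Hill fit beats a flat (constant) fit in an F-test at
p < 0.01.  For responders the depth of response

    DoR = (E0 - Emax) / E0

is < 1 for cytostatic responses (growth slowed) and > 1 for cytotoxic
ones (net mass loss; Emax < 0).  The same machinery fitted to per-condition
SGR standard deviations yields the heterogeneity EC50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DoseResponseData",
    "HillFit",
    "ResponseCall",
    "hill_curve",
    "fit_hill",
    "f_test_response",
    "compute_dor",
    "fit_heterogeneity_ec50",
    "map_control_concentration",
]


@dataclass
class DoseResponseData:
    """Per-condition mean response (SGR or SD of SGR) versus concentration."""

    concentrations_uM: np.ndarray
    mean_response: np.ndarray
    sem: np.ndarray | None = None
    n_per_condition: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations_uM = np.asarray(self.concentrations_uM, dtype=float)
        self.mean_response = np.asarray(self.mean_response, dtype=float)
        if self.concentrations_uM.shape != self.mean_response.shape:
            raise ValueError("concentration/response length mismatch")
        if (self.concentrations_uM <= 0).any():
            raise ValueError(
                "concentrations must be strictly positive "
                "(map solvent controls to a pseudo-concentration first)"
            )
        if len(np.unique(self.concentrations_uM)) < 5:
            raise ValueError("need >= 5 distinct concentrations for a 4-parameter fit")


@dataclass
class HillFit:
    e0: float
    emax: float
    ec50_uM: float
    hs: float
    rss: float
    dof: int

    def predict(self, conc_uM: np.ndarray) -> np.ndarray:
        return hill_curve(np.asarray(conc_uM, dtype=float), self.e0, self.emax,
                          self.ec50_uM, self.hs)


@dataclass
class ResponseCall:
    responded: bool
    f_statistic: float
    p_value: float
    flat_fit_level: float
    dor: float | None = None
    cytotoxic: bool = False


def hill_curve(conc: np.ndarray, e0: float, emax: float, ec50: float, hs: float) -> np.ndarray:
    return emax + (e0 - emax) / (1.0 + (conc / ec50) ** hs)


def map_control_concentration(concentrations_uM: np.ndarray, control_divisor: float = 100.0) -> float:
    """Pseudo-concentration for a solvent control on a log axis."""
    pos = np.asarray(concentrations_uM, float)
    pos = pos[pos > 0]
    if len(pos) == 0:
        raise ValueError("no positive concentrations to anchor the control")
    return float(pos.min() / control_divisor)


def fit_hill(data: DoseResponseData, n_starts: int = 5) -> HillFit:
    """Least-squares 4-parameter Hill fit in log10-concentration space.

    Multi-start over EC50 initial guesses spanning the tested range; the
    Hill slope is bounded to [0.1, 10] and EC50 to [min/100, max*100].
    """
    conc = data.concentrations_uM
    y = data.mean_response
    logc = np.log10(conc)
    lo, hi = logc.min(), logc.max()

    def model(lc, e0, emax, lec50, hs):
        # exponent clamp keeps the optimizer out of overflow territory
        return emax + (e0 - emax) / (1.0 + 10.0 ** np.clip(hs * (lc - lec50), -30.0, 30.0))

    LN10 = np.log(10.0)

    def jac(lc, e0, emax, lec50, hs):
        q = 10.0 ** np.clip(hs * (lc - lec50), -30.0, 30.0)
        denom = 1.0 + q
        inv = 1.0 / denom
        common = (e0 - emax) * q * LN10 / denom**2
        return np.column_stack([inv, 1.0 - inv, common * hs, -common * (lc - lec50)])

    yr = np.ptp(y) or 1.0
    bounds = (
        [y.min() - 2 * yr, y.min() - 2 * yr, lo - 2.0, 0.1],
        [y.max() + 2 * yr, y.max() + 2 * yr, hi + 2.0, 10.0],
    )
    best = None
    for lec0 in np.linspace(lo, hi, n_starts):
        p0 = [y[np.argmin(logc)], y[np.argmax(logc)], lec0, 1.0]
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            popt, _ = optimize.curve_fit(
                model, logc, y, p0=p0, bounds=bounds, jac=jac, maxfev=600
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(((y - model(logc, *popt)) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise RuntimeError("Hill fit failed to converge from all starts")
    rss, (e0, emax, lec50, hs) = best
    return HillFit(float(e0), float(emax), float(10.0**lec50), float(hs),
                   rss, len(y) - 4)


def f_test_response(data: DoseResponseData, hill: HillFit) -> ResponseCall:
    """F-test of the Hill fit against a fitted flat line, alpha = 0.01.

    F = ((RSS_flat - RSS_hill)/(dof_flat - dof_hill)) / (RSS_hill/dof_hill)
    with dof (3, n - 4).  A perfect Hill fit (RSS = 0) responds by
    convention with p = 0.
    """
    y = data.mean_response
    n = len(y)
    flat_level = float(y.mean())
    rss_flat = float(((y - flat_level) ** 2).sum())
    dof_flat, dof_hill = n - 1, n - 4
    if dof_hill <= 0:
        raise ValueError("need more than 4 points for the F-test")
    eps = 1e-25 * max(1.0, float((y**2).sum()))
    if hill.rss <= eps:
        if rss_flat <= eps:
            return ResponseCall(False, 0.0, 1.0, flat_level)  # exactly flat data
        return ResponseCall(True, np.inf, 0.0, flat_level)
    f = ((rss_flat - hill.rss) / (dof_flat - dof_hill)) / (hill.rss / dof_hill)
    p = float(stats.f.sf(f, dof_flat - dof_hill, dof_hill)) if f > 0 else 1.0
    return ResponseCall(p < 0.01, float(f), p, flat_level)


def compute_dor(hill: HillFit) -> tuple[float, bool]:
    """Depth of response (E0 - Emax)/E0 and the cytotoxicity flag (DoR > 1)."""
    if hill.e0 == 0:
        raise ValueError("DoR undefined: E0 = 0")
    dor = (hill.e0 - hill.emax) / hill.e0
    return float(dor), bool(dor > 1.0)


def fit_heterogeneity_ec50(sd_data: DoseResponseData, n_starts: int = 5) -> HillFit:
    """Hill fit of per-condition SGR standard deviation versus concentration."""
    return fit_hill(sd_data, n_starts=n_starts)
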