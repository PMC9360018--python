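"""Specific growth rate (SGR) estimation, filtering, and temporal dynamics.

For each mass-versus-time track the mass is median filtered, time shifted
to start at t = 0, and fitted by ordinary least squares.  The slope is the
growth rate (pg/h), the intercept the initial mass, and

    SGR = slope / intercept        [1/h]

so that for exponential growth SGR equals the exponential growth constant
ln(2)/t_doubling.  Tracks shorter than 20 frames or lighter than 110 pg
(mean, after filtering) are rejected; records whose fit quality (standard
error of the estimate, s_yx) or normalized slope k deviates from the
population median by more than 3 median absolute deviations are removed as
outliers.  Temporal dynamics are computed on overlapping 24-h windows
centred on each imaging time point, grouped 8 adjacent windows per bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .segment import CellTrack

__all__ = [
    "TrackFilterParams",
    "SGRRecord",
    "TemporalSGRSet",
    "sgr_from_doubling_time",
    "doubling_time_from_sgr",
    "compute_sgr",
    "remove_outlier_records",
    "sliding_window_sgr",
    "normalized_mass_curve",
]


@dataclass(frozen=True)
class TrackFilterParams:
    min_frames: int = 20
    median_kernel: int = 5
    min_mean_mass_pg: float = 110.0
    mad_multiplier: float = 3.0
    window_h: float = 24.0

    def __post_init__(self) -> None:
        if min(self.min_frames, self.median_kernel) <= 0 or self.min_mean_mass_pg <= 0:
            raise ValueError("filter parameters must be positive")
        if self.median_kernel % 2 == 0:
            raise ValueError("median kernel must be odd")


@dataclass
class SGRRecord:
    """Per-track regression result."""

    track_id: int
    growth_rate_pg_h: float     # regression slope
    initial_mass_pg: float      # intercept of the time-shifted fit
    sgr_h: float                # k = slope / intercept
    see: float                  # standard error of the estimate, s_yx
    n_frames: int
    well: str = ""
    location_id: str = ""
    accepted: bool = True
    reason: str = ""


@dataclass
class TemporalSGRSet:
    """Windowed SGR values grouped into bins of adjacent intervals."""

    interval_centers_h: np.ndarray
    records_per_interval: list[list[SGRRecord]]
    bin_of_interval: np.ndarray        # bin index per interval, -1 = unbinned
    n_bins: int
    window_h: float = 24.0

    def bin_centers_h(self) -> np.ndarray:
        return np.array([
            self.interval_centers_h[self.bin_of_interval == b].mean()
            for b in range(self.n_bins)
        ])

    def bin_track_means(self, b: int) -> pd.DataFrame:
        """Mean SGR of each track over the intervals of bin ``b``."""
        rows = [
            {"track_id": r.track_id, "well": r.well, "location": r.location_id, "sgr_h": r.sgr_h}
            for i in np.nonzero(self.bin_of_interval == b)[0]
            for r in self.records_per_interval[i]
        ]
        df = pd.DataFrame(rows, columns=["track_id", "well", "location", "sgr_h"])
        if df.empty:
            return df
        return df.groupby(["well", "location", "track_id"], as_index=False)["sgr_h"].mean()

    def bin_kde(self, b: int):
        """Gaussian KDE (Silverman bandwidth) of the per-track mean SGRs in bin b."""
        vals = self.bin_track_means(b)["sgr_h"].to_numpy()
        if len(vals) < 2 or np.std(vals) == 0:
            return None
        return stats.gaussian_kde(vals, bw_method="silverman")


# --------------------------------------------------------------------------
# doubling-time relation
# --------------------------------------------------------------------------

def sgr_from_doubling_time(t_doubling_h: float) -> float:
    """SGR = ln(2) / t_doubling for exponential growth."""
    if t_doubling_h <= 0:
        raise ValueError("doubling time must be positive")
    return float(np.log(2.0) / t_doubling_h)


def doubling_time_from_sgr(sgr_h: float) -> float:
    if sgr_h <= 0:
        raise ValueError("SGR must be positive to define a doubling time")
    return float(np.log(2.0) / sgr_h)


# --------------------------------------------------------------------------
# per-track SGR
# --------------------------------------------------------------------------

def _regress(times: np.ndarray, masses: np.ndarray) -> tuple[float, float, float]:
    """OLS of mass on time-shifted time; returns (slope, intercept, s_yx)."""
    t = times - times[0]
    n = len(t)
    slope, intercept = np.polyfit(t, masses, 1)
    resid = masses - (slope * t + intercept)
    see = float(np.sqrt((resid**2).sum() / max(n - 2, 1)))
    return float(slope), float(intercept), see


def compute_sgr(
    track: CellTrack, params: TrackFilterParams | None = None
) -> SGRRecord:
    """SGR of one track with the standard filtering rules.

    Rejections carry a ``reason`` of ``too_short``, ``low_mass`` or
    ``nonpositive_intercept`` and have ``accepted=False``.
    """
    params = params or TrackFilterParams()
    times, masses = track.times, track.masses
    n = len(times)
    rec = SGRRecord(track.track_id, np.nan, np.nan, np.nan, np.nan, n,
                    track.well, track.location_id)
    if n < params.min_frames:
        rec.accepted, rec.reason = False, "too_short"
        return rec
    filt = ndimage.median_filter(masses, size=min(params.median_kernel, n), mode="nearest")
    if filt.mean() < params.min_mean_mass_pg:
        rec.accepted, rec.reason = False, "low_mass"
        return rec
    slope, intercept, see = _regress(times, filt)
    rec.growth_rate_pg_h, rec.initial_mass_pg, rec.see = slope, intercept, see
    if intercept <= 0:
        rec.accepted, rec.reason = False, "nonpositive_intercept"
        return rec
    rec.sgr_h = slope / intercept
    return rec


def remove_outlier_records(
    records: list[SGRRecord], params: TrackFilterParams | None = None
) -> list[SGRRecord]:
    """Single-pass 3-MAD outlier removal on s_yx and on k (union of flags).

    With MAD = 0 (degenerate, e.g. all-identical values) only records at the
    exact median survive that quantity's test; identical populations are
    therefore retained unchanged.  Fewer than 3 records are returned
    unchanged with a warning.
    """
    params = params or TrackFilterParams()
    accepted = [r for r in records if r.accepted]
    if len(accepted) < 3:
        warnings.warn("fewer than 3 records; outlier removal skipped", stacklevel=2)
        return records
    out = list(records)
    for attr in ("see", "sgr_h"):
        vals = np.array([getattr(r, attr) for r in accepted])
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        for r in accepted:
            if abs(getattr(r, attr) - med) > params.mad_multiplier * mad:
                r.accepted, r.reason = False, f"mad_outlier_{attr}"
    return out


# --------------------------------------------------------------------------
# sliding-window temporal SGR
# --------------------------------------------------------------------------

def sliding_window_sgr(
    tracks: list[CellTrack],
    duration_h: float,
    frame_interval_min: float = 20.0,
    params: TrackFilterParams | None = None,
    bin_size: int = 8,
) -> TemporalSGRSet:
    """Windowed SGR over overlapping 24-h intervals centred on frame times.

    A centre c is valid when [c - W/2, c + W/2) lies inside [0, duration):
    for a 72-h experiment at 20-min spacing this yields exactly 144
    intervals and, grouped ``bin_size`` = 8 adjacent intervals per bin,
    18 bins.  Within each interval the track observations falling in the
    window are re-filtered (>= min_frames points, >= min mean mass) and
    refitted by time-shifted OLS; the interval's records then pass the
    3-MAD outlier rule on s_yx and k.
    """
    params = params or TrackFilterParams()
    W = params.window_h
    if duration_h < W:
        raise ValueError(f"duration {duration_h} h shorter than window {W} h")
    dt = frame_interval_min / 60.0
    n_frames = int(round(duration_h / dt)) + 1
    frame_times = np.arange(n_frames) * dt
    centers = frame_times[(frame_times - W / 2 >= 0) & (frame_times + W / 2 < duration_h)]

    records_per_interval: list[list[SGRRecord]] = []
    for c in centers:
        lo, hi = c - W / 2, c + W / 2
        recs = []
        for tr in tracks:
            t, m = tr.times, tr.masses
            sel = (t >= lo) & (t < hi)
            if sel.sum() < params.min_frames:
                continue
            tw, mw = t[sel], m[sel]
            nw = len(tw)
            filt = ndimage.median_filter(mw, size=min(params.median_kernel, nw), mode="nearest")
            if filt.mean() < params.min_mean_mass_pg:
                continue
            slope, intercept, see = _regress(tw, filt)
            if intercept <= 0:
                continue
            recs.append(
                SGRRecord(tr.track_id, slope, intercept, slope / intercept, see,
                          nw, tr.well, tr.location_id)
            )
        if len(recs) >= 3:
            recs = [r for r in remove_outlier_records(recs, params) if r.accepted]
        records_per_interval.append(recs)

    n_intervals = len(centers)
    n_bins = n_intervals // bin_size
    bin_of_interval = np.full(n_intervals, -1, dtype=int)
    for i in range(n_bins * bin_size):
        bin_of_interval[i] = i // bin_size
    return TemporalSGRSet(centers, records_per_interval, bin_of_interval, n_bins, W)


# --------------------------------------------------------------------------
# normalized mass versus time
# --------------------------------------------------------------------------

def normalized_mass_curve(
    location_mass: pd.DataFrame,
    well_of_location: dict[str, str] | None = None,
    median_kernel: int = 5,
) -> pd.DataFrame:
    """Condition-level normalized total-mass curve.

    ``location_mass`` has columns (location, time_h, total_mass_pg): the
    total image mass of each imaging location over time.  Each location's
    series is median filtered and divided by its initial value; the curve
    is the mean over locations and the spread the standard deviation over
    replicate wells (per-well means), or over locations when no well map
    is given.  Returns columns (time_h, mean_norm_mass, sd_norm_mass).
    """
    per_loc = {}
    for loc, g in location_mass.groupby("location"):
        g = g.sort_values("time_h")
        m = g["total_mass_pg"].to_numpy(dtype=float)
        n = len(m)
        filt = ndimage.median_filter(m, size=max(min(median_kernel, n), 1), mode="nearest")
        if filt[0] == 0:
            raise ValueError(f"zero initial mass in location {loc!r}")
        per_loc[loc] = pd.Series(filt / filt[0], index=g["time_h"].to_numpy())
    wide = pd.DataFrame(per_loc)
    mean_curve = wide.mean(axis=1)
    if well_of_location:
        wells = pd.Series({loc: well_of_location.get(str(loc), str(loc)) for loc in wide.columns})
        well_means = wide.T.groupby(wells).mean().T
        sd_curve = well_means.std(axis=1, ddof=1) if well_means.shape[1] > 1 else mean_curve * 0.0
    else:
        sd_curve = wide.std(axis=1, ddof=1) if wide.shape[1] > 1 else mean_curve * 0.0
    return pd.DataFrame(
        {"time_h": wide.index, "mean_norm_mass": mean_curve.to_numpy(),
         "sd_norm_mass": sd_curve.fillna(0.0).to_numpy()}
    )
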