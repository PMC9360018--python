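"""End-to-end analysis pipeline: tracks -> SGR -> dose response -> dynamics.

Stages can be entered at the raw-frame, phase-image, or track-table level.
Each stage logs its filter bookkeeping (tracks rejected by length, mass,
or MAD outlier status) so accepted + rejected always equals the input
count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics as dyn
from .doseresponse import (
    DoseResponseData,
    compute_dor,
    f_test_response,
    fit_hill,
    map_control_concentration,
)
from .growth import TrackFilterParams, compute_sgr, remove_outlier_records, sliding_window_sgr
from .heterogeneity import sd_at_ec50
from .optics import OpticalConfig, read_frame_tiff, reconstruct_frameset, write_phase_tiff
from .optics import DPCFrameSet
from .segment import (
    SegmentationParams,
    correct_background,
    dataframe_to_tracks,
    link_tracks,
    measure_observations,
    segment_cells,
    tracks_to_dataframe,
)
from .synth import PlateLayout

logger = logging.getLogger("qpiscreen")

__all__ = ["run_pipeline", "sgr_table", "dose_response_table", "tor_table", "PipelineResult"]


@dataclass
class PipelineResult:
    sgr: pd.DataFrame
    dose_response: pd.DataFrame
    tor: pd.DataFrame
    heterogeneity: pd.DataFrame
    filter_counts: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# imaging stages
# --------------------------------------------------------------------------

def reconstruct_directory(
    in_dir: str | Path,
    out_dir: str | Path,
    config: OpticalConfig | None = None,
    pattern: str = "{location}_{timeindex}_{half}.tif",
) -> int:
    """Reconstruct every four-frame set found in ``in_dir``; returns count."""
    cfg = config or OpticalConfig()
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    keys = {}
    for p in sorted(in_dir.glob("*.tif")):
        stem = p.stem.rsplit("_", 2)
        if len(stem) != 3:
            continue
        loc, tidx, half = stem
        keys.setdefault((loc, tidx), {})[half] = p
    n = 0
    for (loc, tidx), halves in sorted(keys.items()):
        if set(halves) != {"top", "bottom", "left", "right"}:
            logger.warning("incomplete frame set %s_%s skipped", loc, tidx)
            continue
        frames = DPCFrameSet(
            **{h: read_frame_tiff(p) for h, p in halves.items()},
            timestamp=float(tidx), location_id=loc,
        )
        phase = reconstruct_frameset(frames, cfg)
        write_phase_tiff(out_dir / f"{loc}_{tidx}_phase.tif", phase)
        n += 1
    return n


def track_phase_series(
    phases: list, frame_times_h: list[float],
    seg_params: SegmentationParams | None = None,
    config: OpticalConfig | None = None,
    well: str = "", location_id: str = "",
) -> pd.DataFrame:
    """Segment, background-correct and link one location's phase series."""
    seg_params = seg_params or SegmentationParams()
    frames_obs = []
    for i, (ph, t) in enumerate(zip(phases, frame_times_h)):
        labels = segment_cells(ph, seg_params)
        corrected = correct_background(ph, labels, seg_params)
        labels = segment_cells(corrected, seg_params)
        frames_obs.append(measure_observations(corrected, labels, i, t, config))
    tracks = link_tracks(frames_obs, well=well, location_id=location_id)
    return tracks_to_dataframe(tracks)


# --------------------------------------------------------------------------
# SGR stage
# --------------------------------------------------------------------------

def sgr_table(
    tracks_df: pd.DataFrame, params: TrackFilterParams | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-track SGR with filtering; returns (table, filter counts).

    The 3-MAD outlier rule is applied within each well (condition
    replicate) across its accepted records.
    """
    params = params or TrackFilterParams()
    tracks = dataframe_to_tracks(tracks_df)
    records = [compute_sgr(t, params) for t in tracks]
    by_well: dict[str, list] = {}
    for r in records:
        by_well.setdefault(r.well, []).append(r)
    for well_records in by_well.values():
        remove_outlier_records(well_records, params)
    rows = [
        {
            "track_id": r.track_id, "well": r.well, "location": r.location_id,
            "sgr_h": r.sgr_h, "growth_rate_pg_h": r.growth_rate_pg_h,
            "initial_mass_pg": r.initial_mass_pg, "see": r.see,
            "n_frames": r.n_frames, "accepted": r.accepted, "reason": r.reason,
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    counts = {"input": len(records), "accepted": int(df["accepted"].sum())}
    for reason, n in df.loc[~df["accepted"], "reason"].value_counts().items():
        counts[reason] = int(n)
    logger.info("SGR filtering: %s", counts)
    return df, counts


# --------------------------------------------------------------------------
# dose-response stage
# --------------------------------------------------------------------------

def _condition_frame(sgr_df: pd.DataFrame, layout: PlateLayout) -> pd.DataFrame:
    acc = sgr_df[sgr_df["accepted"]].copy()
    meta = {
        w: (c.drug, c.concentration_uM, c.solvent) for w, c in layout.wells.items()
    }
    acc["drug"] = acc["well"].map(lambda w: meta[w][0])
    acc["concentration_uM"] = acc["well"].map(lambda w: meta[w][1])
    acc["solvent"] = acc["well"].map(lambda w: meta[w][2])
    return acc


def dose_response_table(
    sgr_df: pd.DataFrame, layout: PlateLayout, alpha: float = 0.01
) -> pd.DataFrame:
    """Hill fit + response call per drug.

    The condition response is the mean over per-location mean SGRs (SEM
    across locations); the solvent control enters every drug's curve at a
    pseudo-concentration of (lowest tested concentration)/100.
    """
    acc = _condition_frame(sgr_df, layout)
    controls = acc[acc["drug"].str.startswith("control_")]
    rows = []
    for drug, g in acc[~acc["drug"].str.startswith("control_")].groupby("drug"):
        loc_means = g.groupby(["concentration_uM", "location"])["sgr_h"].mean().reset_index()
        cond = loc_means.groupby("concentration_uM")["sgr_h"].agg(["mean", "sem", "count"])
        conc = cond.index.to_numpy(dtype=float)
        pseudo = map_control_concentration(conc)
        ctrl_locs = controls.groupby("location")["sgr_h"].mean()
        all_conc = np.concatenate([[pseudo], conc])
        all_mean = np.concatenate([[ctrl_locs.mean()], cond["mean"].to_numpy()])
        all_sem = np.concatenate([[ctrl_locs.sem()], cond["sem"].to_numpy()])
        data = DoseResponseData(all_conc, all_mean, all_sem)
        hill = fit_hill(data)
        call = f_test_response(data, hill)
        dor, cytotoxic = (np.nan, False)
        if call.responded:
            dor, cytotoxic = compute_dor(hill)
        rows.append(
            {
                "drug": drug, "e0": hill.e0, "emax": hill.emax,
                "ec50_uM": hill.ec50_uM, "hs": hill.hs,
                "f_statistic": call.f_statistic, "p_value": call.p_value,
                "responded": call.responded, "dor": dor, "cytotoxic": cytotoxic,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# temporal / ToR stage
# --------------------------------------------------------------------------

def _bin_distributions(
    temporal, bin_range: tuple[float, float] = dyn.DEFAULT_SGR_RANGE
) -> list:
    dists = []
    for b in range(temporal.n_bins):
        vals = temporal.bin_track_means(b)["sgr_h"].to_numpy()
        if len(vals) == 0:
            dists.append(None)
            continue
        dists.append(
            dyn.kde_sgr_distribution(vals, time_center_h=temporal.bin_centers_h()[b])
        )
    return dists


def tor_table(
    tracks_df: pd.DataFrame,
    layout: PlateLayout,
    duration_h: float = 72.0,
    frame_interval_min: float = 20.0,
    params: TrackFilterParams | None = None,
    bin_size: int = 8,
) -> pd.DataFrame:
    """Per drug/concentration time of response from windowed Hellinger series.

    The threshold is the maximum distance between the plate's two control
    groups over time; each treated condition's distance-to-control series
    is fitted by the saturating-exponential model and inverted at the
    threshold.
    """
    params = params or TrackFilterParams()
    meta = {w: (c.drug, c.concentration_uM) for w, c in layout.wells.items()}
    tracks_df = tracks_df.copy()
    tracks_df["drug"] = tracks_df["well"].map(lambda w: meta[w][0])
    tracks_df["concentration_uM"] = tracks_df["well"].map(lambda w: meta[w][1])

    def temporal_of(sub: pd.DataFrame):
        return sliding_window_sgr(
            dataframe_to_tracks(sub), duration_h, frame_interval_min, params,
            bin_size=bin_size,
        )

    controls = sorted(
        d for d in tracks_df["drug"].unique() if str(d).startswith("control_")
    )
    if not controls:
        raise ValueError("no control wells in layout")
    ctrl_main = _bin_distributions(temporal_of(tracks_df[tracks_df["drug"] == controls[0]]))
    if len(controls) > 1:
        ctrl_other = _bin_distributions(temporal_of(tracks_df[tracks_df["drug"] == controls[1]]))
        pairs = [
            (s, u) for s, u in zip(ctrl_main, ctrl_other) if s is not None and u is not None
        ]
        threshold = max(dyn.hellinger_distance(s, u) for s, u in pairs)
    else:
        threshold = 0.05
        logger.warning("single control group; using fallback Hellinger threshold 0.05")

    rows = []
    treated = tracks_df[~tracks_df["drug"].astype(str).str.startswith("control_")]
    for (drug, conc), sub in treated.groupby(["drug", "concentration_uM"]):
        temporal = temporal_of(sub)
        dists = _bin_distributions(temporal)
        times, hs = [], []
        for s, c in zip(dists, temporal.bin_centers_h()):
            if s is None:
                continue
            # compare against the control distribution of the same bin
            b = list(temporal.bin_centers_h()).index(c)
            if ctrl_main[b] is None:
                continue
            times.append(c)
            hs.append(dyn.hellinger_distance(s, ctrl_main[b]))
        status, tor, a, b_, c_ = "no_fit", dyn.NO_RESPONSE, np.nan, np.nan, np.nan
        if len(times) >= 4:
            try:
                fit = dyn.fit_tor_model(dyn.HellingerSeries(np.array(times), np.array(hs)))
                a, b_, c_ = fit.a, fit.b, fit.c
                tor = dyn.compute_tor(fit, threshold, duration_h)
                status = "ok" if isinstance(tor, float) else "no_response"
            except RuntimeError:
                status = "no_fit"
        rows.append(
            {
                "drug": drug, "concentration_uM": conc, "a": a, "b": b_, "c": c_,
                "threshold": threshold,
                "tor_h": tor if isinstance(tor, float) else np.nan,
                "status": status,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# heterogeneity stage
# --------------------------------------------------------------------------

def heterogeneity_table(
    sgr_df: pd.DataFrame, layout: PlateLayout, dr_df: pd.DataFrame
) -> pd.DataFrame:
    acc = _condition_frame(sgr_df, layout)
    rows = []
    for _, dr in dr_df.iterrows():
        g = acc[acc["drug"] == dr["drug"]]
        by_conc = {
            float(c): sub["sgr_h"].to_numpy() for c, sub in g.groupby("concentration_uM")
        }
        max_conc = max(by_conc)
        sd_max = float(np.std(by_conc[max_conc], ddof=1)) if len(by_conc[max_conc]) > 1 else 0.0
        if dr["responded"]:
            c_near, sd_ec50 = sd_at_ec50(by_conc, float(dr["ec50_uM"]))
        else:
            c_near, sd_ec50 = np.nan, np.nan
        rows.append(
            {
                "drug": dr["drug"], "sd_at_ec50": sd_ec50, "conc_at_ec50_uM": c_near,
                "sd_at_max_dose": sd_max, "max_dose_uM": max_conc,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def run_pipeline(
    tracks_df: pd.DataFrame,
    layout: PlateLayout,
    out_dir: str | Path | None = None,
    duration_h: float = 72.0,
    frame_interval_min: float = 20.0,
    params: TrackFilterParams | None = None,
    compute_tor_stage: bool = True,
) -> PipelineResult:
    """Run tracks -> SGR -> dose response -> ToR -> heterogeneity.

    When ``out_dir`` is given, writes sgr.csv, dose_response.csv, tor.csv,
    heterogeneity.csv and summary.json.
    """
    params = params or TrackFilterParams()
    sgr_df, counts = sgr_table(tracks_df, params)
    dr_df = dose_response_table(sgr_df, layout)
    if compute_tor_stage:
        tor_df = tor_table(tracks_df, layout, duration_h, frame_interval_min, params)
    else:
        tor_df = pd.DataFrame()
    het_df = heterogeneity_table(sgr_df, layout, dr_df)
    result = PipelineResult(sgr_df, dr_df, tor_df, het_df, counts)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sgr_df.to_csv(out / "sgr.csv", index=False)
        dr_df.to_csv(out / "dose_response.csv", index=False)
        tor_df.to_csv(out / "tor.csv", index=False)
        het_df.to_csv(out / "heterogeneity.csv", index=False)
        (out / "summary.json").write_text(json.dumps({"filter_counts": counts}, indent=2))
    return result
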