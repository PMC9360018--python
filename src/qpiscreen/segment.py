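"""Cell segmentation, background correction, dry mass, and frame linking.

Phase maps are segmented with a gradient-magnitude (Sobel) edge detector
followed by morphological cleanup, optionally split with a watershed for
single-cell lines.  The background is flattened by removing a 2D
polynomial surface fitted to non-cell pixels and a rolling-ball background.
Dry mass follows from the integrated phase through the specific refractive
increment alpha:

    m = (lambda / 2 pi) * sum(phi) * A_pixel / alpha      [pg]

Objects are linked frame to frame by greedy minimization of a combined
position/mass cost, yielding mass-versus-time tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import feature, filters, morphology, segmentation

from .optics import DEFAULT_ALPHA_UM3_PER_PG, OpticalConfig, PhaseImage

__all__ = [
    "SegmentationParams",
    "CellObservation",
    "CellTrack",
    "segment_cells",
    "correct_background",
    "compute_mass",
    "measure_observations",
    "link_tracks",
    "tracks_to_dataframe",
    "dataframe_to_tracks",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Segmentation and background-correction parameters."""

    background_poly_order: int = 8
    rolling_ball_radius: int = 100
    use_watershed: bool = False
    min_object_area_px: int = 30
    edge_sigma: float = 1.0          # pre-smoothing before the Sobel filter
    closing_radius: int = 2
    watershed_min_distance: int = 8

    def __post_init__(self) -> None:
        if self.background_poly_order < 0:
            raise ValueError("polynomial order must be >= 0")
        if self.rolling_ball_radius <= 0:
            raise ValueError("rolling-ball radius must be positive")


@dataclass
class CellObservation:
    frame_index: int
    time_h: float
    label: int
    centroid_xy: tuple[float, float]
    area_um2: float
    mass_pg: float
    mean_phase: float

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("observation area must be positive")
        if not np.isfinite(self.mass_pg):
            raise ValueError("observation mass must be finite")


@dataclass
class CellTrack:
    track_id: int
    observations: list[CellObservation] = field(default_factory=list)
    well: str = ""
    location_id: str = ""

    @property
    def times(self) -> np.ndarray:
        return np.array([o.time_h for o in self.observations])

    @property
    def masses(self) -> np.ndarray:
        return np.array([o.mass_pg for o in self.observations])

    def append(self, obs: CellObservation) -> None:
        if self.observations and obs.time_h <= self.observations[-1].time_h:
            raise ValueError("track times must be strictly increasing")
        self.observations.append(obs)


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------

def segment_cells(phase: PhaseImage, params: SegmentationParams | None = None) -> np.ndarray:
    """Label cells in a phase map; background = 0.

    Sobel gradient magnitude -> Otsu threshold -> morphological closing and
    hole filling -> small-object removal; when ``use_watershed`` is set the
    mask is split at distance-transform maxima (single-cell lines).
    """
    params = params or SegmentationParams()
    img = phase.phase
    if img.size == 0 or np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=int)
    smooth = filters.gaussian(img, sigma=params.edge_sigma, preserve_range=True)
    grad = filters.sobel(smooth)
    if np.ptp(grad) == 0:
        return np.zeros(img.shape, dtype=int)
    thresh = filters.threshold_otsu(grad)
    mask = grad > thresh
    if params.closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(params.closing_radius))
    mask = ndi.binary_fill_holes(mask)
    mask = _refine_by_intensity(img, mask)
    mask = morphology.remove_small_objects(mask, min_size=params.min_object_area_px)
    if not params.use_watershed:
        return ndi.label(mask)[0]
    distance = ndi.distance_transform_edt(mask)
    coords = feature.peak_local_max(
        distance, min_distance=params.watershed_min_distance, labels=mask
    )
    markers = np.zeros(img.shape, dtype=int)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        return ndi.label(mask)[0]
    labels = segmentation.watershed(-distance, markers, mask=mask)
    return morphology.remove_small_objects(labels, min_size=params.min_object_area_px)


def _refine_by_intensity(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Tighten each edge-derived object with an Otsu cut on its own phase
    values (the filled edge band overshoots the true object boundary)."""
    labels, n = ndi.label(mask)
    out = np.zeros_like(mask)
    for lab in range(1, n + 1):
        region = labels == lab
        vals = img[region]
        if np.ptp(vals) == 0:
            out |= region
            continue
        t = filters.threshold_otsu(vals)
        out |= region & (img > t)
    return out


def _poly_terms(order: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(order + 1) for j in range(order + 1 - i)]


def correct_background(
    phase: PhaseImage, mask: np.ndarray | None = None, params: SegmentationParams | None = None
) -> PhaseImage:
    """Flatten the background of a phase map.

    Fits a 2D polynomial of total degree ``background_poly_order`` to the
    non-cell pixels only (coordinates rescaled to [-1, 1] for conditioning)
    and subtracts it everywhere, then subtracts a rolling-ball background
    (disk radius ``rolling_ball_radius``) and re-centres so the median of
    the background pixels is zero.  If too few background pixels are
    available for the requested order, the order is lowered with a warning.
    """
    params = params or SegmentationParams()
    img = phase.phase.astype(float)
    bg = np.ones(img.shape, dtype=bool) if mask is None else np.asarray(mask) == 0

    order = params.background_poly_order
    n_bg = int(bg.sum())
    while order > 0 and n_bg < len(_poly_terms(order)):
        order -= 1
        warnings.warn(
            f"too few background pixels for degree {params.background_poly_order}; "
            f"falling back to degree {order}",
            stacklevel=2,
        )
    yy, xx = np.indices(img.shape)
    xn = 2 * xx / max(img.shape[1] - 1, 1) - 1
    yn = 2 * yy / max(img.shape[0] - 1, 1) - 1
    terms = _poly_terms(order)
    if n_bg >= len(terms):
        A = np.column_stack([(xn[bg] ** i) * (yn[bg] ** j) for i, j in terms])
        coef, *_ = np.linalg.lstsq(A, img[bg], rcond=None)
        surface = sum(
            c * xn**i * yn**j for c, (i, j) in zip(coef, terms)
        )
        out = img - surface
    else:
        warnings.warn("no background pixels; polynomial correction skipped", stacklevel=2)
        out = img.copy()

    # flat-disk grayscale opening: the rolling-ball background with a disk
    # structuring element (cells narrower than the disk are excluded from
    # the background estimate)
    footprint = morphology.disk(params.rolling_ball_radius)
    background = morphology.opening(out, footprint)
    out = out - background
    if n_bg > 0:
        out = out - np.median(out[bg])
    return PhaseImage(out, phase.pixel_size_um, phase.timestamp, phase.location_id)


# --------------------------------------------------------------------------
# mass
# --------------------------------------------------------------------------

def compute_mass(
    phase: PhaseImage,
    region_mask: np.ndarray | None = None,
    config: OpticalConfig | None = None,
    alpha_um3_per_pg: float = DEFAULT_ALPHA_UM3_PER_PG,
) -> float:
    """Dry mass (pg) of a region: m = (lambda/2pi) * sum(phi) * A_pixel / alpha.

    Additive over disjoint regions.  A negative total (debris, noise) is
    allowed but flagged with a warning.
    """
    if alpha_um3_per_pg <= 0:
        raise ValueError("specific refractive increment must be positive")
    cfg = config or OpticalConfig()
    phi = phase.phase if region_mask is None else phase.phase[np.asarray(region_mask, bool)]
    mass = (cfg.wavelength_um / (2 * np.pi)) * float(phi.sum()) * phase.pixel_area_um2 / alpha_um3_per_pg
    if mass < 0:
        warnings.warn(f"negative mass {mass:.3g} pg (debris or noise?)", stacklevel=2)
    return mass


def measure_observations(
    phase: PhaseImage,
    labels: np.ndarray,
    frame_index: int,
    time_h: float,
    config: OpticalConfig | None = None,
    alpha_um3_per_pg: float = DEFAULT_ALPHA_UM3_PER_PG,
) -> list[CellObservation]:
    """Per-label observations (centroid, area, mass) for one frame."""
    cfg = config or OpticalConfig()
    out = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        m = labels == lab
        area_px = int(m.sum())
        ys, xs = np.nonzero(m)
        phi_sum = float(phase.phase[m].sum())
        mass = (cfg.wavelength_um / (2 * np.pi)) * phi_sum * phase.pixel_area_um2 / alpha_um3_per_pg
        out.append(
            CellObservation(
                frame_index=frame_index,
                time_h=time_h,
                label=int(lab),
                centroid_xy=(float(xs.mean()), float(ys.mean())),
                area_um2=area_px * phase.pixel_area_um2,
                mass_pg=mass,
                mean_phase=phi_sum / area_px,
            )
        )
    return out


# --------------------------------------------------------------------------
# frame-to-frame linking
# --------------------------------------------------------------------------

def _frame_scales(obs: list[CellObservation]) -> tuple[float, float]:
    """(position_scale, mass_scale): 2x median NN spacing, median mass."""
    masses = np.array([abs(o.mass_pg) for o in obs])
    mass_scale = float(np.median(masses)) or 1.0
    if len(obs) < 2:
        return 100.0, mass_scale
    pts = np.array([o.centroid_xy for o in obs])
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    pos_scale = 2.0 * float(np.median(d.min(axis=1))) or 100.0
    return pos_scale, mass_scale


def link_tracks(
    frames: list[list[CellObservation]],
    well: str = "",
    location_id: str = "",
    max_cost: float = 4.0,
) -> list[CellTrack]:
    """Greedy nearest-neighbour linking on combined position/mass cost.

    cost = (d_position / position_scale)^2 + (d_mass / mass_scale)^2 with
    per-frame scales (2x median nearest-neighbour spacing; median object
    mass).  Candidate links are taken lowest cost first (ties broken by
    lowest label); links costing more than ``max_cost`` are refused.
    Unmatched objects start new tracks; unmatched tracks end.  Deterministic
    for identical input.
    """
    tracks: list[CellTrack] = []
    active: dict[int, CellTrack] = {}
    next_id = 0
    for obs in frames:
        if not obs:
            active = {}
            continue
        pos_scale, mass_scale = _frame_scales(obs)
        candidates = []
        for tid, tr in active.items():
            last = tr.observations[-1]
            for j, o in enumerate(obs):
                dp = np.hypot(
                    o.centroid_xy[0] - last.centroid_xy[0],
                    o.centroid_xy[1] - last.centroid_xy[1],
                )
                dm = o.mass_pg - last.mass_pg
                cost = (dp / pos_scale) ** 2 + (dm / mass_scale) ** 2
                if cost <= max_cost:
                    candidates.append((cost, o.label, tid, j))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        used_tracks: set[int] = set()
        used_obs: set[int] = set()
        new_active: dict[int, CellTrack] = {}
        for cost, _, tid, j in candidates:
            if tid in used_tracks or j in used_obs:
                continue
            active[tid].append(obs[j])
            new_active[tid] = active[tid]
            used_tracks.add(tid)
            used_obs.add(j)
        for j, o in enumerate(obs):
            if j in used_obs:
                continue
            tr = CellTrack(next_id, [o], well, location_id)
            tracks.append(tr)
            new_active[next_id] = tr
            next_id += 1
        active = new_active
    # tracks list currently only holds those started here; all tracks were
    # started here, so it is complete
    return tracks


# --------------------------------------------------------------------------
# tabular I/O
# --------------------------------------------------------------------------

TRACK_COLUMNS = [
    "track_id", "well", "location", "frame", "time_h", "x", "y", "area_um2", "mass_pg",
]


def tracks_to_dataframe(tracks: list[CellTrack]) -> pd.DataFrame:
    rows = [
        {
            "track_id": t.track_id,
            "well": t.well,
            "location": t.location_id,
            "frame": o.frame_index,
            "time_h": o.time_h,
            "x": o.centroid_xy[0],
            "y": o.centroid_xy[1],
            "area_um2": o.area_um2,
            "mass_pg": o.mass_pg,
        }
        for t in tracks
        for o in t.observations
    ]
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def dataframe_to_tracks(df: pd.DataFrame) -> list[CellTrack]:
    tracks = []
    for (tid, well, loc), g in df.groupby(["track_id", "well", "location"], sort=True):
        g = g.sort_values("time_h")
        tr = CellTrack(int(tid), [], str(well), str(loc))
        for _, r in g.iterrows():
            tr.append(
                CellObservation(
                    frame_index=int(r["frame"]),
                    time_h=float(r["time_h"]),
                    label=int(tid),
                    centroid_xy=(float(r["x"]), float(r["y"])),
                    area_um2=float(r["area_um2"]),
                    mass_pg=float(r["mass_pg"]),
                    mean_phase=0.0,
                )
            )
        tracks.append(tr)
    return tracks
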