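"""Differential phase contrast (DPC) optics: forward model and phase retrieval.

A DPC microscope records four bright-field images under half-circle LED
illumination (top, bottom, left, right).  For a weakly scattering (small
phase) specimen the normalized difference of each opposing pair,

    g = (I1 - I2) / (I1 + I2),

is linearly related to the specimen phase through a weak-object transfer
function (WOTF) determined by the source shape and the objective pupil.
The phase map is recovered by Tikhonov-regularized deconvolution over the
two orthogonal illumination axes:

    phi = IFT[ sum_j conj(H_j) FT(g_j) / (sum_j |H_j|^2 + beta) ]

This module implements the transfer-function construction (discrete
source-pupil overlap sum over the physical LED grid), the forward
simulator used for fixtures and calibration, the Tikhonov inversion,
LED-alignment checking, and refractive-index calibration with spherical
beads of known geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "OpticalConfig",
    "DPCFrameSet",
    "PhaseImage",
    "BeadCalibrationResult",
    "AlignmentReport",
    "check_led_alignment",
    "compute_phase_gradient",
    "build_phase_transfer_function",
    "tikhonov_reconstruct",
    "simulate_dpc_frames",
    "reconstruct_frameset",
    "bead_phantom",
    "calibrate_with_beads",
    "read_frame_tiff",
    "write_phase_tiff",
    "read_phase_tiff",
]


# --------------------------------------------------------------------------
# configuration and containers
# --------------------------------------------------------------------------

#: specific refractive increment, um^3/pg (1.8e-4 m^3/kg)
DEFAULT_ALPHA_UM3_PER_PG = 0.18


@dataclass(frozen=True)
class OpticalConfig:
    """Optical parameters of the DPC microscope.

    Lengths are in micrometres.  ``coherence_sigma`` is the ratio of
    illumination to objective NA; for the default apertures it is 1.56
    (partially coherent regime, sigma > 1).
    """

    wavelength_um: float = 0.624
    na_objective: float = 0.25
    na_illumination: float = 0.39
    pixel_size_um: float = 0.54
    regularization_beta: float = 1e-3
    illumination_axes: tuple[float, float] = (90.0, 180.0)
    # LED array geometry used to discretize the half-circle source
    led_grid_n: int = 8
    led_extent_mm: float = 18.0
    led_height_mm: float = 24.0

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0:
            raise ValueError("wavelength must be positive")
        if not (0 < self.na_objective <= self.na_illumination):
            raise ValueError("require 0 < NA_objective <= NA_illumination")
        if self.regularization_beta <= 0:
            raise ValueError("regularization beta must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def coherence_sigma(self) -> float:
        return self.na_illumination / self.na_objective

    @property
    def cutoff_frequency(self) -> float:
        """Partially coherent lateral cutoff, cycles/um."""
        return (self.na_objective + self.na_illumination) / self.wavelength_um


HALF_NAMES = ("top", "bottom", "left", "right")


@dataclass
class DPCFrameSet:
    """Four raw intensity frames under half-circle illumination."""

    top: np.ndarray
    bottom: np.ndarray
    left: np.ndarray
    right: np.ndarray
    timestamp: float = 0.0
    location_id: str = ""

    def __post_init__(self) -> None:
        shapes = {np.asarray(getattr(self, n)).shape for n in HALF_NAMES}
        if len(shapes) != 1:
            raise ValueError(f"frame shapes differ: {shapes}")
        for n in HALF_NAMES:
            a = np.asarray(getattr(self, n), dtype=float)
            if (a < 0).any():
                raise ValueError(f"negative intensities in {n} frame")
            setattr(self, n, a)

    @property
    def shape(self) -> tuple[int, int]:
        return self.top.shape

    def pair(self, axis_deg: float) -> tuple[np.ndarray, np.ndarray]:
        """Opposing pair for a DPC axis: 90 deg -> (top, bottom), 180 -> (left, right)."""
        if axis_deg == 90:
            return self.top, self.bottom
        if axis_deg == 180:
            return self.left, self.right
        raise ValueError(f"unsupported DPC axis {axis_deg!r}; expected 90 or 180")


@dataclass
class PhaseImage:
    """Reconstructed optical phase map in radians with physical pixel size."""

    phase: np.ndarray
    pixel_size_um: float
    timestamp: float = 0.0
    location_id: str = ""

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if not np.isfinite(self.phase).all():
            raise ValueError("phase image contains non-finite values")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2


@dataclass
class AlignmentReport:
    half_means: dict[str, float]
    deviations: dict[str, float]
    tolerance: float
    aligned: bool


@dataclass
class BeadCalibrationResult:
    mean_refractive_index: float
    per_bead_indices: list[float]
    medium_index: float
    reference_index: float = 1.583
    temporal_cv: float | None = None


# --------------------------------------------------------------------------
# LED alignment check
# --------------------------------------------------------------------------

def check_led_alignment(frames: DPCFrameSet, tolerance: float = 0.05) -> AlignmentReport:
    """Compare mean intensity of the four half-circle frames of an empty field.

    Each half's deviation is reported relative to the grand mean of the four
    halves; the array is flagged misaligned when any deviation exceeds
    ``tolerance`` (default 5%).
    """
    means = {n: float(np.mean(getattr(frames, n))) for n in HALF_NAMES}
    grand = float(np.mean(list(means.values())))
    if grand <= 0 or any(m <= 0 for m in means.values()):
        raise ValueError("invalid acquisition: zero-intensity frame in alignment check")
    deviations = {n: abs(m - grand) / grand for n, m in means.items()}
    aligned = all(d <= tolerance for d in deviations.values())
    return AlignmentReport(means, deviations, tolerance, aligned)


# --------------------------------------------------------------------------
# DPC signal and transfer functions
# --------------------------------------------------------------------------

def compute_phase_gradient(frame1: np.ndarray, frame2: np.ndarray) -> np.ndarray:
    """Normalized opposing-pair difference (I1 - I2)/(I1 + I2), in [-1, 1].

    Pixels where the sum vanishes are guarded with a machine-epsilon floor
    and a warning.
    """
    a = np.asarray(frame1, dtype=float)
    b = np.asarray(frame2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    s = a + b
    if (s <= 0).any():
        warnings.warn("zero-sum pixels in DPC pair; applying epsilon floor", stacklevel=2)
        s = np.maximum(s, np.finfo(float).tiny)
    return (a - b) / s


def _led_source_frequencies(config: OpticalConfig) -> tuple[np.ndarray, np.ndarray]:
    """Spatial frequencies (cycles/um) of the discrete LED positions.

    The LED board is an n x n grid of total extent ``led_extent_mm`` placed
    ``led_height_mm`` above the sample; each LED illuminates at the angle
    set by its geometric position.
    """
    n = config.led_grid_n
    pitch = config.led_extent_mm / n
    coords = (np.arange(n) - (n - 1) / 2.0) * pitch
    x, y = np.meshgrid(coords, coords, indexing="xy")
    h = config.led_height_mm
    r = np.sqrt(x**2 + y**2 + h**2)
    # direction sines -> illumination spatial frequency
    ux = (x / r) / config.wavelength_um
    uy = (y / r) / config.wavelength_um
    return ux.ravel(), uy.ravel()


def _half_wotf(
    config: OpticalConfig,
    shape: tuple[int, int],
    select: np.ndarray,
    ux: np.ndarray,
    uy: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Weak-object phase transfer function of one half-circle source.

    The source is the union of the selected LEDs, each occupying a patch of
    half the LED pitch in frequency space (LEDs are extended emitters, not
    ideal points), sampled on the image frequency grid.  The overlap
    integral G(u) = sum_{u'} S(u') P(u') P(u' + u) is evaluated by FFT
    cross-correlation and H(u) = i * [G(u) - G(-u)].  Only bright-field
    source samples (inside the pupil) contribute at first order; dark-field
    LEDs only add background.  Returns (H, B) with B the DC background.
    """
    fy = np.fft.fftfreq(shape[0], d=config.pixel_size_um)
    fx = np.fft.fftfreq(shape[1], d=config.pixel_size_um)
    UY, UX = np.meshgrid(fy, fx, indexing="ij")
    na_cut2 = (config.na_objective / config.wavelength_um) ** 2
    P = (UX**2 + UY**2 <= na_cut2).astype(float)

    # frequency-space radius of one LED patch: half the angular pitch
    pitch_mm = config.led_extent_mm / config.led_grid_n
    patch_r = 0.5 * (pitch_mm / config.led_height_mm) / config.wavelength_um
    S = np.zeros(shape, dtype=bool)
    for sx, sy in zip(ux[select], uy[select]):
        S |= (UX - sx) ** 2 + (UY - sy) ** 2 <= patch_r**2
    A = S * P  # bright-field part of the source
    B = float(A.sum())
    if B == 0:
        return np.zeros(shape, dtype=complex), 0.0
    # periodic cross-correlation equals the linear one because the pupil
    # support (radius NA_obj/lambda) fits twice inside the Nyquist cell
    G = np.fft.ifft2(np.conj(np.fft.fft2(A)) * np.fft.fft2(P)).real
    idx0 = (-np.arange(shape[0])) % shape[0]
    idx1 = (-np.arange(shape[1])) % shape[1]
    Gm = G[np.ix_(idx0, idx1)]
    H = 1j * (G - Gm)
    return H, B


def build_phase_transfer_function(
    config: OpticalConfig, axis_deg: float, shape: tuple[int, int]
) -> np.ndarray:
    """WOTF relating specimen phase to the normalized DPC difference image.

    ``axis_deg`` selects the split direction: 90 -> top/bottom halves
    (vertical gradient), 180 -> left/right halves (horizontal gradient).
    The returned array is on the ``np.fft.fftfreq`` grid, purely imaginary,
    antisymmetric under frequency inversion, zero at DC and beyond the
    partially coherent cutoff, and scaled to unit maximum magnitude so the
    Tikhonov constant beta is comparable across image sizes.
    """
    ux, uy = _led_source_frequencies(config)
    if axis_deg == 90:
        pos, neg = uy > 0, uy < 0
    elif axis_deg == 180:
        pos, neg = ux < 0, ux > 0  # left half illuminates with negative ux
    else:
        raise ValueError(f"unsupported DPC axis {axis_deg!r}; expected 90 or 180")

    H1, B1 = _half_wotf(config, shape, pos, ux, uy)
    H2, B2 = _half_wotf(config, shape, neg, ux, uy)
    if B1 + B2 == 0:
        raise ValueError("no bright-field LEDs inside the pupil; check geometry")
    H = (H1 - H2) / (B1 + B2)
    # clip FFT round-off outside the physical support
    fy = np.fft.fftfreq(shape[0], d=config.pixel_size_um)
    fx = np.fft.fftfreq(shape[1], d=config.pixel_size_um)
    UY, UX = np.meshgrid(fy, fx, indexing="ij")
    H[UX**2 + UY**2 > config.cutoff_frequency**2] = 0.0
    m = np.abs(H).max()
    if m > 0:
        H = H / m
    return H


def tikhonov_reconstruct(
    gradients: Sequence[np.ndarray],
    transfer_functions: Sequence[np.ndarray],
    beta: float = 1e-3,
    pixel_size_um: float = 0.54,
    timestamp: float = 0.0,
    location_id: str = "",
) -> PhaseImage:
    """Invert the linear DPC model by Tikhonov-regularized deconvolution.

    phi = IFT[ sum_j conj(H_j) FT(g_j) / (sum_j |H_j|^2 + beta) ].
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if len(gradients) == 0 or len(gradients) != len(transfer_functions):
        raise ValueError("need >= 1 matched gradient/transfer-function pair")
    shape = np.asarray(gradients[0]).shape
    num = np.zeros(shape, dtype=complex)
    den = np.full(shape, float(beta), dtype=float)
    for g, H in zip(gradients, transfer_functions):
        g = np.asarray(g, dtype=float)
        if g.shape != shape or H.shape != shape:
            raise ValueError("gradient/transfer-function shape mismatch")
        num += np.conj(H) * np.fft.fft2(g)
        den += np.abs(H) ** 2
    phi_c = np.fft.ifft2(num / den)
    scale = np.abs(phi_c).max()
    if scale > 0 and np.abs(phi_c.imag).max() > 1e-6 * scale:
        warnings.warn("imaginary residue above tolerance after inverse FT", stacklevel=2)
    return PhaseImage(phi_c.real, pixel_size_um, timestamp, location_id)


def reconstruct_frameset(frames: DPCFrameSet, config: OpticalConfig) -> PhaseImage:
    """Full pipeline for one frame set: pair differences -> Tikhonov phase."""
    grads, tfs = [], []
    for axis in config.illumination_axes:
        a, b = frames.pair(axis)
        grads.append(compute_phase_gradient(a, b))
        tfs.append(build_phase_transfer_function(config, axis, frames.shape))
    return tikhonov_reconstruct(
        grads, tfs, config.regularization_beta, config.pixel_size_um,
        frames.timestamp, frames.location_id,
    )


# --------------------------------------------------------------------------
# forward model (fixture generator)
# --------------------------------------------------------------------------

def simulate_dpc_frames(
    phantom: PhaseImage,
    config: OpticalConfig,
    noise_level: float = 0.0,
    seed: int | None = None,
    background: float = 1.0,
) -> DPCFrameSet:
    """Forward-simulate the four half-circle frames of a weak phase object.

    Uses the same linearized weak-object model the reconstruction inverts:
    for each axis the normalized opposing-pair difference equals the
    real-space response of that axis's transfer function applied to the
    phase.  Optional multiplicative Gaussian noise with relative sigma
    ``noise_level``; deterministic for a fixed seed.
    """
    phi = np.asarray(phantom.phase, dtype=float)
    Ft = np.fft.fft2(phi)
    rng = np.random.default_rng(seed)
    halves = {}
    for axis, (n1, n2) in zip(config.illumination_axes, (("top", "bottom"), ("left", "right"))):
        H = build_phase_transfer_function(config, axis, phi.shape)
        s = np.fft.ifft2(H * Ft).real  # Hermitian product -> real
        halves[n1] = background * (1.0 + s)
        halves[n2] = background * (1.0 - s)
    if noise_level > 0:
        for n in HALF_NAMES:
            halves[n] = halves[n] * (1.0 + noise_level * rng.standard_normal(phi.shape))
    for n in HALF_NAMES:
        halves[n] = np.clip(halves[n], 0.0, None)
    return DPCFrameSet(timestamp=phantom.timestamp, location_id=phantom.location_id, **halves)


# --------------------------------------------------------------------------
# bead calibration
# --------------------------------------------------------------------------

def bead_phantom(
    shape: tuple[int, int],
    centers_px: Sequence[tuple[float, float]],
    radius_um: float,
    bead_index: float = 1.583,
    medium_index: float = 1.56,
    config: OpticalConfig | None = None,
) -> PhaseImage:
    """Phase map of spherical beads: phi = (2 pi / lambda) * dn * thickness."""
    cfg = config or OpticalConfig()
    yy, xx = np.indices(shape)
    phi = np.zeros(shape, dtype=float)
    r_px = radius_um / cfg.pixel_size_um
    dn = bead_index - medium_index
    for cx, cy in centers_px:
        rho2 = (xx - cx) ** 2 + (yy - cy) ** 2
        thickness_um = 2.0 * cfg.pixel_size_um * np.sqrt(np.clip(r_px**2 - rho2, 0.0, None))
        phi += (2 * np.pi / cfg.wavelength_um) * dn * thickness_um
    return PhaseImage(phi, cfg.pixel_size_um)


def calibrate_with_beads(
    phase: PhaseImage | Sequence[PhaseImage],
    centers_px: Sequence[tuple[float, float]],
    radius_um: float,
    medium_index: float = 1.56,
    config: OpticalConfig | None = None,
    mask_margin: float = 1.2,
    background_annulus: tuple[float, float] | None = (2.5, 3.5),
    reference_index: float = 1.583,
) -> BeadCalibrationResult:
    """Recover the refractive index of spherical beads from integrated phase.

    For each bead, n = n_medium + (lambda / 2 pi) * sum(phi) * A_pixel / V,
    with V = (4/3) pi r^3 and the sum over a disk of ``mask_margin`` times
    the bead radius.  Before integration the local background level --
    the median phase in an annulus of ``background_annulus`` bead radii --
    is subtracted, which removes the smooth residual halo the regularized
    deconvolution leaves around compact objects (pass ``None`` to skip).
    Beads whose outer annulus touches the image border are excluded with a
    warning.  Given repeated phase images of the same field, the temporal
    coefficient of variation of the per-frame mean index is also reported.
    """
    images = [phase] if isinstance(phase, PhaseImage) else list(phase)
    cfg = config or OpticalConfig()
    if radius_um <= 0:
        raise ValueError("bead volume is zero")
    volume_um3 = (4.0 / 3.0) * np.pi * radius_um**3
    per_frame_means: list[float] = []
    first_frame_indices: list[float] = []
    for k, img in enumerate(images):
        phi = img.phase
        yy, xx = np.indices(phi.shape)
        r_px = radius_um / img.pixel_size_um
        outer = max(mask_margin, background_annulus[1] if background_annulus else 0.0) * r_px
        indices = []
        for cx, cy in centers_px:
            if (
                cx - outer < 0 or cy - outer < 0
                or cx + outer > phi.shape[1] - 1 or cy + outer > phi.shape[0] - 1
            ):
                warnings.warn(f"bead at ({cx}, {cy}) touches the border; excluded", stacklevel=2)
                continue
            rho2 = (xx - cx) ** 2 + (yy - cy) ** 2
            level = 0.0
            if background_annulus is not None:
                a_in, a_out = background_annulus
                ann = (rho2 > (a_in * r_px) ** 2) & (rho2 <= (a_out * r_px) ** 2)
                level = float(np.median(phi[ann]))
            mask = rho2 <= (mask_margin * r_px) ** 2
            integral = float((phi[mask] - level).sum()) * img.pixel_area_um2
            n = medium_index + (cfg.wavelength_um / (2 * np.pi)) * integral / volume_um3
            indices.append(n)
        if not indices:
            raise ValueError("no beads available for calibration (all excluded)")
        per_frame_means.append(float(np.mean(indices)))
        if k == 0:
            first_frame_indices = indices
    cv = None
    if len(per_frame_means) > 1:
        cv = float(np.std(per_frame_means, ddof=1) / np.mean(per_frame_means))
    return BeadCalibrationResult(
        mean_refractive_index=float(np.mean(per_frame_means)),
        per_bead_indices=first_frame_indices,
        medium_index=medium_index,
        reference_index=reference_index,
        temporal_cv=cv,
    )


# --------------------------------------------------------------------------
# TIFF I/O
# --------------------------------------------------------------------------

def read_frame_tiff(path: str | Path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(str(path)), dtype=float)


def write_phase_tiff(path: str | Path, phase: PhaseImage) -> None:
    import tifffile

    tifffile.imwrite(str(path), phase.phase.astype(np.float32))


def read_phase_tiff(path: str | Path, pixel_size_um: float = 0.54) -> PhaseImage:
    return PhaseImage(read_frame_tiff(path), pixel_size_um)
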