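"""Bulk acoustic properties: surface times, thickness, sound speed,
attenuation, and construct volume from serial B-mode contours.

Thickness and sound speed come from the substitution method: round-trip times
to the specimen's top and bottom surfaces and to a gel-pad reflector with and
without the specimen,

    L   = c_f * [(t_ref - t_gel) + (t_bot - t_top)] / 2
    c_t = 2 L / (t_bot - t_top)
        = c_f * [(t_ref - t_gel) + (t_bot - t_top)] / (t_bot - t_top)

with c_f the fluid sound speed.  Both identities 2L/c_t = t_bot - t_top and
2L/c_f = (t_ref - t_gel) + (t_bot - t_top) hold by construction.

The frequency-dependent attenuation follows from the insertion loss of the
gel-pad echo,

    alpha(f) [dB/cm] = 20 log10(|A0(f)| / |A(f)|) / (2 L)

(|A| and |A0| the gel-pad echo magnitudes with and without specimen, 2L the
round-trip path through it in cm); its slope over a linear fit between
20-55 MHz is the attenuation coefficient in dB/(cm MHz).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .rf import BModeImage, MediumSpec, RFVolume, envelope

log = logging.getLogger(__name__)

__all__ = [
    "EchoTimes",
    "SurfaceMap",
    "BulkProperties",
    "ConstructVolumeEstimate",
    "detect_surfaces",
    "thickness_and_speed",
    "attenuation_coefficient",
    "construct_volume",
    "bulk_properties",
]


@dataclass(frozen=True)
class EchoTimes:
    """Round-trip times (s) to specimen top/bottom and gel pad (with/without)."""

    t_top: float
    t_bot: float
    t_gel: float
    t_ref: float

    def __post_init__(self) -> None:
        if min(self.t_top, self.t_bot, self.t_gel, self.t_ref) <= 0:
            raise ValueError("echo times must be positive")
        if not (self.t_top < self.t_bot < self.t_gel):
            raise ValueError("expected t_top < t_bot < t_gel with a specimen present")


@dataclass
class SurfaceMap:
    """Per-A-line surface times with a validity mask; medians aggregate."""

    t_top: np.ndarray  # (n_lines, n_slices)
    t_bot: np.ndarray
    t_gel: np.ndarray
    t_ref: np.ndarray
    valid: np.ndarray  # bool

    def median(self) -> EchoTimes:
        if not self.valid.any():
            raise ValueError("no A-line produced a valid surface detection")
        m = self.valid
        return EchoTimes(
            t_top=float(np.median(self.t_top[m])),
            t_bot=float(np.median(self.t_bot[m])),
            t_gel=float(np.median(self.t_gel[m])),
            t_ref=float(np.median(self.t_ref[m])),
        )


@dataclass
class BulkProperties:
    """Thickness, sound speed and attenuation of one specimen."""

    thickness_mm: float
    speed_of_sound: float  # m/s
    attenuation_coeff: float  # dB/(cm MHz)
    attenuation_band: tuple[float, float] = (20.0, 55.0)
    fit_r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("thickness must be positive")
        if not 1300.0 <= self.speed_of_sound <= 1700.0:
            log.warning(
                "speed of sound %.0f m/s outside the [1300, 1700] sanity band",
                self.speed_of_sound,
            )
        if self.attenuation_coeff < 0:
            log.warning(
                "fitted attenuation coefficient %.3f dB/(cm MHz) is negative",
                self.attenuation_coeff,
            )


@dataclass
class ConstructVolumeEstimate:
    """Serial-contour volume estimate: per-slice areas times slice spacing."""

    contours: list  # per-slice (N, 2) arrays in (lateral_mm, depth_mm), or None
    areas_mm2: np.ndarray
    slice_spacing_um: float
    volume_mm3: float


# ---------------------------------------------------------------------------
# surface detection


def _subsample_peak(env: np.ndarray, idx: int) -> float:
    """Parabolic refinement of an envelope peak position (in samples)."""
    if idx <= 0 or idx >= env.size - 1:
        return float(idx)
    y0, y1, y2 = env[idx - 1], env[idx], env[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(idx)
    return idx + 0.5 * (y0 - y2) / denom


def detect_surfaces(
    volume: RFVolume,
    reference: RFVolume,
    threshold_db: float = -18.0,
    min_separation_s: float = 0.12e-6,
) -> SurfaceMap:
    """Locate top/bottom/gel-pad echoes on every A-line by envelope peaks.

    Echo candidates are envelope peaks above ``threshold_db`` (relative to the
    per-line maximum) separated by at least ``min_separation_s``.  The first
    candidate is the top surface, the last the gel pad, and the strongest
    candidate in between the bottom surface; the reference line's single
    candidate gives t_ref.  Surface times are refined to sub-sample precision
    by parabolic interpolation of the envelope.  Lines without three distinct
    echoes are flagged invalid and excluded from the aggregate.
    """
    if volume.grid.shape[1:] != reference.grid.shape[1:]:
        raise ValueError("sample and reference scans must share their grid")
    dt = volume.grid.axial_dt
    dist = max(1, int(round(min_separation_s / dt)))
    n_lines, n_slices = volume.grid.n_lines, volume.grid.n_slices
    shape = (n_lines, n_slices)
    t_top = np.full(shape, np.nan)
    t_bot = np.full(shape, np.nan)
    t_gel = np.full(shape, np.nan)
    t_ref = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    for k in range(n_slices):
        env_s = envelope(volume.slice(k))
        env_r = envelope(reference.slice(k))
        for i in range(n_lines):
            es = env_s[:, i]
            height = es.max() * 10.0 ** (threshold_db / 20.0)
            peaks, props = find_peaks(es, height=height, distance=dist)
            er = env_r[:, i]
            r_height = er.max() * 10.0 ** (threshold_db / 20.0)
            r_peaks, r_props = find_peaks(er, height=r_height, distance=dist)
            if r_peaks.size >= 1:
                j = r_peaks[int(np.argmax(r_props["peak_heights"]))]
                t_ref[i, k] = _subsample_peak(er, j) * dt
            if peaks.size >= 3 and np.isfinite(t_ref[i, k]):
                top, gel = peaks[0], peaks[-1]
                interior = peaks[1:-1]
                heights = props["peak_heights"][1:-1]
                bot = interior[int(np.argmax(heights))]
                t_top[i, k] = _subsample_peak(es, top) * dt
                t_bot[i, k] = _subsample_peak(es, bot) * dt
                t_gel[i, k] = _subsample_peak(es, gel) * dt
                valid[i, k] = True
    if not valid.any():
        raise ValueError("surface detection failed on every A-line")
    return SurfaceMap(t_top=t_top, t_bot=t_bot, t_gel=t_gel, t_ref=t_ref, valid=valid)


# ---------------------------------------------------------------------------
# thickness / speed (substitution method)


def thickness_and_speed(times: EchoTimes, medium: MediumSpec) -> tuple[float, float]:
    """Thickness (mm) and sound speed (m/s) from the four echo times.

    L = c_f [(t_ref - t_gel) + (t_bot - t_top)] / 2;  c_t = 2 L / (t_bot - t_top).
    Exact (machine precision) on analytically constructed times.
    """
    if times.t_gel <= times.t_bot:
        raise ValueError("non-physical times: gel-pad echo must follow the bottom echo")
    dt_sample = times.t_bot - times.t_top
    two_l_over_cf = (times.t_ref - times.t_gel) + dt_sample
    if two_l_over_cf <= 0:
        raise ValueError("non-physical times: negative implied thickness")
    thickness_m = medium.c_fluid * two_l_over_cf / 2.0
    c_t = 2.0 * thickness_m / dt_sample
    return thickness_m * 1e3, c_t


# ---------------------------------------------------------------------------
# attenuation (insertion loss of the gel-pad echo)


def attenuation_coefficient(
    volume: RFVolume,
    reference: RFVolume,
    surfaces: SurfaceMap,
    thickness_mm: float,
    fit_band: tuple[float, float] = (20.0, 55.0),
    window_durations: float = 8.0,
    nfft: int = 512,
) -> tuple[float, dict]:
    """Attenuation coefficient (dB/(cm MHz)) from gel-pad insertion loss.

    Gel-pad echoes in the sample and reference scans are Hamming-windowed
    (length ``window_durations`` pulse durations, centred on the envelope
    peak; long relative to the echo so taper smoothing does not flatten the
    spectral ratio), power spectra are averaged across A-lines, and
    alpha(f) = 10 log10(P0/P) / (2 L_cm) is fitted linearly over ``fit_band``.
    Returns the slope plus diagnostics (per-frequency alpha, fit r^2).
    """
    if thickness_mm <= 0:
        raise ValueError("thickness must be positive")
    dt = volume.grid.axial_dt
    # pulse duration from the nominal fractional bandwidth (6 sigma_t support)
    f6 = volume.transducer.bandwidth / 2.0 * 1e6
    sigma_t = math.sqrt(0.6 * math.log(10.0)) / (2.0 * math.pi) / f6
    wlen = max(16, int(round(window_durations * 6.0 * sigma_t / dt)))
    w = np.hamming(wlen)
    half = wlen // 2

    def gel_power(vol: RFVolume, t_map: np.ndarray) -> np.ndarray:
        segs = []
        for k in range(vol.grid.n_slices):
            block = vol.slice(k)
            for i in range(vol.grid.n_lines):
                t = t_map[i, k]
                if not np.isfinite(t):
                    continue
                c = int(round(t / dt))
                lo, hi = c - half, c - half + wlen
                if lo < 0 or hi > block.shape[0]:
                    continue
                segs.append(block[lo:hi, i])
        if not segs:
            raise ValueError("no usable gel-pad echo windows")
        spec = np.fft.rfft(np.asarray(segs) * w, n=nfft, axis=-1)
        return (np.abs(spec) ** 2).mean(axis=0)

    p_sample = gel_power(volume, np.where(surfaces.valid, surfaces.t_gel, np.nan))
    p_ref = gel_power(reference, surfaces.t_ref)
    freqs = np.fft.rfftfreq(nfft, d=dt) / 1e6
    sel = (freqs >= fit_band[0]) & (freqs <= fit_band[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_f = 10.0 * np.log10(p_ref / p_sample) / (2.0 * thickness_mm / 10.0)
    f = freqs[sel]
    a = alpha_f[sel]
    slope, intercept = np.polyfit(f, a, 1)
    pred = slope * f + intercept
    ss_res = float(np.sum((a - pred) ** 2))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    diagnostics = {
        "freqs_mhz": f,
        "alpha_db_per_cm": a,
        "intercept": float(intercept),
        "r2": r2,
    }
    return float(slope), diagnostics


def bulk_properties(
    volume: RFVolume,
    reference: RFVolume,
    medium: MediumSpec = MediumSpec(),
    threshold_db: float = -18.0,
    fit_band: tuple[float, float] = (20.0, 55.0),
) -> tuple[BulkProperties, SurfaceMap]:
    """Convenience: surfaces -> (L, c_t) -> attenuation in one call."""
    surfaces = detect_surfaces(volume, reference, threshold_db=threshold_db)
    times = surfaces.median()
    thickness_mm, c_t = thickness_and_speed(times, medium)
    alpha, diag = attenuation_coefficient(volume, reference, surfaces, thickness_mm, fit_band)
    props = BulkProperties(
        thickness_mm=thickness_mm,
        speed_of_sound=c_t,
        attenuation_coeff=alpha,
        attenuation_band=fit_band,
        fit_r2=diag["r2"],
    )
    return props, surfaces


# ---------------------------------------------------------------------------
# construct volume from serial contours


def _slice_contour_area(
    image: BModeImage,
    threshold_db: float,
    max_depth_sample: int | None = None,
    fill_axial: bool = True,
) -> tuple[np.ndarray | None, float]:
    """Largest above-threshold region's boundary polygon and area (mm^2).

    With ``fill_axial`` the mask is filled per A-line between its first and
    last above-threshold pixel, so a specimen bounded by bright surface
    echoes is segmented as one solid cross-section even where the interior
    speckle is dim.  ``max_depth_sample`` crops echoes from below the
    specimen (the gel-pad reflector) before thresholding.
    """
    from skimage import measure

    mask = image.db >= -abs(threshold_db)
    if max_depth_sample is not None:
        mask[max_depth_sample:, :] = False
    if fill_axial:
        any_col = mask.any(axis=0)
        first = np.argmax(mask, axis=0)
        last = mask.shape[0] - 1 - np.argmax(mask[::-1, :], axis=0)
        rows = np.arange(mask.shape[0])[:, None]
        mask = any_col[None, :] & (rows >= first[None, :]) & (rows <= last[None, :])
    labels = measure.label(mask)
    if labels.max() == 0:
        return None, 0.0
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    largest = int(np.argmax(counts))
    region = labels == largest
    padded = np.pad(region.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return None, 0.0
    contour = max(contours, key=lambda c: c.shape[0]) - 1.0  # undo padding
    axial_mm = image.grid.axial_dt * image.medium.c_fluid / 2.0 * 1e3
    lateral_mm = image.grid.lateral_spacing * 1e-3
    poly = np.column_stack([contour[:, 1] * lateral_mm, contour[:, 0] * axial_mm])
    from shapely.geometry import Polygon

    area = Polygon(poly).buffer(0).area
    return poly, float(area)


def construct_volume(
    bmode_stack: list[BModeImage],
    threshold_db: float = 30.0,
    slice_spacing_um: float | None = None,
    max_depth_sample: int | None = None,
    fill_axial: bool = True,
    rule: str = "rectangular",
) -> ConstructVolumeEstimate:
    """Volume from threshold contours of serial B-mode slices.

    Per slice, the boundary of the largest connected region brighter than
    ``threshold_db`` below the maximum is polygonized; the volume is the
    rectangular rule, sum of areas times the slice spacing (``rule =
    "trapezoidal"`` averages adjacent areas instead).  Slices with no
    above-threshold region contribute zero area (logged).
    """
    if not bmode_stack:
        raise ValueError("need at least one B-mode slice")
    spacing = slice_spacing_um or bmode_stack[0].grid.slice_spacing
    contours = []
    areas = []
    for idx, img in enumerate(bmode_stack):
        poly, area = _slice_contour_area(img, threshold_db, max_depth_sample, fill_axial)
        if poly is None:
            log.warning("slice %d: no region above threshold, zero area recorded", idx)
        contours.append(poly)
        areas.append(area)
    areas_arr = np.asarray(areas)
    if rule == "rectangular":
        volume = float(areas_arr.sum() * spacing * 1e-3)
    elif rule == "trapezoidal":
        volume = float(np.trapezoid(areas_arr, dx=spacing * 1e-3)) if areas_arr.size > 1 else 0.0
    else:
        raise ValueError("rule must be 'rectangular' or 'trapezoidal'")
    return ConstructVolumeEstimate(
        contours=contours,
        areas_mm2=areas_arr,
        slice_spacing_um=spacing,
        volume_mm3=volume,
    )
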