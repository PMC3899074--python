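"""Calibrated spectrum analysis and scatterer-property inversion.

The estimation chain follows the classical spectrum-analysis framework for
soft-tissue backscatter (Lizzi; Insana's Gaussian form factor):

1. Windowed, Hamming-tapered power spectra of RF segments inside the sample
   are divided by the spectrum of a specular reference echo, removing the
   system/transducer response ("calibrated spectrum", in dB).
2. A straight line is regressed onto the calibrated spectrum over the -9 dB
   band of the reference: slope ``m'`` (dB/MHz) and mid-band fit ``MBF'``
   (dB, the fitted value at the band centre f_c).
3. Both are compensated for frequency-dependent attenuation of the sample:
   ``m = m' + 2*alpha*z`` and ``MBF = MBF' + 2*alpha*z*f_c`` with ``alpha`` in
   dB/(cm*MHz) and ``z`` the one-way propagation distance in the sample (cm).
4. The corrected parameters are inverted for the effective scatterer radius
   ``a``, the acoustic concentration ``CQ^2`` and — given one of the factors —
   the number concentration ``C`` or relative impedance ``Q``; an impedance
   increase between time points is converted to a deposited calcium mass.

Spectral model
--------------
For identical spherical scatterers of radius ``a`` (um) in a medium with
sound speed ``c`` (m/s), Poisson-distributed at number concentration ``C``
(mm^-3) with relative impedance ``Q``, the expected calibrated power spectrum
in dB is modelled as

    S(f) = E + 10*log10(C Q^2 a^6) + 10*n*log10(f) - (10/ln 10) * phi(f),

    phi(f) = 0.827 * (2 pi f a / c)^2      [f in MHz, a in um, c in m/s]

where ``exp(-phi)`` is the Gaussian form factor, ``n`` is the geometry
(frequency power-law) parameter (4 for small spheres) and ``E`` is a
shape/system constant in dB that absorbs beam geometry, gate length and the
reference reflectivity.  Ordinary least squares of ``S`` over a band
``[f1, f2]`` has a closed form: the quadratic ``phi`` term contributes slope
``-2 kappa f_c a^2`` exactly, and the ``log f`` term contributes the OLS slope
of ``ln f`` over the band.  The radius and concentration inversions below are
the exact algebraic inverses of this forward model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .rf import RFVolume

log = logging.getLogger(__name__)

GAUSSIAN_FF_COEF = 0.827  # exponent coefficient of the Gaussian form factor
DB10 = 10.0 / math.log(10.0)

__all__ = [
    "SpectralFit",
    "ScattererModel",
    "CalciumEstimate",
    "RoiSpec",
    "WindowSpec",
    "CalibratedSpectra",
    "band_log_slope",
    "band_log_mean",
    "slope_from_radius",
    "radius_from_slope",
    "mbf_from_concentration",
    "acoustic_concentration_from_mbf",
    "concentration_and_impedance",
    "equivalent_scatterer_number",
    "relative_impedance",
    "scatterer_density_from_impedance",
    "impedance_after_deposition",
    "calcium_mass",
    "reference_spectrum",
    "calibrated_spectrum",
    "fit_slope_mbf",
    "correct_attenuation",
    "fit_window_table",
    "ensemble_fit",
    "roi_statistics",
    "calibrate_shape_parameter",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class SpectralFit:
    """Linear-regression parameters of one calibrated spectrum window.

    ``slope_raw``/``mbf_raw`` are the uncorrected regression parameters
    (dB/MHz and dB); ``slope``/``mbf`` the attenuation-corrected ones.
    ``analysis_band`` is the regression band in MHz; ``depth_mm`` the one-way
    propagation distance of the window centre below the sample top surface.
    """

    slope_raw: float
    mbf_raw: float
    analysis_band: tuple[float, float]
    depth_mm: float = 0.0
    window_id: tuple[int, int, int] = (0, 0, 0)
    slope: float | None = None
    mbf: float | None = None
    n_points: int = 0

    @property
    def band_center(self) -> float:
        return 0.5 * (self.analysis_band[0] + self.analysis_band[1])

    @property
    def band_width(self) -> float:
        return self.analysis_band[1] - self.analysis_band[0]


@dataclass
class ScattererModel:
    """Effective-scatterer description recovered from spectral parameters."""

    radius_um: float
    geometry_parameter: float = 4.0
    shape_parameter_db: float = 0.0
    acoustic_concentration: float | None = None  # C Q^2, mm^-3
    number_concentration: float | None = None  # C, mm^-3
    relative_impedance: float | None = None  # Q

    def __post_init__(self) -> None:
        if (
            self.acoustic_concentration is not None
            and self.number_concentration is not None
            and self.relative_impedance is not None
        ):
            expect = self.number_concentration * self.relative_impedance**2
            if not math.isclose(self.acoustic_concentration, expect, rel_tol=1e-6):
                raise ValueError("CQ^2 inconsistent with C * Q^2")


@dataclass
class CalciumEstimate:
    """Deposited calcium inferred from an impedance increase Q_0 -> Q_i."""

    q_baseline: float
    q_day: float
    rho_ecm: float  # kg/m^3
    c_ecm: float  # m/s
    c_scatterer: float  # m/s
    n_cells: float
    scatterer_volume_mm3: float
    calcium_mass_ug: float
    calcium_concentration_ug_per_ml: float | None = None


@dataclass(frozen=True)
class RoiSpec:
    """Statistical element volume: lateral x elevational x full thickness."""

    lateral_mm: float = 0.6
    elevational_mm: float = 5.0
    axial: str = "thickness"


@dataclass(frozen=True)
class WindowSpec:
    """Sliding analysis-window geometry for spectral estimation.

    ``periods`` is the axial gate length in carrier periods of the transducer
    centre frequency; adjacent-line periodograms are averaged in groups of
    ``lines_per_group`` before regression, and windows keep ``margin_mm``
    (one-way) clear of the detected surfaces.
    """

    periods: float = 32.0
    overlap: float = 0.5
    lines_per_group: int = 5
    margin_mm: float = 0.1
    band_drop_db: float = 9.0

    def length_samples(self, sampling_rate: float, center_frequency_mhz: float) -> int:
        return int(round(self.periods * sampling_rate / (center_frequency_mhz * 1e6)))


@dataclass
class CalibratedSpectra:
    """Per-window calibrated power spectra plus the reference they share."""

    freqs_mhz: np.ndarray  # (n_freq,)
    spectra_db: np.ndarray  # (n_windows, n_freq)
    depth_mm: np.ndarray  # (n_windows,) one-way depth below top surface
    window_ids: list[tuple[int, int, int]]  # (slice, first line of group, axial)
    band: tuple[float, float]  # -9 dB band of the reference spectrum, MHz
    reference_power: np.ndarray  # (n_freq,) linear units
    window_samples: int
    center_sample: np.ndarray | None = None  # (n_windows,) axial window centres
    center_line: np.ndarray | None = None  # (n_windows,) lateral group centres
    lines_per_group: int = 1

    @property
    def n_windows(self) -> int:
        return self.spectra_db.shape[0]


# ---------------------------------------------------------------------------
# closed-form band statistics of the spectral model


def band_log_mean(f1: float, f2: float) -> float:
    """Mean of ln f over the band [f1, f2] (continuous)."""
    b = f2 - f1
    return (f2 * math.log(f2) - f1 * math.log(f1)) / b - 1.0


def band_log_slope(f1: float, f2: float) -> float:
    """OLS slope of ln f against f over the band [f1, f2] (continuous).

    Equal to 12/b^3 * integral (f - f_c)(ln f - mean) df; closed form via
    antiderivatives of ln f and f ln f.
    """
    b = f2 - f1
    fc = 0.5 * (f1 + f2)
    i1 = (f2 * math.log(f2) - f2) - (f1 * math.log(f1) - f1)
    i2 = (0.5 * f2**2 * math.log(f2) - 0.25 * f2**2) - (
        0.5 * f1**2 * math.log(f1) - 0.25 * f1**2
    )
    return 12.0 / b**3 * (i2 - fc * i1)


def _kappa(c_t: float) -> float:
    """Quadratic-term coefficient: S contains -kappa * a^2 * f^2 dB."""
    return DB10 * GAUSSIAN_FF_COEF * (2.0 * math.pi / c_t) ** 2


def form_factor_exponent(f_mhz, radius_um: float, c_t: float):
    """phi(f) = 0.827 (2 pi f a / c)^2 with f in MHz, a in um, c in m/s."""
    f = np.asarray(f_mhz, dtype=float)
    return GAUSSIAN_FF_COEF * (2.0 * math.pi * f * radius_um / c_t) ** 2


def slope_from_radius(
    radius_um: float,
    band: tuple[float, float],
    n: float = 4.0,
    c_t: float = 1540.0,
) -> float:
    """Forward map: expected corrected spectral slope (dB/MHz) of the model.

    Sum of the geometry power-law contribution ``(10 n / ln 10) * g(f1, f2)``
    and the Gaussian form-factor contribution ``-2 kappa f_c a^2``.
    """
    f1, f2 = band
    fc = 0.5 * (f1 + f2)
    return DB10 * n * band_log_slope(f1, f2) - 2.0 * _kappa(c_t) * fc * radius_um**2


def radius_from_slope(
    fit: "SpectralFit | float",
    n: float = 4.0,
    c_t: float = 1540.0,
    band: tuple[float, float] | None = None,
) -> float:
    """Invert the corrected slope for the effective scatterer radius (um).

    Exact algebraic inverse of :func:`slope_from_radius`.  Slopes steeper than
    the zero-radius system slope have a negative radicand and are flagged
    non-physical by returning ``nan`` (callers exclude them from statistics
    rather than clipping, which would bias means).
    """
    if isinstance(fit, SpectralFit):
        slope = fit.slope if fit.slope is not None else fit.slope_raw
        band = fit.analysis_band
    else:
        slope = float(fit)
        if band is None:
            raise ValueError("band required when passing a bare slope")
    f1, f2 = band
    fc = 0.5 * (f1 + f2)
    radicand = (DB10 * n * band_log_slope(f1, f2) - slope) / (2.0 * _kappa(c_t) * fc)
    if radicand < 0:
        return float("nan")
    return math.sqrt(radicand)


def mbf_from_concentration(
    cq2: float,
    radius_um: float,
    band: tuple[float, float],
    n: float = 4.0,
    c_t: float = 1540.0,
    shape_parameter_db: float = 0.0,
) -> float:
    """Forward map: expected corrected MBF (dB) of the model.

    The MBF of the OLS line over a symmetric band equals the band mean of the
    model spectrum; the band mean of f^2 is f_c^2 + b^2/12.
    """
    f1, f2 = band
    fc = 0.5 * (f1 + f2)
    b = f2 - f1
    if cq2 <= 0 or radius_um <= 0:
        raise ValueError("cq2 and radius must be positive")
    return (
        shape_parameter_db
        + 10.0 * math.log10(cq2 * radius_um**6)
        + DB10 * n * band_log_mean(f1, f2)
        - _kappa(c_t) * radius_um**2 * (fc**2 + b**2 / 12.0)
    )


def acoustic_concentration_from_mbf(
    fit: "SpectralFit | float",
    radius_um: float,
    n: float = 4.0,
    c_t: float = 1540.0,
    shape_parameter_db: float = 0.0,
    band: tuple[float, float] | None = None,
) -> float:
    """Invert the corrected MBF for the acoustic concentration CQ^2 (mm^-3).

    Exact algebraic inverse of :func:`mbf_from_concentration`.  Returns ``nan``
    for a non-physical radius.
    """
    if isinstance(fit, SpectralFit):
        mbf = fit.mbf if fit.mbf is not None else fit.mbf_raw
        band = fit.analysis_band
    else:
        mbf = float(fit)
        if band is None:
            raise ValueError("band required when passing a bare MBF")
    if not np.isfinite(radius_um) or radius_um <= 0:
        return float("nan")
    f1, f2 = band
    fc = 0.5 * (f1 + f2)
    b = f2 - f1
    exponent = (
        mbf
        - shape_parameter_db
        - DB10 * n * band_log_mean(f1, f2)
        + _kappa(c_t) * radius_um**2 * (fc**2 + b**2 / 12.0)
    )
    return 10.0 ** (exponent / 10.0) / radius_um**6


def concentration_and_impedance(
    cq2: float,
    known_c: float | None = None,
    known_q: float | None = None,
) -> tuple[float, float]:
    """Complete (C, Q) from CQ^2 plus exactly one known factor.

    Returns ``(C, Q)`` with C in mm^-3.
    """
    if (known_c is None) == (known_q is None):
        raise ValueError("supply exactly one of known_c, known_q")
    if cq2 < 0:
        raise ValueError("cq2 must be non-negative")
    if known_c is not None:
        if known_c <= 0:
            raise ValueError("known_c must be positive")
        return known_c, math.sqrt(cq2 / known_c)
    if known_q <= 0:
        raise ValueError("known_q must be positive")
    return cq2 / known_q**2, known_q


def equivalent_scatterer_number(cq2: float, construct_volume_mm3: float) -> float:
    """Equivalent number of acoustic scatterers: CQ^2 times construct volume."""
    if cq2 < 0 or construct_volume_mm3 < 0:
        raise ValueError("cq2 and volume must be non-negative")
    return cq2 * construct_volume_mm3


# ---------------------------------------------------------------------------
# impedance and calcium


def relative_impedance(rho_i: float, c_i: float, rho: float, c: float) -> float:
    """Relative acoustic impedance Q = (rho_i c_i - rho c) / (rho c)."""
    return (rho_i * c_i - rho * c) / (rho * c)


def scatterer_density_from_impedance(q: float, c_i: float, rho: float, c: float) -> float:
    """Invert the impedance definition for the scatterer density (kg/m^3)."""
    return (1.0 + q) * rho * c / c_i


def impedance_after_deposition(
    q_baseline: float,
    calcium_mass_ug: float,
    n_cells: float,
    radius_um: float,
    rho_ecm: float = 1000.0,
    c_ecm: float = 1540.0,
    c_scatterer: float = 1540.0,
) -> float:
    """Forward model: impedance after deposing ``calcium_mass_ug`` on N cells.

    The deposited mineral raises the mean density of each scatterer (volume
    (4/3) pi a^3) by ``mass / (N V_i)``; the sound speed of the scatterer is
    taken as unchanged, so the impedance rises linearly with the added mass.
    """
    v_i_m3 = (4.0 / 3.0) * math.pi * (radius_um * 1e-6) ** 3
    delta_rho = calcium_mass_ug * 1e-9 / (n_cells * v_i_m3)  # kg/m^3
    return q_baseline + delta_rho * c_scatterer / (rho_ecm * c_ecm)


def calcium_mass(
    q_baseline: float,
    q_day: float,
    n_cells: float,
    radius_um: float,
    rho_ecm: float = 1000.0,
    c_ecm: float = 1540.0,
    c_scatterer: float = 1540.0,
    construct_volume_mm3: float | None = None,
) -> CalciumEstimate:
    """Deposited calcium mass from the impedance rise Q_0 -> Q_i.

        M = N_i * V_i * rho * c * (Q_i - Q_0) / c_i,   V_i = (4/3) pi a^3

    the exact algebraic inverse of :func:`impedance_after_deposition`.
    ``Q_i < Q_0`` yields zero mass with a warning (mass cannot be negative).
    """
    v_i_m3 = (4.0 / 3.0) * math.pi * (radius_um * 1e-6) ** 3
    dq = q_day - q_baseline
    if dq < 0:
        log.warning("q_day %.4f below baseline %.4f; reporting zero calcium", q_day, q_baseline)
        dq = 0.0
    mass_kg = n_cells * v_i_m3 * rho_ecm * c_ecm * dq / c_scatterer
    mass_ug = mass_kg * 1e9
    conc = None
    if construct_volume_mm3:
        conc = mass_ug / (construct_volume_mm3 * 1e-3)  # ug per ml
    return CalciumEstimate(
        q_baseline=q_baseline,
        q_day=q_day,
        rho_ecm=rho_ecm,
        c_ecm=c_ecm,
        c_scatterer=c_scatterer,
        n_cells=n_cells,
        scatterer_volume_mm3=v_i_m3 * 1e9,
        calcium_mass_ug=mass_ug,
        calcium_concentration_ug_per_ml=conc,
    )


# ---------------------------------------------------------------------------
# calibrated spectra


def _hamming_periodogram(segments: np.ndarray, window: np.ndarray) -> np.ndarray:
    """Mean |rfft|^2 of Hamming-tapered segments (segments on axis -1)."""
    spec = np.fft.rfft(segments * window, axis=-1)
    power = np.abs(spec) ** 2
    if power.ndim > 1:
        power = power.mean(axis=tuple(range(power.ndim - 1)))
    return power


def reference_spectrum(
    reference: RFVolume,
    window_samples: int,
    t_ref: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged power spectrum of the reference (water-path) reflector echo.

    Each A-line of the reference scan is windowed around the envelope peak of
    its gel-pad echo; periodograms are averaged over all lines.  Returns
    ``(freqs_mhz, power)``.
    """
    from .rf import envelope

    fs = 1.0 / reference.grid.axial_dt
    w = np.hamming(window_samples)
    half = window_samples // 2
    segs = []
    for k in range(reference.grid.n_slices):
        block = reference.slice(k)
        env = envelope(block)
        for i in range(reference.grid.n_lines):
            if t_ref is not None:
                center = int(round(t_ref[i, k] / reference.grid.axial_dt))
            else:
                center = int(np.argmax(env[:, i]))
            lo = center - half
            hi = lo + window_samples
            if lo < 0 or hi > block.shape[0]:
                continue
            segs.append(block[lo:hi, i])
    if not segs:
        raise ValueError("no usable reference echo segments")
    power = _hamming_periodogram(np.asarray(segs), w)
    freqs = np.fft.rfftfreq(window_samples, d=1.0 / fs) / 1e6
    return freqs, power


def _band_from_reference(freqs: np.ndarray, power: np.ndarray, drop_db: float) -> tuple[float, float]:
    """Contiguous band around the spectral peak within ``drop_db`` of it."""
    peak = int(np.argmax(power))
    thresh = power[peak] * 10.0 ** (-drop_db / 10.0)
    lo = peak
    while lo > 0 and power[lo - 1] >= thresh:
        lo -= 1
    hi = peak
    while hi < power.size - 1 and power[hi + 1] >= thresh:
        hi += 1
    return float(freqs[lo]), float(freqs[hi])


def calibrated_spectrum(
    volume: RFVolume,
    reference: RFVolume,
    surfaces,
    window: WindowSpec = WindowSpec(),
    c_t: float = 1540.0,
) -> CalibratedSpectra:
    """Sliding-window calibrated power spectra of the sample interior.

    ``surfaces`` is the :class:`susi.bulk.SurfaceMap` of the sample scan; the
    analysis windows slide between the detected top and bottom surfaces with a
    safety margin, are Hamming-tapered, and periodograms are averaged over
    ``window.lines_per_group`` adjacent A-lines before calibration by the
    reference-echo spectrum.  The analysis band is the -9 dB span of the
    reference spectrum.  Windows whose group has no valid surface detection
    are skipped with a log entry.
    """
    if volume.grid.shape[1:] != reference.grid.shape[1:]:
        raise ValueError("sample and reference grids do not match")
    dt = volume.grid.axial_dt
    fs = 1.0 / dt
    wlen = window.length_samples(fs, volume.transducer.center_frequency)
    w = np.hamming(wlen)
    freqs, ref_power = reference_spectrum(reference, wlen, t_ref=surfaces.t_ref)
    band = _band_from_reference(freqs, ref_power, window.band_drop_db)

    margin_samples = int(round(window.margin_mm * 1e-3 * 2.0 / c_t / dt))
    step = max(1, int(round(wlen * (1.0 - window.overlap))))

    spectra = []
    depths = []
    ids = []
    centers_ax = []
    centers_line = []
    n_lines = volume.grid.n_lines
    for k in range(volume.grid.n_slices):
        block = volume.slice(k)
        for g0 in range(0, n_lines - window.lines_per_group + 1, window.lines_per_group):
            lines = np.arange(g0, g0 + window.lines_per_group)
            valid = surfaces.valid[lines, k]
            if valid.sum() < max(1, window.lines_per_group // 2):
                log.debug("group (%d, %d): insufficient valid surfaces, skipped", k, g0)
                continue
            t_top = np.median(surfaces.t_top[lines[valid], k])
            t_bot = np.median(surfaces.t_bot[lines[valid], k])
            i_top = int(round(t_top / dt))
            i_bot = int(round(t_bot / dt))
            start = i_top + margin_samples
            stop = i_bot - margin_samples
            if stop - start < wlen:
                continue
            ax = 0
            pos = start
            while pos + wlen <= stop:
                segs = block[pos : pos + wlen, lines].T  # (n_lines, wlen)
                power = _hamming_periodogram(segs, w)
                with np.errstate(divide="ignore"):
                    cal_db = 10.0 * np.log10(power / ref_power)
                t_center = (pos + wlen / 2.0) * dt
                z_mm = (t_center - t_top) / 2.0 * c_t * 1e3
                spectra.append(cal_db)
                depths.append(z_mm)
                ids.append((k, int(g0), ax))
                centers_ax.append(pos + wlen / 2.0)
                centers_line.append(g0 + (window.lines_per_group - 1) / 2.0)
                ax += 1
                pos += step
    if not spectra:
        raise ValueError("no analysis windows inside the sample interior")
    return CalibratedSpectra(
        freqs_mhz=freqs,
        spectra_db=np.asarray(spectra),
        depth_mm=np.asarray(depths),
        window_ids=ids,
        band=band,
        reference_power=ref_power,
        window_samples=wlen,
        center_sample=np.asarray(centers_ax),
        center_line=np.asarray(centers_line),
        lines_per_group=window.lines_per_group,
    )


# ---------------------------------------------------------------------------
# regression and correction


def fit_slope_mbf(
    spectrum_db: np.ndarray,
    freqs_mhz: np.ndarray,
    band: tuple[float, float],
    depth_mm: float = 0.0,
    window_id: tuple[int, int, int] = (0, 0, 0),
) -> SpectralFit:
    """OLS of the calibrated spectrum (dB) against frequency over ``band``.

    ``slope_raw`` is the fitted slope in dB/MHz; ``mbf_raw`` the fitted value
    at the band centre.
    """
    sel = (freqs_mhz >= band[0]) & (freqs_mhz <= band[1])
    if sel.sum() < 5:
        raise ValueError("analysis band narrower than 5 regression points")
    f = freqs_mhz[sel]
    s = np.asarray(spectrum_db)[sel]
    slope, intercept = np.polyfit(f, s, 1)
    fc = 0.5 * (band[0] + band[1])
    return SpectralFit(
        slope_raw=float(slope),
        mbf_raw=float(slope * fc + intercept),
        analysis_band=band,
        depth_mm=depth_mm,
        window_id=window_id,
        n_points=int(sel.sum()),
    )


def correct_attenuation(
    fit: SpectralFit,
    alpha_db_cm_mhz: float,
    z_cm: float | None = None,
    f_c: float | None = None,
) -> SpectralFit:
    """Attenuation compensation: m = m' + 2 a z, MBF = MBF' + 2 a z f_c.

    ``z`` is the one-way propagation distance in the sample in cm (defaults to
    the window depth recorded in the fit); ``f_c`` defaults to the analysis
    band centre.  At alpha = 0 the corrected parameters equal the raw ones.
    """
    if z_cm is None:
        z_cm = fit.depth_mm / 10.0
    if z_cm < 0:
        raise ValueError("propagation distance z must be non-negative")
    if f_c is None:
        f_c = fit.band_center
    return replace(
        fit,
        slope=fit.slope_raw + 2.0 * alpha_db_cm_mhz * z_cm,
        mbf=fit.mbf_raw + 2.0 * alpha_db_cm_mhz * z_cm * f_c,
    )


# ---------------------------------------------------------------------------
# batch estimation over windows


def fit_window_table(
    spectra: CalibratedSpectra,
    alpha_db_cm_mhz: float,
    n: float = 4.0,
    c_t: float = 1540.0,
    shape_parameter_db: float = 0.0,
    grid=None,
) -> pd.DataFrame:
    """Per-window regression, correction and inversion as a tidy table.

    Columns: window coordinates, m', MBF', m, MBF, z (mm), the recovered
    radius/diameter (um) and acoustic concentration CQ^2 (mm^-3).  Windows
    with non-physical inversions carry NaN and are excluded by downstream
    statistics, not clipped.
    """
    rows = []
    for i in range(spectra.n_windows):
        fit = fit_slope_mbf(
            spectra.spectra_db[i],
            spectra.freqs_mhz,
            spectra.band,
            depth_mm=float(spectra.depth_mm[i]),
            window_id=spectra.window_ids[i],
        )
        fit = correct_attenuation(fit, alpha_db_cm_mhz)
        a = radius_from_slope(fit, n=n, c_t=c_t)
        cq2 = acoustic_concentration_from_mbf(
            fit, a, n=n, c_t=c_t, shape_parameter_db=shape_parameter_db
        )
        sl, ln, ax = fit.window_id
        row = {
            "slice": sl,
            "line": ln,
            "axial": ax,
            "z_mm": fit.depth_mm,
            "slope_raw": fit.slope_raw,
            "mbf_raw": fit.mbf_raw,
            "slope": fit.slope,
            "mbf": fit.mbf,
            "radius_um": a,
            "diameter_um": 2.0 * a,
            "cq2_mm3": cq2,
        }
        if spectra.center_sample is not None:
            row["axial_sample"] = float(spectra.center_sample[i])
            row["line_center"] = float(spectra.center_line[i])
        if grid is not None:
            row["lateral_mm"] = ln * grid.lateral_spacing * 1e-3
            row["elevational_mm"] = sl * grid.slice_spacing * 1e-3
        rows.append(row)
    return pd.DataFrame(rows)


def ensemble_fit(
    spectra: CalibratedSpectra,
    alpha_db_cm_mhz: float,
    n: float = 4.0,
    c_t: float = 1540.0,
    shape_parameter_db: float = 0.0,
) -> dict:
    """Construct-level estimate from the attenuation-compensated mean spectrum.

    Each window's calibrated power spectrum is compensated exactly per
    frequency (``+2 alpha z f`` dB), the linear powers are averaged over all
    windows, and a single regression/inversion is performed.  This pools the
    full scatterer ensemble and is the preferred estimator at low number
    concentration, where individual windows hold few scatterers.
    """
    comp_db = (
        spectra.spectra_db
        + 2.0
        * alpha_db_cm_mhz
        * (spectra.depth_mm[:, None] / 10.0)
        * spectra.freqs_mhz[None, :]
    )
    mean_power = np.mean(10.0 ** (comp_db / 10.0), axis=0)
    mean_db = 10.0 * np.log10(mean_power)
    fit = fit_slope_mbf(mean_db, spectra.freqs_mhz, spectra.band)
    fit = correct_attenuation(fit, 0.0)  # compensation already applied per bin
    a = radius_from_slope(fit, n=n, c_t=c_t)
    cq2 = acoustic_concentration_from_mbf(
        fit, a, n=n, c_t=c_t, shape_parameter_db=shape_parameter_db
    )
    return {
        "slope": fit.slope,
        "mbf": fit.mbf,
        "band": spectra.band,
        "radius_um": a,
        "diameter_um": 2.0 * a,
        "cq2_mm3": cq2,
        "n_windows": spectra.n_windows,
    }


def roi_statistics(
    table: pd.DataFrame,
    roi: RoiSpec = RoiSpec(),
    lateral_spacing_um: float = 31.0,
    slice_spacing_um: float = 200.0,
    parameters: tuple[str, ...] = ("diameter_um", "cq2_mm3"),
    min_windows: int = 5,
) -> pd.DataFrame:
    """Mean and standard deviation of window estimates per statistical ROI.

    Windows are binned by their group-centre coordinates into elements of
    ``roi.lateral_mm`` by ``roi.elevational_mm`` spanning the full thickness.
    ROIs with fewer than ``min_windows`` valid windows are excluded with a log
    entry.  The returned table carries one row per ROI plus per-parameter
    mean/sd columns; the construct-level mean is the window-count-weighted
    mean of ROI means.
    """
    lat_lines = max(1, int(roi.lateral_mm * 1e3 // lateral_spacing_um))
    elev_slices = max(1, int(roi.elevational_mm * 1e3 // slice_spacing_um))
    df = table.copy()
    df["roi_lat"] = (df["line"] // lat_lines).astype(int)
    df["roi_elev"] = (df["slice"] // elev_slices).astype(int)
    out = []
    for (rl, re), grp in df.groupby(["roi_lat", "roi_elev"]):
        n_valid = int(grp[list(parameters)].notna().all(axis=1).sum())
        if n_valid < min_windows:
            log.info("ROI (%d, %d): only %d valid windows, excluded", rl, re, n_valid)
            continue
        row = {"roi_lat": rl, "roi_elev": re, "n_windows": n_valid}
        for p in parameters:
            row[f"{p}_mean"] = grp[p].mean()
            row[f"{p}_sd"] = grp[p].std(ddof=1)
        out.append(row)
    return pd.DataFrame(out)


def calibrate_shape_parameter(
    spectra: CalibratedSpectra,
    alpha_db_cm_mhz: float,
    true_cq2: float,
    true_radius_um: float,
    n: float = 4.0,
    c_t: float = 1540.0,
) -> float:
    """One-off empirical calibration of the shape/system constant E (dB).

    Given calibrated spectra of a specimen with known CQ^2 and radius, E is
    the offset that makes the measured ensemble MBF match the forward model.
    """
    res = ensemble_fit(spectra, alpha_db_cm_mhz, n=n, c_t=c_t, shape_parameter_db=0.0)
    predicted = mbf_from_concentration(
        true_cq2, true_radius_um, spectra.band, n=n, c_t=c_t, shape_parameter_db=0.0
    )
    return res["mbf"] - predicted
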