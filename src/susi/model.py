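"""Model/Results facade tying the whole quantification pipeline together.

:class:`SusiModel` is constructed from a (sample, reference) scan pair plus an
analysis configuration; :meth:`SusiModel.fit` runs surface detection, the
substitution-method bulk acoustics, serial-contour volumetry, calibrated
spectral analysis and the scatterer-property inversions, and returns a
:class:`SusiResults` carrying the estimates, their window-to-window spread,
diagnostics and a ``summary()`` table.  Parametric-map rendering and report
export hang off the results object.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bulk as _bulk
from . import maps as _maps
from . import spectral as _spectral
from .rf import BModeImage, MediumSpec, RFVolume, envelope_bmode, read_container
from .simulate import default_beam_diameter_mm, shape_parameter_from_system
from .spectral import RoiSpec, WindowSpec

log = logging.getLogger(__name__)

__all__ = ["SusiConfig", "SusiModel", "SusiResults", "run_pipeline"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class SusiConfig:
    """Analysis configuration shared by the facade and the CLI.

    ``known_c`` (mm^-3) or ``known_q`` completes the acoustic-concentration
    factorization; supply at most one.  ``shape_parameter_db`` (E) defaults to
    the analytic system value derived from the effective beam diameter and the
    reference reflector amplitude.  Calcium estimation additionally needs the
    baseline impedance ``q_baseline`` and the cell count ``n_cells``.
    """

    medium: MediumSpec = field(default_factory=MediumSpec)
    window: WindowSpec = field(default_factory=WindowSpec)
    roi: RoiSpec = field(default_factory=RoiSpec)
    geometry_parameter: float = 4.0
    shape_parameter_db: float | None = None
    beam_diameter_mm: float | None = None
    reference_amplitude: float = 0.02
    known_c: float | None = None
    known_q: float | None = None
    surface_threshold_db: float = -18.0
    volume_threshold_db: float = 30.0
    bmode_dynamic_range_db: float = 50.0
    attenuation_band: tuple[float, float] = (20.0, 55.0)
    # calcium estimation (optional)
    q_baseline: float | None = None
    n_cells: float | None = None
    rho_ecm: float = 1000.0
    c_ecm: float = 1540.0
    c_scatterer: float = 1540.0

    def __post_init__(self) -> None:
        if self.known_c is not None and self.known_q is not None:
            raise ValueError("supply at most one of known_c, known_q")


class SusiModel:
    """Spectral-ultrasound quantification model for one scan pair."""

    def __init__(self, sample: RFVolume, reference: RFVolume, config: SusiConfig | None = None):
        if sample.kind != "sample" or reference.kind != "reference":
            log.warning("scan kinds are (%s, %s); expected (sample, reference)", sample.kind, reference.kind)
        self.sample = sample
        self.reference = reference
        self.config = config or SusiConfig()

    @classmethod
    def from_containers(
        cls, sample_dir, reference_dir, config: SusiConfig | None = None
    ) -> "SusiModel":
        return cls(read_container(sample_dir), read_container(reference_dir), config)

    def fit(self) -> "SusiResults":
        cfg = self.config
        log.info("stage bulk: surface detection and substitution-method acoustics")
        props, surfaces = _bulk.bulk_properties(
            self.sample,
            self.reference,
            cfg.medium,
            threshold_db=cfg.surface_threshold_db,
            fit_band=cfg.attenuation_band,
        )
        c_t = props.speed_of_sound

        log.info("stage volume: serial-contour volumetry over %d slices", self.sample.grid.n_slices)
        bmodes = [
            envelope_bmode(self.sample, k, cfg.bmode_dynamic_range_db, cfg.medium)
            for k in range(self.sample.grid.n_slices)
        ]
        # crop everything below the specimen (gel-pad reflector) before contouring
        times = surfaces.median()
        cutoff = int(round((times.t_bot + times.t_gel) / 2.0 / self.sample.grid.axial_dt))
        vol_est = _bulk.construct_volume(
            bmodes, threshold_db=cfg.volume_threshold_db, max_depth_sample=cutoff
        )

        log.info("stage spectral: calibrated spectra and window regression")
        spectra = _spectral.calibrated_spectrum(
            self.sample, self.reference, surfaces, cfg.window, c_t=c_t
        )
        e_db = cfg.shape_parameter_db
        if e_db is None:
            beam = cfg.beam_diameter_mm or default_beam_diameter_mm(
                self.sample.transducer, cfg.medium
            )
            e_db = shape_parameter_from_system(
                beam, cfg.reference_amplitude, self.sample.transducer, cfg.window, c_t
            )
        table = _spectral.fit_window_table(
            spectra,
            props.attenuation_coeff,
            n=cfg.geometry_parameter,
            c_t=c_t,
            shape_parameter_db=e_db,
            grid=self.sample.grid,
        )
        ensemble = _spectral.ensemble_fit(
            spectra,
            props.attenuation_coeff,
            n=cfg.geometry_parameter,
            c_t=c_t,
            shape_parameter_db=e_db,
        )
        roi_table = _spectral.roi_statistics(
            table,
            cfg.roi,
            lateral_spacing_um=self.sample.grid.lateral_spacing,
            slice_spacing_um=self.sample.grid.slice_spacing,
        )

        cq2 = ensemble["cq2_mm3"]
        number_c = impedance = None
        if cfg.known_c is not None:
            number_c, impedance = _spectral.concentration_and_impedance(cq2, known_c=cfg.known_c)
        elif cfg.known_q is not None:
            number_c, impedance = _spectral.concentration_and_impedance(cq2, known_q=cfg.known_q)
        scatterer = _spectral.ScattererModel(
            radius_um=ensemble["radius_um"],
            geometry_parameter=cfg.geometry_parameter,
            shape_parameter_db=e_db,
            acoustic_concentration=cq2,
            number_concentration=number_c,
            relative_impedance=impedance,
        )

        calcium = None
        if cfg.q_baseline is not None and impedance is not None and cfg.n_cells is not None:
            calcium = _spectral.calcium_mass(
                cfg.q_baseline,
                impedance,
                cfg.n_cells,
                ensemble["radius_um"],
                rho_ecm=cfg.rho_ecm,
                c_ecm=cfg.c_ecm,
                c_scatterer=cfg.c_scatterer,
                construct_volume_mm3=vol_est.volume_mm3,
            )

        return SusiResults(
            model=self,
            bulk=props,
            surfaces=surfaces,
            volume=vol_est,
            spectra=spectra,
            shape_parameter_db=e_db,
            window_table=table,
            roi_table=roi_table,
            ensemble=ensemble,
            scatterer=scatterer,
            calcium=calcium,
            bmodes=bmodes,
        )


@dataclass
class SusiResults:
    """Fitted quantities, spreads and diagnostics for one scan pair."""

    model: SusiModel
    bulk: _bulk.BulkProperties
    surfaces: _bulk.SurfaceMap
    volume: _bulk.ConstructVolumeEstimate
    spectra: _spectral.CalibratedSpectra
    shape_parameter_db: float
    window_table: pd.DataFrame
    roi_table: pd.DataFrame
    ensemble: dict
    scatterer: _spectral.ScattererModel
    calcium: _spectral.CalciumEstimate | None
    bmodes: list[BModeImage]

    # -- headline accessors -------------------------------------------------

    @property
    def diameter_um(self) -> float:
        """Construct-level effective scatterer diameter (ensemble spectrum)."""
        return self.ensemble["diameter_um"]

    @property
    def cq2_mm3(self) -> float:
        return self.ensemble["cq2_mm3"]

    def median_window_diameter(self) -> float:
        return float(self.window_table["diameter_um"].median(skipna=True))

    # -- reporting ----------------------------------------------------------

    def to_report(self) -> dict:
        g = self.model.sample.grid
        rep = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "grid": {
                "n_samples": g.n_samples,
                "n_lines": g.n_lines,
                "n_slices": g.n_slices,
                "lateral_spacing_um": g.lateral_spacing,
                "slice_spacing_um": g.slice_spacing,
            },
            "bulk": {
                "thickness_mm": self.bulk.thickness_mm,
                "speed_of_sound_m_s": self.bulk.speed_of_sound,
                "attenuation_db_cm_mhz": self.bulk.attenuation_coeff,
                "attenuation_band_mhz": list(self.bulk.attenuation_band),
                "attenuation_fit_r2": self.bulk.fit_r2,
            },
            "volume_mm3": self.volume.volume_mm3,
            "spectral": {
                "band_mhz": list(self.spectra.band),
                "n_windows": self.spectra.n_windows,
                "shape_parameter_db": self.shape_parameter_db,
                "slope_db_mhz": self.ensemble["slope"],
                "mbf_db": self.ensemble["mbf"],
                "diameter_um": self.ensemble["diameter_um"],
                "median_window_diameter_um": self.median_window_diameter(),
                "cq2_mm3": self.ensemble["cq2_mm3"],
                "number_concentration_mm3": self.scatterer.number_concentration,
                "relative_impedance": self.scatterer.relative_impedance,
            },
            "equivalent_scatterer_number": _spectral.equivalent_scatterer_number(
                max(self.ensemble["cq2_mm3"], 0.0), self.volume.volume_mm3
            )
            if np.isfinite(self.ensemble["cq2_mm3"])
            else None,
            "roi": self.roi_table.to_dict(orient="records"),
        }
        if self.calcium is not None:
            rep["calcium"] = {
                "mass_ug": self.calcium.calcium_mass_ug,
                "concentration_ug_per_ml": self.calcium.calcium_concentration_ug_per_ml,
                "q_baseline": self.calcium.q_baseline,
                "q_day": self.calcium.q_day,
            }
        return rep

    def save_report(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_report(), indent=1, sort_keys=True, default=float))
        return path

    def summary(self) -> str:
        """Human-readable summary table of the fitted quantities."""
        r = self.to_report()
        lines = [
            "Spectral ultrasound quantification",
            "=" * 50,
            f"{'thickness':<28}{r['bulk']['thickness_mm']:>10.3f}  mm",
            f"{'speed of sound':<28}{r['bulk']['speed_of_sound_m_s']:>10.1f}  m/s",
            f"{'attenuation coefficient':<28}{r['bulk']['attenuation_db_cm_mhz']:>10.3f}  dB/(cm MHz)",
            f"{'construct volume':<28}{r['volume_mm3']:>10.2f}  mm^3",
            "-" * 50,
            f"{'analysis band':<28}{r['spectral']['band_mhz'][0]:>6.1f} - {r['spectral']['band_mhz'][1]:.1f}  MHz",
            f"{'analysis windows':<28}{r['spectral']['n_windows']:>10d}",
            f"{'spectral slope m':<28}{r['spectral']['slope_db_mhz']:>10.4f}  dB/MHz",
            f"{'mid-band fit MBF':<28}{r['spectral']['mbf_db']:>10.2f}  dB",
            f"{'scatterer diameter':<28}{r['spectral']['diameter_um']:>10.2f}  um",
            f"{'acoustic conc. CQ^2':<28}{r['spectral']['cq2_mm3']:>10.1f}  /mm^3",
        ]
        if r["spectral"]["relative_impedance"] is not None:
            lines.append(
                f"{'relative impedance Q':<28}{r['spectral']['relative_impedance']:>10.3f}"
            )
        if r["spectral"]["number_concentration_mm3"] is not None:
            lines.append(
                f"{'number concentration C':<28}{r['spectral']['number_concentration_mm3']:>10.1f}  /mm^3"
            )
        if "calcium" in r:
            lines += [
                "-" * 50,
                f"{'calcium mass':<28}{r['calcium']['mass_ug']:>10.3f}  ug",
                f"{'calcium concentration':<28}{r['calcium']['concentration_ug_per_ml']:>10.1f}  ug/ml",
            ]
        return "\n".join(lines)

    # -- maps ---------------------------------------------------------------

    def parametric_map(
        self, parameter: str, slice_index: int = 0, **kwargs
    ) -> _maps.ParametricMap:
        return _maps.build_parametric_map(
            self.bmodes[slice_index],
            self.window_table,
            parameter,
            slice_index=slice_index,
            window_samples=self.spectra.window_samples,
            lines_per_group=self.spectra.lines_per_group,
            **kwargs,
        )

    def render_map(self, parameter: str, out_path, slice_index: int = 0, **kwargs):
        pmap = self.parametric_map(parameter, slice_index)
        return _maps.render_overlay(self.bmodes[slice_index], pmap, out_path, **kwargs)


def run_pipeline(sample_dir, reference_dir, config: SusiConfig | None = None, out_dir=None) -> dict:
    """End-to-end: containers -> bulk -> spectral -> maps -> report bundle.

    Writes ``report.json``, the per-window CSV table and diameter/CQ^2 overlay
    PNGs of the central slice into ``out_dir`` (if given) and returns the
    report dict.  Deterministic for fixed inputs and configuration.
    """
    model = SusiModel.from_containers(sample_dir, reference_dir, config)
    results = model.fit()
    report = results.to_report()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.save_report(out / "report.json")
        results.window_table.to_csv(out / "windows.csv", index=False)
        mid = model.sample.grid.n_slices // 2
        for parameter in ("diameter", "cq2"):
            try:
                results.render_map(parameter, out / f"map_{parameter}.png", slice_index=mid)
            except Exception as exc:  # map rendering must not sink the report
                log.warning("map %s not rendered: %s", parameter, exc)
    return report
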