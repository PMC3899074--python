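"""Canonical desk-scale validation studies.

These functions define the simulation conditions used to validate every
estimator by parameter recovery — bead-phantom series at four diameters,
cell-scale constructs, a concentration-linearity series, and a mineralizing
timecourse — and run the full pipeline on them.  The acceptance script and
the test suite both drive these protocols, so the conditions live in one
place.

Conditions (fixed):

* bead phantoms: diameters 6, 10, 16, 25 um; C = 1000 /mm^3; Q = 0.6;
  alpha = 0.5 dB/(cm MHz); agar-like matrix at 1540 m/s; 2 mm thick;
  SNR 30 dB,
* cell-scale construct: 14 um scatterers at 2e6 /ml (2000 /mm^3), day-0
  attenuation 0.1 dB/(cm MHz), matrix at 1520 m/s,
* concentration series: 0.5, 1, 2, 5 e6 /ml at fixed Q = 0.6.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .bulk import bulk_properties
from .model import SusiConfig, SusiModel
from .rf import AcquisitionGrid, MediumSpec, TransducerSpec
from .simulate import (
    PhantomConfig,
    analytic_shape_parameter,
    default_timecourse,
    simulate_scan,
    simulate_timecourse,
)
from .spectral import (
    WindowSpec,
    calibrated_spectrum,
    calcium_mass,
    concentration_and_impedance,
    ensemble_fit,
    fit_window_table,
)

__all__ = [
    "PHANTOM_DIAMETERS_UM",
    "bead_phantom_config",
    "cell_construct_config",
    "recover_scan",
    "phantom_size_study",
    "impedance_recovery_study",
    "concentration_series_study",
    "timecourse_study",
]

PHANTOM_DIAMETERS_UM = (6.0, 10.0, 16.0, 25.0)
CELL_DIAMETER_UM = 14.0
CELL_CONCENTRATION_MM3 = 2000.0  # 2e6 cells/ml
TRUE_Q = 0.6


def bead_phantom_config(diameter_um: float, seed: int = 0, concentration: float = 1000.0) -> PhantomConfig:
    """Bead phantom mirroring the polystyrene-microsphere validation series."""
    return PhantomConfig(
        scatterer_diameter_um=diameter_um,
        number_concentration=concentration,
        relative_impedance=TRUE_Q,
        medium_speed=1540.0,
        attenuation_coeff=0.5,
        thickness_mm=2.0,
        standoff_mm=2.0,
        gelpad_depth_mm=4.5,
        rng_seed=seed,
    )


def cell_construct_config(
    seed: int = 0, concentration: float = CELL_CONCENTRATION_MM3
) -> PhantomConfig:
    """Day-0 cell-seeded construct: 14 um scatterers in a soft matrix."""
    return PhantomConfig(
        scatterer_diameter_um=CELL_DIAMETER_UM,
        number_concentration=concentration,
        relative_impedance=TRUE_Q,
        medium_speed=1520.0,
        attenuation_coeff=0.1,
        thickness_mm=1.5,
        standoff_mm=2.0,
        gelpad_depth_mm=4.2,
        rng_seed=seed,
    )


def recover_scan(
    config: PhantomConfig,
    seed: int,
    n_lines: int = 120,
    transducer: TransducerSpec | None = None,
    medium: MediumSpec | None = None,
    window: WindowSpec | None = None,
) -> dict:
    """Simulate one scan pair and run the spectral recovery on it.

    Returns ground truth plus per-window diameters, the ensemble estimates
    and the fitted bulk properties.
    """
    transducer = transducer or TransducerSpec()
    medium = medium or MediumSpec()
    window = window or WindowSpec()
    grid = AcquisitionGrid(n_lines=n_lines, n_slices=1)
    cfg = replace(config, rng_seed=seed)
    sample, reference = simulate_scan(cfg, transducer, grid, medium, seed=seed)
    props, surfaces = bulk_properties(sample, reference, medium)
    spectra = calibrated_spectrum(sample, reference, surfaces, window, c_t=props.speed_of_sound)
    e_db = analytic_shape_parameter(cfg, transducer, medium, window, c_t=props.speed_of_sound)
    table = fit_window_table(
        spectra,
        props.attenuation_coeff,
        n=cfg.geometry_parameter,
        c_t=props.speed_of_sound,
        shape_parameter_db=e_db,
    )
    ens = ensemble_fit(
        spectra,
        props.attenuation_coeff,
        n=cfg.geometry_parameter,
        c_t=props.speed_of_sound,
        shape_parameter_db=e_db,
    )
    return {
        "true_diameter_um": cfg.scatterer_diameter_um,
        "true_cq2": cfg.number_concentration * cfg.relative_impedance**2,
        "true_c": cfg.number_concentration,
        "true_q": cfg.relative_impedance,
        "window_diameters": table["diameter_um"].dropna().to_numpy(),
        "ensemble_diameter_um": ens["diameter_um"],
        "ensemble_cq2": ens["cq2_mm3"],
        "n_windows": spectra.n_windows,
        "bulk": props,
    }


def phantom_size_study(
    diameter_um: float,
    seeds: range | list[int],
    config_factory=bead_phantom_config,
    n_lines: int = 120,
) -> dict:
    """Multi-seed size-recovery study; pools windows across seeds.

    Returns the pooled median and mean recovered diameter, the per-seed
    ensemble CQ^2 values and the window count.
    """
    pooled = []
    cq2s = []
    for seed in seeds:
        res = recover_scan(config_factory(diameter_um, seed), seed, n_lines=n_lines)
        pooled.append(res["window_diameters"])
        cq2s.append(res["ensemble_cq2"])
    diam = np.concatenate(pooled)
    return {
        "true_diameter_um": diameter_um,
        "median_diameter_um": float(np.median(diam)),
        "mean_diameter_um": float(np.mean(diam)),
        "n_windows": int(diam.size),
        "ensemble_cq2": cq2s,
    }


def impedance_recovery_study(seeds: range | list[int], n_lines: int = 120) -> dict:
    """Recover Q from cell-scale scans with the true C supplied."""
    qs = []
    n_windows = 0
    for seed in seeds:
        res = recover_scan(cell_construct_config(seed), seed, n_lines=n_lines)
        _, q = concentration_and_impedance(max(res["ensemble_cq2"], 0.0), known_c=res["true_c"])
        qs.append(q)
        n_windows += res["n_windows"]
    return {
        "true_q": TRUE_Q,
        "mean_q": float(np.mean(qs)),
        "per_seed_q": qs,
        "n_seeds": len(qs),
        "n_windows": n_windows,
    }


def concentration_series_study(
    seeds: range | list[int],
    concentrations_mm3=(500.0, 1000.0, 2000.0, 5000.0),
    n_lines: int = 120,
) -> dict:
    """Estimated-versus-true concentration linearity at fixed, known Q.

    Fits estimated C against true C by least squares and reports R^2.
    """
    true_c = []
    est_c = []
    for conc in concentrations_mm3:
        for seed in seeds:
            res = recover_scan(cell_construct_config(seed, concentration=conc), seed, n_lines=n_lines)
            c, _ = concentration_and_impedance(max(res["ensemble_cq2"], 0.0), known_q=TRUE_Q)
            true_c.append(conc)
            est_c.append(c)
    x = np.asarray(true_c)
    y = np.asarray(est_c)
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    r2 = 1.0 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
    return {
        "true_c": x,
        "est_c": y,
        "slope": float(slope),
        "intercept": float(intercept),
        "r2": float(r2),
    }


def timecourse_study(seed: int = 0, grid: AcquisitionGrid | None = None) -> dict:
    """Run the full pipeline on the default mineralizing timecourse.

    Per day: volume, bulk properties and ensemble spectral estimates; Q is
    factored out of CQ^2 with the known per-day cell concentration, and the
    day-21 calcium mass follows from the impedance rise over day 1.
    """
    grid = grid or AcquisitionGrid(n_lines=126, n_slices=20)
    course = default_timecourse(seed)
    scans = simulate_timecourse(course, grid=grid, seed=seed)
    days = []
    for entry in scans:
        truth = entry["truth"]
        cfg = SusiConfig(
            known_c=truth["concentration_mm3"],
            beam_diameter_mm=None,
            reference_amplitude=course.base.gel_reflection,
        )
        results = SusiModel(entry["sample"], entry["reference"], cfg).fit()
        days.append({"truth": truth, "results": results})
    base = days[0]
    q0 = base["results"].scatterer.relative_impedance
    last = days[-1]
    est = calcium_mass(
        q0,
        last["results"].scatterer.relative_impedance,
        last["truth"]["n_cells"],
        last["results"].ensemble["radius_um"],
        construct_volume_mm3=last["results"].volume.volume_mm3,
    )
    return {
        "days": days,
        "volume_ratio_est": days[1]["results"].volume.volume_mm3
        / days[0]["results"].volume.volume_mm3,
        "volume_ratio_true": days[1]["truth"]["volume_mm3"] / days[0]["truth"]["volume_mm3"],
        "q_baseline_est": q0,
        "calcium": est,
        "calcium_true_ug": last["truth"]["calcium_mass_ug"],
        "calcium_true_conc": last["truth"]["calcium_conc_ug_per_ml"],
    }
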