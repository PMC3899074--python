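"""Shared fixtures: default acquisition objects and cached simulated scans."""

from __future__ import annotations

import numpy as np
import pytest

from susi.bulk import bulk_properties
from susi.rf import AcquisitionGrid, MediumSpec, TransducerSpec
from susi.simulate import PhantomConfig, analytic_shape_parameter, simulate_scan
from susi.spectral import WindowSpec, calibrated_spectrum


@pytest.fixture(scope="session")
def transducer() -> TransducerSpec:
    return TransducerSpec()


@pytest.fixture(scope="session")
def medium() -> MediumSpec:
    return MediumSpec()


@pytest.fixture(scope="session")
def cell_config() -> PhantomConfig:
    """14 um scatterers at 2e6 /ml in a 1.5 mm construct."""
    return PhantomConfig(
        scatterer_diameter_um=14.0,
        number_concentration=2000.0,
        relative_impedance=0.6,
        medium_speed=1520.0,
        attenuation_coeff=0.1,
        thickness_mm=1.5,
        standoff_mm=2.0,
        gelpad_depth_mm=4.2,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def cell_scan(cell_config, transducer, medium):
    """One simulated (sample, reference) pair shared across tests."""
    grid = AcquisitionGrid(n_lines=60, n_slices=1)
    return simulate_scan(cell_config, transducer, grid, medium, seed=7)


@pytest.fixture(scope="session")
def cell_analysis(cell_scan, cell_config, transducer, medium):
    """Bulk properties, calibrated spectra and the system constant E."""
    sample, reference = cell_scan
    props, surfaces = bulk_properties(sample, reference, medium)
    window = WindowSpec()
    spectra = calibrated_spectrum(sample, reference, surfaces, window, c_t=props.speed_of_sound)
    e_db = analytic_shape_parameter(cell_config, transducer, medium, window, c_t=props.speed_of_sound)
    return {
        "sample": sample,
        "reference": reference,
        "props": props,
        "surfaces": surfaces,
        "spectra": spectra,
        "e_db": e_db,
        "config": cell_config,
    }


@pytest.fixture(scope="session")
def phantom_scan(transducer, medium):
    """Bead phantom (10 um, alpha = 0.5) with 120 lines for ensemble tests."""
    cfg = PhantomConfig(
        scatterer_diameter_um=10.0,
        number_concentration=1000.0,
        relative_impedance=0.6,
        medium_speed=1540.0,
        attenuation_coeff=0.5,
        thickness_mm=2.0,
        rng_seed=3,
    )
    grid = AcquisitionGrid(n_lines=120, n_slices=1)
    sample, reference = simulate_scan(cfg, transducer, grid, medium, seed=3)
    return cfg, sample, reference


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
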