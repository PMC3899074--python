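"""Domain types for RF ultrasound acquisitions and the on-disk container.

A scan is a 3-D block of radio-frequency (RF) A-lines: the first axis is fast
time (axial), the second the lateral position of the transducer, the third the
elevational slice position of the motor stage.  Everything downstream — B-mode
rendering, surface detection, spectral analysis — consumes :class:`RFVolume`.

The container format is deliberately plain: a directory holding a JSON metadata
file and one little-endian float32 raw array per elevational slice
(axial-fastest ordering), so volumes diff cleanly and can be read from any
language without binary dependencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import hilbert

SCHEMA_VERSION = 1

__all__ = [
    "TransducerSpec",
    "AcquisitionGrid",
    "MediumSpec",
    "RFVolume",
    "BModeImage",
    "write_container",
    "read_container",
    "envelope_bmode",
    "export_bmode_png",
    "export_bmode_csv",
]


@dataclass(frozen=True)
class TransducerSpec:
    """Single-element high-frequency imaging transducer.

    Defaults describe a 55 MHz probe with a 20-75 MHz (-6 dB) bandwidth,
    4.5 mm focal distance and 1.5 mm depth of focus, digitized at
    420 MS/s.  ``center_frequency`` and ``bandwidth`` are in MHz,
    ``sampling_rate`` in samples/s, distances in mm.
    """

    center_frequency: float = 55.0
    bandwidth: float = 55.0
    focal_distance: float = 4.5
    depth_of_focus: float = 1.5
    sampling_rate: float = 420e6

    def __post_init__(self) -> None:
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be positive")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        lo, hi = self.band
        nyq = self.sampling_rate / 2 / 1e6
        if lo <= 0 or hi >= nyq:
            raise ValueError(
                f"band [{lo}, {hi}] MHz must lie within (0, {nyq}) MHz"
            )

    @property
    def band(self) -> tuple[float, float]:
        """Nominal analysis band (f_c - b/2, f_c + b/2) in MHz."""
        return (
            self.center_frequency - self.bandwidth / 2,
            self.center_frequency + self.bandwidth / 2,
        )


@dataclass(frozen=True)
class AcquisitionGrid:
    """Sampling geometry of a 3-D scan.

    ``axial_dt`` is the fast-time sampling interval in seconds; lateral and
    slice spacings are in micrometres (31 um between adjacent A-lines and
    200 um between adjacent B-scans by default).
    """

    axial_dt: float = 1.0 / 420e6
    lateral_spacing: float = 31.0
    slice_spacing: float = 200.0
    n_samples: int = 0
    n_lines: int = 0
    n_slices: int = 0

    def __post_init__(self) -> None:
        if self.axial_dt <= 0 or self.lateral_spacing <= 0 or self.slice_spacing <= 0:
            raise ValueError("grid spacings must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_samples, self.n_lines, self.n_slices)

    def with_shape(self, n_samples: int, n_lines: int, n_slices: int) -> "AcquisitionGrid":
        return replace(self, n_samples=n_samples, n_lines=n_lines, n_slices=n_slices)


@dataclass(frozen=True)
class MediumSpec:
    """Acoustic properties of the coupling fluid and the background matrix.

    ``c_fluid`` is the sound speed of the surrounding fluid (1480 m/s for
    culture medium at room temperature); ``rho_ecm``/``c_ecm`` are the density
    and sound speed of the extracellular matrix hosting the scatterers.
    """

    c_fluid: float = 1480.0
    rho_ecm: float = 1000.0
    c_ecm: float = 1540.0

    def __post_init__(self) -> None:
        if min(self.c_fluid, self.rho_ecm, self.c_ecm) <= 0:
            raise ValueError("medium properties must be positive")


@dataclass
class RFVolume:
    """A 3-D block of RF traces plus its acquisition metadata.

    ``samples`` has shape ``(n_samples, n_lines, n_slices)`` in arbitrary
    linear amplitude units.  ``kind`` is ``"sample"`` for a scan with the
    specimen present and ``"reference"`` for the matching water-path scan.
    """

    samples: np.ndarray
    grid: AcquisitionGrid
    transducer: TransducerSpec = field(default_factory=TransducerSpec)
    kind: str = "sample"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 3:
            raise ValueError("samples must be a 3-D array (axial, lateral, slice)")
        if self.grid.shape != self.samples.shape:
            if self.grid.shape == (0, 0, 0):
                self.grid = self.grid.with_shape(*self.samples.shape)
            else:
                raise ValueError(
                    f"grid shape {self.grid.shape} != samples shape {self.samples.shape}"
                )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")
        if self.kind not in ("sample", "reference"):
            raise ValueError("kind must be 'sample' or 'reference'")

    @property
    def times(self) -> np.ndarray:
        """Fast-time axis in seconds (round-trip time from the transducer)."""
        return np.arange(self.grid.n_samples) * self.grid.axial_dt

    def slice(self, index: int) -> np.ndarray:
        return self.samples[:, :, index]


@dataclass
class BModeImage:
    """Log-compressed envelope of one elevational slice, in dB re slice max."""

    db: np.ndarray  # (n_samples, n_lines), values in [-dynamic_range, 0]
    dynamic_range: float
    grid: AcquisitionGrid
    medium: MediumSpec = field(default_factory=MediumSpec)

    @property
    def extent_mm(self) -> tuple[float, float, float, float]:
        """(lateral_min, lateral_max, depth_max, depth_min) in mm for imshow."""
        lat = self.grid.n_lines * self.grid.lateral_spacing * 1e-3
        depth = (
            self.grid.n_samples * self.grid.axial_dt * self.medium.c_fluid / 2 * 1e3
        )
        return (0.0, lat, depth, 0.0)


# ---------------------------------------------------------------------------
# container I/O


def _transducer_to_dict(t: TransducerSpec) -> dict:
    return {
        "center_frequency_mhz": t.center_frequency,
        "bandwidth_mhz": t.bandwidth,
        "focal_distance_mm": t.focal_distance,
        "depth_of_focus_mm": t.depth_of_focus,
        "sampling_rate_hz": t.sampling_rate,
    }


def _grid_to_dict(g: AcquisitionGrid) -> dict:
    return {
        "axial_dt_s": g.axial_dt,
        "lateral_spacing_um": g.lateral_spacing,
        "slice_spacing_um": g.slice_spacing,
        "n_samples": g.n_samples,
        "n_lines": g.n_lines,
        "n_slices": g.n_slices,
    }


def write_container(volume: RFVolume, path: str | Path, provenance: dict | None = None) -> Path:
    """Write ``volume`` to a directory container.

    Layout: ``meta.json`` plus ``slice_NNN.f32`` (little-endian float32,
    axial-fastest ordering) per elevational slice.  Round trip through
    :func:`read_container` is byte-exact at 32-bit precision.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "kind": volume.kind,
        "transducer": _transducer_to_dict(volume.transducer),
        "grid": _grid_to_dict(volume.grid),
        "provenance": provenance or {},
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    for k in range(volume.grid.n_slices):
        # axial-fastest on disk: one contiguous A-line after another
        arr = np.ascontiguousarray(volume.samples[:, :, k].T, dtype="<f4")
        arr.tofile(path / f"slice_{k:03d}.f32")
    return path


def read_container(path: str | Path) -> RFVolume:
    """Read a container written by :func:`write_container`."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no meta.json in {path}")
    meta = json.loads(meta_path.read_text())
    version = meta.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {version!r}")
    t = meta["transducer"]
    transducer = TransducerSpec(
        center_frequency=t["center_frequency_mhz"],
        bandwidth=t["bandwidth_mhz"],
        focal_distance=t["focal_distance_mm"],
        depth_of_focus=t["depth_of_focus_mm"],
        sampling_rate=t["sampling_rate_hz"],
    )
    g = meta["grid"]
    grid = AcquisitionGrid(
        axial_dt=g["axial_dt_s"],
        lateral_spacing=g["lateral_spacing_um"],
        slice_spacing=g["slice_spacing_um"],
        n_samples=g["n_samples"],
        n_lines=g["n_lines"],
        n_slices=g["n_slices"],
    )
    files = sorted(path.glob("slice_*.f32"))
    if len(files) != grid.n_slices:
        raise ValueError(
            f"metadata declares {grid.n_slices} slices but {len(files)} arrays present"
        )
    samples = np.empty(grid.shape, dtype=np.float64)
    for k, f in enumerate(files):
        raw = np.fromfile(f, dtype="<f4")
        if raw.size != grid.n_samples * grid.n_lines:
            raise ValueError(f"{f.name}: expected {grid.n_samples * grid.n_lines} samples, got {raw.size}")
        samples[:, :, k] = raw.reshape((grid.n_lines, grid.n_samples)).T
    if not np.all(np.isfinite(samples)):
        raise ValueError("container holds non-finite RF samples")
    return RFVolume(samples=samples, grid=grid, transducer=transducer, kind=meta["kind"])


# ---------------------------------------------------------------------------
# envelope / B-mode


def envelope(trace_block: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal along axis 0."""
    return np.abs(hilbert(trace_block, axis=0))


def envelope_bmode(
    volume: RFVolume,
    slice_index: int = 0,
    dynamic_range_db: float = 50.0,
    medium: MediumSpec | None = None,
) -> BModeImage:
    """Log-compressed B-mode image of one slice.

    The envelope is the magnitude of the analytic signal of each A-line;
    compression is 20*log10 relative to the slice maximum, clipped to
    ``[-dynamic_range_db, 0]``.  An all-zero slice maps to a uniform floor
    at ``-dynamic_range_db`` rather than raising on the log of zero.
    """
    if dynamic_range_db <= 0:
        raise ValueError("dynamic_range_db must be positive")
    if not 0 <= slice_index < volume.grid.n_slices:
        raise IndexError(f"slice_index {slice_index} out of range")
    env = envelope(volume.slice(slice_index))
    peak = env.max()
    if peak == 0:
        db = np.full(env.shape, -dynamic_range_db)
    else:
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(env / peak)
        db = np.clip(db, -dynamic_range_db, 0.0)
    return BModeImage(
        db=db,
        dynamic_range=dynamic_range_db,
        grid=volume.grid,
        medium=medium or MediumSpec(),
    )


def export_bmode_png(image: BModeImage, path: str | Path) -> Path:
    """Save the B-mode as an 8-bit grayscale PNG (0 = floor, 255 = 0 dB)."""
    from PIL import Image

    scaled = (image.db + image.dynamic_range) / image.dynamic_range
    arr = np.round(scaled * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))
    return Path(path)


def export_bmode_csv(image: BModeImage, path: str | Path) -> Path:
    """Save the dB values of the B-mode as CSV (rows = axial samples)."""
    np.savetxt(Path(path), image.db, delimiter=",", fmt="%.3f")
    return Path(path)
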