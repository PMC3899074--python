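"""Parametric color maps of scatterer properties overlaid on B-mode images.

Window-level estimates (diameter, acoustic concentration, MBF, slope, calcium
concentration) are rasterized onto the pixel grid of a B-mode slice —
nearest-window by default, optionally bilinear — and rendered as a
semi-transparent color overlay with a colorbar.  Pixels outside the analysed
region, or belonging to windows whose inversion was non-physical, stay
transparent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rf import BModeImage

PARAMETER_COLUMNS = {
    "diameter": "diameter_um",
    "calcium": "calcium_ug_per_ml",
    "mbf": "mbf",
    "slope": "slope",
    "cq2": "cq2_mm3",
}

PARAMETER_LABELS = {
    "diameter": "scatterer diameter (um)",
    "calcium": "calcium concentration (ug/ml)",
    "mbf": "mid-band fit (dB)",
    "slope": "spectral slope (dB/MHz)",
    "cq2": "acoustic concentration (mm^-3)",
}

__all__ = ["ParametricMap", "build_parametric_map", "render_overlay", "PARAMETER_COLUMNS"]


@dataclass
class ParametricMap:
    """Per-pixel parameter values aligned to one B-mode slice."""

    parameter: str
    values: np.ndarray  # (n_samples, n_lines), NaN outside mask
    mask: np.ndarray  # bool, True where a valid window value applies
    value_range: tuple[float, float]
    colormap: str = "viridis"

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must share their shape")


def build_parametric_map(
    bmode: BModeImage,
    window_table: pd.DataFrame,
    parameter: str,
    slice_index: int = 0,
    interpolation: str = "nearest",
    colormap: str = "viridis",
    value_range: tuple[float, float] | None = None,
    window_samples: int | None = None,
    lines_per_group: int | None = None,
) -> ParametricMap:
    """Rasterize window estimates for one slice onto the B-mode pixel grid.

    The covered region is the union of window footprints (half a gate long,
    half a line group wide around each window centre); each covered pixel
    takes the value of its nearest window centre (or a bilinear blend with
    ``interpolation="linear"``).  Windows with NaN values are dropped from the
    rasterization, so their footprint stays transparent unless covered by a
    neighbour.
    """
    if parameter not in PARAMETER_COLUMNS:
        raise KeyError(
            f"unknown parameter {parameter!r}; choose from {sorted(PARAMETER_COLUMNS)}"
        )
    column = PARAMETER_COLUMNS[parameter]
    if column not in window_table.columns:
        raise KeyError(f"window table lacks column {column!r}")
    df = window_table[window_table["slice"] == slice_index]
    shape = bmode.db.shape
    values = np.full(shape, np.nan)
    mask = np.zeros(shape, dtype=bool)
    df = df.dropna(subset=[column, "axial_sample", "line_center"])
    if df.empty:
        return ParametricMap(parameter, values, mask, (0.0, 0.0), colormap)

    ax = df["axial_sample"].to_numpy()
    ln = df["line_center"].to_numpy()
    val = df[column].to_numpy(dtype=float)
    if window_samples is not None:
        half_ax = window_samples / 2.0
    else:
        uniq = np.unique(ax)
        half_ax = float(np.min(np.diff(uniq))) if uniq.size > 1 else 64.0
    half_ln = (lines_per_group or 5) / 2.0

    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    for a, l in zip(ax, ln):
        mask |= (np.abs(rows - a) <= half_ax) & (np.abs(cols - l) <= half_ln)

    rr, cc = np.nonzero(mask)
    if interpolation == "nearest":
        from scipy.spatial import cKDTree

        # normalize axes so axial and lateral distances are in window units
        tree = cKDTree(np.column_stack([ax / max(half_ax, 1), ln / max(half_ln, 1)]))
        _, idx = tree.query(
            np.column_stack([rr / max(half_ax, 1), cc / max(half_ln, 1)])
        )
        values[rr, cc] = val[idx]
    elif interpolation == "linear":
        from scipy.interpolate import griddata

        pts = np.column_stack([ax, ln])
        interp = griddata(pts, val, np.column_stack([rr, cc]), method="linear")
        nearest = griddata(pts, val, np.column_stack([rr, cc]), method="nearest")
        interp = np.where(np.isnan(interp), nearest, interp)
        values[rr, cc] = interp
    else:
        raise ValueError("interpolation must be 'nearest' or 'linear'")

    finite = values[np.isfinite(values)]
    if value_range is None:
        value_range = (
            (float(finite.min()), float(finite.max())) if finite.size else (0.0, 0.0)
        )
    mask &= np.isfinite(values)
    return ParametricMap(parameter, values, mask, value_range, colormap)


def render_overlay(
    bmode: BModeImage,
    pmap: ParametricMap,
    out_path,
    alpha: float = 0.6,
    title: str | None = None,
    dpi: int = 100,
):
    """Render B-mode underlay plus color overlay to a PNG with a colorbar.

    Rendering is deterministic: identical inputs produce byte-identical files.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if bmode.db.shape != pmap.values.shape:
        raise ValueError("B-mode and parametric map geometries do not match")
    fig, axis = plt.subplots(figsize=(6, 5), dpi=dpi)
    extent = bmode.extent_mm
    axis.imshow(
        bmode.db, cmap="gray", aspect="auto", extent=extent,
        vmin=-bmode.dynamic_range, vmax=0.0,
    )
    overlay = np.ma.masked_where(~pmap.mask, pmap.values)
    vmin, vmax = pmap.value_range
    if vmin == vmax:
        vmax = vmin + 1.0
    im = axis.imshow(
        overlay, cmap=pmap.colormap, aspect="auto", extent=extent,
        vmin=vmin, vmax=vmax, alpha=alpha,
    )
    fig.colorbar(im, ax=axis, label=PARAMETER_LABELS.get(pmap.parameter, pmap.parameter))
    axis.set_xlabel("lateral (mm)")
    axis.set_ylabel("depth (mm)")
    axis.set_title(title or pmap.parameter)
    fig.savefig(out_path, metadata={"Software": "susi"})
    plt.close(fig)
    return out_path
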