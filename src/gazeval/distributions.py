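"""Numeric cores of the standard gaze-quality visualizations.

Everything here returns plain arrays/dataclasses so the aggregates can be
tested and exported without a plotting backend; :func:`render` is a thin
matplotlib layer that only draws what these functions computed.

* :func:`kde_curve` — Gaussian kernel density estimate of an error
  distribution (default bandwidth 0.2°), the numeric core of the error
  distribution curves.
* :func:`error_surface` — mean angular error over an nx×ny partition of
  the screen (the "3-D error magnitude over the display" plot).
* :func:`eccentricity_surface` — the same aggregation over yaw/pitch
  visual-angle bins.
* :func:`stacked_histograms` — normalized histograms of several datasets
  on shared edges (stacked distribution comparison).
* :func:`point_density` — 2-D Gaussian KDE (Scott bandwidth) evaluated at
  each gaze point, for density-colored scatter plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import ScreenGeometry, ValidationError
from .similarity import Histogram, build_histogram

__all__ = [
    "KdeCurve",
    "GridSurface",
    "kde_curve",
    "error_surface",
    "eccentricity_surface",
    "stacked_histograms",
    "point_density",
    "render",
]


@dataclass
class KdeCurve:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        """Trapezoidal integral of the density over the grid."""
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class GridSurface:
    """Mean error per cell of a 2-D partition; empty cells are NaN, not 0."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    cell_value: np.ndarray
    cell_count: np.ndarray

    @property
    def n_samples(self) -> int:
        return int(self.cell_count.sum())


def kde_curve(
    errors,
    bandwidth: float = 0.2,
    grid_points: int = 200,
    allow_single: bool = False,
) -> KdeCurve:
    """Gaussian KDE of an error sample on a grid spanning data ± 4 bandwidths.

    density(g) = (1/(n·h)) Σᵢ φ((g − xᵢ)/h) with φ the standard normal
    density and h the bandwidth in degrees.
    """
    x = np.asarray(errors, dtype=float).ravel()
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if x.size < 2 and not allow_single:
        raise ValidationError("need at least 2 samples (or allow_single=True)")
    if x.size == 0:
        raise ValidationError("empty sample")
    h = bandwidth
    grid = np.linspace(x.min() - 4 * h, x.max() + 4 * h, grid_points)
    z = (grid[:, None] - x[None, :]) / h
    density = np.exp(-0.5 * z**2).sum(axis=1) / (x.size * h * np.sqrt(2 * np.pi))
    return KdeCurve(grid, density, h)


def _mean_surface(x, y, values, x_edges, y_edges) -> GridSurface:
    mean, _, _, _ = sps.binned_statistic_2d(x, y, values, statistic="mean", bins=[x_edges, y_edges])
    count, _, _, _ = sps.binned_statistic_2d(x, y, values, statistic="count", bins=[x_edges, y_edges])
    return GridSurface(np.asarray(x_edges), np.asarray(y_edges), mean, count.astype(int))


def error_surface(session: pd.DataFrame, screen: ScreenGeometry, nx: int = 8, ny: int = 5) -> GridSurface:
    """Mean ``DIFF GZ`` over an nx×ny equal-cell partition of the display.

    Samples are assigned to cells by their ground-truth (target) position;
    off-screen targets are invalid input.
    """
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 cells per axis")
    gx = session["GTX"].to_numpy(float)
    gy = session["GTY"].to_numpy(float)
    if (np.abs(gx) > screen.half_width_px).any() or (np.abs(gy) > screen.half_height_px).any():
        raise ValidationError("session has off-screen ground-truth points")
    x_edges = np.linspace(-screen.half_width_px, screen.half_width_px, nx + 1)
    y_edges = np.linspace(-screen.half_height_px, screen.half_height_px, ny + 1)
    return _mean_surface(gx, gy, session["DIFF GZ"].to_numpy(float), x_edges, y_edges)


def eccentricity_surface(session: pd.DataFrame, yaw_bins: int = 8, pitch_bins: int = 8) -> GridSurface:
    """Mean ``DIFF GZ`` over estimated yaw/pitch visual-angle bins (degrees)."""
    if yaw_bins < 2 or pitch_bins < 2:
        raise ValueError("need at least 2 bins per axis")
    yaw = session["YAW DATA"].to_numpy(float)
    pitch = session["PITCH DATA"].to_numpy(float)
    pad = 1e-9  # keep the extreme samples inside the outer bins
    x_edges = np.linspace(yaw.min() - pad, yaw.max() + pad, yaw_bins + 1)
    y_edges = np.linspace(pitch.min() - pad, pitch.max() + pad, pitch_bins + 1)
    return _mean_surface(yaw, pitch, session["DIFF GZ"].to_numpy(float), x_edges, y_edges)


def stacked_histograms(datasets, bins: int = 32) -> list[Histogram]:
    """Normalized histograms of ≥ 2 datasets on shared global-range edges."""
    arrays = [np.asarray(d, float).ravel() for d in datasets]
    if len(arrays) < 2:
        raise ValidationError("need at least two datasets to stack")
    if any(a.size == 0 for a in arrays):
        raise ValidationError("empty dataset in stack")
    lo = min(a.min() for a in arrays)
    hi = max(a.max() for a in arrays)
    if not hi > lo:
        raise ValidationError("degenerate range: all pooled values identical")
    edges = np.linspace(lo, hi, bins + 1)
    return [build_histogram(a, edges) for a in arrays]


def point_density(x, y) -> np.ndarray:
    """2-D Gaussian KDE (Scott bandwidth) evaluated at each input point."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValidationError("need at least 3 (x, y) points")
    try:
        kde = sps.gaussian_kde(np.vstack([x, y]))
    except np.linalg.LinAlgError as exc:
        raise ValidationError(f"degenerate point cloud: {exc}") from exc
    return kde(np.vstack([x, y]))


def _sidecar_frame(obj) -> pd.DataFrame:
    if isinstance(obj, KdeCurve):
        return pd.DataFrame({"grid_deg": obj.grid, "density": obj.density})
    if isinstance(obj, GridSurface):
        xc = 0.5 * (obj.x_edges[:-1] + obj.x_edges[1:])
        yc = 0.5 * (obj.y_edges[:-1] + obj.y_edges[1:])
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        return pd.DataFrame(
            {
                "x_center": xx.ravel(),
                "y_center": yy.ravel(),
                "mean_error_deg": obj.cell_value.ravel(),
                "count": obj.cell_count.ravel(),
            }
        )
    if isinstance(obj, list) and obj and isinstance(obj[0], Histogram):
        cols = {"bin_left": obj[0].bin_edges[:-1], "bin_right": obj[0].bin_edges[1:]}
        for i, h in enumerate(obj):
            cols[f"p{i}"] = h.probabilities
        return pd.DataFrame(cols)
    raise ValueError(f"cannot serialize object of type {type(obj).__name__}")


def render(obj, path, kind: str | None = None, sidecar: bool = True) -> None:
    """Write a PNG/SVG of a numeric structure (plus a CSV sidecar of it).

    Purely presentational: every number drawn was computed beforehand by
    the functions above.  ``kind`` defaults to a choice based on the
    object type: ``kde`` for curves, ``surface`` for grid surfaces,
    ``hist3d`` for histogram stacks.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if kind is None:
        kind = {KdeCurve: "kde", GridSurface: "surface"}.get(type(obj), "hist3d" if isinstance(obj, list) else None)
    if kind not in ("kde", "surface", "ecc", "hist3d"):
        raise ValueError(f"unknown render kind {kind!r}")

    fig, ax = plt.subplots(figsize=(6, 4))
    try:
        if kind == "kde":
            ax.plot(obj.grid, obj.density)
            ax.set_xlabel("gaze error (deg)")
            ax.set_ylabel("density")
        elif kind in ("surface", "ecc"):
            masked = np.ma.masked_invalid(obj.cell_value.T)
            im = ax.pcolormesh(obj.x_edges, obj.y_edges, masked)
            fig.colorbar(im, ax=ax, label="mean error (deg)")
            unit = "deg" if kind == "ecc" else "px"
            ax.set_xlabel(f"x ({unit})")
            ax.set_ylabel(f"y ({unit})")
        else:
            width = np.diff(obj[0].bin_edges)
            bottom = np.zeros_like(obj[0].probabilities)
            for i, h in enumerate(obj):
                ax.bar(h.bin_edges[:-1], h.probabilities, width=width, bottom=bottom,
                       align="edge", label=f"dataset {i}", alpha=0.8)
                bottom = bottom + h.probabilities
            ax.legend()
            ax.set_xlabel("gaze error (deg)")
            ax.set_ylabel("probability")
        fig.savefig(path)
    finally:
        plt.close(fig)
    if sidecar:
        _sidecar_frame(obj).to_csv(str(path) + ".csv", index=False)
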