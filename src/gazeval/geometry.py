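"""Visual-angle geometry: pixels → mm → gaze angles → angular accuracy.

The viewing model is a single cyclopean eye on the perpendicular through
the display center at distance ``d``.  A screen point at ``(x, y)`` mm from
the center subtends

* yaw   = atan(x / d)          (horizontal angle, signed, +right)
* pitch = atan(y / d)          (vertical angle, signed, +up)
* primary = atan(sqrt(x² + y²) / d)   (total eccentricity, ≥ 0)

all reported in degrees.  Gaze angular accuracy (``DIFF GZ``) is the
absolute difference between ground-truth and estimated primary angles; a
direction-sensitive alternative, the angle between the two 3-D gaze
vectors, is available as :func:`angle_between_3d`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    PROCESSED_COLUMNS,
    ScreenGeometry,
    SessionMeta,
    ValidationError,
)

__all__ = [
    "AngleTriple",
    "px_to_mm",
    "mm_to_px",
    "point_angles",
    "angles_from_mm",
    "angular_errors",
    "angle_between_3d",
    "assign_aoi",
    "process_session",
]


@dataclass(frozen=True)
class AngleTriple:
    """Yaw, pitch and primary (total eccentricity) angle of one gaze point."""

    yaw_deg: float
    pitch_deg: float
    primary_deg: float

    def __post_init__(self) -> None:
        if self.primary_deg < 0:
            raise ValidationError("primary angle is non-negative by construction")


def px_to_mm(x_px, y_px, geometry: ScreenGeometry):
    """Convert display-center pixel coordinates to millimetres."""
    mu = geometry.pixel_pitch_mm
    return np.multiply(x_px, mu), np.multiply(y_px, mu)


def mm_to_px(x_mm, y_mm, geometry: ScreenGeometry):
    """Inverse of :func:`px_to_mm`."""
    mu = geometry.pixel_pitch_mm
    return np.divide(x_mm, mu), np.divide(y_mm, mu)


def angles_from_mm(x_mm, y_mm, user_distance_mm):
    """Vectorized (yaw, pitch, primary) in degrees for mm coordinates."""
    d = np.asarray(user_distance_mm, float)
    if not (d > 0).all():
        raise ValidationError("user distance must be positive")
    x = np.asarray(x_mm, float)
    y = np.asarray(y_mm, float)
    yaw = np.degrees(np.arctan2(x, d))
    pitch = np.degrees(np.arctan2(y, d))
    primary = np.degrees(np.arctan2(np.hypot(x, y), d))
    return yaw, pitch, primary


def point_angles(x_mm: float, y_mm: float, user_distance_mm: float) -> AngleTriple:
    """Gaze angles of a single screen point (mm, display-center origin)."""
    yaw, pitch, primary = angles_from_mm(x_mm, y_mm, user_distance_mm)
    return AngleTriple(float(yaw), float(pitch), float(primary))


def angular_errors(gaze: AngleTriple, truth: AngleTriple):
    """Absolute primary/yaw/pitch angular errors in degrees."""
    return (
        abs(truth.primary_deg - gaze.primary_deg),
        abs(truth.yaw_deg - gaze.yaw_deg),
        abs(truth.pitch_deg - gaze.pitch_deg),
    )


def angle_between_3d(x1_mm, y1_mm, x2_mm, y2_mm, user_distance_mm):
    """Angle in degrees between the 3-D gaze vectors to two screen points.

    Unlike the primary-angle difference this is sensitive to direction:
    two points at equal eccentricity on opposite sides of the center give
    a nonzero angle here but zero primary-angle difference.
    """
    d = user_distance_mm
    v1 = np.stack(np.broadcast_arrays(x1_mm, y1_mm, np.full_like(np.asarray(x1_mm, float), d)), axis=-1)
    v2 = np.stack(np.broadcast_arrays(x2_mm, y2_mm, np.full_like(np.asarray(x2_mm, float), d)), axis=-1)
    cross = np.linalg.norm(np.cross(v1, v2), axis=-1)
    dot = np.sum(v1 * v2, axis=-1)
    return np.degrees(np.arctan2(cross, dot))


def assign_aoi(gt_x, gt_y):
    """Run-length stimulus indices for a piecewise-constant target sequence.

    Consecutive samples sharing the same ground-truth point form one
    fixation episode (area of interest).  Indices count *runs* in time
    order starting at 0, so a revisited location gets a fresh index.
    """
    gt_x = np.asarray(gt_x, float)
    gt_y = np.asarray(gt_y, float)
    if gt_x.size == 0:
        return np.array([], dtype=int)
    new_run = np.ones(gt_x.size, dtype=bool)
    new_run[1:] = (gt_x[1:] != gt_x[:-1]) | (gt_y[1:] != gt_y[:-1])
    return np.cumsum(new_run) - 1


def process_session(
    meta: SessionMeta, geometry: ScreenGeometry, samples: pd.DataFrame
) -> pd.DataFrame:
    """Convert a raw session into the 21-column processed format.

    Populates mm coordinates, ground-truth and estimated yaw/pitch/primary
    angles, the angular accuracy column ``DIFF GZ`` and, per stimulus
    (AOI), the mean and sample standard deviation of ``DIFF GZ`` repeated
    on every row of that AOI.  Single-sample AOIs get a standard deviation
    of 0.
    """
    samples = pd.DataFrame(samples)
    if len(samples) == 0:
        raise ValidationError("cannot process an empty session")
    d = meta.user_distance_mm

    gt_x_px = samples["gt_x_px"].to_numpy(float)
    gt_y_px = samples["gt_y_px"].to_numpy(float)
    gz_x_px = samples["gaze_x_px"].to_numpy(float)
    gz_y_px = samples["gaze_y_px"].to_numpy(float)

    gt_xmm, gt_ymm = px_to_mm(gt_x_px, gt_y_px, geometry)
    xmm, ymm = px_to_mm(gz_x_px, gz_y_px, geometry)

    yaw_gt, pitch_gt, gaze_gt = angles_from_mm(gt_xmm, gt_ymm, d)
    yaw_dt, pitch_dt, gaze_ang = angles_from_mm(xmm, ymm, d)
    diff_gz = np.abs(gaze_gt - gaze_ang)

    aoi = assign_aoi(gt_x_px, gt_y_px)
    t = samples["t_ms"].to_numpy(float)

    out = pd.DataFrame(
        {
            "TIM REL": t - t[0],
            "GTX": gt_x_px,
            "GTY": gt_y_px,
            "XRAW": gz_x_px,
            "YRAW": gz_y_px,
            "GT Xmm": gt_xmm,
            "GT Ymm": gt_ymm,
            "Xmm": xmm,
            "Ymm": ymm,
            "YAW GT": yaw_gt,
            "YAW DATA": yaw_dt,
            "PITCH GT": pitch_gt,
            "PITCH DATA": pitch_dt,
            "GAZE GT": gaze_gt,
            "GAZE ANG": gaze_ang,
            "DIFF GZ": diff_gz,
            "AOI": aoi,
            "AOI_X": gt_x_px,
            "AOI_Y": gt_y_px,
        }
    )
    grouped = out.groupby("AOI")["DIFF GZ"]
    out["MEAN_ERR"] = grouped.transform("mean")
    out["STD ERR"] = grouped.transform(lambda s: s.std(ddof=1)).fillna(0.0)
    return out[list(PROCESSED_COLUMNS)]


def recompute_aoi_stats(session: pd.DataFrame) -> pd.DataFrame:
    """Refresh MEAN_ERR / STD ERR from the current DIFF GZ values."""
    out = session.copy()
    grouped = out.groupby("AOI")["DIFF GZ"]
    out["MEAN_ERR"] = grouped.transform("mean")
    out["STD ERR"] = grouped.transform(lambda s: s.std(ddof=1)).fillna(0.0)
    return out
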