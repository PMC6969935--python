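"""CSV readers/writers and validators for gaze-session files.

Two dialects are supported:

* the *raw* session file: per-sample gaze and ground-truth screen
  coordinates in pixels (display-center origin, +x right, +y up) together
  with the display geometry and user distance repeated on every row, so a
  file is self-describing;
* the *processed* session file: the 21-column evaluation format carrying
  millimetre coordinates, yaw/pitch/primary gaze angles, the angular
  accuracy column ``DIFF GZ`` and per-stimulus error aggregates.

Both are plain comma-separated UTF-8 text with a mandatory header row and
"." as the decimal mark.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PLATFORMS",
    "RAW_COLUMNS",
    "PROCESSED_COLUMNS",
    "ScreenGeometry",
    "SessionMeta",
    "FormatError",
    "ValidationError",
    "EmptyInputError",
    "session_filename",
    "parse_session_filename",
    "read_raw_session",
    "write_raw_session",
    "read_processed_session",
    "write_processed_session",
    "validate_processed",
]

#: Recognised acquisition platforms.
PLATFORMS = ("desk", "lap", "tab")

#: Raw-session column layout.  The last four values are session metadata,
#: repeated on every row; readers take them from the first data row.
RAW_COLUMNS = (
    "TIME_MS",
    "XRAW",
    "YRAW",
    "GTX",
    "GTY",
    "RES_X",
    "RES_Y",
    "PIX_PITCH",
    "USER_DIST",
)

#: The 21 columns of a processed session file, in file order.
PROCESSED_COLUMNS = (
    "TIM REL",
    "GTX",
    "GTY",
    "XRAW",
    "YRAW",
    "GT Xmm",
    "GT Ymm",
    "Xmm",
    "Ymm",
    "YAW GT",
    "YAW DATA",
    "PITCH GT",
    "PITCH DATA",
    "GAZE GT",
    "GAZE ANG",
    "DIFF GZ",
    "AOI",
    "AOI_X",
    "AOI_Y",
    "MEAN_ERR",
    "STD ERR",
)


class FormatError(ValueError):
    """A file does not have the expected columns / layout."""


class ValidationError(ValueError):
    """A file has the right layout but invalid content."""


class EmptyInputError(ValidationError):
    """A file or sequence contains no data rows."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical description of the display on which gaze was tracked.

    Parameters
    ----------
    res_x, res_y:
        Display resolution in pixels.
    pixel_pitch_mm:
        Physical size of one pixel in millimetres (the conversion factor
        between pixel and millimetre coordinates).
    platform_label:
        One of ``desk``, ``lap``, ``tab``.
    """

    res_x: int
    res_y: int
    pixel_pitch_mm: float
    platform_label: str = "desk"

    def __post_init__(self) -> None:
        if self.res_x <= 0 or self.res_y <= 0:
            raise ValidationError("display resolution must be positive")
        if not self.pixel_pitch_mm > 0:
            raise ValidationError("pixel pitch must be positive")
        if self.platform_label not in PLATFORMS:
            raise ValidationError(
                f"platform_label must be one of {PLATFORMS}, "
                f"got {self.platform_label!r}"
            )

    @property
    def half_width_px(self) -> float:
        return self.res_x / 2.0

    @property
    def half_height_px(self) -> float:
        return self.res_y / 2.0


@dataclass(frozen=True)
class SessionMeta:
    """Identity and acquisition parameters of one recording session."""

    user_id: int
    condition_label: str
    platform_label: str
    user_distance_mm: float
    sampling_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        if self.user_id < 1:
            raise ValidationError("user ids start at 1")
        if not self.user_distance_mm > 0:
            raise ValidationError("user distance must be positive")
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling rate must be positive")
        if self.platform_label not in PLATFORMS:
            raise ValidationError(
                f"platform_label must be one of {PLATFORMS}, "
                f"got {self.platform_label!r}"
            )


_FILENAME_RE = re.compile(r"^us(\d{2})_([A-Za-z0-9]+)_(desk|lap|tab)\.csv$")


def session_filename(meta: SessionMeta) -> str:
    """File name for a session: ``usNN_CONDITION_PLATFORM.csv``.

    User numbers are zero padded to two digits (``us01_80_desk.csv``), so
    only ids 1..99 are representable.
    """
    if meta.user_id >= 100:
        raise ValidationError("user_id must be < 100 for the usNN naming scheme")
    return f"us{meta.user_id:02d}_{meta.condition_label}_{meta.platform_label}.csv"


def parse_session_filename(name: str) -> tuple[int, str, str] | None:
    """Inverse of :func:`session_filename`; ``None`` if the name does not match."""
    m = _FILENAME_RE.match(os.path.basename(name))
    if m is None:
        return None
    return int(m.group(1)), m.group(2), m.group(3)


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def _coerce_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    """Convert all cells to float, rejecting non-numeric or missing values."""
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna()
    if bad.to_numpy().any():
        rows = np.flatnonzero(bad.any(axis=1))
        cols = [c for c in out.columns if bad[c].any()]
        raise ValidationError(
            f"{path}: non-numeric or NaN values in column(s) {cols} "
            f"at row(s) {rows[:10].tolist()}"
        )
    return out


def read_raw_session(path, strict: bool = True):
    """Read a raw gaze session file.

    Returns ``(meta, geometry, samples)`` where *samples* is a DataFrame
    with columns ``t_ms, gaze_x_px, gaze_y_px, gt_x_px, gt_y_px`` in file
    order.  Display geometry and user distance are taken from the first
    data row.  User id, condition and platform are recovered from the file
    name when it follows the ``usNN_CONDITION_PLATFORM.csv`` convention,
    otherwise placeholder values are used.  The sampling rate is inferred
    from the median timestamp increment.

    With ``strict=True`` ground-truth points are additionally required to
    lie on the display (gaze estimates may fall off screen; targets cannot).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    _require_columns(df, RAW_COLUMNS, path)
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")
    df = _coerce_numeric(df[list(RAW_COLUMNS)], path)

    first = df.iloc[0]
    geometry = ScreenGeometry(
        res_x=int(first["RES_X"]),
        res_y=int(first["RES_Y"]),
        pixel_pitch_mm=float(first["PIX_PITCH"]),
        platform_label=_platform_from_name(path),
    )
    t = df["TIME_MS"].to_numpy(float)
    dt = np.diff(t)
    rate = 1000.0 / float(np.median(dt)) if dt.size and np.median(dt) > 0 else 60.0

    parsed = parse_session_filename(path)
    user_id, condition = (parsed[0], parsed[1]) if parsed else (1, "NA")
    meta = SessionMeta(
        user_id=user_id,
        condition_label=condition,
        platform_label=geometry.platform_label,
        user_distance_mm=float(first["USER_DIST"]),
        sampling_rate_hz=rate,
    )

    samples = pd.DataFrame(
        {
            "t_ms": t,
            "gaze_x_px": df["XRAW"].to_numpy(float),
            "gaze_y_px": df["YRAW"].to_numpy(float),
            "gt_x_px": df["GTX"].to_numpy(float),
            "gt_y_px": df["GTY"].to_numpy(float),
        }
    )
    if strict:
        gx, gy = samples["gt_x_px"].to_numpy(), samples["gt_y_px"].to_numpy()
        on = (np.abs(gx) <= geometry.half_width_px) & (
            np.abs(gy) <= geometry.half_height_px
        )
        if not on.all():
            raise ValidationError(
                f"{path}: ground-truth points off screen at row(s) "
                f"{np.flatnonzero(~on)[:10].tolist()}"
            )
    return meta, geometry, samples


def _platform_from_name(path) -> str:
    parsed = parse_session_filename(path)
    return parsed[2] if parsed else "desk"


def write_raw_session(path, meta: SessionMeta, geometry: ScreenGeometry, samples) -> None:
    """Write a raw session file in the layout read by :func:`read_raw_session`."""
    samples = pd.DataFrame(samples)
    if len(samples) == 0:
        raise EmptyInputError("refusing to write an empty raw session")
    out = pd.DataFrame(
        {
            "TIME_MS": samples["t_ms"].to_numpy(float),
            "XRAW": samples["gaze_x_px"].to_numpy(float),
            "YRAW": samples["gaze_y_px"].to_numpy(float),
            "GTX": samples["gt_x_px"].to_numpy(float),
            "GTY": samples["gt_y_px"].to_numpy(float),
            "RES_X": geometry.res_x,
            "RES_Y": geometry.res_y,
            "PIX_PITCH": geometry.pixel_pitch_mm,
            "USER_DIST": meta.user_distance_mm,
        }
    )
    out.to_csv(path, index=False, lineterminator="\n")


def read_processed_session(path) -> pd.DataFrame:
    """Read a 21-column processed session file.

    The header must carry exactly the 21 canonical column names in
    canonical order; any deviation is a :class:`FormatError`.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if tuple(df.columns) != PROCESSED_COLUMNS:
        raise FormatError(
            f"{path}: expected the 21 canonical processed columns, "
            f"got {list(df.columns)}"
        )
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")
    df = _coerce_numeric(df, path)
    validate_processed(df)
    return df


def write_processed_session(path, session: pd.DataFrame) -> None:
    """Write a processed session; the header is byte-identical across writes."""
    session = pd.DataFrame(session)
    if len(session) == 0:
        raise EmptyInputError("refusing to write an empty processed session")
    if tuple(session.columns) != PROCESSED_COLUMNS:
        raise FormatError(
            "processed session must have exactly the 21 canonical columns "
            f"in order; got {list(session.columns)}"
        )
    validate_processed(session)
    session.to_csv(path, index=False, lineterminator="\n")


def validate_processed(session: pd.DataFrame, pixel_pitch_mm: float | None = None) -> None:
    """Check processed-session invariants.

    ``DIFF GZ`` must be non-negative and all cells finite.  When the pixel
    pitch is supplied, the mm columns are checked against the pixel columns
    to 1e-9 mm.
    """
    arr = session.to_numpy(float)
    if not np.isfinite(arr).all():
        raise ValidationError("processed session contains non-finite values")
    if (session["DIFF GZ"].to_numpy(float) < 0).any():
        raise ValidationError("DIFF GZ must be non-negative")
    if pixel_pitch_mm is not None:
        for px, mm in (("GTX", "GT Xmm"), ("GTY", "GT Ymm"), ("XRAW", "Xmm"), ("YRAW", "Ymm")):
            expect = session[px].to_numpy(float) * pixel_pitch_mm
            if not np.allclose(session[mm].to_numpy(float), expect, atol=1e-9, rtol=0):
                raise ValidationError(f"{mm} inconsistent with {px} * pixel pitch")
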