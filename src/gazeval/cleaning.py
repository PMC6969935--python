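"""Outlier detection/removal and median-filter denoising for gaze error series.

Gaze recordings are nearly always contaminated by sporadic spikes (blinks,
track losses, reflections); error patterns only become visible once these
are removed.  Three robust strategies are provided:

* ``median_filter`` — flag samples far from their 1-D median-filtered value
  (also usable as a plain smoother);
* ``mad`` — flag samples more than ``k`` scaled median absolute deviations
  from the median (scale 1.4826 makes the MAD consistent for Gaussian data);
* ``iqr`` — Tukey fences at Q1 − f·IQR and Q3 + f·IQR with quartiles by
  linear interpolation.

All masks are invariant under adding a constant to the series; the MAD and
IQR masks are additionally invariant under positive scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import recompute_aoi_stats
from .io_formats import ValidationError

__all__ = [
    "MAD_SCALE",
    "OutlierResult",
    "median_filter",
    "detect_outliers_median_filter",
    "detect_outliers_mad",
    "detect_outliers_iqr",
    "remove_outliers",
]

#: Gaussian-consistency scale for the median absolute deviation.
MAD_SCALE = 1.4826


@dataclass
class OutlierResult:
    """Boolean outlier mask plus the method and parameters that produced it."""

    mask: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    @property
    def n_flagged(self) -> int:
        return int(np.count_nonzero(self.mask))


def _as_series(series) -> np.ndarray:
    x = np.asarray(series, dtype=float).ravel()
    if not np.isfinite(x).all():
        raise ValidationError("series contains non-finite values")
    return x


def median_filter(series, window: int = 5) -> np.ndarray:
    """1-D running-median smoother with replicate (nearest) edge padding."""
    x = _as_series(series)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if window > x.size:
        raise ValueError("window cannot exceed the series length")
    return ndimage.median_filter(x, size=window, mode="nearest")


def detect_outliers_median_filter(
    series, window: int = 5, threshold: float | None = None
) -> OutlierResult:
    """Flag samples whose residual from the median-filtered series is large.

    The default threshold is 3 scaled MADs of the residuals; a residual MAD
    of zero flags nothing.
    """
    x = _as_series(series)
    resid = x - median_filter(x, window)
    if threshold is None:
        mad = np.median(np.abs(resid - np.median(resid)))
        threshold = 3.0 * MAD_SCALE * mad
    if threshold <= 0:
        mask = np.zeros(x.size, dtype=bool)
    else:
        mask = np.abs(resid) > threshold
    return OutlierResult(mask, "median_filter", {"window": window, "threshold": threshold})


def detect_outliers_mad(series, k: float = 3.0) -> OutlierResult:
    """Flag samples with |x − median| > k · 1.4826 · MAD.

    A zero MAD (at least half the samples identical) flags nothing rather
    than everything.
    """
    x = _as_series(series)
    if x.size < 3:
        raise ValueError("MAD detection needs at least 3 samples")
    if k <= 0:
        raise ValueError("k must be positive")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        mask = np.zeros(x.size, dtype=bool)
    else:
        mask = np.abs(x - med) > k * MAD_SCALE * mad
    return OutlierResult(mask, "mad", {"k": k})


def detect_outliers_iqr(series, fence: float = 1.5) -> OutlierResult:
    """Flag samples outside the Tukey fences [Q1 − f·IQR, Q3 + f·IQR]."""
    x = _as_series(series)
    if x.size < 4:
        raise ValueError("IQR detection needs at least 4 samples")
    if fence <= 0:
        raise ValueError("fence must be positive")
    q1, q3 = np.percentile(x, [25.0, 75.0])  # linear interpolation
    iqr = q3 - q1
    mask = (x < q1 - fence * iqr) | (x > q3 + fence * iqr)
    return OutlierResult(mask, "iqr", {"fence": fence})


_DETECTORS = {
    "median_filter": detect_outliers_median_filter,
    "median": detect_outliers_median_filter,
    "mad": detect_outliers_mad,
    "iqr": detect_outliers_iqr,
}


def detect_outliers(series, method: str = "iqr", **params) -> OutlierResult:
    """Dispatch to one of the detection strategies by name."""
    try:
        detector = _DETECTORS[method]
    except KeyError:
        raise ValueError(f"unknown outlier method {method!r}") from None
    return detector(series, **params)


def remove_outliers(
    processed: pd.DataFrame, method: str = "iqr", **params
) -> tuple[pd.DataFrame, OutlierResult]:
    """Drop outlier rows of a processed session, judged on ``DIFF GZ``.

    Per-AOI MEAN_ERR / STD ERR aggregates are recomputed on the surviving
    rows.  Removing every row is an error: an empty session is never
    returned.
    """
    processed = pd.DataFrame(processed)
    if len(processed) == 0:
        raise ValidationError("cannot clean an empty session")
    result = detect_outliers(processed["DIFF GZ"].to_numpy(float), method, **params)
    if result.mask.all():
        raise ValidationError("outlier removal would discard every sample")
    cleaned = processed.loc[~result.mask].reset_index(drop=True)
    cleaned = recompute_aoi_stats(cleaned)
    return cleaned, result
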