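"""Summary statistics for gaze angular error.

The summaries mirror the descriptive rows conventionally reported for
gaze-accuracy benchmarks: mean, sample standard deviation, raw (unscaled)
median absolute deviation, interquartile range, a 95% confidence interval
for the mean and per-sample z-scores.

Notes on conventions
--------------------
* The MAD reported here is the *raw* median absolute deviation.  On
  heavy-tailed gaze error data the raw MAD can exceed the mean; the
  Gaussian-consistency factor 1.4826 is applied only inside outlier
  detection (:mod:`gazeval.cleaning`), never in summaries.
* The 95% CI uses the normal approximation mean ± 1.96·s/√n, adequate for
  the thousands of samples a session produces; a seeded bootstrap CI is
  available via :func:`bootstrap_ci`.
* Z-scores of a zero-variance series are defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ValidationError

__all__ = ["ErrorStats", "summarize_errors", "bootstrap_ci", "per_condition_table", "format_condition_table"]


@dataclass
class ErrorStats:
    n: int
    mean_deg: float
    std_deg: float
    mad_deg: float
    iqr_deg: float
    ci95_low_deg: float
    ci95_high_deg: float
    zscores: np.ndarray


def summarize_errors(errors) -> ErrorStats:
    """Descriptive statistics of an angular-error sequence (degrees)."""
    x = np.asarray(errors, dtype=float).ravel()
    if x.size < 2:
        raise ValidationError("need at least 2 error samples")
    if not np.isfinite(x).all():
        raise ValidationError("errors contain non-finite values")
    n = x.size
    mean = float(np.mean(x))
    std = float(np.std(x, ddof=1))
    mad = float(np.median(np.abs(x - np.median(x))))
    q1, q3 = np.percentile(x, [25.0, 75.0])
    half = 1.96 * std / np.sqrt(n)
    z = (x - mean) / std if std > 0 else np.zeros_like(x)
    return ErrorStats(
        n=n,
        mean_deg=mean,
        std_deg=std,
        mad_deg=mad,
        iqr_deg=float(q3 - q1),
        ci95_low_deg=mean - half,
        ci95_high_deg=mean + half,
        zscores=z,
    )


def bootstrap_ci(errors, n_boot: int = 10_000, seed: int | None = None, level: float = 0.95):
    """Percentile bootstrap CI for the mean (seeded, 10 000 resamples)."""
    x = np.asarray(errors, dtype=float).ravel()
    if x.size < 2:
        raise ValidationError("need at least 2 error samples")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def per_condition_table(datasets: dict) -> pd.DataFrame:
    """One row of summary statistics per experimental condition.

    ``datasets`` maps condition labels (e.g. ``UD50``, ``Y20``) to error
    sequences; rows keep the given order.
    """
    if not datasets:
        raise ValidationError("no conditions given")
    rows = {}
    for label, errs in datasets.items():
        s = summarize_errors(errs)
        rows[label] = {
            "n": s.n,
            "mean_deg": s.mean_deg,
            "std_deg": s.std_deg,
            "mad_deg": s.mad_deg,
            "iqr_deg": s.iqr_deg,
            "ci95_low_deg": s.ci95_low_deg,
            "ci95_high_deg": s.ci95_high_deg,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def format_condition_table(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Reshape a per-condition table into the conventional published layout.

    Conditions become columns; rows are Mean, MAD, IQR and the 95% interval
    rendered as ``low–high``.
    """
    fmt = f"{{:.{decimals}f}}"
    out = {}
    for label, row in table.iterrows():
        out[label] = {
            "Mean": fmt.format(row["mean_deg"]),
            "MAD": fmt.format(row["mad_deg"]),
            "IQR": fmt.format(row["iqr_deg"]),
            "95% interval": fmt.format(row["ci95_low_deg"]) + "–" + fmt.format(row["ci95_high_deg"]),
        }
    return pd.DataFrame(out, index=["Mean", "MAD", "IQR", "95% interval"])
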