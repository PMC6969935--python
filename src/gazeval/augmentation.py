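"""Synthesize variants of gaze data series for dataset augmentation.

Seven methods are available: white-noise injection, colored (1/f^α)
noise injection, linear interpolation to a denser time base, circular
time-shifting, convolution with a unit-sum raised-cosine kernel, and the
two combinations noise+shift and noise+convolve.  Augmented sessions can
feed machine-learning models of tracker error patterns without new
recordings.

Augmentation can target either the estimated angular series (yaw/pitch,
the default) or the raw pixel coordinates; in both cases every dependent
column of the processed format is re-derived afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import geometry
from .io_formats import ScreenGeometry, SessionMeta, ValidationError

__all__ = ["METHODS", "AugmentationSpec", "augment", "augment_dataset", "default_specs"]

METHODS = (
    "white_noise",
    "colored_noise",
    "interpolate",
    "time_shift",
    "cosine_convolve",
    "noise_plus_shift",
    "noise_plus_convolve",
)


@dataclass(frozen=True)
class AugmentationSpec:
    """Recipe for one augmentation run.

    Parameters
    ----------
    method:
        One of :data:`METHODS`.
    sigma:
        Noise standard deviation, in the units of the augmented series
        (degrees for angular series, pixels for pixel series).
    alpha:
        Spectral exponent of the colored noise (power ∝ 1/f^α); 1 = pink.
    upsample:
        Integer resampling factor for ``interpolate``; a factor ``m``
        turns n samples into m·(n−1)+1.
    shift:
        Circular shift in samples for ``time_shift``.
    kernel_width:
        Odd width (≥ 3) of the raised-cosine smoothing kernel.
    seed:
        RNG seed; identical seeds reproduce identical outputs.
    """

    method: str
    sigma: float = 0.5
    alpha: float = 1.0
    upsample: int = 2
    shift: int = 10
    kernel_width: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown augmentation method {self.method!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.upsample < 1 or int(self.upsample) != self.upsample:
            raise ValueError("upsample must be a positive integer")
        if self.kernel_width < 3 or self.kernel_width % 2 == 0:
            raise ValueError("kernel_width must be an odd integer >= 3")


def _white_noise(x, spec, rng):
    return x + rng.normal(0.0, spec.sigma, size=x.size) if spec.sigma > 0 else x.copy()


def _colored_noise(x, spec, rng):
    """Add 1/f^α-shaped Gaussian noise scaled to sample SD ``sigma``."""
    if spec.sigma == 0:
        return x.copy()
    n = x.size
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-spec.alpha / 2.0)
    noise = np.fft.irfft(spectrum * shaping, n)
    noise -= noise.mean()
    sd = noise.std()
    if sd > 0:
        noise *= spec.sigma / sd
    return x + noise


def _interpolate(x, spec, rng):
    n = x.size
    old = np.arange(n)
    new = np.linspace(0.0, n - 1.0, spec.upsample * (n - 1) + 1)
    return np.interp(new, old, x)


def _time_shift(x, spec, rng):
    return np.roll(x, spec.shift)


def raised_cosine_kernel(width: int) -> np.ndarray:
    """Strictly positive raised-cosine window of odd *width*, summing to 1."""
    if width < 3 or width % 2 == 0:
        raise ValueError("kernel width must be an odd integer >= 3")
    # Hann window on width+2 points, endpoints (zeros) dropped.
    j = np.arange(1, width + 1)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * j / (width + 1)))
    return w / w.sum()


def _cosine_convolve(x, spec, rng):
    k = raised_cosine_kernel(spec.kernel_width)
    if x.size < spec.kernel_width:
        raise ValidationError("series shorter than the convolution kernel")
    pad = spec.kernel_width // 2
    padded = np.concatenate([np.full(pad, x[0]), x, np.full(pad, x[-1])])
    return np.convolve(padded, k, mode="valid")


_SINGLE = {
    "white_noise": _white_noise,
    "colored_noise": _colored_noise,
    "interpolate": _interpolate,
    "time_shift": _time_shift,
    "cosine_convolve": _cosine_convolve,
}


def augment(series, spec: AugmentationSpec) -> np.ndarray:
    """Apply one augmentation method to a 1-D series.

    Combination methods apply their two named steps in order (noise
    first).  Deterministic under ``spec.seed``.
    """
    x = np.asarray(series, dtype=float).ravel()
    if not np.isfinite(x).all():
        raise ValidationError("series contains non-finite values")
    rng = np.random.default_rng(spec.seed)
    if spec.method in _SINGLE:
        return _SINGLE[spec.method](x, spec, rng)
    if spec.method == "noise_plus_shift":
        return _time_shift(_white_noise(x, spec, rng), spec, rng)
    if spec.method == "noise_plus_convolve":
        return _cosine_convolve(_white_noise(x, spec, rng), spec, rng)
    raise ValueError(f"unknown augmentation method {spec.method!r}")


def default_specs(seed: int = 0, sigma: float = 0.5) -> list[AugmentationSpec]:
    """One spec per method, with seeds derived from *seed*."""
    return [
        AugmentationSpec(method=m, sigma=sigma, seed=seed + i)
        for i, m in enumerate(METHODS)
    ]


def _suffix(spec: AugmentationSpec) -> str:
    parts = [spec.method]
    if spec.method in ("white_noise", "colored_noise", "noise_plus_shift", "noise_plus_convolve"):
        parts.append(f"sig{spec.sigma:g}")
    if spec.method == "colored_noise":
        parts.append(f"a{spec.alpha:g}")
    if spec.method == "interpolate":
        parts.append(f"x{spec.upsample}")
    if spec.method == "time_shift" or spec.method == "noise_plus_shift":
        parts.append(f"k{spec.shift}")
    if spec.method in ("cosine_convolve", "noise_plus_convolve"):
        parts.append(f"w{spec.kernel_width}")
    if spec.seed is not None:
        parts.append(f"seed{spec.seed}")
    return "_".join(parts)


def augment_dataset(
    session: pd.DataFrame,
    specs,
    meta: SessionMeta,
    screen: ScreenGeometry,
    target: str = "angles",
) -> list[tuple[str, pd.DataFrame]]:
    """Produce one augmented processed session per spec.

    ``target="angles"`` perturbs the estimated yaw/pitch series and maps
    back to screen coordinates through the viewing geometry;
    ``target="pixels"`` perturbs the raw pixel coordinates directly.
    Either way the full 21-column processed session is rebuilt, so angle,
    error and per-AOI aggregate columns stay mutually consistent.  Each
    output is paired with a provenance suffix encoding method, parameters
    and seed, suitable for a file-name tag.
    """
    if target not in ("angles", "pixels"):
        raise ValueError("target must be 'angles' or 'pixels'")
    out: list[tuple[str, pd.DataFrame]] = []
    d = meta.user_distance_mm
    mu = screen.pixel_pitch_mm
    for spec in specs:
        # Independent sub-seeds for the x- and y-channel of one spec.
        if spec.seed is None:
            sx = sy = None
        else:
            sx, sy = np.random.SeedSequence(spec.seed).generate_state(2) >> 1
        spec_x = replace(spec, seed=None if sx is None else int(sx))
        spec_y = replace(spec, seed=None if sy is None else int(sy))

        if target == "angles":
            yaw = augment(session["YAW DATA"].to_numpy(float), spec_x)
            pitch = augment(session["PITCH DATA"].to_numpy(float), spec_y)
            gaze_x_px = d * np.tan(np.radians(yaw)) / mu
            gaze_y_px = d * np.tan(np.radians(pitch)) / mu
        else:
            gaze_x_px = augment(session["XRAW"].to_numpy(float), spec_x)
            gaze_y_px = augment(session["YRAW"].to_numpy(float), spec_y)

        t = session["TIM REL"].to_numpy(float)
        gtx = session["GTX"].to_numpy(float)
        gty = session["GTY"].to_numpy(float)
        if spec.method == "interpolate":
            # Time base and targets resampled onto the same denser grid.
            t = _interpolate(t, spec, None)
            gtx = _interpolate(gtx, spec, None)
            gty = _interpolate(gty, spec, None)
        raw = pd.DataFrame(
            {
                "t_ms": t,
                "gaze_x_px": gaze_x_px,
                "gaze_y_px": gaze_y_px,
                "gt_x_px": gtx,
                "gt_y_px": gty,
            }
        )
        out.append((_suffix(spec), geometry.process_session(meta, screen, raw)))
    return out
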