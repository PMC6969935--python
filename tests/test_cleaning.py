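import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazeval import cleaning
from gazeval.cleaning import (
    MAD_SCALE,
    OutlierResult,
    detect_outliers_iqr,
    detect_outliers_mad,
    detect_outliers_median_filter,
    median_filter,
    remove_outliers,
)
from gazeval.io_formats import ValidationError


# ---------------------------------------------------------------- median filter
def test_median_filter_suppresses_lone_spike():
    np.testing.assert_array_equal(median_filter([1, 9, 1, 1, 1], 3), [1, 1, 1, 1, 1])


def test_median_filter_constant_fixed_point():
    const = np.full(7, 4.2)
    np.testing.assert_array_equal(median_filter(const, 3), const)
    np.testing.assert_array_equal(median_filter(median_filter(const, 3), 3), const)


@pytest.mark.parametrize("window", [2, 4, 1, -3])
def test_median_filter_rejects_bad_windows(window):
    with pytest.raises(ValueError):
        median_filter([1.0, 2.0, 3.0, 4.0, 5.0], window)


def test_median_filter_window_cannot_exceed_length():
    with pytest.raises(ValueError):
        median_filter([1.0, 2.0, 3.0], 5)


# ----------------------------------------------------------------- MAD strategy
def test_mad_zero_spread_flags_nothing():
    assert detect_outliers_mad([2, 2, 2, 2], k=3).n_flagged == 0


def test_mad_flags_the_known_outlier():
    # median 3, MAD 1 -> fence 3 +/- 3*1.4826
    res = detect_outliers_mad([1, 2, 3, 4, 100], k=3)
    np.testing.assert_array_equal(res.mask, [False, False, False, False, True])
    assert res.n_flagged == 1
    assert res.method == "mad"


def test_mad_rejects_bad_params():
    with pytest.raises(ValueError):
        detect_outliers_mad([1, 2, 3], k=0)
    with pytest.raises(ValueError):
        detect_outliers_mad([1, 2], k=3)


# ----------------------------------------------------------------- IQR strategy
def test_iqr_flags_the_known_outlier():
    # Q1=2, Q3=4 (linear interpolation), fences (-1, 7)
    res = detect_outliers_iqr([1, 2, 3, 4, 100], fence=1.5)
    np.testing.assert_array_equal(res.mask, [False, False, False, False, True])


def test_iqr_clean_series_has_no_flags():
    assert detect_outliers_iqr([1, 2, 3, 4, 5]).n_flagged == 0


def test_iqr_wider_fence_never_flags_more(rng):
    x = rng.normal(0, 1, 200)
    x[:5] += 30
    flagged = [detect_outliers_iqr(x, fence=f).n_flagged for f in (0.5, 1.0, 1.5, 3.0)]
    assert flagged == sorted(flagged, reverse=True)


# ------------------------------------------------------- shared mask invariants
@given(
    data=st.lists(st.sampled_from([0.0, 1.0, 5.0, 50.0]), min_size=4, max_size=8),
    shift=st.sampled_from([-7.0, 0.0, 13.5]),
    scale=st.sampled_from([0.5, 1.0, 4.0]),
)
@settings(derandomize=True, max_examples=200, deadline=None)
def test_masks_match_brute_force_and_are_affine_invariant(data, shift, scale):
    """MAD/IQR masks equal a from-scratch implementation of each rule and are
    invariant under translation (both) and positive scaling (both)."""
    x = np.array(data)

    def brute_quantile(values, q):
        xs = sorted(values)
        h = (len(xs) - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, len(xs) - 1)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    def brute_median(values):
        return brute_quantile(values, 0.5)

    med = brute_median(x)
    mad = brute_median([abs(v - med) for v in x])
    brute_mad_mask = [abs(v - med) > 3 * MAD_SCALE * mad if mad else False for v in x]
    np.testing.assert_array_equal(detect_outliers_mad(x, 3).mask, brute_mad_mask)

    q1, q3 = brute_quantile(x, 0.25), brute_quantile(x, 0.75)
    brute_iqr_mask = [v < q1 - 1.5 * (q3 - q1) or v > q3 + 1.5 * (q3 - q1) for v in x]
    np.testing.assert_array_equal(detect_outliers_iqr(x, 1.5).mask, brute_iqr_mask)

    for detect in (detect_outliers_mad, detect_outliers_iqr):
        base = detect(x).mask
        np.testing.assert_array_equal(detect(x + shift).mask, base)
        np.testing.assert_array_equal(detect(x * scale).mask, base)


def test_median_filter_mask_translation_invariant(rng):
    x = rng.normal(0, 1, 60)
    x[10] += 25
    base = detect_outliers_median_filter(x).mask
    np.testing.assert_array_equal(detect_outliers_median_filter(x + 100.0).mask, base)
    assert base[10]


# ------------------------------------------------------------- remove_outliers
def test_remove_outliers_zero_noise_removes_nothing(desk_meta, desk_screen, desk_grid):
    from gazeval import geometry, synthetic

    model = synthetic.ConditionModel("60", bias_deg=0.0, sigma_deg=0.0, outlier_rate=0.0)
    raw = synthetic.simulate_session(desk_meta, desk_screen, desk_grid, model, seed=0)
    proc = geometry.process_session(desk_meta, desk_screen, raw)
    cleaned, res = remove_outliers(proc, "iqr")
    assert res.n_flagged == 0
    assert len(cleaned) == len(proc)


def test_remove_outliers_catches_injected_spikes_exactly():
    import math

    import pandas as pd

    from gazeval import geometry
    from gazeval.io_formats import ScreenGeometry, SessionMeta

    d, mu = 500.0, 0.25
    errors = [1.0] * 47 + [30.0] * 3
    x_px = [d * math.tan(math.radians(a)) / mu for a in errors]
    raw = pd.DataFrame(
        {
            "t_ms": np.arange(50) * 16.0,
            "gaze_x_px": x_px,
            "gaze_y_px": 0.0,
            "gt_x_px": 0.0,
            "gt_y_px": 0.0,
        }
    )
    proc = geometry.process_session(
        SessionMeta(1, "60", "desk", d), ScreenGeometry(1680, 1050, mu), raw
    )
    cleaned, res = remove_outliers(proc, "iqr")
    assert res.n_flagged == 3
    assert len(cleaned) + res.n_flagged == len(proc)
    np.testing.assert_allclose(cleaned["DIFF GZ"], 1.0, atol=1e-9)
    np.testing.assert_allclose(cleaned["MEAN_ERR"], 1.0, atol=1e-9)


def test_remove_outliers_flags_under_half_of_default_synthetic(noisy_session):
    _, res = remove_outliers(noisy_session, "iqr")
    assert res.n_flagged < 0.5 * len(noisy_session)


def test_remove_outliers_refuses_to_empty_the_session(noisy_session, monkeypatch):
    monkeypatch.setitem(
        cleaning._DETECTORS,
        "all",
        lambda s: OutlierResult(np.ones(len(s), dtype=bool), "all"),
    )
    with pytest.raises(ValidationError):
        remove_outliers(noisy_session, "all")


def test_unknown_method_is_an_error(noisy_session):
    with pytest.raises(ValueError):
        remove_outliers(noisy_session, "zscore")
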