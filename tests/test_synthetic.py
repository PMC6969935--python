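import numpy as np
import pandas as pd
import pytest

from gazeval import cleaning, geometry, synthetic
from gazeval.io_formats import (
    PROCESSED_COLUMNS,
    SessionMeta,
    ValidationError,
    read_processed_session,
    read_raw_session,
)


def test_default_grid_protocol(desk_screen, desk_grid):
    assert desk_grid.n_points == 15
    assert desk_grid.dwell_s == 3.0
    xy = desk_grid.xy()
    # odd x odd grid: the display center is a stimulus
    assert (np.abs(xy).sum(axis=1) == 0).any()
    # symmetric under point reflection through the center
    as_set = {tuple(p) for p in np.round(xy, 9)}
    assert {tuple(p) for p in np.round(-xy, 9)} == as_set
    # all points on screen, inside margins
    assert (np.abs(xy[:, 0]) <= 0.4 * desk_screen.res_x + 1e-9).all()
    assert (np.abs(xy[:, 1]) <= 0.4 * desk_screen.res_y + 1e-9).all()


def test_grid_parameter_validation(desk_screen):
    with pytest.raises(ValueError):
        synthetic.make_stimulus_grid(desk_screen, margin_frac=0.5)
    with pytest.raises(ValueError):
        synthetic.make_stimulus_grid(desk_screen, n_points=15, cols=4)


def test_session_sample_arithmetic(desk_meta, desk_screen, desk_grid):
    model = synthetic.ConditionModel("60", bias_deg=1.0)
    raw = synthetic.simulate_session(desk_meta, desk_screen, desk_grid, model, seed=0)
    # 15 points x 3 s x 60 Hz
    assert len(raw) == 2700
    assert geometry.assign_aoi(raw["gt_x_px"], raw["gt_y_px"]).max() == 14


def test_zero_model_reproduces_ground_truth(desk_meta, desk_screen, desk_grid):
    model = synthetic.ConditionModel("60", bias_deg=0.0, sigma_deg=0.0, outlier_rate=0.0)
    raw = synthetic.simulate_session(desk_meta, desk_screen, desk_grid, model, seed=1)
    np.testing.assert_allclose(raw["gaze_x_px"], raw["gt_x_px"], atol=1e-9)
    np.testing.assert_allclose(raw["gaze_y_px"], raw["gt_y_px"], atol=1e-9)


def test_determinism_under_seed(desk_meta, desk_screen, desk_grid):
    model = synthetic.ConditionModel("60", bias_deg=2.0)
    a = synthetic.simulate_session(desk_meta, desk_screen, desk_grid, model, seed=9)
    b = synthetic.simulate_session(desk_meta, desk_screen, desk_grid, model, seed=9)
    pd.testing.assert_frame_equal(a, b)
    c = synthetic.simulate_session(desk_meta, desk_screen, desk_grid, model, seed=10)
    assert not np.allclose(a["gaze_x_px"], c["gaze_x_px"])


def test_transitions_insert_moving_target_samples(desk_meta, desk_screen, desk_grid):
    model = synthetic.ConditionModel("60", bias_deg=1.0)
    fix = synthetic.simulate_session(desk_meta, desk_screen, desk_grid, model, seed=2)
    mov = synthetic.simulate_session(
        desk_meta, desk_screen, desk_grid, model, seed=2, include_transitions=True
    )
    assert len(mov) > len(fix)
    # transition samples have intermediate (non-grid) target coordinates
    grid_x = {x for _, x, _ in desk_grid.points}
    assert not set(np.unique(mov["gt_x_px"])).issubset(grid_x)


def test_condition_model_validation():
    with pytest.raises(ValidationError):
        synthetic.ConditionModel("x", bias_deg=1.0, outlier_rate=0.3)
    with pytest.raises(ValidationError):
        synthetic.ConditionModel("x", bias_deg=1.0, sigma_deg=-0.1)
    with pytest.raises(ValidationError):
        synthetic.ConditionModel("x", bias_deg=-1.0)


def test_condition_distance_mapping():
    assert synthetic.condition_distance_mm("50") == 500.0
    assert synthetic.condition_distance_mm("80") == 800.0
    assert synthetic.condition_distance_mm("Y20") == 600.0


def test_injected_outlier_count_within_binomial_bounds(desk_meta, desk_screen, desk_grid):
    model = synthetic.default_condition_models("desk")["60"]
    _, info = synthetic.simulate_session(
        desk_meta, desk_screen, desk_grid, model, seed=4, return_info=True
    )
    n, p = 2700, model.outlier_rate
    sd = np.sqrt(n * p * (1 - p))
    lo, hi = n * p - 2.58 * sd, n * p + 2.58 * sd  # 99% binomial band
    assert lo <= info["outlier_mask"].sum() <= hi


def test_cleaning_recovers_injected_spikes(desk_meta, desk_screen, desk_grid):
    """At spike scale >= 10 sigma, IQR detection on the radial angular error
    magnitude recovers at least 90% of the injected outliers."""
    model = synthetic.default_condition_models("desk")["60"]
    assert model.outlier_scale_deg >= 10 * model.sigma_deg
    for seed in range(5):
        raw, info = synthetic.simulate_session(
            desk_meta, desk_screen, desk_grid, model, seed=seed, return_info=True
        )
        proc = geometry.process_session(desk_meta, desk_screen, raw)
        radial = np.hypot(
            proc["YAW GT"] - proc["YAW DATA"], proc["PITCH GT"] - proc["PITCH DATA"]
        ).to_numpy()
        flagged = cleaning.detect_outliers_iqr(radial).mask
        spikes = info["outlier_mask"]
        assert spikes.sum() > 0
        assert (flagged & spikes).sum() >= 0.9 * spikes.sum()


def test_parameter_recovery_against_mc_reference(desk_screen, desk_grid):
    """Pipeline mean after cleaning matches the brute-force Monte-Carlo
    reference (10x noise samples, same realized bias directions)."""
    model = synthetic.default_condition_models("desk")["70"]
    d = synthetic.condition_distance_mm("70")
    pooled, dirs = [], []
    for u in range(8):
        meta = SessionMeta(u + 1, "70", "desk", d)
        raw, info = synthetic.simulate_session(
            meta, desk_screen, desk_grid, model, seed=300 + u, return_info=True
        )
        proc = geometry.process_session(meta, desk_screen, raw)
        pooled.append(proc["DIFF GZ"].to_numpy())
        dirs.append(info["bias_direction_rad"])
    errs = np.concatenate(pooled)
    mask = cleaning.detect_outliers_iqr(errs).mask
    recovered = errs[~mask].mean()
    reference = synthetic.mc_reference_mean(
        desk_screen, desk_grid, model, d, dirs, samples_per_point=1800, seed=77
    )
    assert recovered == pytest.approx(reference, abs=0.05)


def test_build_dataset_tree_layout_and_manifest(tmp_path, desk_screen):
    manifest = synthetic.build_dataset_tree(
        tmp_path, users=2, conditions=("60", "80"), platforms=("desk",), seed=5
    )
    # 2 users x 2 conditions x 1 platform, raw + processed each
    assert len(manifest) == 8
    proc_rows = manifest[manifest["kind"] == "proc"]
    assert len(proc_rows) == 4
    for rel in proc_rows["path"]:
        session = read_processed_session(tmp_path / rel)
        assert tuple(session.columns) == PROCESSED_COLUMNS
    raw_rel = manifest[manifest["kind"] == "raw"]["path"].iloc[0]
    meta, screen, samples = read_raw_session(tmp_path / raw_rel)
    assert screen == desk_screen
    assert len(samples) == 2700
    assert (tmp_path / "manifest.csv").exists()
    listed = pd.read_csv(tmp_path / "manifest.csv")
    assert len(listed) == len(manifest)


def test_preset_means_are_ordered_by_user_distance(desk_screen, desk_grid):
    """Cleaned pooled means must fall with user distance: UD50 > UD60 > UD70 >= UD80."""
    means = {}
    for label in ("50", "60", "70", "80"):
        model = synthetic.default_condition_models("desk")[label]
        d = synthetic.condition_distance_mm(label)
        pooled = []
        for u in range(6):
            meta = SessionMeta(u + 1, label, "desk", d)
            raw = synthetic.simulate_session(
                meta, desk_screen, desk_grid, model, seed=1000 + u
            )
            proc = geometry.process_session(meta, desk_screen, raw)
            pooled.append(proc["DIFF GZ"].to_numpy())
        errs = np.concatenate(pooled)
        means[label] = errs[~cleaning.detect_outliers_iqr(errs).mask].mean()
    assert means["50"] > means["60"] > means["70"] >= means["80"]
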