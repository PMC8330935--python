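import dataclasses

import numpy as np
import pytest
from scipy.special import logit

from ccfdq import (
    SLAB_20_AT_29,
    SimulationConfig,
    read_fixture_set,
    simulate_cohort,
    simulate_eye,
    simulate_truth_cohort,
    write_fixture_set,
)
from ccfdq.synthetic_octa import ChecksumError


def test_same_seed_gives_bit_identical_scenes(small_cohort_config):
    a = simulate_eye(small_cohort_config, 1, "control")
    b = simulate_eye(small_cohort_config, 1, "control")
    assert np.array_equal(a.angio.pixels, b.angio.pixels)
    assert np.array_equal(a.structural.pixels, b.structural.pixels)
    assert np.array_equal(a.truth.lcv_mask.pixels, b.truth.lcv_mask.pixels)
    assert a.truth.ct_um == b.truth.ct_um


def test_different_seeds_differ(small_cohort_config):
    other = dataclasses.replace(small_cohort_config, seed=small_cohort_config.seed + 1)
    a = simulate_eye(small_cohort_config, 0, "iamd")
    b = simulate_eye(other, 0, "iamd")
    assert not np.array_equal(a.angio.pixels, b.angio.pixels)


def test_degenerate_no_deficit_scene():
    cfg = SimulationConfig(
        seed=3,
        n_iamd=0,
        n_control=2,
        image_size_px=128,
        fd_fraction_control=0.0,
        noise_sd=0.0,
        lcv_render=False,
        drusen_rate=0.0,
    )
    scene = simulate_eye(cfg, 0, "control")
    assert all(v == 0.0 for v in scene.truth.sector_fd_fraction.values())
    # outside projection streaks the flow band stays well above the deficit
    # band: no sub-threshold texture pixels at all
    analyzable = ~scene.truth.vessel_mask.pixels
    assert scene.angio.pixels[analyzable].min() > 0.5
    assert not scene.truth.lcv_mask.pixels.any()


def test_cohort_sizes_and_laterality():
    cfg = SimulationConfig(seed=5, n_iamd=2, n_control=1, image_size_px=128)
    scenes = simulate_cohort(cfg)
    assert [s.group for s in scenes] == ["iamd", "iamd", "control"]
    assert [s.laterality for s in scenes] == ["OD", "OS", "OD"]
    sector_df, eye_df = simulate_truth_cohort(cfg)
    assert len(sector_df) == 12 and len(eye_df) == 3


def test_full_cohort_truth_row_counts():
    sector_df, eye_df = simulate_truth_cohort(SimulationConfig(seed=1, n_iamd=69, n_control=49))
    assert len(sector_df) == 472
    assert len(eye_df) == 118
    assert sector_df.eye_id.nunique() == 118


def test_truth_cohort_matches_rendered_truth(small_cohort_config):
    sector_df, eye_df = simulate_truth_cohort(small_cohort_config)
    scene = simulate_eye(small_cohort_config, 0, "iamd")
    rows = sector_df[sector_df.eye_id == scene.eye_id].set_index("sector")
    for j in (1, 2, 3, 4):
        assert rows.loc[j, "ct_um"] == pytest.approx(scene.truth.ct_um[j])
        assert bool(rows.loc[j, "lcv"]) == scene.truth.lcv_flags[j]


def test_lcv_masks_identical_across_slab_settings(small_cohort_config):
    """LCV presence must conform 100% between the two slab conventions."""
    other = dataclasses.replace(small_cohort_config, slab=SLAB_20_AT_29)
    a = simulate_eye(small_cohort_config, 0, "iamd")
    b = simulate_eye(other, 0, "iamd")
    assert np.array_equal(a.truth.lcv_mask.pixels, b.truth.lcv_mask.pixels)
    assert a.truth.lcv_flags == b.truth.lcv_flags


def test_lcv_replaces_rather_than_adds_signal(small_cohort_config):
    """Outside the LCV footprint the angio image is unchanged by rendering."""
    off = dataclasses.replace(small_cohort_config, lcv_render=False, noise_sd=0.0, lcv_intercept=50.0)
    on = dataclasses.replace(small_cohort_config, lcv_render=True, noise_sd=0.0, lcv_intercept=50.0)
    a_on = simulate_eye(on, 0, "iamd")
    a_off = simulate_eye(off, 0, "iamd")
    lcv = a_on.truth.lcv_mask.pixels
    assert lcv.any()
    # feathering extends 20 um beyond the mask; beyond that nothing changes
    from scipy import ndimage

    reach = ndimage.distance_transform_edt(~lcv) * on.pitch_um <= 20.0
    assert np.array_equal(a_on.angio.pixels[~reach], a_off.angio.pixels[~reach])


def test_sector_lcv_frequency_follows_logistic_law():
    """500 sectors at fixed CT; the empirical rate stays within 3 SE of 26%."""
    target = 0.26
    alpha = float(logit(target) - np.log(0.94) * 150.0)
    cfg = SimulationConfig(
        seed=9,
        n_iamd=125,
        n_control=0,
        lcv_intercept=alpha,
        lcv_nasal_shift=0.0,
        lcv_sigma_u=0.0,
        ct_sector_means_um=(150.0, 150.0, 150.0, 150.0),
        ct_sector_sd_um=1e-6,
    )
    sector_df, _ = simulate_truth_cohort(cfg)
    assert len(sector_df) == 500
    rate = sector_df.lcv.mean()
    se = np.sqrt(target * (1 - target) / 500)
    assert abs(rate - target) < 3 * se


def test_logistic_slope_recovery_from_truth_tables():
    """Plain logistic regression on >=200 simulated eyes recovers the CT slope."""
    import statsmodels.api as sm

    gamma = np.log(0.94)
    cfg = SimulationConfig(seed=13, n_iamd=150, n_control=100, lcv_sigma_u=0.0)
    sector_df, _ = simulate_truth_cohort(cfg)
    X = sm.add_constant(
        np.column_stack([sector_df.ct_um, (sector_df.orientation == "nasal").astype(float)])
    )
    fit = sm.Logit(sector_df.lcv.astype(float).to_numpy(), X).fit(disp=0)
    assert abs(fit.params[1] - gamma) < 3 * fit.bse[1]


def test_fixture_round_trip(tmp_path, small_cohort_config):
    scenes = simulate_cohort(dataclasses.replace(small_cohort_config, n_iamd=1, n_control=1))
    manifest = write_fixture_set(scenes, tmp_path)
    assert len(manifest["eyes"]) == 2
    for entry in manifest["eyes"].values():
        assert len(entry["files"]) >= 6
    loaded = read_fixture_set(tmp_path)
    by_id = {s.eye_id: s for s in loaded}
    for scene in scenes:
        other = by_id[scene.eye_id]
        assert np.array_equal(scene.angio.pixels, other.angio.pixels)
        assert np.array_equal(scene.structural.pixels, other.structural.pixels)
        assert np.array_equal(scene.truth.lcv_mask.pixels, other.truth.lcv_mask.pixels)
        assert np.array_equal(
            scene.truth.ct_surfaces.sclera_inner_depth, other.truth.ct_surfaces.sclera_inner_depth
        )
        assert other.truth.lcv_flags == scene.truth.lcv_flags


def test_fixture_tampering_is_detected(tmp_path, small_cohort_config):
    scenes = simulate_cohort(dataclasses.replace(small_cohort_config, n_iamd=1, n_control=1))
    write_fixture_set(scenes, tmp_path)
    victim = next(tmp_path.glob("*/angio.tif"))
    blob = bytearray(victim.read_bytes())
    blob[-1] ^= 0xFF
    victim.write_bytes(bytes(blob))
    with pytest.raises(ChecksumError):
        read_fixture_set(tmp_path)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(seed=1, n_iamd=1, n_control=0)  # fewer than two eyes
    with pytest.raises(ValueError):
        SimulationConfig(seed=1, n_iamd=2, n_control=2, fd_fraction_iamd=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(seed=1, n_iamd=2, n_control=2, lcv_contrast=0.5)
    with pytest.raises(ValueError):
        simulate_eye(SimulationConfig(seed=1, n_iamd=1, n_control=1, image_size_px=128), 0, "sick")


def test_ct_surfaces_are_consistent(small_scene):
    surf = small_scene.truth.ct_surfaces
    assert np.all(surf.sclera_inner_depth > surf.bm_outer_depth)
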