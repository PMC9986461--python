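"""Phantom generator: geometry, labels, morphology, gait synthesis, IO."""

import numpy as np
import pytest

from fracwindow.phantom import (
    DEFAULT_PRIORITY,
    GaitTrial,
    LabeledVoxelGrid,
    PhantomConfig,
    Segment,
    apply_morph_filters,
    build_phantom,
    callus_volume_analytic,
    synth_gait,
)


@pytest.fixture(scope="module")
def fibop_grid():
    return build_phantom(PhantomConfig(seed=11))


# ---------------------------------------------------------------------------
# configuration validation
# ---------------------------------------------------------------------------


def test_invalid_configurations_rejected():
    with pytest.raises(ValueError, match="configuration"):
        PhantomConfig(configuration="Fib??")
    with pytest.raises(ValueError, match="nail_length"):
        PhantomConfig(nail_length_mm=500.0)
    with pytest.raises(ValueError, match="tibial_gap"):
        PhantomConfig(tibial_gap_mm=60.0)
    with pytest.raises(ValueError, match="plate"):
        PhantomConfig(configuration="NoFib", plate=True)
    with pytest.raises(ValueError, match="positive"):
        PhantomConfig(voxel_size_mm=-1.0)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def test_intact_configuration_has_no_fibular_gap():
    grid = build_phantom(PhantomConfig(configuration="FibIntact", seed=0))
    cfg = PhantomConfig(configuration="FibIntact", seed=0)
    # every axial level of the fibula shaft contains fibula voxels
    fib = grid.labels == Segment.FIBULA
    per_slice = fib.sum(axis=(0, 1))
    zs = grid.voxel_centers()[2]
    shaft = zs < cfg.tibia_length_mm
    assert np.all(per_slice[shaft] > 0)
    assert grid.count(Segment.PLATE) == 0


def test_removed_fibula_has_no_fibular_voxels():
    grid = build_phantom(PhantomConfig(configuration="NoFib", seed=0))
    for seg in (Segment.FIBULA, Segment.PLATE, Segment.MEMBRANE):
        assert grid.count(seg) == 0


def test_fibop_has_plate_and_fractured_fibula(fibop_grid):
    assert fibop_grid.count(Segment.PLATE) > 0
    fib = fibop_grid.labels == Segment.FIBULA
    per_slice = fib.sum(axis=(0, 1))
    assert np.any(per_slice == 0)  # interrupted at the fracture levels


def test_callus_volume_matches_analytic_annulus(fibop_grid):
    """Voxel count of the callus equals the closed-form gap-annulus volume
    within the 5 % discretisation tolerance."""
    cfg = PhantomConfig(seed=11)
    vox = fibop_grid.count(Segment.CALLUS) * cfg.voxel_size_mm**3
    assert vox == pytest.approx(callus_volume_analytic(cfg), rel=0.05)


def test_callus_confined_to_gap_slab(fibop_grid):
    cfg = PhantomConfig(seed=11)
    zs = fibop_grid.voxel_centers()[2]
    zc = cfg.tibial_gap_center_frac * cfg.tibia_length_mm
    cal = fibop_grid.labels == Segment.CALLUS
    in_gap = np.abs(zs - zc) <= cfg.tibial_gap_mm / 2 + 1e-9
    assert not np.any(cal[:, :, ~in_gap])


def test_foreground_grayscale_finite_and_label_partition(fibop_grid):
    fg = fibop_grid.labels != Segment.BACKGROUND
    assert np.all(np.isfinite(fibop_grid.grayscale[fg]))
    assert fibop_grid.grayscale.shape == fibop_grid.labels.shape


def test_same_seed_bit_identical_grid():
    a = build_phantom(PhantomConfig(seed=5))
    b = build_phantom(PhantomConfig(seed=5))
    np.testing.assert_array_equal(a.labels, b.labels)
    np.testing.assert_array_equal(a.grayscale, b.grayscale)
    c = build_phantom(PhantomConfig(seed=6))
    assert not np.array_equal(a.grayscale, c.grayscale)
    np.testing.assert_array_equal(a.labels, c.labels)  # geometry is seed-free


def test_volumes_scale_with_cube_of_geometric_factor():
    base = PhantomConfig(seed=0, voxel_size_mm=2.0)
    big = base.scaled(2.0)
    ga, gb = build_phantom(base), build_phantom(big)
    for seg in (Segment.TIBIA, Segment.NAIL, Segment.CALLUS):
        ratio = gb.count(seg) / ga.count(seg)
        assert ratio == pytest.approx(2.0**3, rel=0.08)  # +-1-voxel surface error


# ---------------------------------------------------------------------------
# morphological filters
# ---------------------------------------------------------------------------


def test_island_removal_and_cavity_fill():
    labels = np.zeros((12, 12, 12), dtype=np.uint8)
    labels[2:10, 2:10, 2:10] = Segment.TIBIA
    labels[5, 5, 5] = 0  # 1-voxel internal cavity
    labels[0, 0, 0] = Segment.TIBIA  # 1-voxel island
    out = apply_morph_filters(labels, [int(Segment.TIBIA)])
    assert out[0, 0, 0] == 0
    assert out[5, 5, 5] == Segment.TIBIA


def test_priority_order_protects_higher_segments():
    labels = np.zeros((10, 10, 10), dtype=np.uint8)
    labels[1:9, 1:9, 1:9] = Segment.TIBIA
    labels[4:6, 4:6, 1:9] = Segment.NAIL
    out = apply_morph_filters(labels, [int(Segment.NAIL), int(Segment.TIBIA)])
    # closing of the tibia may reach into the nail region, but the nail wins
    assert np.all(out[4:6, 4:6, 1:9] == Segment.NAIL)


def test_filters_idempotent_on_clean_phantom():
    grid = build_phantom(PhantomConfig(seed=2))
    prio = [int(s) for s in DEFAULT_PRIORITY]
    once = apply_morph_filters(grid.labels, prio)
    twice = apply_morph_filters(once, prio)
    np.testing.assert_array_equal(once, twice)


def test_empty_segment_warns_not_errors():
    labels = np.zeros((8, 8, 8), dtype=np.uint8)
    labels[1, 1, 1] = Segment.TIBIA  # below island threshold -> removed
    with pytest.warns(UserWarning, match="empty"):
        out = apply_morph_filters(labels, [int(Segment.TIBIA)])
    assert out.sum() == 0


# ---------------------------------------------------------------------------
# gait synthesis
# ---------------------------------------------------------------------------


def _stance_peak_count(trial):
    from fracwindow.gait import classify_shape, detect_steps

    steps = detect_steps(trial)
    return [classify_shape(trial.grf_N[i0:i1]) for i0, i1 in steps]


@pytest.mark.parametrize("velocity,expected", [(1.0, "bicuspid"), (1.5, "bicuspid"), (2.0, "monocuspid")])
def test_grf_shape_switches_with_velocity(velocity, expected):
    trial = synth_gait(velocity, n_steps=10, seed=4)
    shapes = _stance_peak_count(trial)
    assert len(shapes) == 10
    assert all(s == expected for s in shapes)


def test_zero_cap_gives_identically_zero_grf():
    trial = synth_gait(1.0, cap_kg=0.0, n_steps=5, seed=0)
    assert np.all(trial.grf_N == 0.0)


def test_negative_cap_rejected():
    with pytest.raises(ValueError, match="cap_kg"):
        synth_gait(1.0, cap_kg=-1.0)


def test_grf_nonnegative_and_peak_bounded():
    from fracwindow.phantom import G_MS2, OVERSHOOT_FACTOR

    trial = synth_gait(1.5, body_mass_kg=95.0, cap_kg=20.0, n_steps=20, seed=9)
    assert np.all(trial.grf_N >= 0)
    assert trial.grf_N.max() <= 20.0 * G_MS2 * OVERSHOOT_FACTOR + 1e-9


def test_same_seed_reproducible_trial():
    a = synth_gait(1.0, n_steps=5, seed=3)
    b = synth_gait(1.0, n_steps=5, seed=3)
    np.testing.assert_array_equal(a.grf_N, b.grf_N)


def test_trial_invariants_enforced():
    with pytest.raises(ValueError, match="strictly increasing"):
        GaitTrial(
            time_s=np.array([0.0, 0.0, 1.0]),
            grf_N=np.zeros(3),
            joint_angles_deg={},
            velocity_kmh=1.0,
            body_mass_kg=95.0,
        )
    with pytest.raises(ValueError, match="non-negative"):
        GaitTrial(
            time_s=np.arange(3.0),
            grf_N=np.array([0.0, -1.0, 0.0]),
            joint_angles_deg={},
            velocity_kmh=1.0,
            body_mass_kg=95.0,
        )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def test_gait_csv_round_trip(tmp_path):
    trial = synth_gait(1.0, n_steps=3, seed=1)
    path = tmp_path / "gait_left_1p0.csv"
    trial.to_csv(path)
    header = path.read_text().splitlines()[0]
    assert header.startswith("time_s,grf_N,")
    assert "hip_flexex_deg" in header
    back = GaitTrial.from_csv(path, velocity_kmh=1.0, body_mass_kg=95.0)
    np.testing.assert_allclose(back.grf_N, trial.grf_N)
    np.testing.assert_allclose(back.joint_angles_deg["knee_flexex"],
                               trial.joint_angles_deg["knee_flexex"])


def test_raw_round_trip(tmp_path, fibop_grid):
    fibop_grid.to_raw(tmp_path / "phantom")
    back = LabeledVoxelGrid.from_raw(tmp_path / "phantom")
    np.testing.assert_array_equal(back.labels, fibop_grid.labels)
    np.testing.assert_allclose(back.grayscale, fibop_grid.grayscale, rtol=1e-6)
    assert back.voxel_size_mm == fibop_grid.voxel_size_mm


def test_nifti_round_trip(tmp_path, fibop_grid):
    gp, lp = tmp_path / "g.nii.gz", tmp_path / "l.nii.gz"
    fibop_grid.to_nifti(gp, lp)
    back = LabeledVoxelGrid.from_nifti(gp, lp)
    np.testing.assert_array_equal(back.labels, fibop_grid.labels)
    np.testing.assert_allclose(back.grayscale, fibop_grid.grayscale, atol=1e-3)
    np.testing.assert_allclose(back.origin_mm, fibop_grid.origin_mm)
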