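"""Stance detection, shape classes, compliance, load model, ROM statistics."""

import numpy as np
import pytest

from fracwindow.fem import LoadCase
from fracwindow.gait import (
    LoadModelParams,
    classify_shape,
    compliance_audit,
    detect_steps,
    load_case_at_phase,
    loads_from_gait,
    rom_summary,
    stance_events,
    two_group_test,
)
from fracwindow.phantom import G_MS2, GaitTrial, synth_gait

PARAMS = LoadModelParams()
ANTHRO = {"body_mass_kg": 95.0}
FIXED = np.array([0, 1, 2])
PLATEAU = np.array([3, 4, 5])


def _manual_trial(grf, dt=0.01, velocity=1.0, angles=None):
    grf = np.asarray(grf, dtype=float)
    return GaitTrial(
        time_s=np.arange(len(grf)) * dt,
        grf_N=grf,
        joint_angles_deg=angles or {},
        velocity_kmh=velocity,
        body_mass_kg=95.0,
    )


# ---------------------------------------------------------------------------
# detection and classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("velocity", [1.0, 1.5, 2.0])
def test_thirty_step_trial_yields_thirty_stances(velocity):
    trial = synth_gait(velocity, n_steps=30, seed=0)
    assert len(detect_steps(trial)) == 30


def test_all_zero_trace_detects_nothing():
    trial = _manual_trial(np.zeros(500))
    with pytest.warns(UserWarning, match="no step"):
        assert detect_steps(trial) == []


def test_single_clean_bump_spans_the_bump():
    grf = np.zeros(300)
    grf[100:200] = 400.0 * np.clip(np.sin(np.pi * np.arange(100) / 99), 0, None)
    trial = _manual_trial(grf)
    steps = detect_steps(trial)
    assert len(steps) == 1
    i0, i1 = steps[0]
    assert 100 <= i0 < 110 and 190 < i1 <= 200


def test_half_sine_is_monocuspid():
    seg = np.sin(np.pi * np.linspace(0, 1, 101))
    assert classify_shape(seg) == "monocuspid"


def test_three_peak_segment_flagged_irregular():
    s = np.linspace(0, 1, 301)
    seg = 1.0 + 0.5 * np.sin(6 * np.pi * s)
    seg *= np.sin(np.pi * s) ** 0.2
    assert classify_shape(seg) == "irregular"


# ---------------------------------------------------------------------------
# compliance
# ---------------------------------------------------------------------------


def test_thirty_five_kg_peaks_violate_twenty_kg_cap():
    trial = synth_gait(1.0, body_mass_kg=95.0, n_steps=10, seed=1)  # ~35 kg peaks
    audit = compliance_audit(trial, prescribed_cap_kg=20.0)
    assert not audit["compliant"]
    assert audit["peak_load_kg"] == pytest.approx(35.0, rel=0.07)
    assert audit["exceedance_fraction"] > 0.9


def test_peak_exactly_at_cap_is_compliant():
    grf = np.zeros(300)
    grf[50:150] = 20.0 * G_MS2 * np.clip(np.sin(np.pi * np.arange(100) / 99), 0, None)
    audit = compliance_audit(_manual_trial(grf), prescribed_cap_kg=20.0)
    assert audit["compliant"]


def test_zero_trace_compliant_with_zero_peak():
    audit = compliance_audit(_manual_trial(np.zeros(100)), prescribed_cap_kg=20.0)
    assert audit["compliant"] and audit["peak_load_kg"] == 0.0


def test_peak_invariant_under_resampling():
    trial = synth_gait(1.0, n_steps=5, seed=2)
    fine_t = np.linspace(trial.time_s[0], trial.time_s[-1], 4 * len(trial.time_s))
    fine = GaitTrial(
        time_s=fine_t,
        grf_N=np.interp(fine_t, trial.time_s, trial.grf_N),
        joint_angles_deg={},
        velocity_kmh=1.0,
        body_mass_kg=95.0,
    )
    a = compliance_audit(trial, 20.0)["peak_load_kg"]
    b = compliance_audit(fine, 20.0)["peak_load_kg"]
    assert b == pytest.approx(a, rel=1e-3)


# ---------------------------------------------------------------------------
# stance events
# ---------------------------------------------------------------------------


def test_symmetric_two_bump_template_midstance_at_valley_center():
    s = np.linspace(0, 1, 201)
    seg = np.exp(-0.5 * ((s - 0.3) / 0.1) ** 2) + np.exp(-0.5 * ((s - 0.7) / 0.1) ** 2)
    ev = stance_events(seg)
    assert ev.shape == "bicuspid"
    assert ev.midstance == pytest.approx(100, abs=2)
    assert ev.first_peak == pytest.approx(60, abs=2)
    assert ev.terminal_stance == pytest.approx(140, abs=2)
    assert ev.pre_swing > ev.terminal_stance


def test_half_sine_midstance_is_argmax():
    seg = np.sin(np.pi * np.linspace(0, 1, 101))
    ev = stance_events(seg)
    assert ev.shape == "monocuspid"
    assert ev.midstance == ev.terminal_stance == int(np.argmax(seg))


def test_known_second_peak_found():
    s = np.linspace(0, 1, 101)
    seg = 0.8 * np.exp(-0.5 * ((s - 0.25) / 0.08) ** 2) + np.exp(
        -0.5 * ((s - 0.60) / 0.08) ** 2
    )
    ev = stance_events(seg)
    assert ev.terminal_stance == 60


# ---------------------------------------------------------------------------
# load model
# ---------------------------------------------------------------------------


def _simple_stance():
    trial = synth_gait(1.0, n_steps=3, seed=0)
    steps = detect_steps(trial)
    i0, i1 = steps[1]
    return trial, stance_events(trial.grf_N[i0:i1], offset=i0)


def test_zero_grf_frame_gives_zero_load_case():
    trial = _manual_trial(np.zeros(100) + 1e-9)
    trial.grf_N[:] = 0.0
    case = LoadCase("f", FIXED, point_loads=[(PLATEAU, np.zeros(3))])
    # via loads_from_gait on a fabricated zero stance
    from fracwindow.gait import StanceEvents

    ev = StanceEvents(0, 100, 50, 50, 50, 50, 90, "monocuspid")
    cases = loads_from_gait(trial, ev, ANTHRO, PARAMS, FIXED, PLATEAU, n_frames=4)
    for c in cases:
        for _, F in c.point_loads:
            assert np.allclose(F, 0.0)
        for _, M in c.moments:
            assert np.allclose(M, 0.0)


def test_midstance_moment_small_fraction_of_terminal_stance():
    trial, ev = _simple_stance()
    mid = load_case_at_phase(trial, ev, "midstance", ANTHRO, PARAMS, FIXED, PLATEAU)
    ts = load_case_at_phase(trial, ev, "terminal_stance", ANTHRO, PARAMS, FIXED, PLATEAU)
    m_mid = np.linalg.norm(mid.moments[0][1])
    m_ts = np.linalg.norm(ts.moments[0][1])
    assert m_mid <= 0.10 * m_ts


def test_pre_swing_moment_exceeds_terminal_stance():
    trial, ev = _simple_stance()
    ts = load_case_at_phase(trial, ev, "terminal_stance", ANTHRO, PARAMS, FIXED, PLATEAU)
    ps = load_case_at_phase(trial, ev, "pre_swing", ANTHRO, PARAMS, FIXED, PLATEAU)
    assert np.linalg.norm(ps.moments[0][1]) > np.linalg.norm(ts.moments[0][1])


def test_doubling_grf_doubles_forces_and_moments():
    trial, ev = _simple_stance()
    case1 = load_case_at_phase(trial, ev, "terminal_stance", ANTHRO, PARAMS, FIXED, PLATEAU)
    trial.grf_N = 2.0 * trial.grf_N
    case2 = load_case_at_phase(trial, ev, "terminal_stance", ANTHRO, PARAMS, FIXED, PLATEAU)
    np.testing.assert_allclose(case2.point_loads[0][1], 2 * case1.point_loads[0][1])
    np.testing.assert_allclose(case2.moments[0][1], 2 * case1.moments[0][1])


def test_missing_anthropometry_rejected():
    trial, ev = _simple_stance()
    with pytest.raises(ValueError, match="body_mass_kg"):
        loads_from_gait(trial, ev, {}, PARAMS, FIXED, PLATEAU)


def test_detection_round_trip_recovers_generator_settings():
    """detect_steps + classify_shape recover the generator's configured
    step count and curve shape at the default noise level."""
    for v, shape in [(1.0, "bicuspid"), (2.0, "monocuspid")]:
        trial = synth_gait(v, n_steps=12, seed=7)
        steps = detect_steps(trial)
        assert len(steps) == 12
        assert all(classify_shape(trial.grf_N[i0:i1]) == shape for i0, i1 in steps)


# ---------------------------------------------------------------------------
# ROM statistics
# ---------------------------------------------------------------------------


def _sinusoid_trial(amplitude, n_cycles=8, n_per=100, noise=0.0, seed=0):
    """GRF bumps aligned with full angle cycles so every step sees one
    complete sinusoid period sampled through its extremes."""
    rng = np.random.default_rng(seed)
    n = n_cycles * n_per
    t = np.arange(n) * 0.01
    grf = np.zeros(n)
    for k in range(n_cycles):
        grf[k * n_per : k * n_per + 60] = 300.0 * np.sin(np.pi * np.arange(60) / 59)
    phase = 2 * np.pi * np.arange(n) / n_per
    angle = amplitude * np.sin(phase) + noise * rng.normal(size=n)
    return GaitTrial(
        time_s=t,
        grf_N=grf,
        joint_angles_deg={"knee_flexex": angle},
        velocity_kmh=1.0,
        body_mass_kg=95.0,
    )


def test_constant_angle_trace_gives_zero_range():
    trial = _sinusoid_trial(0.0)
    summary = rom_summary({"left": trial})
    row = summary.table.iloc[0]
    assert row["mean_delta_deg"] == 0.0


def test_sinusoid_range_is_twice_amplitude_with_zero_sem():
    A = 12.5
    trial = _sinusoid_trial(A, n_per=100)  # period divides sampling, extremes hit
    summary = rom_summary({"left": trial})
    row = summary.table.set_index("channel").loc["knee_flexex"]
    assert row["mean_delta_deg"] == pytest.approx(2 * A, rel=1e-9)
    assert row["sem_deg"] == pytest.approx(0.0, abs=1e-12)


def test_mean_range_invariant_to_step_order():
    trial = _sinusoid_trial(8.0, noise=0.5, seed=3)
    summary1 = rom_summary({"g": trial})
    # concatenate the same steps in reversed order
    from fracwindow.gait import detect_steps as ds

    steps = ds(trial)
    onsets = [i0 for i0, _ in steps]
    bounds = list(zip(onsets, onsets[1:] + [len(trial.time_s)]))
    order = bounds[::-1]
    grf = np.concatenate([trial.grf_N[a:b] for a, b in order])
    ang = np.concatenate([trial.joint_angles_deg["knee_flexex"][a:b] for a, b in order])
    trial2 = GaitTrial(
        time_s=np.arange(len(grf)) * 0.01,
        grf_N=grf,
        joint_angles_deg={"knee_flexex": ang},
        velocity_kmh=1.0,
        body_mass_kg=95.0,
    )
    summary2 = rom_summary({"g": trial2})
    a = summary1.table.iloc[0]["mean_delta_deg"]
    b = summary2.table.iloc[0]["mean_delta_deg"]
    assert b == pytest.approx(a, rel=1e-9)


def test_five_degree_shift_detected_significant():
    """Two groups with a 5-degree mean shift (sigma = 1, n = 30) are flagged
    at p < 0.05 (power is ~1 at this effect size)."""
    rng = np.random.default_rng(0)
    x = rng.normal(20.0, 1.0, 30)
    y = rng.normal(25.0, 1.0, 30)
    test, p = two_group_test(x, y)
    assert p < 0.05


def test_rom_group_comparison_flags_shifted_group():
    a = _sinusoid_trial(10.0, noise=0.5, seed=1)
    b = _sinusoid_trial(15.0, noise=0.5, seed=2)
    summary = rom_summary({"left": a, "right": b})
    comp = summary.comparisons.set_index("channel").loc["knee_flexex"]
    assert comp["significant"]


def test_three_group_comparison_runs_with_velocity_groups():
    trials = {f"v{v}": _sinusoid_trial(10.0 + v, noise=0.5, seed=int(v * 10)) for v in (1.0, 1.5, 2.0)}
    summary = rom_summary(trials)
    comp = summary.comparisons.iloc[0]
    assert comp["test"] in ("anova+holm-sidak", "kruskal+dunn")
    assert 0.0 <= comp["p"] <= 1.0


def test_single_step_group_flags_undefined_sem():
    grf = np.zeros(200)
    grf[20:100] = 300.0
    trial = _manual_trial(grf, angles={"knee_flexex": np.linspace(0, 10, 200)})
    summary = rom_summary({"only": trial})
    row = summary.table.iloc[0]
    assert not row["sem_defined"]
    assert np.isnan(row["sem_deg"])
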