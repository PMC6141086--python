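"""Filtering, hip-centre regression, inverse kinematics and calibration."""

import numpy as np
import pytest

from hipdyn.kinematics import (
    FilterConfig,
    KinematicsError,
    apply_harrington_constraint,
    fill_marker_gaps,
    harrington_hjc,
    lowpass_zero_phase,
    optimize_marker_params,
    solve_frame_ik,
    solve_trial_ik,
)
from hipdyn.model import ModelError, Posture, marker_positions
from hipdyn.synthetic import GaitGeneratorParams, generate_gait_trial


# ---------------------------------------------------------------------------
# zero-phase low-pass filter
# ---------------------------------------------------------------------------

def test_filter_dc_gain_is_one():
    x = np.full(500, 3.7)
    y = lowpass_zero_phase(x, FilterConfig(), rate=100.0)
    assert np.allclose(y, 3.7, atol=1e-10)


def test_filter_cutoff_sinusoid_half_amplitude():
    """Two passes of a 2nd-order Butterworth at its cutoff: |H|^2 = 1/2."""
    rate, f = 100.0, 5.0
    t = np.arange(4000) / rate
    x = np.sin(2 * np.pi * f * t)
    y = lowpass_zero_phase(x, FilterConfig(cutoff=5.0), rate)
    mid = slice(1000, 3000)
    amp = (y[mid].max() - y[mid].min()) / 2
    assert np.isclose(amp, 0.5, atol=0.01)


def test_filter_zero_phase_no_lag():
    rate = 100.0
    t = np.arange(2000) / rate
    x = np.sin(2 * np.pi * 1.0 * t) + 0.3 * np.sin(2 * np.pi * 2.0 * t)
    y = lowpass_zero_phase(x, FilterConfig(), rate)
    xc = np.correlate(x[200:-200] - x.mean(), y[200:-200] - y.mean(), "full")
    lag = np.argmax(xc) - (len(x[200:-200]) - 1)
    assert lag == 0


def test_filter_rejects_bad_cutoff_and_nan():
    with pytest.raises(KinematicsError, match="Nyquist"):
        lowpass_zero_phase(np.zeros(100), FilterConfig(cutoff=60.0), rate=100.0)
    x = np.zeros(100)
    x[10] = np.nan
    with pytest.raises(KinematicsError, match="gap"):
        lowpass_zero_phase(x, FilterConfig(), rate=100.0)


def test_filter_differentiation_commutes():
    rate = 100.0
    t = np.arange(1500) / rate
    x = np.sin(2 * np.pi * 1.3 * t) + 0.2 * np.cos(2 * np.pi * 3.1 * t)
    cfg = FilterConfig()
    a = np.gradient(lowpass_zero_phase(x, cfg, rate), 1 / rate)
    b = lowpass_zero_phase(np.gradient(x, 1 / rate), cfg, rate)
    assert np.allclose(a[100:-100], b[100:-100], atol=1e-8)


def test_gap_fill_short_and_long():
    x = np.tile(np.linspace(0, 1, 50)[:, None], (1, 3))
    x[10:13] = np.nan          # 0.03 s gap at 100 Hz -> filled
    x[30:45] = np.nan          # 0.15 s gap -> dropped
    filled, dropped = fill_marker_gaps(x, rate=100.0, max_gap_s=0.1)
    assert np.all(np.isfinite(filled[10:13]))
    assert dropped[30:45].all() and not dropped[:30].any()


# ---------------------------------------------------------------------------
# hip joint centre regression
# ---------------------------------------------------------------------------

def test_harrington_left_right_mirror():
    r = harrington_hjc(0.24, 0.18, 0.9, side="right")
    l = harrington_hjc(0.24, 0.18, 0.9, side="left")
    assert np.allclose(r[:2], l[:2])
    assert np.isclose(r[2], -l[2])
    assert r[2] > 0  # lateral on the right


def test_harrington_hand_evaluated_adult_dimensions():
    """PW=240 mm, PD=180 mm, LL=900 mm against a by-hand evaluation of the
    transcribed regression coefficients."""
    got = harrington_hjc(0.240, 0.180, 0.900) * 1e3   # mm
    x = -0.24 * 180 - 9.9
    y = -0.16 * 240 - 0.04 * 900 - 7.1
    z = 0.28 * 180 + 0.16 * 240 + 7.9
    assert np.allclose(got, [x, y, z], atol=1e-9)


def test_harrington_affine_structure_under_doubling():
    a = harrington_hjc(0.24, 0.18, 0.9)
    b = harrington_hjc(0.48, 0.36, 1.8)
    offs = np.array([-9.9, -7.1, 7.9]) * 1e-3
    # doubling inputs doubles only the linear part, not the intercepts
    assert np.allclose(b - offs, 2 * (a - offs), atol=1e-12)


def test_harrington_rejects_nonpositive():
    with pytest.raises(ModelError):
        harrington_hjc(0.0, 0.18, 0.9)


def test_harrington_constraint_pins_hip_centre(lowerlimb):
    m2 = apply_harrington_constraint(lowerlimb, "hip")
    # the shipped fixture is built Harrington-consistent
    assert np.allclose(m2.joints["hip"].location_in_parent,
                       lowerlimb.joints["hip"].location_in_parent, atol=1e-3)


# ---------------------------------------------------------------------------
# inverse kinematics
# ---------------------------------------------------------------------------

def test_ik_exact_fit_recovers_pose(lowerlimb, rng):
    q_true = rng.uniform(-0.4, 0.4, lowerlimb.n_dof)
    frame = marker_positions(lowerlimb, Posture(q=q_true))
    post = solve_frame_ik(lowerlimb, frame, q_init=np.zeros(lowerlimb.n_dof))
    assert np.abs(post.q - q_true).max() < 1e-8


def test_ik_weight_scale_invariance(lowerlimb, rng):
    q_true = rng.uniform(-0.3, 0.3, lowerlimb.n_dof)
    frame = marker_positions(lowerlimb, Posture(q=q_true))
    for name, tr in frame.items():
        frame[name] = tr + rng.normal(0, 0.002, 3)
    w1 = {m.name: m.weight for m in lowerlimb.markers}
    w2 = {k: 2.0 * v for k, v in w1.items()}
    qa = solve_frame_ik(lowerlimb, frame, np.zeros(12), weights=w1).q
    qb = solve_frame_ik(lowerlimb, frame, np.zeros(12), weights=w2).q
    assert np.abs(qa - qb).max() < 1e-7


def test_ik_far_start_reaches_same_optimum(abductor_rig, rng):
    q_true = np.array([0.3, -0.2, 0.1])
    frame = marker_positions(abductor_rig, Posture(q=q_true))
    q_near = solve_frame_ik(abductor_rig, frame, q_true).q
    q_far = solve_frame_ik(abductor_rig, frame, np.array([-0.6, 0.5, -0.4])).q
    assert np.abs(q_near - q_far).max() < 1e-8


def test_ik_underdetermined_raises(planar):
    # one marker coordinate set cannot constrain... drop both markers
    with pytest.raises(KinematicsError):
        solve_frame_ik(planar, {}, np.zeros(1))


def test_ik_roundtrip_with_noise_consistent_bounds(lowerlimb, rng):
    """Gaussian marker noise perturbs the pose by a noise-consistent amount."""
    sigma = 0.002
    q_true = rng.uniform(-0.3, 0.3, lowerlimb.n_dof)
    frame = marker_positions(lowerlimb, Posture(q=q_true))
    noisy = {k: v + rng.normal(0, sigma, 3) for k, v in frame.items()}
    q = solve_frame_ik(lowerlimb, noisy, q_true).q
    # joint angles stay within a generous multiple of noise / lever arm
    assert np.abs(q - q_true).max() < 50 * sigma


def test_increasing_bony_weight_does_not_raise_its_residual(lowerlimb, rng):
    q_true = rng.uniform(-0.3, 0.3, lowerlimb.n_dof)
    frame = marker_positions(lowerlimb, Posture(q=q_true))
    noisy = {k: v + rng.normal(0, 0.004, 3) for k, v in frame.items()}
    weights = {m.name: m.weight for m in lowerlimb.markers}

    def resid(w, name):
        post = solve_frame_ik(lowerlimb, noisy, q_true, weights=w)
        virt = marker_positions(lowerlimb, post)
        return np.linalg.norm(virt[name] - noisy[name])

    name = "RASI"
    r1 = resid(weights, name)
    boosted = {**weights, name: weights[name] * 20.0}
    r2 = resid(boosted, name)
    assert r2 <= r1 + 1e-12


# ---------------------------------------------------------------------------
# trial-level calibration
# ---------------------------------------------------------------------------

def test_calibration_zero_iterations_is_noop(lowerlimb):
    trial, _ = generate_gait_trial(lowerlimb, GaitGeneratorParams(seed=5),
                                   compute_reference=False)
    res = optimize_marker_params(lowerlimb, trial,
                                 scale_segments=["femur", "shank"],
                                 frames=[0, 50], max_iter=0)
    assert res.scales == {"femur": 1.0, "shank": 1.0}
    assert res.objective >= 0
    assert set(res.marker_rms_m) == {m.name for m in lowerlimb.markers}


def test_trial_ik_tracks_generated_angles(lowerlimb):
    trial, truth = generate_gait_trial(lowerlimb, GaitGeneratorParams(seed=5),
                                       compute_reference=False)
    postures = solve_trial_ik(lowerlimb, trial)
    Q = np.array([p.q for p in postures])
    assert np.abs(Q - truth.q).max() < 1e-6
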