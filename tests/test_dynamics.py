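"""Inverse dynamics: statics, Lagrangian cross-check, free-body terms."""

import numpy as np
import pytest
import sympy as sp

from hipdyn.dynamics import (
    DynamicsError,
    ExternalLoad,
    ExternalLoadSet,
    inverse_dynamics,
    inverse_dynamics_frame,
    limb_free_body,
)
from hipdyn.model import Posture, build_model, fk_with_derivatives
from hipdyn.synthetic import GaitGeneratorParams, generate_gait_trial, make_toy_model


def _pendulum(m=2.0, c=0.2):
    return build_model({
        "root": "base", "floating_base": False, "subject_mass": m, "subject_height": 1,
        "segments": [{"name": "base", "mass": 0.0, "length": 0.3},
                     {"name": "link", "mass": m, "com": [0, 0, -c],
                      "inertia": [[0.02, 0, 0], [0, 0.02, 0], [0, 0, 0.001]],
                      "length": 0.4}],
        "joints": [{"name": "h", "kind": "hinge", "parent": "base", "child": "link",
                    "axis": [0, 1, 0]}],
    })


def test_static_horizontal_pendulum_moment():
    """2 kg at 0.2 m lever, g = 9.81: hinge moment magnitude 3.924 N*m."""
    model = _pendulum()
    q = np.array([np.pi / 2])      # link horizontal
    post = Posture(q=q, qd=np.zeros(1), qdd=np.zeros(1))
    loads, base = inverse_dynamics_frame(model, post)
    assert np.isclose(abs(loads["h"].hinge_scalar), 2.0 * 9.81 * 0.2, atol=1e-12)


def test_zero_gravity_zero_accel_all_zero():
    model = _pendulum()
    model.gravity = np.zeros(3)
    post = Posture(q=np.array([0.7]), qd=np.zeros(1), qdd=np.zeros(1))
    loads, _ = inverse_dynamics_frame(model, post)
    assert np.allclose(loads["h"].force, 0, atol=1e-12)
    assert np.allclose(loads["h"].moment, 0, atol=1e-12)


def test_requires_rates():
    model = _pendulum()
    with pytest.raises(DynamicsError, match="qd"):
        inverse_dynamics_frame(model, Posture(q=np.array([0.1])))


@pytest.fixture(scope="module")
def double_pendulum_oracle():
    """Symbolically derived equations of motion for a 2-hinge chain."""
    L1, c1, m1, I1 = 0.4, 0.18, 3.0, 0.05
    c2, m2, I2 = 0.15, 1.5, 0.02
    g = 9.81
    model = build_model({
        "root": "base", "floating_base": False, "subject_mass": 5, "subject_height": 1,
        "segments": [
            {"name": "base", "mass": 0.0, "length": 0.3},
            {"name": "l1", "mass": m1, "com": [0, 0, -c1],
             "inertia": [[I1, 0, 0], [0, I1, 0], [0, 0, 0.001]], "length": L1},
            {"name": "l2", "mass": m2, "com": [0, 0, -c2],
             "inertia": [[I2, 0, 0], [0, I2, 0], [0, 0, 0.001]], "length": 0.3}],
        "joints": [
            {"name": "j1", "kind": "hinge", "parent": "base", "child": "l1",
             "axis": [0, 1, 0]},
            {"name": "j2", "kind": "hinge", "parent": "l1", "child": "l2",
             "location_in_parent": [0, 0, -L1], "axis": [0, 1, 0]}],
    })
    t = sp.symbols("t")
    th1, th2 = sp.Function("th1")(t), sp.Function("th2")(t)
    x1, z1 = -c1 * sp.sin(th1), -c1 * sp.cos(th1)
    jx, jz = -L1 * sp.sin(th1), -L1 * sp.cos(th1)
    x2, z2 = jx - c2 * sp.sin(th1 + th2), jz - c2 * sp.cos(th1 + th2)
    T = (m1 * (sp.diff(x1, t) ** 2 + sp.diff(z1, t) ** 2) / 2
         + I1 * sp.diff(th1, t) ** 2 / 2
         + m2 * (sp.diff(x2, t) ** 2 + sp.diff(z2, t) ** 2) / 2
         + I2 * (sp.diff(th1, t) + sp.diff(th2, t)) ** 2 / 2)
    V = m1 * g * z1 + m2 * g * z2
    Lag = T - V
    q1, q2, qd1, qd2, qdd1, qdd2 = sp.symbols("q1 q2 qd1 qd2 qdd1 qdd2")
    subs = {sp.diff(th1, t, 2): qdd1, sp.diff(th2, t, 2): qdd2,
            sp.diff(th1, t): qd1, sp.diff(th2, t): qd2, th1: q1, th2: q2}
    fns = [sp.lambdify((q1, q2, qd1, qd2, qdd1, qdd2),
                       (sp.diff(sp.diff(Lag, sp.diff(q, t)), t)
                        - sp.diff(Lag, q)).subs(subs))
           for q in (th1, th2)]
    return model, fns


def test_newton_euler_matches_lagrangian(double_pendulum_oracle, rng):
    model, fns = double_pendulum_oracle
    for _ in range(30):
        q = rng.uniform(-1.5, 1.5, 2)
        qd = rng.uniform(-3, 3, 2)
        qdd = rng.uniform(-10, 10, 2)
        loads, _ = inverse_dynamics_frame(model, Posture(q=q, qd=qd, qdd=qdd))
        rne = np.array([loads["j1"].hinge_scalar, loads["j2"].hinge_scalar])
        lag = np.array([fns[0](*q, *qd, *qdd), fns[1](*q, *qd, *qdd)])
        assert np.abs(rne - lag).max() < 1e-8


def test_base_reaction_closes_newton_second_law(lowerlimb, rng):
    """f_base + sum(F_ext) + sum(m g) == sum(m a), bookkeeping check."""
    model = lowerlimb
    q = rng.uniform(-0.3, 0.3, 12)
    qd = rng.uniform(-2, 2, 12)
    qdd = rng.uniform(-8, 8, 12)
    post = Posture(q=q, qd=qd, qdd=qdd)
    ext = [ExternalLoad(segment="foot", force=np.array([30.0, -10.0, 400.0]),
                        point=np.array([0.2, -0.1, 0.0]))]
    loads, base = inverse_dynamics_frame(model, post, ext)
    kin = fk_with_derivatives(model, post)
    tot_ma = np.zeros(3)
    for name, seg in model.segments.items():
        k = kin[name]
        tot_ma += seg.mass * (k.pdd + k.Rdd @ seg.com_local)
    lhs = base[:3] + ext[0].force + model.total_mass * model.gravity
    assert np.allclose(lhs, tot_ma, atol=1e-8)


def test_joint_force_distal_proximal_complement(lowerlimb, rng):
    """Net joint force via the distal sum equals total minus the proximal
    remainder — equivalent to re-rooting the recursion."""
    model = lowerlimb
    post = Posture(q=rng.uniform(-0.3, 0.3, 12), qd=rng.uniform(-2, 2, 12),
                   qdd=rng.uniform(-5, 5, 12))
    loads, base = inverse_dynamics_frame(model, post)
    kin = fk_with_derivatives(model, post)

    def wrench(segments):
        F = np.zeros(3)
        for name in segments:
            seg = model.segments[name]
            k = kin[name]
            F += seg.mass * (k.pdd + k.Rdd @ seg.com_local) - seg.mass * model.gravity
        return F

    for joint in ("hip", "knee", "talocrural"):
        distal = model.distal_segments(joint)
        proximal = set(model.segments) - distal
        f_distal = wrench(distal)
        f_via_proximal = base[:3] - wrench(proximal)
        assert np.allclose(loads[joint].force, f_distal, atol=1e-8)
        assert np.allclose(f_distal, f_via_proximal, atol=1e-8)


def test_series_length_mismatch_raises(lowerlimb):
    posts = [Posture(q=np.zeros(12), qd=np.zeros(12), qdd=np.zeros(12))] * 3
    loads = ExternalLoadSet(frames=[[]] * 2)
    with pytest.raises(DynamicsError, match="differ"):
        inverse_dynamics(lowerlimb, posts, loads)


# ---------------------------------------------------------------------------
# limb free body
# ---------------------------------------------------------------------------

def test_stationary_limb_free_body(lowerlimb):
    posts = [Posture(q=np.zeros(12), qd=np.zeros(12), qdd=np.zeros(12))]
    fb = limb_free_body(lowerlimb, posts, None, "hip")
    distal_mass = sum(lowerlimb.segments[s].mass
                      for s in lowerlimb.distal_segments("hip"))
    assert np.allclose(fb.f_inertial[0], 0, atol=1e-12)
    assert np.allclose(fb.f_gravity[0], distal_mass * lowerlimb.gravity, atol=1e-12)
    assert np.allclose(fb.grf_sum[0], 0)


def test_uniform_translation_inertial_force(lowerlimb):
    a = np.array([1.2, -0.4, 2.0])
    qdd = np.zeros(12)
    qdd[0:3] = a
    posts = [Posture(q=np.zeros(12), qd=np.zeros(12), qdd=qdd)]
    fb = limb_free_body(lowerlimb, posts, None, "hip")
    distal_mass = sum(lowerlimb.segments[s].mass
                      for s in lowerlimb.distal_segments("hip"))
    assert np.allclose(fb.f_inertial[0], -distal_mass * a, atol=1e-10)


def test_inertial_force_equals_momentum_rate(lowerlimb):
    """F_inertial equals minus the differentiated distal linear momentum,
    with the momentum evaluated from velocity-level kinematics only."""
    from hipdyn.synthetic import _default_profiles, _fourier_eval

    params = GaitGeneratorParams(seed=2)
    trial, truth = generate_gait_trial(lowerlimb, params, compute_reference=False)
    fb = limb_free_body(lowerlimb, truth.postures, None, "hip")
    profiles = _default_profiles(params)
    distal = lowerlimb.distal_segments("hip")
    T = params.cycle_duration
    omega = 2 * np.pi / T

    def momentum(tval):
        phi = np.array([tval / T])
        q = np.zeros(12)
        qd = np.zeros(12)
        for i, name in enumerate(lowerlimb.dof_names):
            if name == "pelvis_tx":
                q[i], qd[i] = params.walking_speed * tval, params.walking_speed
            elif name in profiles:
                a0, harm = profiles[name]
                v, vd, _ = _fourier_eval(a0, harm, phi, omega)
                q[i], qd[i] = v[0], vd[0]
        kin = fk_with_derivatives(lowerlimb, Posture(q=q, qd=qd))
        p = np.zeros(3)
        for s in distal:
            seg = lowerlimb.segments[s]
            k = kin[s]
            p += seg.mass * (k.pd + k.Rd @ seg.com_local)
        return p

    h = 1e-4
    for idx in (10, 40, 80):
        tval = truth.postures[idx].time

        def central(hh):
            return (momentum(tval + hh) - momentum(tval - hh)) / (2 * hh)

        pdot = (4.0 * central(h / 2) - central(h)) / 3.0   # Richardson
        assert np.abs(fb.f_inertial[idx] + pdot).max() < 1e-6


def test_cut_at_unknown_joint_raises(lowerlimb):
    with pytest.raises(DynamicsError):
        limb_free_body(lowerlimb, [], None, "shoulder")
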