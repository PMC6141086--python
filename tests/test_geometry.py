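"""Muscle path geometry: wrapping, lines of action, moment arms, sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hipdyn.geometry import (
    GeometryError,
    compute_path,
    distribute_origins,
    line_of_action,
    moment_arm,
    moment_arm_sweep,
    muscle_spans_joint,
    wrap_over_cylinder,
)
from hipdyn.model import (
    Posture,
    SegmentKinematics,
    WrapCylinder,
    build_model,
    forward_kinematics,
)

IDENT = SegmentKinematics(R=np.eye(3), p=np.zeros(3))


def _cyl(side=1, r=1.0):
    return WrapCylinder("c", "seg", [0, 0, 0], [0, 0, 1], r, wrap_side=side)


# ---------------------------------------------------------------------------
# single-cylinder wrapping
# ---------------------------------------------------------------------------

def test_planar_tangent_arc_tangent_closed_form():
    _, L, engaged, arc = wrap_over_cylinder([-2, 0, 0], [2, 0, 0], _cyl(), IDENT)
    assert engaged
    assert np.isclose(L, 2 * np.sqrt(3) + np.pi / 3, atol=1e-12)
    assert np.isclose(arc["dphi"], np.pi / 3, atol=1e-12)


def test_clearing_segment_not_engaged():
    _, L, engaged, _ = wrap_over_cylinder([-2, 2, 0], [2, 2, 0], _cyl(), IDENT)
    assert not engaged
    assert np.isclose(L, 4.0)


def test_mirror_symmetry_equal_tangent_lengths():
    pts, L, engaged, arc = wrap_over_cylinder([-2, 0.5, 0], [2, 0.5, 0], _cyl(), IDENT)
    assert engaged
    t1 = np.linalg.norm(pts[0] - np.array([-2, 0.5, 0]))
    t2 = np.linalg.norm(pts[1] - np.array([2, 0.5, 0]))
    assert np.isclose(t1, t2, atol=1e-12)


def test_endpoint_inside_cylinder_raises_with_muscle_name():
    with pytest.raises(GeometryError, match="biceps"):
        wrap_over_cylinder([0.5, 0, 0], [2, 0, 0], _cyl(), IDENT, muscle_name="biceps")


def test_endpoint_on_axis_degenerate():
    with pytest.raises(GeometryError, match="axis"):
        wrap_over_cylinder([0, 0, 1], [2, 0, 0], _cyl(), IDENT, muscle_name="m")


def test_helical_wrap_length_is_flat_hypotenuse():
    _, L, engaged, _ = wrap_over_cylinder([-2, 0, -0.5], [2, 0, 1.0], _cyl(), IDENT)
    assert engaged
    assert np.isclose(L, np.hypot(2 * np.sqrt(3) + np.pi / 3, 1.5), atol=1e-12)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.integers(0, 10_000))
def test_wrapped_length_at_least_straight_distance(seed):
    rng = np.random.default_rng(seed)
    r = rng.uniform(0.2, 1.5)

    def pt():
        rho = r * rng.uniform(1.2, 4.0)
        th = rng.uniform(0, 2 * np.pi)
        return np.array([rho * np.cos(th), rho * np.sin(th), rng.uniform(-1, 1)])

    p, s = pt(), pt()
    side = int(rng.choice([-1, 1]))
    _, L, engaged, _ = wrap_over_cylinder(p, s, _cyl(side, r), IDENT)
    d = np.linalg.norm(s - p)
    if engaged:
        assert L >= d - 1e-12
    else:
        assert np.isclose(L, d, atol=1e-12)


def test_length_continuous_across_engage():
    """Sweep an endpoint across the grazing configuration; length is C0."""
    ys = np.linspace(0.95, 1.05, 201)
    Ls = [wrap_over_cylinder([-3, y, 0], [3, y, 0], _cyl(), IDENT)[1] for y in ys]
    steps = np.abs(np.diff(Ls))
    assert steps.max() < 2e-3   # fine sweep: no jump at engage/disengage


# ---------------------------------------------------------------------------
# whole paths
# ---------------------------------------------------------------------------

def test_two_node_path_is_euclidean(lowerlimb):
    kin = forward_kinematics(lowerlimb, Posture(q=np.zeros(12)))
    mus = next(m for m in lowerlimb.muscles if m.name == "vastus")
    path = compute_path(lowerlimb, kin, mus)
    d = sum(np.linalg.norm(path.points[i + 1].position - path.points[i].position)
            for i in range(len(path.points) - 1))
    assert np.isclose(path.length, d, atol=1e-12)


def test_collinear_via_point_preserves_length():
    cfg = {
        "root": "a", "floating_base": False, "subject_mass": 1, "subject_height": 1,
        "segments": [{"name": "a", "mass": 1.0, "length": 1.0}],
        "joints": [],
        "muscles": [
            {"name": "direct", "group": "g", "strength": 1,
             "nodes": [{"segment": "a", "point": [0, 0, 0]},
                       {"segment": "a", "point": [0.3, 0.3, 0.3]}]},
            {"name": "via", "group": "g", "strength": 1,
             "nodes": [{"segment": "a", "point": [0, 0, 0]},
                       {"segment": "a", "point": [0.15, 0.15, 0.15]},
                       {"segment": "a", "point": [0.3, 0.3, 0.3]}]},
        ],
    }
    m = build_model(cfg)
    kin = forward_kinematics(m, Posture(q=np.zeros(0)))
    L0 = compute_path(m, kin, m.muscles[0]).length
    L1 = compute_path(m, kin, m.muscles[1]).length
    assert np.isclose(L0, L1, atol=1e-12)


def test_condyle_wrap_reproduces_knee_flexor_defect(lowerlimb):
    """Wrapped hamstrings keep a knee arm at full extension; the unwrapped
    path has almost none — the motivating geometric defect."""
    from hipdyn.synthetic import perturb_model

    post = Posture(q=np.zeros(12))
    kin = forward_kinematics(lowerlimb, post)
    ham = next(m for m in lowerlimb.muscles if m.name == "ham_med")
    path = compute_path(lowerlimb, kin, ham)
    assert any(path.engaged.values())
    arm_wrapped = moment_arm(lowerlimb, post, ham, "knee_angle")
    bad, _ = perturb_model(lowerlimb, {"remove_wrap": ["ham_med"]})
    ham_bad = next(m for m in bad.muscles if m.name == "ham_med")
    arm_bare = moment_arm(bad, post, ham_bad, "knee_angle")
    assert arm_wrapped > 0.02
    assert abs(arm_bare) < 0.005


# ---------------------------------------------------------------------------
# lines of action
# ---------------------------------------------------------------------------

def test_line_of_action_simple_two_node(lowerlimb):
    kin = forward_kinematics(lowerlimb, Posture(q=np.zeros(12)))
    mus = next(m for m in lowerlimb.muscles if m.name == "glut_med_ant")
    u, anchor, (prox, dist) = line_of_action(lowerlimb, kin, mus, "hip")
    a = kin["pelvis"].point(mus.nodes[0][1])
    b = kin["femur"].point(mus.nodes[1][1])
    assert np.allclose(u, (a - b) / np.linalg.norm(a - b), atol=1e-12)
    assert np.allclose(anchor, b, atol=1e-12)


def test_line_of_action_unit_norm_random_postures(lowerlimb, rng):
    for _ in range(20):
        q = rng.uniform(-0.4, 0.4, 12)
        kin = forward_kinematics(lowerlimb, Posture(q=q))
        for mus in lowerlimb.muscles:
            if muscle_spans_joint(lowerlimb, mus, "hip"):
                u, _, _ = line_of_action(lowerlimb, kin, mus, "hip")
                assert np.isclose(np.linalg.norm(u), 1.0, atol=1e-12)


def test_line_of_action_crossing_piece_matches_path(lowerlimb):
    """Biarticular hamstring at the knee: the crossing span starts at the exit
    tangent of the femur-owned condyle wrap."""
    kin = forward_kinematics(lowerlimb, Posture(q=np.zeros(12)))
    ham = next(m for m in lowerlimb.muscles if m.name == "ham_lat")
    path = compute_path(lowerlimb, kin, ham)
    u, anchor, (prox, dist) = line_of_action(lowerlimb, kin, ham, "knee", path=path)
    # proximal point of the knee-crossing span is the last femur-side tangent
    femur_tangent = [p for p in path.points if p.kind == "tangent"][-1]
    assert np.allclose(prox, femur_tangent.position, atol=1e-12)
    assert np.allclose(anchor, path.points[-1].position, atol=1e-12)


def test_line_of_action_not_spanning_raises(lowerlimb):
    kin = forward_kinematics(lowerlimb, Posture(q=np.zeros(12)))
    vastus = next(m for m in lowerlimb.muscles if m.name == "vastus")
    with pytest.raises(GeometryError, match="span"):
        line_of_action(lowerlimb, kin, vastus, "hip")


# ---------------------------------------------------------------------------
# moment arms
# ---------------------------------------------------------------------------

def test_perpendicular_geometry_arm_equals_radius():
    rho = 0.07
    cfg = {
        "root": "base", "floating_base": False, "subject_mass": 1, "subject_height": 1,
        "segments": [{"name": "base", "mass": 1.0, "length": 0.3},
                     {"name": "link", "mass": 1.0, "com": [0, 0, -0.1],
                      "inertia": [[0.01, 0, 0], [0, 0.01, 0], [0, 0, 0.001]],
                      "length": 0.3}],
        "joints": [{"name": "h", "kind": "hinge", "parent": "base", "child": "link",
                    "axis": [0, 1, 0]}],
        "muscles": [{"name": "m", "group": "m", "strength": 1,
                     # far origin along -z, insertion at radius rho along x:
                     # the line of action is perpendicular to the lever
                     "nodes": [{"segment": "base", "point": [rho, 0, -5.0]},
                               {"segment": "link", "point": [rho, 0, -0.2]}]}],
    }
    m = build_model(cfg)
    arm = moment_arm(m, Posture(q=np.zeros(1)), m.muscles[0], "h_angle")
    assert np.isclose(abs(arm), rho, atol=1e-6)


def test_collinear_muscle_through_joint_centre_zero_arm():
    cfg = {
        "root": "base", "floating_base": False, "subject_mass": 1, "subject_height": 1,
        "segments": [{"name": "base", "mass": 1.0, "length": 0.3},
                     {"name": "link", "mass": 1.0, "com": [0, 0, -0.1],
                      "inertia": [[0.01, 0, 0], [0, 0.01, 0], [0, 0, 0.001]],
                      "length": 0.3}],
        "joints": [{"name": "h", "kind": "hinge", "parent": "base", "child": "link",
                    "axis": [0, 1, 0]}],
        "muscles": [{"name": "m", "group": "m", "strength": 1,
                     "nodes": [{"segment": "base", "point": [0, 0, 0.4]},
                               {"segment": "link", "point": [0, 0, -0.25]}]}],
    }
    m = build_model(cfg)
    arm = moment_arm(m, Posture(q=np.zeros(1)), m.muscles[0], "h_angle")
    assert abs(arm) < 1e-9


def _geometric_arm(model, post, mus, dof_name):
    """Independent oracle: g_k . ((anchor - joint centre) x u)."""
    from hipdyn.dynamics import _joint_velocity_basis
    from hipdyn.geometry import _dof_joint

    d = model.dof_index(dof_name)
    j = _dof_joint(model, d)
    kin = forward_kinematics(model, post)
    u, anchor, _ = line_of_action(model, kin, mus, j.name)
    centre = kin[j.parent_segment].point(j.location_in_parent)
    sl = model.joint_dof_slice(j.name)
    G = _joint_velocity_basis(model, j, kin[j.parent_segment], post.q[sl])
    g = G[:, d - sl.start]
    return float(g @ np.cross(anchor - centre, u))


def test_tendon_excursion_matches_geometric_oracle(lowerlimb, rng):
    """Dual-method equivalence on random smooth configurations."""
    pairs = [("glut_med_ant", "hip_rx"), ("glut_med_post", "hip_ry"),
             ("adductor", "hip_rx"), ("tfl", "hip_rz"),
             ("tibialis_ant", "talocrural_angle"), ("soleus", "talocrural_angle")]
    for _ in range(10):
        q = np.zeros(12)
        q[6:9] = rng.uniform(-0.3, 0.3, 3)
        q[10] = rng.uniform(-0.3, 0.3)
        post = Posture(q=q)
        for mname, dof in pairs:
            mus = next(m for m in lowerlimb.muscles if m.name == mname)
            a = moment_arm(lowerlimb, post, mus, dof)
            b = _geometric_arm(lowerlimb, post, mus, dof)
            assert abs(a - b) < 1e-5, (mname, dof, a, b)


def test_moment_arm_not_spanning_is_structural_zero(lowerlimb):
    vastus = next(m for m in lowerlimb.muscles if m.name == "vastus")
    assert moment_arm(lowerlimb, Posture(q=np.zeros(12)), vastus, "hip_ry") == 0.0
    assert not muscle_spans_joint(lowerlimb, vastus, "hip")


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def test_abductor_sweep_continuous_no_flags(abductor_rig):
    angles = np.radians(np.linspace(-40, 30, 71))
    for mus in abductor_rig.muscles:
        table, flags = moment_arm_sweep(abductor_rig, mus, "hip_rx", angles)
        assert table.shape == (71, 3)
        assert flags == []
        # abduction lever maintained over the whole range
        assert (-table[:, 1] > 0.02).all()


def test_undersized_wrap_flags_discontinuity():
    """A chord traversing an undersized cylinder pops off on the far side."""
    cfg = {
        "root": "base", "floating_base": False, "subject_mass": 10, "subject_height": 1,
        "segments": [{"name": "base", "mass": 1.0, "length": 0.3},
                     {"name": "link", "mass": 1.0, "com": [0, 0, 0.1],
                      "inertia": [[0.01, 0, 0], [0, 0.01, 0], [0, 0, 0.001]],
                      "length": 0.2}],
        "joints": [{"name": "hinge", "kind": "hinge", "parent": "base", "child": "link",
                    "axis": [0, 1, 0]}],
        "wrap_cylinders": [{"name": "cyl", "segment": "base",
                            "center": [0.0, 0.0, 0.175], "axis": [0, 1, 0],
                            "radius": 0.012, "wrap_side": -1}],
        "muscles": [{"name": "m", "group": "m", "strength": 100,
                     "nodes": [{"segment": "base", "point": [-0.25, 0.0, 0.115]},
                               {"segment": "link", "point": [0.0, 0.0, 0.25]}],
                     "wraps": [{"cylinder": "cyl", "span": 0}]}],
    }
    m = build_model(cfg)
    angles = np.radians(np.linspace(0, 60, 121))
    _, flags = moment_arm_sweep(m, m.muscles[0], "hinge_angle", angles)
    assert len(flags) >= 1


def test_empty_sweep_grid(lowerlimb):
    mus = lowerlimb.muscles[0]
    table, flags = moment_arm_sweep(lowerlimb, mus, "hip_rx", np.array([]))
    assert table.shape == (0, 3) and flags == []


def test_distribute_origins_even_arc_length():
    poly = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]])
    pts = distribute_origins(poly, 5)
    assert np.allclose(pts[0], [0, 0, 0]) and np.allclose(pts[-1], [1, 1, 0])
    d = [np.linalg.norm(pts[i + 1] - pts[i]) for i in range(4)]
    assert np.allclose(d, 0.5, atol=1e-12)
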