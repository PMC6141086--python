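"""Muscle path geometry: cylinder wrapping, lengths, lines of action, moment arms.

A muscle element is a chain of segment-fixed points. Between two consecutive
points a single wrapping cylinder may apply; when the straight span would cut
through the cylinder the path follows the shortest tangent–helix–tangent
route on the configured side. Because a wrapping surface belongs to exactly
one segment, the span where a muscle crosses a joint is always a straight
line, which defines the muscle's line of action at that joint.

Moment arms use the tendon-excursion definition, -dL/dq, evaluated by
Richardson-extrapolated central differences; the sign convention is that a
positive arm means positive muscle tension produces a positive generalized
force on that dof.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    ModelError,
    MuscleElement,
    Posture,
    SegmentKinematics,
    SkeletalModel,
    WrapCylinder,
    forward_kinematics,
)

__all__ = [
    "GeometryError",
    "MusclePath",
    "PathPoint",
    "wrap_over_cylinder",
    "compute_path",
    "line_of_action",
    "moment_arm",
    "moment_arm_matrix",
    "moment_arm_sweep",
    "muscle_spans_joint",
    "distribute_origins",
]


class GeometryError(ValueError):
    pass


@dataclass
class PathPoint:
    """A distinguished point on a muscle path with its owning segment."""

    position: np.ndarray
    segment: str
    kind: str  # "node" | "tangent"


@dataclass
class MusclePath:
    """Piecewise muscle path: straight segments and helical arcs on cylinders."""

    points: list[PathPoint]
    length: float
    engaged: dict[int, bool] = field(default_factory=dict)
    arcs: list[dict] = field(default_factory=list)

    @property
    def straight_distance(self) -> float:
        return float(np.linalg.norm(self.points[-1].position - self.points[0].position))


# ---------------------------------------------------------------------------
# single-cylinder wrapping
# ---------------------------------------------------------------------------

def _cylinder_frame(cyl: WrapCylinder, kin: SegmentKinematics):
    """World-frame (origin, x̂, ŷ, ẑ=axis) basis of a posed cylinder."""
    c = kin.point(cyl.center)
    z = kin.R @ cyl.axis
    # any perpendicular; deterministic choice
    ref = np.array([1.0, 0.0, 0.0])
    if abs(z @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    x = ref - (ref @ z) * z
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return c, x, y, z


def _seg_min_dist_2d(p, s):
    """Min distance of the 2D segment p→s to the origin, attained in [0,1]."""
    d = s - p
    dd = d @ d
    if dd == 0:
        return np.hypot(*p)
    t = np.clip(-(p @ d) / dd, 0.0, 1.0)
    c = p + t * d
    return np.hypot(*c)


def wrap_over_cylinder(p_start, p_end, cyl: WrapCylinder, kin: SegmentKinematics,
                       muscle_name: str = "?"):
    """Shortest path from ``p_start`` to ``p_end`` around a posed cylinder.

    Returns ``(points, length, engaged, arc)`` where ``points`` are the world
    tangent points (empty when disengaged) and ``arc`` holds the helix
    parameters. The path engages when the straight span's projected distance
    to the cylinder axis is below the radius; it then follows the two tangent
    lines and the geodesic (helix) between the tangent points on the
    configured ``wrap_side``. The geodesic property makes the out-of-plane
    coordinate advance linearly with unrolled arc length, so the total length
    is ``hypot(l1 + r*dphi + l2, dz)`` built from projected lengths.
    """
    p_start = np.asarray(p_start, float)
    p_end = np.asarray(p_end, float)
    c, x, y, z = _cylinder_frame(cyl, kin)
    r, side = cyl.radius, cyl.wrap_side

    def to_local(v):
        w = v - c
        return np.array([w @ x, w @ y, w @ z])

    P = to_local(p_start)
    S = to_local(p_end)
    for name, pt in (("start", P), ("end", S)):
        rho = np.hypot(pt[0], pt[1])
        if rho < 1e-12:
            raise GeometryError(
                f"muscle {muscle_name!r}: path {name}point lies on wrap axis of {cyl.name!r}"
            )
        if rho <= r * (1.0 + 1e-12):
            raise GeometryError(
                f"muscle {muscle_name!r}: path {name}point inside wrap cylinder {cyl.name!r}"
            )

    p2, s2 = P[:2], S[:2]
    if _seg_min_dist_2d(p2, s2) >= r:
        length = float(np.linalg.norm(p_end - p_start))
        return [], length, False, None

    # 2D tangent construction
    def tangent_angle(pt2, entry: bool):
        rho = np.hypot(pt2[0], pt2[1])
        alpha = np.arctan2(pt2[1], pt2[0])
        beta = np.arccos(np.clip(r / rho, -1.0, 1.0))
        return alpha - side * beta if entry else alpha + side * beta

    th1 = tangent_angle(p2, entry=True)
    th2 = tangent_angle(s2, entry=False)
    dphi = (side * (th1 - th2)) % (2.0 * np.pi)
    l1 = float(np.sqrt(max(p2 @ p2 - r * r, 0.0)))
    l2 = float(np.sqrt(max(s2 @ s2 - r * r, 0.0)))
    larc = r * dphi
    flat = l1 + larc + l2
    dz = S[2] - P[2]
    length = float(np.hypot(flat, dz))

    # z of tangent points: linear in unrolled arc length (geodesic)
    z1 = P[2] + dz * (l1 / flat) if flat > 0 else P[2]
    z2 = P[2] + dz * ((l1 + larc) / flat) if flat > 0 else S[2]
    t1_local = np.array([r * np.cos(th1), r * np.sin(th1), z1])
    t2_local = np.array([r * np.cos(th2), r * np.sin(th2), z2])

    def to_world(v):
        return c + v[0] * x + v[1] * y + v[2] * z

    arc = {
        "cylinder": cyl.name,
        "theta1": float(th1),
        "theta2": float(th2),
        "dphi": float(dphi),
        "z1": float(z1),
        "z2": float(z2),
        "frame": (c, x, y, z),
    }
    return [to_world(t1_local), to_world(t2_local)], length, True, arc


# ---------------------------------------------------------------------------
# whole-path computation
# ---------------------------------------------------------------------------

def compute_path(model: SkeletalModel, kin: dict[str, SegmentKinematics],
                 muscle: MuscleElement) -> MusclePath:
    """World-space path of a muscle element in the posed model."""
    pts: list[PathPoint] = []
    arcs: list[dict] = []
    engaged: dict[int, bool] = {}
    length = 0.0
    world_nodes = [(seg, kin[seg].point(loc)) for seg, loc in muscle.nodes]
    pts.append(PathPoint(world_nodes[0][1], world_nodes[0][0], "node"))
    for i in range(len(world_nodes) - 1):
        a_seg, a = world_nodes[i]
        b_seg, b = world_nodes[i + 1]
        if i in muscle.wraps:
            cyl = muscle.wraps[i]
            try:
                tpts, piece_len, eng, arc = wrap_over_cylinder(
                    a, b, cyl, kin[cyl.segment], muscle_name=muscle.name
                )
            except GeometryError:
                raise
            engaged[i] = eng
            if eng:
                pts.append(PathPoint(tpts[0], cyl.segment, "tangent"))
                pts.append(PathPoint(tpts[1], cyl.segment, "tangent"))
                arcs.append(arc)
            length += piece_len
        else:
            length += float(np.linalg.norm(b - a))
        pts.append(PathPoint(b, b_seg, "node"))
    return MusclePath(points=pts, length=length, engaged=engaged, arcs=arcs)


def muscle_length(model: SkeletalModel, posture: Posture, muscle: MuscleElement,
                  kin=None) -> float:
    if kin is None:
        kin = forward_kinematics(model, posture)
    return compute_path(model, kin, muscle).length


# ---------------------------------------------------------------------------
# lines of action
# ---------------------------------------------------------------------------

def muscle_spans_joint(model: SkeletalModel, muscle: MuscleElement, joint_name: str) -> bool:
    distal = model.distal_segments(joint_name)
    owners = {s for s, _ in muscle.nodes}
    return bool(owners & distal) and bool(owners - distal)


def line_of_action(model: SkeletalModel, kin: dict[str, SegmentKinematics],
                   muscle: MuscleElement, joint_name: str,
                   path: MusclePath | None = None):
    """Unit vector of the straight path span crossing ``joint_name``.

    Returns ``(u, anchor, (prox_point, dist_point))`` with ``u`` oriented from
    the distal-side point toward the proximal-side point (the direction the
    muscle pulls the distal body) and ``anchor`` the distal-side point. The
    crossing span runs from the last proximal-side path point (attachment node
    or exit tangent of a proximal-owned wrap) to the first distal-side point.
    """
    if not muscle_spans_joint(model, muscle, joint_name):
        raise GeometryError(f"muscle {muscle.name!r} does not span joint {joint_name!r}")
    if path is None:
        path = compute_path(model, kin, muscle)
    distal = model.distal_segments(joint_name)
    sides = [pp.segment in distal for pp in path.points]
    for k in range(len(sides) - 1):
        if not sides[k] and sides[k + 1]:
            prox_pt = path.points[k].position
            dist_pt = path.points[k + 1].position
            u = prox_pt - dist_pt
            n = np.linalg.norm(u)
            if n < 1e-12:
                raise GeometryError(
                    f"muscle {muscle.name!r}: degenerate crossing span at joint {joint_name!r}"
                )
            return u / n, dist_pt, (prox_pt, dist_pt)
    raise GeometryError(
        f"muscle {muscle.name!r}: no proximal→distal crossing found at joint {joint_name!r}"
    )


# ---------------------------------------------------------------------------
# moment arms (tendon excursion)
# ---------------------------------------------------------------------------

def _dof_joint(model: SkeletalModel, dof_index: int):
    """Joint owning a generalized coordinate (None for floating-base dofs)."""
    base = 6 if model.floating_base else 0
    if dof_index < base:
        return None
    for seg in model.topological_order():
        j = model.joint_of_child(seg)
        if j is None:
            continue
        sl = model.joint_dof_slice(j.name)
        if sl.start <= dof_index < sl.stop:
            return j
    raise ModelError(f"dof index {dof_index} out of range")


def moment_arm(model: SkeletalModel, posture: Posture, muscle: MuscleElement,
               dof: int | str, step: float = 1e-5) -> float:
    """Signed moment arm of a muscle about one generalized coordinate, in m.

    Tendon-excursion definition ``-dL/dq`` by central difference with one
    Richardson extrapolation step (h and h/2). Returns 0.0 when the muscle
    does not span the joint owning the dof (check ``muscle_spans_joint`` to
    distinguish a structural zero from a true zero arm).
    """
    if isinstance(dof, str):
        dof = model.dof_index(dof)
    j = _dof_joint(model, dof)
    if j is None or not muscle_spans_joint(model, muscle, j.name):
        return 0.0

    def L(h):
        q = np.array(posture.q, dtype=float)
        q[dof] += h
        return muscle_length(model, Posture(q=q), muscle)

    def central(h):
        return (L(h) - L(-h)) / (2.0 * h)

    d1 = central(step)
    d2 = central(step / 2.0)
    return float(-(4.0 * d2 - d1) / 3.0)


def moment_arm_matrix(model: SkeletalModel, posture: Posture,
                      muscles: list[MuscleElement], dofs: list[int]) -> np.ndarray:
    """Moment-arm matrix R with R[k, i] = arm of muscle i about dof k."""
    R = np.zeros((len(dofs), len(muscles)))
    for i, mus in enumerate(muscles):
        for k, d in enumerate(dofs):
            R[k, i] = moment_arm(model, posture, mus, d)
    return R


def moment_arm_sweep(model: SkeletalModel, muscle: MuscleElement, dof: int | str,
                     angles: np.ndarray, q_ref: np.ndarray | None = None,
                     jump_threshold: float = 0.01):
    """Moment arm of one muscle over a grid of one dof's angles.

    Returns ``(table, flags)``: table rows (angle_rad, arm_m, engaged) and a
    list of flagged grid indices where the arm jumps by more than
    ``jump_threshold`` m between adjacent grid points — the discontinuity
    check used to verify that wrapped muscles engage and disengage smoothly.
    """
    if isinstance(dof, str):
        dof = model.dof_index(dof)
    angles = np.asarray(angles, float)
    if angles.size == 0:
        return np.zeros((0, 3)), []
    q0 = np.zeros(model.n_dof) if q_ref is None else np.array(q_ref, float)
    rows = []
    for a in angles:
        q = q0.copy()
        q[dof] = a
        post = Posture(q=q)
        arm = moment_arm(model, post, muscle, dof)
        kin = forward_kinematics(model, post)
        path = compute_path(model, kin, muscle)
        eng = any(path.engaged.values()) if path.engaged else False
        rows.append((a, arm, float(eng)))
    table = np.array(rows)
    arms = table[:, 1]
    flags = [int(i) for i in range(1, len(arms)) if abs(arms[i] - arms[i - 1]) > jump_threshold]
    return table, flags


# ---------------------------------------------------------------------------
# attachment-area helpers
# ---------------------------------------------------------------------------

def distribute_origins(polyline: np.ndarray, n: int) -> np.ndarray:
    """Place ``n`` element origins evenly (by arc length) along a polyline.

    Helper for redistributing the origins of a multi-element muscle across
    the span of its attachment area; purely config-data generation.
    """
    pl = np.asarray(polyline, float)
    if pl.ndim != 2 or pl.shape[0] < 2:
        raise GeometryError("polyline needs at least two points")
    seglen = np.linalg.norm(np.diff(pl, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    targets = np.linspace(0.0, s[-1], n)
    out = np.empty((n, pl.shape[1]))
    for k, t in enumerate(targets):
        i = int(np.clip(np.searchsorted(s, t) - 1, 0, len(seglen) - 1))
        w = (t - s[i]) / seglen[i] if seglen[i] > 0 else 0.0
        out[k] = pl[i] + w * (pl[i + 1] - pl[i])
    return out
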