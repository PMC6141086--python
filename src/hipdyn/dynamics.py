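"""Inverse dynamics: net joint loads and single-limb free-body force terms.

A recursive Newton–Euler pass from the leaves to the root computes, for every
joint, the force and moment that all structures crossing that joint must
supply given the motion (q, qd, qdd), gravity and the external (ground
reaction) loads. Generalized net moments — the projections onto each joint's
velocity basis — are what muscle recruitment must balance, since muscle
moment arms are defined against the same generalized coordinates.

The limb free-body terms mirror the single-limb force balance

    HCF + F_inertial + F_gravity + GRF + MF_hip = 0

with F_inertial = -Σ m_s a_s and F_gravity = Σ m_s g over every segment
distal to the hip cut, and GRF the sum of plate forces applied to those
segments. Signs follow the convention that a positive force pulls (or
pushes) the system, so each term is a force acting ON the free body.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Posture, SegmentKinematics, SkeletalModel, fk_with_derivatives

__all__ = [
    "ExternalLoad",
    "ExternalLoadSet",
    "NetJointLoads",
    "LimbFreeBodyState",
    "DynamicsError",
    "inverse_dynamics_frame",
    "inverse_dynamics",
    "limb_free_body",
    "generalized_base_load",
]


class DynamicsError(RuntimeError):
    pass


@dataclass
class ExternalLoad:
    """One external force applied to a segment at a world point."""

    segment: str
    force: np.ndarray          # N, world
    point: np.ndarray          # application point (centre of pressure), world
    free_moment: np.ndarray = field(default_factory=lambda: np.zeros(3))


@dataclass
class ExternalLoadSet:
    """Per-frame external loads (typically GRF at the centre of pressure)."""

    frames: list[list[ExternalLoad]]

    def __len__(self):
        return len(self.frames)


@dataclass
class JointLoad:
    force: np.ndarray            # force from parent on child, world frame
    moment: np.ndarray           # moment about the joint centre, world frame
    moment_child: np.ndarray     # same moment resolved in the child frame
    generalized: np.ndarray      # projection on the joint's dof velocity basis
    hinge_scalar: float | None = None


@dataclass
class NetJointLoads:
    """Per-frame, per-joint net loads plus the floating-base residual load."""

    frames: list[dict[str, JointLoad]]
    base_residual: list[np.ndarray] | None = None   # 6-vector per frame

    def moment_series(self, joint: str, component: int | None = None) -> np.ndarray:
        if component is None:
            return np.array([f[joint].hinge_scalar for f in self.frames])
        return np.array([f[joint].moment[component] for f in self.frames])

    def generalized_series(self, joint: str) -> np.ndarray:
        return np.array([f[joint].generalized for f in self.frames])


@dataclass
class LimbFreeBodyState:
    """Free-body force terms for the limb distal to a joint cut, per frame."""

    f_inertial: np.ndarray   # (n, 3)
    f_gravity: np.ndarray    # (n, 3)
    grf_sum: np.ndarray      # (n, 3)


# ---------------------------------------------------------------------------
# Newton–Euler recursion
# ---------------------------------------------------------------------------

def _joint_velocity_basis(model: SkeletalModel, joint, kin_parent: SegmentKinematics,
                          q_joint: np.ndarray) -> np.ndarray:
    """Columns g_k (world) with ω_joint = Σ g_k * qd_k.

    For a hinge the single column is the world hinge axis. For a ball joint
    with intrinsic X-Y-Z Euler angles the columns are e_x, Rx e_y, Rx Ry e_z
    rotated into the world by the parent attitude. The generalized net moment
    on dof k is g_k · n_world, consistent with the tendon-excursion moment
    arm -dL/dq_k.
    """
    from .model import rot_x, rot_y

    Rp = kin_parent.R
    if joint.kind == "hinge":
        return (Rp @ joint.hinge_axis).reshape(3, 1)
    ex = np.array([1.0, 0, 0])
    ey = np.array([0, 1.0, 0])
    ez = np.array([0, 0, 1.0])
    g1 = ex
    g2 = rot_x(q_joint[0]) @ ey
    g3 = rot_x(q_joint[0]) @ rot_y(q_joint[1]) @ ez
    return Rp @ np.column_stack([g1, g2, g3])


def inverse_dynamics_frame(model: SkeletalModel, posture: Posture,
                           loads: list[ExternalLoad] | None = None,
                           kin: dict[str, SegmentKinematics] | None = None):
    """Net joint loads for a single frame.

    Requires qd and qdd in the posture. Returns ``(joint_loads, base_load)``
    where ``base_load`` is the 6-vector (force, moment about the root frame
    origin, world axes) that residual actuators must supply at a floating
    base; it is None for fixed-base models.
    """
    if posture.qd is None or posture.qdd is None:
        raise DynamicsError("inverse dynamics needs qd and qdd in the posture")
    if kin is None:
        kin = fk_with_derivatives(model, posture)
    loads = loads or []
    g = model.gravity

    ext_by_seg: dict[str, list[ExternalLoad]] = {}
    for ld in loads:
        if ld.segment not in model.segments:
            raise DynamicsError(f"external load targets unknown segment {ld.segment!r}")
        ext_by_seg.setdefault(ld.segment, []).append(ld)

    order = model.topological_order()
    children: dict[str, list[str]] = {}
    for j in model.joints.values():
        children.setdefault(j.parent_segment, []).append(j.child_segment)

    # backward pass: forces/moments transmitted through each segment's parent joint
    f_at: dict[str, np.ndarray] = {}
    n_at: dict[str, np.ndarray] = {}    # moment about own parent-joint centre
    jcentre: dict[str, np.ndarray] = {}
    for seg in reversed(order):
        s = model.segments[seg]
        k = kin[seg]
        xc = k.point(s.com_local)
        acc = k.pdd + k.Rdd @ s.com_local
        Iw = k.R @ s.inertia_local @ k.R.T
        om, al = k.omega, k.alpha
        Ldot = Iw @ al + np.cross(om, Iw @ om)

        F = s.mass * acc - s.mass * g
        N = Ldot  # about com
        for ld in ext_by_seg.get(seg, []):
            F = F - ld.force
            N = N - np.cross(ld.point - xc, ld.force) - ld.free_moment
        for ch in children.get(seg, []):
            F = F + f_at[ch]
            N = N + n_at[ch] + np.cross(jcentre[ch] - xc, f_at[ch])
        j = model.joint_of_child(seg)
        if j is not None:
            jc = kin[j.parent_segment].point(j.location_in_parent)
        else:
            jc = k.p   # root: refer to the base frame origin
        jcentre[seg] = jc
        f_at[seg] = F
        n_at[seg] = N + np.cross(xc - jc, F)

    out: dict[str, JointLoad] = {}
    q = posture.q
    for seg in order:
        j = model.joint_of_child(seg)
        if j is None:
            continue
        sl = model.joint_dof_slice(j.name)
        G = _joint_velocity_basis(model, j, kin[j.parent_segment], np.real(q[sl]))
        n_world = n_at[seg]
        load = JointLoad(
            force=f_at[seg],
            moment=n_world,
            moment_child=kin[seg].R.T @ n_world,
            generalized=G.T @ n_world,
        )
        if j.kind == "hinge":
            load.hinge_scalar = float(load.generalized[0])
        out[j.name] = load

    base_load = None
    if model.floating_base:
        base_load = np.concatenate([f_at[model.root], n_at[model.root]])
    return out, base_load


def inverse_dynamics(model: SkeletalModel, postures: list[Posture],
                     load_set: ExternalLoadSet | None = None) -> NetJointLoads:
    """Net joint loads over a posture series (feet-to-pelvis recursion)."""
    if load_set is not None and len(load_set) != len(postures):
        raise DynamicsError(
            f"load series ({len(load_set)}) and posture series ({len(postures)}) differ"
        )
    frames, base = [], []
    for i, post in enumerate(postures):
        loads = load_set.frames[i] if load_set is not None else None
        jl, bl = inverse_dynamics_frame(model, post, loads)
        frames.append(jl)
        base.append(bl)
    return NetJointLoads(frames=frames, base_residual=base if base[0] is not None else None)


def generalized_base_load(base_load: np.ndarray) -> np.ndarray:
    """Residual actuator loads at the floating base (reported, not recruited)."""
    return np.asarray(base_load)


# ---------------------------------------------------------------------------
# limb free body
# ---------------------------------------------------------------------------

def limb_free_body(model: SkeletalModel, postures: list[Posture],
                   load_set: ExternalLoadSet | None, cut_joint: str) -> LimbFreeBodyState:
    """F_inertial, F_gravity and GRF sums for the limb distal to ``cut_joint``."""
    if cut_joint not in model.joints:
        raise DynamicsError(f"unknown joint {cut_joint!r}")
    distal = model.distal_segments(cut_joint)
    n = len(postures)
    fi = np.zeros((n, 3))
    fg = np.zeros((n, 3))
    gs = np.zeros((n, 3))
    g = model.gravity
    for i, post in enumerate(postures):
        kin = fk_with_derivatives(model, post)
        for seg in distal:
            s = model.segments[seg]
            if s.mass == 0:
                continue
            k = kin[seg]
            if k.pdd is None:
                raise DynamicsError("limb_free_body needs accelerations (qdd)")
            acc = k.pdd + k.Rdd @ s.com_local
            fi[i] -= s.mass * acc
            fg[i] += s.mass * g
        if load_set is not None:
            for ld in load_set.frames[i]:
                if ld.segment in distal:
                    gs[i] += ld.force
    return LimbFreeBodyState(f_inertial=fi, f_gravity=fg, grf_sum=gs)
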