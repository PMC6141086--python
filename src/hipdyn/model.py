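"""Rigid-body skeletal model: segments, joints, muscles, markers, scaling.

The model is a tree of rigid segments rooted at the pelvis. Joints are either
3-DOF ball-and-socket (hip) or 1-DOF hinges (knee, talocrural, subtalar); the
patella, when present, is pose-coupled to the knee flexion angle and adds no
degrees of freedom. Muscles are constant-strength actuators whose geometry is
an ordered chain of segment-fixed points, optionally wrapped over cylinders.

All quantities are SI (m, kg, s, N) in right-handed frames; body-weight
normalisation happens only at reporting boundaries.

Rotation helpers are written dtype-generically (plain ``sin``/``cos`` matrix
products, no compiled rotation library) so that complex-step differentiation
works on every kinematic quantity; the test-suite oracles rely on this.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "Segment",
    "Joint",
    "PatellaCoupler",
    "MarkerDef",
    "MarkerProtocol",
    "WrapCylinder",
    "MuscleElement",
    "SkeletalModel",
    "Posture",
    "AnthropometricScaling",
    "ModelError",
    "build_model",
    "load_model",
    "forward_kinematics",
    "fk_with_derivatives",
    "scale_model",
    "fat_fraction_from_bmi",
    "lmf_strength_factor",
]

GRAVITY_DEFAULT = np.array([0.0, 0.0, -9.81])


class ModelError(ValueError):
    """Raised for structural or referential defects in a model definition."""


# ---------------------------------------------------------------------------
# rotations (dtype-generic: work for float and complex arguments)
# ---------------------------------------------------------------------------

def _eye(dtype):
    return np.eye(3, dtype=dtype)


def rot_x(t):
    c, s = np.cos(t), np.sin(t)
    one, zero = c * 0 + 1, c * 0
    return np.array([[one, zero, zero], [zero, c, -s], [zero, s, c]])


def rot_y(t):
    c, s = np.cos(t), np.sin(t)
    one, zero = c * 0 + 1, c * 0
    return np.array([[c, zero, s], [zero, one, zero], [-s, zero, c]])


def rot_z(t):
    c, s = np.cos(t), np.sin(t)
    one, zero = c * 0 + 1, c * 0
    return np.array([[c, -s, zero], [s, c, zero], [zero, zero, one]])


def skew(v):
    return np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])


def rodrigues(axis, t):
    """Rotation of angle ``t`` about a unit ``axis`` (Rodrigues formula)."""
    a = np.asarray(axis, dtype=float)
    k = skew(a)
    return np.eye(3) + np.sin(t) * k + (1.0 - np.cos(t)) * (k @ k)


_EULER_AXES = (np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))
_EULER_ROTS = (rot_x, rot_y, rot_z)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """A rigid body of the kinematic tree.

    ``com_local`` and ``inertia_local`` are about the segment frame origin /
    the centre of mass respectively, expressed in the segment frame. ``length``
    is the characteristic (longitudinal) dimension used by linear scaling.
    """

    name: str
    mass: float = 0.0
    com_local: np.ndarray = field(default_factory=lambda: np.zeros(3))
    inertia_local: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    length: float = 1.0
    parent_joint: str | None = None

    def __post_init__(self):
        self.com_local = np.asarray(self.com_local, dtype=float)
        self.inertia_local = np.asarray(self.inertia_local, dtype=float)
        if self.mass < 0:
            raise ModelError(f"segment {self.name!r}: negative mass")
        if not np.allclose(self.inertia_local, self.inertia_local.T, atol=1e-12):
            raise ModelError(f"segment {self.name!r}: inertia not symmetric")
        if self.mass > 0 and np.min(np.linalg.eigvalsh(self.inertia_local)) < -1e-12:
            raise ModelError(f"segment {self.name!r}: inertia not PSD")


@dataclass
class Joint:
    """Connection between two segments: ``ball`` (3 dof) or ``hinge`` (1 dof)."""

    name: str
    kind: str
    parent_segment: str
    child_segment: str
    location_in_parent: np.ndarray
    location_in_child: np.ndarray
    hinge_axis: np.ndarray | None = None
    dof_names: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("ball", "hinge"):
            raise ModelError(f"joint {self.name!r}: unknown kind {self.kind!r}")
        self.location_in_parent = np.asarray(self.location_in_parent, dtype=float)
        self.location_in_child = np.asarray(self.location_in_child, dtype=float)
        if self.kind == "hinge":
            if self.hinge_axis is None:
                raise ModelError(f"joint {self.name!r}: hinge needs an axis")
            self.hinge_axis = np.asarray(self.hinge_axis, dtype=float)
            n = np.linalg.norm(self.hinge_axis)
            if abs(n - 1.0) > 1e-9:
                self.hinge_axis = self.hinge_axis / n
        if not self.dof_names:
            base = self.name
            self.dof_names = (
                (f"{base}_rx", f"{base}_ry", f"{base}_rz")
                if self.kind == "ball"
                else (f"{base}_angle",)
            )

    @property
    def n_dof(self) -> int:
        return 3 if self.kind == "ball" else 1


@dataclass
class PatellaCoupler:
    """Patella pose as an interpolated function of knee flexion angle.

    ``pose_table`` rows: (knee_angle_rad, tx, ty, tz, rx, ry, rz) — the patella
    frame relative to the femur frame, Euler XYZ.  Interpolation is linear and
    strictly restricted to the table range.
    """

    knee_joint: str
    patella_segment: str
    femur_segment: str
    pose_table: np.ndarray

    def __post_init__(self):
        self.pose_table = np.asarray(self.pose_table, dtype=float)
        ang = self.pose_table[:, 0]
        if not np.all(np.diff(ang) > 0):
            raise ModelError("patella coupler table must be strictly increasing in angle")

    def pose(self, knee_angle: float):
        ang = self.pose_table[:, 0]
        a = float(np.real(knee_angle))
        if a < ang[0] - 1e-12 or a > ang[-1] + 1e-12:
            raise ModelError(
                f"knee angle {a:.4f} rad outside patella coupler range "
                f"[{ang[0]:.4f}, {ang[-1]:.4f}]"
            )
        vals = [np.interp(a, ang, self.pose_table[:, k]) for k in range(1, 7)]
        t = np.array(vals[:3])
        R = rot_x(vals[3]) @ rot_y(vals[4]) @ rot_z(vals[5])
        return R, t


@dataclass
class MarkerDef:
    name: str
    segment: str
    local: np.ndarray
    weight: float = 1.0
    is_bony_landmark: bool = False
    optimize_local: tuple[bool, bool, bool] = (False, False, False)

    def __post_init__(self):
        self.local = np.asarray(self.local, dtype=float)
        if not np.isfinite(self.weight) or self.weight < 0:
            raise ModelError(f"marker {self.name!r}: weight must be finite and >= 0")


@dataclass
class MarkerProtocol:
    """Named skin markers with owner segment, local position and fit weight."""

    markers: dict[str, MarkerDef] = field(default_factory=dict)

    def __post_init__(self):
        if self.markers:
            bony = [m.weight for m in self.markers.values() if m.is_bony_landmark]
            other = [m.weight for m in self.markers.values() if not m.is_bony_landmark]
            if bony and other and min(bony) < max(other):
                raise ModelError(
                    "bony-landmark marker weights must be >= non-landmark weights"
                )

    def __iter__(self):
        return iter(self.markers.values())

    def __getitem__(self, name):
        return self.markers[name]


@dataclass
class WrapCylinder:
    """Infinite cylinder obstacle, fixed in one segment's frame.

    ``wrap_side`` (+1/-1) selects the chirality of the wrap about the axis:
    the on-surface arc runs in the ``+wrap_side`` angular direction from the
    entry tangent point to the exit tangent point, so the path can never slide
    off to the other side as the joint articulates.
    """

    name: str
    segment: str
    center: np.ndarray
    axis: np.ndarray
    radius: float
    wrap_side: int = 1

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise ModelError(f"wrap {self.name!r}: zero axis")
        self.axis = self.axis / n
        if self.radius <= 0:
            raise ModelError(f"wrap {self.name!r}: radius must be > 0")
        if self.wrap_side not in (-1, 1):
            raise ModelError(f"wrap {self.name!r}: wrap_side must be +1 or -1")


@dataclass
class MuscleElement:
    """One muscle element: origin→insertion node chain with optional wraps.

    ``nodes``: ordered list of (segment_name, local_point).  ``wraps`` maps the
    index ``i`` of a path span (between node i and node i+1) to a WrapCylinder.
    ``strength`` is the constant isometric strength N_i; activation is
    force / strength.
    """

    name: str
    group: str
    nodes: list[tuple[str, np.ndarray]]
    wraps: dict[int, WrapCylinder] = field(default_factory=dict)
    strength: float = 1000.0

    def __post_init__(self):
        if len(self.nodes) < 2:
            raise ModelError(f"muscle {self.name!r}: needs at least 2 path nodes")
        if self.strength <= 0:
            raise ModelError(f"muscle {self.name!r}: strength must be > 0")
        self.nodes = [(s, np.asarray(p, dtype=float)) for s, p in self.nodes]
        for i in self.wraps:
            if not (0 <= i < len(self.nodes) - 1):
                raise ModelError(f"muscle {self.name!r}: wrap span {i} out of range")


@dataclass
class Posture:
    """Generalized coordinates (and optionally rates) at one instant."""

    q: np.ndarray
    qd: np.ndarray | None = None
    qdd: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self):
        self.q = np.asarray(self.q)
        if self.qd is not None:
            self.qd = np.asarray(self.qd)
        if self.qdd is not None:
            self.qdd = np.asarray(self.qdd)


@dataclass
class SkeletalModel:
    segments: dict[str, Segment]
    joints: dict[str, Joint]
    root: str
    muscles: list[MuscleElement] = field(default_factory=list)
    markers: MarkerProtocol = field(default_factory=MarkerProtocol)
    patella_couplers: list[PatellaCoupler] = field(default_factory=list)
    gravity: np.ndarray = field(default_factory=lambda: GRAVITY_DEFAULT.copy())
    subject_mass: float | None = None
    subject_height: float | None = None
    floating_base: bool = True
    # analysis conventions shipped with the model: hip/knee joint names, femur
    # segment, clinical-frame anterior axis, constrained recruitment dofs, ...
    analysis: dict = field(default_factory=dict)

    def __post_init__(self):
        self.gravity = np.asarray(self.gravity, dtype=float)
        self._validate()

    # -- structure ---------------------------------------------------------
    def _validate(self):
        for j in self.joints.values():
            for s in (j.parent_segment, j.child_segment):
                if s not in self.segments:
                    raise ModelError(f"joint {j.name!r} references unknown segment {s!r}")
        # every non-root segment must be the child of exactly one joint
        children = {}
        for j in self.joints.values():
            if j.child_segment in children:
                raise ModelError(f"segment {j.child_segment!r} has two parent joints")
            children[j.child_segment] = j
        coupled = {c.patella_segment for c in self.patella_couplers}
        for name in self.segments:
            if name == self.root or name in coupled:
                continue
            if name not in children:
                raise ModelError(f"segment {name!r} is not connected to the tree")
            self.segments[name].parent_joint = children[name].name
        # cycle check via topological walk from root
        order = self.topological_order()
        reachable = set(order) | coupled
        if reachable != set(self.segments):
            missing = set(self.segments) - reachable
            raise ModelError(f"cyclic or disconnected joint graph at segments {sorted(missing)}")
        for m in self.muscles:
            for s, _ in m.nodes:
                if s not in self.segments:
                    raise ModelError(f"muscle {m.name!r} references unknown segment {s!r}")
            for w in m.wraps.values():
                if w.segment not in self.segments:
                    raise ModelError(f"wrap {w.name!r} references unknown segment {w.segment!r}")
        for mk in self.markers:
            if mk.segment not in self.segments:
                raise ModelError(f"marker {mk.name!r} references unknown segment {mk.segment!r}")

    def topological_order(self) -> list[str]:
        """Segment names root-first; raises on cycles."""
        kids = {}
        for j in self.joints.values():
            kids.setdefault(j.parent_segment, []).append(j.child_segment)
        order, seen = [], set()
        stack = [self.root]
        while stack:
            s = stack.pop()
            if s in seen:
                raise ModelError(f"cycle detected at segment {s!r}")
            seen.add(s)
            order.append(s)
            stack.extend(sorted(kids.get(s, []), reverse=True))
        return order

    def joint_of_child(self, segment: str) -> Joint | None:
        for j in self.joints.values():
            if j.child_segment == segment:
                return j
        return None

    # -- dof bookkeeping ---------------------------------------------------
    @property
    def dof_names(self) -> list[str]:
        names = []
        if self.floating_base:
            names += [f"{self.root}_{c}" for c in ("tx", "ty", "tz", "rx", "ry", "rz")]
        for seg in self.topological_order():
            j = self.joint_of_child(seg)
            if j is not None:
                names += list(j.dof_names)
        return names

    @property
    def n_dof(self) -> int:
        n = 6 if self.floating_base else 0
        return n + sum(j.n_dof for j in self.joints.values())

    def dof_index(self, dof_name: str) -> int:
        return self.dof_names.index(dof_name)

    def joint_dof_slice(self, joint_name: str) -> slice:
        """Indices of a joint's dofs within the generalized coordinate vector."""
        i = 6 if self.floating_base else 0
        for seg in self.topological_order():
            j = self.joint_of_child(seg)
            if j is None:
                continue
            if j.name == joint_name:
                return slice(i, i + j.n_dof)
            i += j.n_dof
        raise ModelError(f"unknown joint {joint_name!r}")

    @property
    def body_weight(self) -> float:
        m = self.subject_mass if self.subject_mass else self.total_mass
        bw = m * float(np.linalg.norm(self.gravity))
        if bw <= 0:
            raise ModelError("body weight must be positive")
        return bw

    @property
    def total_mass(self) -> float:
        return sum(s.mass for s in self.segments.values())

    def distal_segments(self, joint_name: str) -> set[str]:
        """All segments on the child side of the given joint's cut."""
        j = self.joints[joint_name]
        kids = {}
        for jj in self.joints.values():
            kids.setdefault(jj.parent_segment, []).append(jj.child_segment)
        out, stack = set(), [j.child_segment]
        while stack:
            s = stack.pop()
            out.add(s)
            stack.extend(kids.get(s, []))
        for c in self.patella_couplers:
            if c.femur_segment in out:
                out.add(c.patella_segment)
        return out

    def copy(self) -> "SkeletalModel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# model construction from a config document
# ---------------------------------------------------------------------------

def build_model(config: dict | str) -> SkeletalModel:
    """Build a SkeletalModel from a parsed config dict (or YAML string).

    The document has sections ``segments``, ``joints``, ``muscles``,
    ``markers``, ``wrap_cylinders``, ``couplers`` plus scalar fields ``root``,
    ``subject_mass``, ``subject_height``, ``floating_base``, ``gravity``.
    Deterministic: the same document always produces the same model.
    """
    if isinstance(config, str):
        config = yaml.safe_load(config)
    segs = {}
    for s in config.get("segments", []):
        segs[s["name"]] = Segment(
            name=s["name"],
            mass=float(s.get("mass", 0.0)),
            com_local=s.get("com", [0, 0, 0]),
            inertia_local=s.get("inertia", np.zeros((3, 3))),
            length=float(s.get("length", 1.0)),
        )
    joints = {}
    for j in config.get("joints", []):
        for ref in (j["parent"], j["child"]):
            if ref not in segs:
                raise ModelError(f"joint {j['name']!r} references unknown segment {ref!r}")
        joints[j["name"]] = Joint(
            name=j["name"],
            kind=j["kind"],
            parent_segment=j["parent"],
            child_segment=j["child"],
            location_in_parent=j.get("location_in_parent", [0, 0, 0]),
            location_in_child=j.get("location_in_child", [0, 0, 0]),
            hinge_axis=j.get("axis"),
        )
    cylinders = {}
    for w in config.get("wrap_cylinders", []):
        if w["segment"] not in segs:
            raise ModelError(f"wrap {w['name']!r} references unknown segment {w['segment']!r}")
        cylinders[w["name"]] = WrapCylinder(
            name=w["name"],
            segment=w["segment"],
            center=w["center"],
            axis=w["axis"],
            radius=float(w["radius"]),
            wrap_side=int(w.get("wrap_side", 1)),
        )
    muscles = []
    for m in config.get("muscles", []):
        nodes = []
        for nd in m["nodes"]:
            if nd["segment"] not in segs:
                raise ModelError(
                    f"muscle {m['name']!r} references unknown segment {nd['segment']!r}"
                )
            nodes.append((nd["segment"], np.asarray(nd["point"], dtype=float)))
        wraps = {}
        for wref in m.get("wraps", []):
            cname = wref["cylinder"]
            if cname not in cylinders:
                raise ModelError(f"muscle {m['name']!r} references unknown wrap {cname!r}")
            wraps[int(wref["span"])] = cylinders[cname]
        muscles.append(
            MuscleElement(
                name=m["name"],
                group=m.get("group", m["name"]),
                nodes=nodes,
                wraps=wraps,
                strength=float(m.get("strength", 1000.0)),
            )
        )
    markers = {}
    for mk in config.get("markers", []):
        if mk["segment"] not in segs:
            raise ModelError(f"marker {mk['name']!r} references unknown segment {mk['segment']!r}")
        markers[mk["name"]] = MarkerDef(
            name=mk["name"],
            segment=mk["segment"],
            local=mk["point"],
            weight=float(mk.get("weight", 1.0)),
            is_bony_landmark=bool(mk.get("bony", False)),
            optimize_local=tuple(mk.get("optimize_local", (False, False, False))),
        )
    couplers = [
        PatellaCoupler(
            knee_joint=c["knee_joint"],
            patella_segment=c["patella"],
            femur_segment=c["femur"],
            pose_table=np.asarray(c["table"], dtype=float),
        )
        for c in config.get("couplers", [])
    ]
    return SkeletalModel(
        segments=segs,
        joints=joints,
        root=config["root"],
        muscles=muscles,
        markers=MarkerProtocol(markers),
        patella_couplers=couplers,
        gravity=np.asarray(config.get("gravity", GRAVITY_DEFAULT), dtype=float),
        subject_mass=config.get("subject_mass"),
        subject_height=config.get("subject_height"),
        floating_base=bool(config.get("floating_base", True)),
        analysis=config.get("analysis", {}),
    )


def load_model(path) -> SkeletalModel:
    with open(path) as fh:
        return build_model(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# forward kinematics (with exact first/second time derivatives)
# ---------------------------------------------------------------------------

def _joint_rotation_factors(joint: Joint, q):
    """Rotation factor list [(R_k, S_k)] for a joint: R = prod_k R_k,
    with dR_k/dq_k = S_k @ R_k (skew of the axis in the pre-rotation frame)."""
    if joint.kind == "hinge":
        return [(rodrigues(joint.hinge_axis, q[0]), skew(joint.hinge_axis))]
    return [
        (_EULER_ROTS[k](q[k]), skew(_EULER_AXES[k])) for k in range(3)
    ]


def _rot_chain(factors, qd=None, qdd=None):
    """Compose R = prod R_k and (optionally) its first/second time derivative."""
    n = len(factors)
    R = np.eye(3)
    for Rk, _ in factors:
        R = R @ Rk
    if qd is None:
        return R, None, None
    # dR/dq_k = prod with S_k inserted before R_k
    dRs = []
    for k in range(n):
        M = np.eye(3)
        for i, (Ri, Si) in enumerate(factors):
            M = M @ (Si @ Ri if i == k else Ri)
        dRs.append(M)
    Rdot = sum(dRs[k] * qd[k] for k in range(n))
    if qdd is None:
        return R, Rdot, None
    Rddot = sum(dRs[k] * qdd[k] for k in range(n))
    for k in range(n):
        for l in range(n):
            M = np.eye(3)
            for i, (Ri, Si) in enumerate(factors):
                F = Ri
                if i == k:
                    F = Si @ F
                if i == l:
                    F = Si @ F
                M = M @ F
            Rddot = Rddot + M * (qd[k] * qd[l])
    return R, Rdot, Rddot


@dataclass
class SegmentKinematics:
    """World pose (and optional derivatives) of one segment."""

    R: np.ndarray
    p: np.ndarray                      # frame origin, world
    Rd: np.ndarray | None = None
    pd: np.ndarray | None = None
    Rdd: np.ndarray | None = None
    pdd: np.ndarray | None = None

    def point(self, local):
        return self.p + self.R @ np.asarray(local)

    @property
    def omega(self):
        W = self.Rd @ self.R.T
        return np.array([W[2, 1], W[0, 2], W[1, 0]])

    @property
    def alpha(self):
        W = self.Rd @ self.R.T
        A = self.Rdd @ self.R.T - W @ W
        return np.array([A[2, 1], A[0, 2], A[1, 0]])


def fk_with_derivatives(model: SkeletalModel, posture: Posture) -> dict[str, SegmentKinematics]:
    """Forward kinematics; includes pose rates when Posture carries qd/qdd.

    Child pose: ``R_c = R_p R_j``, ``p_c = p_p + R_p l_p - R_c l_c`` where
    ``l_p``/``l_c`` are the joint locations in the parent/child frames.
    Derivatives propagate by the product rule, so accelerations are exact for
    the supplied (q, qd, qdd) — no frame-to-frame differencing here.
    """
    q = posture.q
    if len(q) != model.n_dof:
        raise ModelError(f"posture has {len(q)} dofs, model has {model.n_dof}")
    qd, qdd = posture.qd, posture.qdd
    want_d = qd is not None
    want_dd = qdd is not None
    out: dict[str, SegmentKinematics] = {}

    if model.floating_base:
        tr = q[0:3]
        factors = [(_EULER_ROTS[k](q[3 + k]), skew(_EULER_AXES[k])) for k in range(3)]
        R, Rd, Rdd = _rot_chain(factors, qd[3:6] if want_d else None, qdd[3:6] if want_dd else None)
        out[model.root] = SegmentKinematics(
            R=R,
            p=np.asarray(tr),
            Rd=Rd,
            pd=qd[0:3] if want_d else None,
            Rdd=Rdd,
            pdd=qdd[0:3] if want_dd else None,
        )
    else:
        out[model.root] = SegmentKinematics(
            R=np.eye(3),
            p=np.zeros(3),
            Rd=np.zeros((3, 3)) if want_d else None,
            pd=np.zeros(3) if want_d else None,
            Rdd=np.zeros((3, 3)) if want_dd else None,
            pdd=np.zeros(3) if want_dd else None,
        )

    for seg in model.topological_order():
        j = model.joint_of_child(seg)
        if j is None:
            continue
        par = out[j.parent_segment]
        sl = model.joint_dof_slice(j.name)
        factors = _joint_rotation_factors(j, q[sl])
        Rj, Rjd, Rjdd = _rot_chain(
            factors, qd[sl] if want_d else None, qdd[sl] if want_dd else None
        )
        R = par.R @ Rj
        p = par.p + par.R @ j.location_in_parent - R @ j.location_in_child
        kin = SegmentKinematics(R=R, p=p)
        if want_d:
            Rd = par.Rd @ Rj + par.R @ Rjd
            kin.Rd = Rd
            kin.pd = par.pd + par.Rd @ j.location_in_parent - Rd @ j.location_in_child
        if want_dd:
            Rdd = par.Rdd @ Rj + 2.0 * par.Rd @ Rjd + par.R @ Rjdd
            kin.Rdd = Rdd
            kin.pdd = par.pdd + par.Rdd @ j.location_in_parent - Rdd @ j.location_in_child
        out[seg] = kin

    # patella(e): pose-coupled to knee flexion, no dofs (rates not propagated;
    # coupled bodies are treated as massless attachment frames)
    for c in model.patella_couplers:
        sl = model.joint_dof_slice(c.knee_joint)
        Rrel, trel = c.pose(q[sl][0] if model.joints[c.knee_joint].kind == "hinge" else q[sl][0])
        fem = out[c.femur_segment]
        out[c.patella_segment] = SegmentKinematics(R=fem.R @ Rrel, p=fem.p + fem.R @ trel)
    return out


def forward_kinematics(model: SkeletalModel, posture: Posture) -> dict[str, SegmentKinematics]:
    """Pose-only forward kinematics (world rotation + origin per segment)."""
    return fk_with_derivatives(model, Posture(q=posture.q, time=posture.time))


def marker_positions(model: SkeletalModel, posture: Posture,
                     kin: dict[str, SegmentKinematics] | None = None) -> dict[str, np.ndarray]:
    """World positions of all protocol markers ('virtual markers')."""
    if kin is None:
        kin = forward_kinematics(model, posture)
    return {mk.name: kin[mk.segment].point(mk.local) for mk in model.markers}


# ---------------------------------------------------------------------------
# anthropometric scaling
# ---------------------------------------------------------------------------

@dataclass
class AnthropometricScaling:
    """Per-segment linear scale factors plus mass/height/fat targets.

    ``fat_fraction`` defaults to the BMI-derived estimate used by the
    length-mass-fat strength scaling law; pass an explicit value to override.
    """

    length_scales: dict[str, float]
    target_mass: float
    target_height: float
    fat_fraction: float | None = None

    def __post_init__(self):
        for s, f in self.length_scales.items():
            if not (f > 0):
                raise ModelError(f"scale factor for {s!r} must be > 0")
        if self.target_mass <= 0 or self.target_height <= 0:
            raise ModelError("target mass and height must be > 0")
        if self.fat_fraction is not None and not (0 <= self.fat_fraction < 1):
            raise ModelError("fat fraction must lie in [0, 1)")


def fat_fraction_from_bmi(bmi: float) -> float:
    """Body-fat fraction estimated from BMI.

    Quadratic regression f = -0.09 + 0.0149*BMI - 0.00009*BMI**2 (dimensionless
    fraction), the population relation underlying the length-mass-fat strength
    scaling law. Clipped to [0, 0.6]. All constants of the law live here so
    they can be checked against the source in one place.
    """
    f = -0.09 + 0.0149 * bmi - 0.00009 * bmi * bmi
    return float(np.clip(f, 0.0, 0.6))


def lmf_strength_factor(mass_ratio: float, length_ratio: float,
                        fat_generic: float, fat_target: float) -> float:
    """Length-mass-fat muscle strength scale factor.

    Strength scales with muscle physiological cross-section: (lean segment
    mass) / (segment length).  With segment mass ratio ``m``, length ratio
    ``l`` and fat fractions ``f``:  s = m * (1-f_target)/(1-f_generic) / l.
    """
    return mass_ratio * (1.0 - fat_target) / (1.0 - fat_generic) / length_ratio


def scale_model(model: SkeletalModel, scaling: AnthropometricScaling) -> SkeletalModel:
    """Linearly scale a model; returns a new model, the input is untouched.

    Segment lengths and every segment-fixed point (joint locations, muscle
    nodes, wrap centres/radii, marker locals, com) scale by the owner
    segment's factor; masses are redistributed so the total equals
    ``target_mass`` with the generic model's mass fractions; inertias scale by
    (mass ratio * factor^2); muscle strengths scale by the length-mass-fat
    factor of the segment owning the muscle's origin node.
    """
    m2 = model.copy()
    total0 = model.total_mass
    if total0 <= 0:
        raise ModelError("cannot scale a massless model")
    s_of = lambda seg: scaling.length_scales.get(seg, 1.0)

    generic_height = model.subject_height or scaling.target_height
    bmi_gen = total0 / generic_height**2
    bmi_tgt = scaling.target_mass / scaling.target_height**2
    f_gen = fat_fraction_from_bmi(bmi_gen)
    f_tgt = scaling.fat_fraction if scaling.fat_fraction is not None else fat_fraction_from_bmi(bmi_tgt)

    mass_ratio_total = scaling.target_mass / total0
    for name, seg in m2.segments.items():
        s = s_of(name)
        mr = mass_ratio_total  # generic mass fractions preserved
        seg.length *= s
        seg.com_local = seg.com_local * s
        seg.inertia_local = seg.inertia_local * (mr * s * s)
        seg.mass *= mr
    for j in m2.joints.values():
        j.location_in_parent = j.location_in_parent * s_of(j.parent_segment)
        j.location_in_child = j.location_in_child * s_of(j.child_segment)
    for mus in m2.muscles:
        mus.nodes = [(sname, p * s_of(sname)) for sname, p in mus.nodes]
        for w in mus.wraps.values():
            sw = s_of(w.segment)
            w.center = w.center * sw
            w.radius = w.radius * sw
        origin_seg = mus.nodes[0][0]
        factor = lmf_strength_factor(
            mass_ratio_total, s_of(origin_seg), f_gen, f_tgt
        )
        mus.strength *= factor
    for mk in m2.markers:
        mk.local = mk.local * s_of(mk.segment)
    for c in m2.patella_couplers:
        sf = s_of(c.femur_segment)
        c.pose_table = c.pose_table.copy()
        c.pose_table[:, 1:4] *= sf
    m2.subject_mass = scaling.target_mass
    m2.subject_height = scaling.target_height
    return m2
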