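"""Static-optimization muscle recruitment and joint contact forces.

Per frame, muscle forces f ≥ 0 are found by minimizing the polynomial
recruitment criterion Σ_i (f_i/N_i)^p (default p = 3, the sum of cubed
activations) subject to moment equilibrium R f = τ on the constrained dofs,
where R is the tendon-excursion moment-arm matrix and τ the generalized net
joint moments from inverse dynamics.

The KKT conditions give, for active muscles, p a_i^{p-1} / N_i = λ·r_i, i.e.

    f_i(λ) = N_i * ( N_i * max(0, λ·r_i) / p )^{1/(p-1)},

a smooth monotone map from the multipliers λ to forces. Equilibrium is solved
as the root of R f(λ) - τ = 0 by a damped Newton iteration (the Jacobian is
symmetric positive semidefinite), with an SLSQP fall-back and a linear-program
feasibility certificate when no nonnegative solution exists.

The hip contact force then follows from the single-limb force balance:

    HCF = -(F_inertial + F_gravity + GRF + Σ_i f_i u_i)

with u_i the line of action of each muscle element crossing the hip, and is
reported in the femur-based clinical frame (AP, ML, PD) in body weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .dynamics import LimbFreeBodyState
from .geometry import compute_path, line_of_action, muscle_spans_joint
from .model import Posture, SkeletalModel, forward_kinematics

__all__ = [
    "RecruitmentConfig",
    "MuscleState",
    "JointContactForce",
    "InfeasibleEquilibrium",
    "solve_recruitment",
    "hip_crossing_forces",
    "joint_contact_force",
    "FemurFrame",
    "femur_frame_axes",
]


class InfeasibleEquilibrium(RuntimeError):
    """No nonnegative muscle force solution satisfies moment equilibrium."""


@dataclass
class RecruitmentConfig:
    """Settings of the polynomial recruitment criterion.

    ``exponent`` ≥ 2 (3 = sum of cubed activations). Activations are unbounded
    above by default — constant-strength actuators with a polynomial
    criterion; set ``activation_upper_bound`` to e.g. 1.0 to enforce
    saturation.
    """

    exponent: float = 3.0
    activation_upper_bound: float | None = None
    tolerance: float = 1e-9
    max_iter: int = 200

    def __post_init__(self):
        if self.exponent < 2:
            raise ValueError("recruitment exponent must be >= 2")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class MuscleState:
    """Solved per-frame muscle forces and activations (one frame)."""

    forces: np.ndarray        # N, per element
    activations: np.ndarray   # forces / strengths
    multipliers: np.ndarray   # KKT multipliers of the equilibrium constraints
    kkt_residual: float

    @property
    def objective(self) -> float:
        return float(np.sum(self.activations**3))


@dataclass
class JointContactForce:
    """Hip contact force in the femur-based frame, body-weight normalized."""

    ap: float
    ml: float
    pd: float
    world: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def total(self) -> float:
        return float(np.sqrt(self.ap**2 + self.ml**2 + self.pd**2))

    @property
    def components(self) -> np.ndarray:
        return np.array([self.ap, self.ml, self.pd])


# ---------------------------------------------------------------------------
# recruitment solver
# ---------------------------------------------------------------------------

def _forces_of_lambda(lam, R, N, p):
    s = np.maximum(N * (R.T @ lam), 0.0)
    return N * (s / p) ** (1.0 / (p - 1.0))


def _jac_of_lambda(lam, R, N, p):
    s = np.maximum(N * (R.T @ lam), 0.0)
    active = s > 0
    df = np.zeros_like(s)
    if np.any(active):
        df[active] = (
            N[active] ** 2 / (p * (p - 1.0)) * (s[active] / p) ** ((2.0 - p) / (p - 1.0))
        )
    return (R * df) @ R.T


def solve_recruitment(moment_targets: np.ndarray, moment_arm_matrix: np.ndarray,
                      strengths: np.ndarray,
                      config: RecruitmentConfig | None = None) -> MuscleState:
    """Solve min Σ a_i^p subject to R f = τ, f ≥ 0 for one frame.

    ``moment_arm_matrix`` has one row per constrained dof and one column per
    muscle element; ``moment_targets`` are the generalized net moments the
    muscles must supply (N·m). Raises :class:`InfeasibleEquilibrium` when no
    nonnegative force vector satisfies the equality constraints.
    """
    config = config or RecruitmentConfig()
    tau = np.asarray(moment_targets, float).ravel()
    R = np.atleast_2d(np.asarray(moment_arm_matrix, float))
    N = np.asarray(strengths, float).ravel()
    if R.shape != (tau.size, N.size):
        raise ValueError(f"moment-arm matrix shape {R.shape} does not match "
                         f"{tau.size} dofs x {N.size} muscles")
    p = config.exponent

    scale = max(np.max(np.abs(tau)), 1.0)
    if np.allclose(tau, 0.0):
        f = np.zeros(N.size)
        return MuscleState(f, f / N, np.zeros(tau.size), 0.0)

    # damped Newton on the dual: solve R f(lam) = tau.  Start along the
    # least-squares multiplier direction, scaled until some muscle is active
    # (at lam = 0 the dual Jacobian is identically zero).
    lam0 = np.linalg.lstsq(R @ R.T + 1e-14 * np.eye(tau.size), tau, rcond=None)[0]
    nrm = np.linalg.norm(lam0)
    lam0 = lam0 / nrm if nrm > 0 else np.ones(tau.size)
    c = 1e-6
    for _ in range(80):
        f0 = _forces_of_lambda(c * lam0, R, N, p)
        if np.linalg.norm(R @ f0) >= 0.5 * np.linalg.norm(tau):
            break
        c *= 2.0
    lam = _newton_dual(c * lam0, tau, R, N, p, config)
    f = _forces_of_lambda(lam, R, N, p)
    res = np.linalg.norm(R @ f - tau)
    if res > config.tolerance * scale:
        f, lam, res = _slsqp_fallback(tau, R, N, p, config)
        if res > 1e-6 * scale:
            _certify_feasibility(tau, R)
            raise InfeasibleEquilibrium(
                f"recruitment failed to converge (residual {res:.3e} N*m)"
            )
    a = f / N
    if config.activation_upper_bound is not None:
        if np.any(a > config.activation_upper_bound + 1e-9):
            f, lam, res = _slsqp_fallback(tau, R, N, p, config,
                                          upper=config.activation_upper_bound)
            a = f / N
    return MuscleState(forces=f, activations=a, multipliers=lam,
                       kkt_residual=float(res))


def _newton_dual(lam, tau, R, N, p, config):
    for _ in range(config.max_iter):
        f = _forces_of_lambda(lam, R, N, p)
        r = R @ f - tau
        if np.linalg.norm(r) <= 0.5 * config.tolerance * max(np.max(np.abs(tau)), 1.0):
            break
        J = _jac_of_lambda(lam, R, N, p)
        # regularize: J is PSD; inactive regions can make it singular
        J = J + 1e-12 * np.trace(J + np.eye(len(lam))) * np.eye(len(lam))
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            step = -np.linalg.lstsq(J, r, rcond=None)[0]
        t = 1.0
        norm0 = np.linalg.norm(r)
        for _ in range(60):
            trial = lam + t * step
            rt = R @ _forces_of_lambda(trial, R, N, p) - tau
            if np.linalg.norm(rt) < norm0:
                lam = trial
                break
            t *= 0.5
        else:
            lam = lam + 1e-3 * step
    return lam


def _slsqp_fallback(tau, R, N, p, config, upper=None):
    n = N.size
    x0 = np.full(n, 0.1)
    bounds = [(0.0, None if upper is None else upper * N[i]) for i in range(n)]

    def obj(f):
        return float(np.sum((f / N) ** p))

    def grad(f):
        return p * (f / N) ** (p - 1.0) / N

    cons = {"type": "eq", "fun": lambda f: R @ f - tau, "jac": lambda f: R}
    sol = optimize.minimize(obj, x0, jac=grad, bounds=bounds, constraints=[cons],
                            method="SLSQP",
                            options={"maxiter": 500, "ftol": 1e-14})
    f = np.maximum(sol.x, 0.0)
    res = float(np.linalg.norm(R @ f - tau))
    a = f / N
    lam = np.linalg.lstsq(R.T, p * a ** (p - 1.0) / N, rcond=None)[0]
    return f, lam, res


def _certify_feasibility(tau, R):
    """Raise with the violated dofs if R f = tau, f >= 0 is infeasible."""
    n = R.shape[1]
    m = R.shape[0]
    # phase-1 LP: min sum(s+ + s-) s.t. R f + s+ - s- = tau
    c = np.concatenate([np.zeros(n), np.ones(2 * m)])
    A_eq = np.hstack([R, np.eye(m), -np.eye(m)])
    sol = optimize.linprog(c, A_eq=A_eq, b_eq=tau,
                           bounds=[(0, None)] * (n + 2 * m), method="highs")
    if sol.status == 0 and sol.fun > 1e-8 * max(np.max(np.abs(tau)), 1.0):
        slack = sol.x[n:n + m] + sol.x[n + m:]
        bad = [k for k in range(m) if slack[k] > 1e-10]
        raise InfeasibleEquilibrium(
            f"no nonnegative muscle forces satisfy equilibrium on dofs {bad} "
            f"(unbalanced moment {sol.fun:.4g} N*m)"
        )


# ---------------------------------------------------------------------------
# joint contact force
# ---------------------------------------------------------------------------

@dataclass
class FemurFrame:
    """Construction of the femur-based clinical frame.

    Axes built in the femur segment frame: PD along the mechanical axis from
    the hip centre toward the knee centre; AP along the anterior direction
    orthogonalized against PD; ML completes the right-handed triad (lateral
    for a right limb). Components are reported in the order (AP, ML, PD).
    """

    hip_center_local: np.ndarray
    knee_center_local: np.ndarray
    anterior_local: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0]))

    def axes_local(self) -> np.ndarray:
        pd = np.asarray(self.knee_center_local, float) - np.asarray(self.hip_center_local, float)
        pd = pd / np.linalg.norm(pd)
        ap = np.asarray(self.anterior_local, float)
        ap = ap - (ap @ pd) * pd
        ap = ap / np.linalg.norm(ap)
        ml = np.cross(pd, ap)
        return np.column_stack([ap, ml, pd])


def femur_frame_axes(model: SkeletalModel, hip_joint: str, knee_joint: str,
                     anterior_local=np.array([1.0, 0, 0])) -> FemurFrame:
    hip = model.joints[hip_joint]
    knee = model.joints[knee_joint]
    return FemurFrame(
        hip_center_local=hip.location_in_child,
        knee_center_local=knee.location_in_parent,
        anterior_local=np.asarray(anterior_local, float),
    )


def hip_crossing_forces(model: SkeletalModel, posture: Posture, forces: np.ndarray,
                        hip_joint: str, kin=None):
    """World muscle force vectors f_i u_i for the elements crossing the hip."""
    if kin is None:
        kin = forward_kinematics(model, posture)
    out = []
    for mus, f in zip(model.muscles, forces):
        if not muscle_spans_joint(model, mus, hip_joint):
            out.append(None)
            continue
        path = compute_path(model, kin, mus)
        u, anchor, _ = line_of_action(model, kin, mus, hip_joint, path=path)
        out.append(f * u)
    return out


def joint_contact_force(model: SkeletalModel, posture: Posture, state: MuscleState,
                        free_body_frame: np.ndarray, femur: FemurFrame,
                        hip_joint: str, femur_segment: str,
                        kin=None) -> JointContactForce:
    """Hip contact force of one frame from the limb force balance.

    ``free_body_frame`` is the 3x3 stack [F_inertial, F_gravity, GRF_sum] of
    that frame (world, N). The result is rotated into the femur clinical frame
    and divided by body weight.
    """
    if kin is None:
        kin = forward_kinematics(model, posture)
    fi, fg, grf = free_body_frame
    mf = np.zeros(3)
    contribs = hip_crossing_forces(model, posture, state.forces, hip_joint, kin=kin)
    n_cross = 0
    for c in contribs:
        if c is not None:
            mf += c
            n_cross += 1
    if n_cross == 0 and np.any(state.forces > 0):
        pass  # a model may legitimately have no hip-crossing muscles loaded
    hcf_world = -(fi + fg + grf + mf)
    A = femur.axes_local()                      # femur-local clinical axes
    Rf = kin[femur_segment].R
    comp = A.T @ (Rf.T @ hcf_world) / model.body_weight
    return JointContactForce(ap=float(comp[0]), ml=float(comp[1]), pd=float(comp[2]),
                             world=hcf_world)
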