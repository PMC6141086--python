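"""Marker kinematics: filtering, hip-joint-centre regression, IK, calibration.

The measured marker and force-plate streams are low-pass filtered (2nd-order
zero-phase Butterworth, 5 Hz default), segment length scales and optionally
local marker coordinates are calibrated by minimizing the cumulative weighted
distance between measured and model ("virtual") markers over the trial, and
per-frame postures are solved by weighted nonlinear least squares. Markers on
palpable bony landmarks carry higher weights than skin-cluster markers. The
hip joint centre can be constrained throughout to the pelvis-landmark
regression of the ASIS/PSIS geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .model import (
    AnthropometricScaling,
    MarkerProtocol,
    ModelError,
    Posture,
    SkeletalModel,
    forward_kinematics,
    marker_positions,
    scale_model,
)

__all__ = [
    "FilterConfig",
    "GrfRecord",
    "GaitTrial",
    "KinematicsError",
    "lowpass_zero_phase",
    "harrington_hjc",
    "apply_harrington_constraint",
    "solve_frame_ik",
    "solve_trial_ik",
    "optimize_marker_params",
    "differentiate_postures",
    "fill_marker_gaps",
]


class KinematicsError(RuntimeError):
    pass


@dataclass
class FilterConfig:
    """Second-order zero-phase low-pass Butterworth settings."""

    order: int = 2
    cutoff: float = 5.0
    zero_phase: bool = True


@dataclass
class GrfRecord:
    """One force plate's per-frame record (world frame)."""

    name: str
    force: np.ndarray        # (n, 3) N
    cop: np.ndarray          # (n, 3) m
    free_moment: np.ndarray  # (n, 3) N*m
    target_segment: str | None = None   # foot this plate loads (sidecar config)


@dataclass
class GaitTrial:
    """Time-synchronized marker trajectories, GRF and optional measured HCF."""

    time: np.ndarray                                  # (n,) s, uniform
    markers: dict[str, np.ndarray]                    # name -> (n, 3) m (NaN = missing)
    grf: list[GrfRecord] = field(default_factory=list)
    measured_hcf: np.ndarray | None = None            # (n, 3) femur frame, BW
    events: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        n = len(self.time)
        for name, tr in self.markers.items():
            if tr.shape != (n, 3):
                raise KinematicsError(f"marker {name!r} stream shape {tr.shape} != ({n},3)")
        for rec in self.grf:
            if rec.force.shape != (n, 3):
                raise KinematicsError(f"plate {rec.name!r} force stream misaligned")
            if not np.all(np.isfinite(rec.force)):
                raise KinematicsError(f"plate {rec.name!r} has non-finite forces")

    @property
    def rate(self) -> float:
        dt = np.diff(self.time)
        if dt.size and (np.max(dt) - np.min(dt)) > 1e-9 * max(np.max(dt), 1.0):
            raise KinematicsError("trial time base is not uniform")
        return 1.0 / dt[0] if dt.size else 0.0

    @property
    def n_frames(self) -> int:
        return len(self.time)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def lowpass_zero_phase(series: np.ndarray, cfg: FilterConfig, rate: float) -> np.ndarray:
    """Forward–backward Butterworth low-pass along axis 0.

    Zero phase by construction (filtfilt); the effective amplitude response is
    the squared single-pass magnitude, so a sinusoid at the cutoff frequency
    comes out at half amplitude. NaNs must be gap-filled first.
    """
    x = np.asarray(series, float)
    if np.any(np.isnan(x)):
        raise KinematicsError("series contains NaN; gap-fill before filtering "
                              "(see fill_marker_gaps)")
    nyq = rate / 2.0
    if not (0.0 < cfg.cutoff < nyq):
        raise KinematicsError(f"cutoff {cfg.cutoff} Hz outside (0, Nyquist={nyq}) Hz")
    b, a = signal.butter(cfg.order, cfg.cutoff, fs=rate)
    if x.shape[0] < 3 * max(len(a), len(b)):
        raise KinematicsError("series too short to filter")
    return signal.filtfilt(b, a, x, axis=0)


def fill_marker_gaps(traj: np.ndarray, rate: float, max_gap_s: float = 0.1):
    """Linear interpolation of NaN runs up to ``max_gap_s``; longer gaps stay NaN.

    Returns ``(filled, dropped_mask)`` where the mask marks frames whose gap
    was too long to fill (those frames are excluded from IK with a warning).
    """
    x = np.array(traj, float)
    n = x.shape[0]
    bad = np.any(np.isnan(x), axis=1)
    dropped = np.zeros(n, bool)
    if not bad.any():
        return x, dropped
    max_len = int(round(max_gap_s * rate))
    i = 0
    idx = np.arange(n)
    while i < n:
        if not bad[i]:
            i += 1
            continue
        j = i
        while j < n and bad[j]:
            j += 1
        gap = j - i
        if gap <= max_len and i > 0 and j < n:
            for c in range(3):
                x[i:j, c] = np.interp(idx[i:j], [i - 1, j], [x[i - 1, c], x[j, c]])
        else:
            dropped[i:j] = True
        i = j
    return x, dropped


# ---------------------------------------------------------------------------
# hip joint centre regression
# ---------------------------------------------------------------------------

def harrington_hjc(pelvis_width: float, pelvis_depth: float, leg_length: float,
                   side: str = "right") -> np.ndarray:
    """Hip joint centre in the pelvis frame from pelvic landmark geometry.

    Multiple linear regression on pelvis width PW (inter-ASIS distance),
    pelvis depth PD (mid-ASIS to mid-PSIS) and leg length LL, transcribed
    coefficients (millimetres):

        x = -0.24*PD - 9.9              (anterior +)
        y = -0.16*PW - 0.04*LL - 7.1    (superior +)
        z = +(0.28*PD + 0.16*PW + 7.9)  (lateral; mirrored for the left side)

    Pelvis frame: origin at the mid-ASIS point, x anterior, y superior,
    z to the subject's right. Inputs and output in metres.
    """
    if min(pelvis_width, pelvis_depth, leg_length) <= 0:
        raise ModelError("pelvis dimensions and leg length must be positive")
    pw, pd, ll = pelvis_width * 1e3, pelvis_depth * 1e3, leg_length * 1e3
    x = -0.24 * pd - 9.9
    y = -0.16 * pw - 0.04 * ll - 7.1
    z = 0.28 * pd + 0.16 * pw + 7.9
    if side not in ("right", "left"):
        raise ModelError(f"side must be 'right' or 'left', got {side!r}")
    if side == "left":
        z = -z
    return np.array([x, y, z]) * 1e-3


def pelvis_dimensions_from_markers(model: SkeletalModel,
                                   rasis="RASI", lasis="LASI",
                                   rpsis="RPSI", lpsis="LPSI"):
    """(width, depth) from the model's pelvis-local ASIS/PSIS marker positions."""
    mk = model.markers
    ra, la = mk[rasis].local, mk[lasis].local
    rp, lp = mk[rpsis].local, mk[lpsis].local
    width = float(np.linalg.norm(ra - la))
    depth = float(np.linalg.norm((ra + la) / 2 - (rp + lp) / 2))
    return width, depth


def apply_harrington_constraint(model: SkeletalModel, hip_joint: str,
                                leg_length: float | None = None,
                                side: str = "right",
                                pelvis_axes: np.ndarray | None = None,
                                pelvis_origin: np.ndarray | None = None) -> SkeletalModel:
    """Pin a hip joint's pelvis-frame location to the landmark regression.

    ``pelvis_axes`` columns map the regression frame (x ant, y sup, z right)
    into the model's pelvis segment frame (identity when the pelvis frame
    already uses that convention); ``pelvis_origin`` is the mid-ASIS point in
    the pelvis frame (computed from the ASIS markers when omitted).
    """
    m2 = model.copy()
    width, depth = pelvis_dimensions_from_markers(m2)
    if leg_length is None:
        leg_length = sum(
            s.length for s in m2.segments.values()
            if s.name not in (m2.root,) and "patella" not in s.name
        )
    hjc_reg = harrington_hjc(width, depth, leg_length, side=side)
    if pelvis_axes is None:
        pelvis_axes = m2.analysis.get("pelvis_axes")
    A = np.eye(3) if pelvis_axes is None else np.asarray(pelvis_axes, float)
    if pelvis_origin is None:
        mk = m2.markers
        pelvis_origin = (mk["RASI"].local + mk["LASI"].local) / 2.0
    m2.joints[hip_joint].location_in_parent = pelvis_origin + A @ hjc_reg
    return m2


# ---------------------------------------------------------------------------
# inverse kinematics
# ---------------------------------------------------------------------------

def _frame_residuals(model, q, frame_markers, weights):
    post = Posture(q=q)
    virt = marker_positions(model, post)
    res = []
    for name, meas in frame_markers.items():
        w = np.sqrt(weights[name])
        res.append(w * (virt[name] - meas))
    return np.concatenate(res)


def solve_frame_ik(model: SkeletalModel, frame_markers: dict[str, np.ndarray],
                   q_init: np.ndarray, weights: dict[str, float] | None = None) -> Posture:
    """Weighted least-squares pose for one frame of marker positions.

    Minimizes Σ_m w_m ||virtual_m(q) - measured_m||². Raises on rank
    deficiency, naming the unobservable dofs.
    """
    if weights is None:
        weights = {m.name: m.weight for m in model.markers}
    frame_markers = {k: np.asarray(v, float) for k, v in frame_markers.items()
                     if k in weights and np.all(np.isfinite(v))}
    if 3 * len(frame_markers) < model.n_dof:
        raise KinematicsError(
            f"{len(frame_markers)} markers cannot determine {model.n_dof} dofs"
        )
    q0 = np.asarray(q_init, float)
    sol = optimize.least_squares(
        lambda q: _frame_residuals(model, q, frame_markers, weights),
        q0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400,
    )
    J = sol.jac
    rank = np.linalg.matrix_rank(J, tol=1e-8 * max(1.0, np.abs(J).max()))
    if rank < model.n_dof:
        _, _, vt = np.linalg.svd(J)
        names = np.array(model.dof_names)
        bad = []
        for v in vt[rank:]:
            bad.extend(names[np.abs(v) > 0.3].tolist())
        raise KinematicsError(f"pose underdetermined; unobservable dofs: {sorted(set(bad))}")
    return Posture(q=sol.x)


def solve_trial_ik(model: SkeletalModel, trial: GaitTrial,
                   q_init: np.ndarray | None = None) -> list[Posture]:
    """Per-frame IK over a trial, warm-starting each frame from the previous."""
    q = np.zeros(model.n_dof) if q_init is None else np.asarray(q_init, float)
    out = []
    for i in range(trial.n_frames):
        frame = {name: tr[i] for name, tr in trial.markers.items()}
        post = solve_frame_ik(model, frame, q)
        q = post.q
        post.time = float(trial.time[i])
        out.append(post)
    return out


def differentiate_postures(postures: list[Posture], rate: float) -> list[Posture]:
    """Fill qd/qdd by central finite differences (one-sided at the ends)."""
    Q = np.array([p.q for p in postures])
    Qd = np.gradient(Q, 1.0 / rate, axis=0, edge_order=2)
    Qdd = np.gradient(Qd, 1.0 / rate, axis=0, edge_order=2)
    return [Posture(q=Q[i], qd=Qd[i], qdd=Qdd[i], time=postures[i].time)
            for i in range(len(postures))]


# ---------------------------------------------------------------------------
# trial-level parameter calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    model: SkeletalModel
    scales: dict[str, float]
    postures: list[Posture]
    marker_rms_m: dict[str, float]
    objective: float


def optimize_marker_params(model: SkeletalModel, trial: GaitTrial,
                           scale_segments: list[str] | None = None,
                           frames: list[int] | None = None,
                           hip_joint: str | None = None,
                           harrington_side: str = "right",
                           max_iter: int = 200,
                           tol: float = 1e-10) -> CalibrationResult:
    """Calibrate segment length scales (and the hip centre) against a trial.

    Minimizes the cumulative weighted squared distance between measured and
    virtual markers over the selected frames, jointly over per-segment length
    scales and the per-frame postures (solved as an inner IK for every outer
    evaluation). When ``hip_joint`` is given, the hip centre is re-pinned to
    the pelvic landmark regression after every scale update, so the
    constraint holds throughout the optimization.

    With ``max_iter=0`` the routine evaluates the initial model unchanged and
    reports its residuals.
    """
    if scale_segments is None:
        scale_segments = [s for s in model.segments if model.segments[s].mass > 0]
    if frames is None:
        step = max(1, trial.n_frames // 10)
        frames = list(range(0, trial.n_frames, step))
    for seg in model.segments.values():
        n_on_seg = sum(1 for m in model.markers if m.segment == seg.name)
        if 0 < n_on_seg < 3:
            import warnings

            warnings.warn(f"segment {seg.name!r} carries only {n_on_seg} markers; "
                          "its scale may be poorly observable")
    weights = {m.name: m.weight for m in model.markers}
    total_mass = model.total_mass
    height = model.subject_height or 1.75

    q_seeds = {}

    def build(scale_vec):
        scaling = AnthropometricScaling(
            length_scales=dict(zip(scale_segments, scale_vec)),
            target_mass=total_mass, target_height=height,
        )
        m2 = scale_model(model, scaling)
        if hip_joint is not None:
            m2 = apply_harrington_constraint(m2, hip_joint, side=harrington_side)
        return m2

    def residuals(scale_vec):
        m2 = build(scale_vec)
        res = []
        qprev = q_seeds.get("last", np.zeros(model.n_dof))
        for fi in frames:
            frame = {n: tr[fi] for n, tr in trial.markers.items()}
            post = solve_frame_ik(m2, frame, q_seeds.get(fi, qprev))
            q_seeds[fi] = post.q
            qprev = post.q
            res.append(_frame_residuals(m2, post.q, frame, weights))
        q_seeds["last"] = q_seeds[frames[0]]
        return np.concatenate(res)

    x0 = np.ones(len(scale_segments))
    if max_iter == 0:
        r = residuals(x0)
        sol_x, obj = x0, float(r @ r)
    else:
        sol = optimize.least_squares(
            residuals, x0, method="trf",
            bounds=(0.2, 5.0), xtol=tol, ftol=tol, gtol=tol,
            diff_step=1e-6, max_nfev=max_iter,
        )
        if not sol.success and sol.status == 0:
            raise KinematicsError(
                f"calibration did not converge within {max_iter} evaluations; "
                f"last objective {2 * sol.cost:.3e}"
            )
        sol_x, obj = sol.x, float(2 * sol.cost)

    final = build(sol_x)
    postures = solve_trial_ik(final, trial, q_init=q_seeds.get(frames[0]))
    per_marker: dict[str, list] = {m.name: [] for m in model.markers}
    for post in postures:
        virt = marker_positions(final, post)
        i = int(round((post.time - trial.time[0]) * trial.rate))
        for name in per_marker:
            meas = trial.markers[name][i]
            if np.all(np.isfinite(meas)):
                per_marker[name].append(np.linalg.norm(virt[name] - meas))
    rms = {n: float(np.sqrt(np.mean(np.square(v)))) if v else float("nan")
           for n, v in per_marker.items()}
    return CalibrationResult(
        model=final,
        scales=dict(zip(scale_segments, sol_x)),
        postures=postures,
        marker_rms_m=rms,
        objective=obj,
    )
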