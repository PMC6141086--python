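"""Synthetic gait trials and toy models with known ground truth.

Stands in for an instrumented-implant gait trial: joint-angle profiles are
built from a truncated Fourier basis (≤3 harmonics, so derivatives exist in
closed form), markers are generated by forward kinematics plus optional
i.i.d. Gaussian noise, the vertical ground reaction force is a double-bump
profile whose cycle average over both feet equals body weight, and the centre
of pressure travels heel-to-toe under the stance foot. The reference hip
contact force is produced by running the analysis pipeline itself on the
noise-free trial with the uncorrupted model, so every downstream stage can be
regression-tested against a self-consistent ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .kinematics import GaitTrial, GrfRecord
from .model import ModelError, Posture, SkeletalModel, build_model, fk_with_derivatives

__all__ = [
    "GaitGeneratorParams",
    "GaitGroundTruth",
    "generate_gait_trial",
    "make_toy_model",
    "toy_model_catalogue",
    "perturb_model",
]

_CATALOGUE = {
    "planar-2seg": "planar_2seg.yaml",
    "hip-abductor-rig": "hip_abductor_rig.yaml",
    "lowerlimb-12m": "lowerlimb_12m.yaml",
}


def toy_model_catalogue() -> list[str]:
    return sorted(_CATALOGUE)


def make_toy_model(name: str) -> SkeletalModel:
    """Load a documented fixture model from the shipped catalogue."""
    if name not in _CATALOGUE:
        raise ModelError(
            f"unknown toy model {name!r}; catalogue: {toy_model_catalogue()}"
        )
    text = resources.files("hipdyn.fixtures").joinpath(_CATALOGUE[name]).read_text()
    return build_model(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# gait parameters
# ---------------------------------------------------------------------------

@dataclass
class GaitGeneratorParams:
    """Conditions of the emulated gait trial.

    Defaults describe steady adult walking: 120 steps/min cadence (1.0 s
    cycle), 100 Hz capture, 60% stance, double-bump vertical GRF whose
    two-plate cycle average equals body weight, and noise-free markers unless
    ``marker_noise_std`` is set (2 mm is a typical soft-tissue/labelling
    magnitude).  Angle profiles are Fourier coefficients per dof name:
    ``{dof: (a0, [(cos_k, sin_k), ...])}`` in radians; the shipped defaults
    cover the lowerlimb-12m fixture.
    """

    cadence_steps_per_min: float = 120.0
    rate_hz: float = 100.0
    stance_fraction: float = 0.6
    marker_noise_std: float = 0.0
    grf_shape: float = 0.35          # relative depth of the mid-stance valley
    ap_shear_bw: float = 0.15
    ml_shear_bw: float = 0.05
    walking_speed: float = 1.1       # m/s pelvis advance
    pelvis_height: float = 0.93      # m
    seed: int = 0
    angle_profiles: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rate_hz < 50:
            raise ModelError("sampling rate must be >= 50 Hz")
        if not (0.3 < self.stance_fraction < 0.8):
            raise ModelError("stance fraction must lie in (0.3, 0.8)")
        if self.marker_noise_std < 0:
            raise ModelError("marker noise must be >= 0")

    @property
    def cycle_duration(self) -> float:
        return 120.0 / self.cadence_steps_per_min


def _default_profiles(params: GaitGeneratorParams) -> dict:
    """Fourier joint-angle profiles (rad) for the lowerlimb-12m fixture.

    Signs follow the fixture's axes: hip_ry positive = extension, knee_angle
    positive = flexion, talocrural positive = plantarflexion.
    """
    d = np.pi / 180.0
    prof = {
        # hip flexion 25° at heel strike -> ~11° extension mid-stance
        "hip_ry": (-7 * d, [(-18 * d, -5 * d)]),
        "hip_rx": (2 * d, [(1.5 * d, -3 * d)]),
        "hip_rz": (0.0, [(1 * d, 2 * d)]),
        "knee_angle": (22 * d, [(-12 * d, -16 * d), (-4 * d, 3 * d)]),
        "talocrural_angle": (2 * d, [(-3 * d, -5 * d), (1 * d, 2 * d)]),
        "subtalar_angle": (0.0, []),
        "pelvis_ty": (0.0, [(0.0, 0.02)]),
        "pelvis_tz": (params.pelvis_height, [(0.0, 0.0), (0.008, 0.0)]),
        "pelvis_rx": (0.0, [(0.0, 1.5 * d)]),
        "pelvis_ry": (2 * d, [(1 * d, 0.0)]),
        "pelvis_rz": (0.0, [(0.0, -2 * d)]),
    }
    prof.update(params.angle_profiles)
    return prof


def _fourier_eval(a0, harmonics, phi, omega):
    """Value, first and second time derivative of a Fourier profile."""
    val = np.full_like(phi, a0, dtype=float)
    vel = np.zeros_like(phi)
    acc = np.zeros_like(phi)
    for k, (ck, sk) in enumerate(harmonics, start=1):
        w = k * omega
        arg = k * 2.0 * np.pi * phi
        val += ck * np.cos(arg) + sk * np.sin(arg)
        vel += w * (-ck * np.sin(arg) + sk * np.cos(arg))
        acc += w * w * (-ck * np.cos(arg) - sk * np.sin(arg))
    return val, vel, acc


@dataclass
class GaitGroundTruth:
    """Everything the generator knows exactly about the trial it emitted."""

    postures: list[Posture]
    q: np.ndarray
    qd: np.ndarray
    qdd: np.ndarray
    reference_hcf: np.ndarray | None = None    # (n, 3) femur frame, BW
    reference_results: object | None = None    # full TrialResults on clean input


def _vertical_grf_profile(tau, shape):
    """Double-bump vertical stance profile, unit amplitude; zero at ends."""
    return np.sin(np.pi * tau) * (1.0 + shape * np.cos(2.0 * np.pi * tau))


def generate_gait_trial(model: SkeletalModel, params: GaitGeneratorParams | None = None,
                        compute_reference: bool = True):
    """Generate one gait cycle for the given model.

    Returns ``(trial, truth)``. The trial contains marker trajectories
    (forward kinematics + optional noise), two force-plate records (right
    foot, and the phase-shifted contralateral plate so the two-plate vertical
    cycle average equals body weight), and — when ``compute_reference`` is
    true — the reference hip contact force computed by the full pipeline on
    the clean trial, stored as the trial's measured HCF.
    """
    params = params or GaitGeneratorParams()
    rng = np.random.default_rng(params.seed)
    T = params.cycle_duration
    n = int(round(T * params.rate_hz)) + 1
    t = np.arange(n) / params.rate_hz
    phi = t / T
    omega = 2.0 * np.pi / T

    profiles = _default_profiles(params)
    dof_names = model.dof_names
    nq = model.n_dof
    Q = np.zeros((n, nq))
    Qd = np.zeros((n, nq))
    Qdd = np.zeros((n, nq))
    for i, name in enumerate(dof_names):
        short = name.split("_", 1)[1] if name.startswith(model.root) else name
        key = f"{model.root}_{short}" if name.startswith(model.root) else name
        if key == f"{model.root}_tx":
            Q[:, i] = params.walking_speed * t
            Qd[:, i] = params.walking_speed
            continue
        if key in profiles:
            a0, harm = profiles[key]
            Q[:, i], Qd[:, i], Qdd[:, i] = _fourier_eval(a0, harm, phi, omega)

    postures = [Posture(q=Q[i], qd=Qd[i], qdd=Qdd[i], time=float(t[i])) for i in range(n)]

    # markers by forward kinematics (+ optional noise)
    markers = {mk.name: np.zeros((n, 3)) for mk in model.markers}
    foot_ref = {}
    for i, post in enumerate(postures):
        kin = fk_with_derivatives(model, Posture(q=post.q))
        for mk in model.markers:
            markers[mk.name][i] = kin[mk.segment].point(mk.local)
        if "foot" in model.segments:
            k = kin["foot"]
            foot_ref[i] = (k.point([-0.06, 0.0, -0.04]), k.point([0.17, 0.0, -0.04]))
    if params.marker_noise_std > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(
                0.0, params.marker_noise_std, size=(n, 3)
            )

    # ground reaction forces
    bw = model.body_weight
    sf = params.stance_fraction
    # per-foot cycle-average vertical force = BW/2  =>  amplitude from the
    # analytic mean of the double-bump shape
    shape_mean = (2.0 / np.pi) * (1.0 - params.grf_shape / 3.0)
    amp = bw / (2.0 * sf * shape_mean)

    def plate(phase_shift, name, target):
        tau = ((phi - phase_shift) % 1.0) / sf
        in_stance = tau < 1.0
        tau = np.clip(tau, 0.0, 1.0)
        fz = np.where(in_stance, amp * _vertical_grf_profile(tau, params.grf_shape), 0.0)
        fx = np.where(in_stance, -params.ap_shear_bw * bw * np.sin(2 * np.pi * tau), 0.0)
        fy = np.where(in_stance, -params.ml_shear_bw * bw * np.sin(np.pi * tau), 0.0)
        force = np.column_stack([fx, fy, fz])
        cop = np.zeros((n, 3))
        for i in range(n):
            if not in_stance[i]:
                continue
            prog = 0.12 + 0.5 * tau[i]
            if target == "foot" and i in foot_ref:
                heel, toe = foot_ref[i]
                cop[i] = heel + prog * (toe - heel)
            else:
                cop[i] = np.array([params.walking_speed * (phase_shift * T) + prog * 0.25,
                                   0.12, 0.0])
        return GrfRecord(name=name, force=force, cop=cop,
                         free_moment=np.zeros((n, 3)), target_segment=target_seg(target))

    def target_seg(target):
        return "foot" if target == "foot" and "foot" in model.segments else None

    grf = [plate(0.0, "plate_r", "foot"), plate(0.5, "plate_l", "contra")]

    trial = GaitTrial(time=t, markers=markers, grf=grf,
                      events={"stance_fraction": sf, "cycle_start": 0.0})
    truth = GaitGroundTruth(postures=postures, q=Q, qd=Qd, qdd=Qdd)

    if compute_reference:
        from .pipeline import AnalysisSettings, analyze_trial  # lazy: avoids cycle

        clean = trial
        if params.marker_noise_std > 0:
            clean_markers = {}
            for mk in model.markers:
                arr = np.zeros((n, 3))
                for i, post in enumerate(postures):
                    kin = fk_with_derivatives(model, Posture(q=post.q))
                    arr[i] = kin[mk.segment].point(mk.local)
                clean_markers[mk.name] = arr
            clean = GaitTrial(time=t, markers=clean_markers, grf=grf,
                              events=dict(trial.events))
        results = analyze_trial(model, clean, AnalysisSettings())
        truth.reference_results = results
        truth.reference_hcf = results.hcf_components.copy()
        trial.measured_hcf = results.hcf_components.copy()

    return trial, truth


# ---------------------------------------------------------------------------
# model perturbations (creating the "defective" states)
# ---------------------------------------------------------------------------

def perturb_model(model: SkeletalModel, spec: dict) -> tuple[SkeletalModel, list[str]]:
    """Apply a perturbation spec; returns (modified copy, diff report).

    Supported operations::

        {"remove_wrap": [muscle_name, ...]}
        {"shift_origin": {"muscles": [...], "delta": [dx, dy, dz]}}
        {"shift_via": {"muscles": [...], "node": k, "delta": [dx, dy, dz]}}

    Mirrors, in reverse, the kind of geometry refinements studied on the full
    model: removing a condyle wrap reproduces the knee-flexor defect where
    the elements lose their knee moment arm near full extension.
    """
    m2 = model.copy()
    report: list[str] = []
    by_name = {m.name: m for m in m2.muscles}

    def pick(names):
        out = []
        for nm in names:
            if nm not in by_name:
                raise ModelError(f"perturbation targets unknown muscle {nm!r}")
            out.append(by_name[nm])
        return out

    for key, val in spec.items():
        if key == "remove_wrap":
            for mus in pick(val):
                if mus.wraps:
                    report.append(f"removed {len(mus.wraps)} wrap(s) from {mus.name}")
                    mus.wraps = {}
        elif key == "shift_origin":
            delta = np.asarray(val["delta"], float)
            for mus in pick(val["muscles"]):
                seg, p = mus.nodes[0]
                mus.nodes[0] = (seg, p + delta)
                if np.any(delta != 0):
                    report.append(f"shifted origin of {mus.name} by {delta.tolist()}")
        elif key == "shift_via":
            delta = np.asarray(val["delta"], float)
            k = int(val["node"])
            for mus in pick(val["muscles"]):
                if not (0 < k < len(mus.nodes) - 1):
                    raise ModelError(f"muscle {mus.name!r} has no via node {k}")
                seg, p = mus.nodes[k]
                mus.nodes[k] = (seg, p + delta)
                if np.any(delta != 0):
                    report.append(f"shifted via {k} of {mus.name} by {delta.tolist()}")
        else:
            raise ModelError(f"unknown perturbation {key!r}")
    return m2, report
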