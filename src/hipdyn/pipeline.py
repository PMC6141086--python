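"""Pipeline orchestration: in-memory analysis and file-based stages.

``analyze_trial`` runs the whole chain in memory: filter → inverse
kinematics → differentiation → inverse dynamics → muscle recruitment → hip
contact force → decomposition → flagging → validation. The file-based stage
functions (``stage_ik`` … ``stage_validate``) wrap the same code, reading
their inputs from and writing their outputs to a working directory, so CLI
subcommands compose to exactly the end-to-end result; ``run_pipeline`` simply
executes the stages in order and writes a manifest with content hashes for
reproducibility checks.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .contributions import FlagThresholds, MuscleContribution, decompose_hcf, flag_suspect_muscles
from .dynamics import (
    ExternalLoad,
    ExternalLoadSet,
    NetJointLoads,
    inverse_dynamics,
    limb_free_body,
)
from .geometry import moment_arm, muscle_spans_joint
from .kinematics import (
    FilterConfig,
    GaitTrial,
    differentiate_postures,
    lowpass_zero_phase,
    solve_trial_ik,
)
from .model import Posture, SkeletalModel, load_model
from .recruitment import (
    FemurFrame,
    RecruitmentConfig,
    femur_frame_axes,
    hip_crossing_forces,
    joint_contact_force,
    solve_recruitment,
)
from .validation import detect_gait_events, rmse_report

__all__ = [
    "AnalysisSettings",
    "TrialResults",
    "PipelineConfig",
    "PipelineError",
    "analyze_trial",
    "run_pipeline",
    "STAGES",
]


class PipelineError(RuntimeError):
    pass


@dataclass
class AnalysisSettings:
    """Tunable parameters of the analysis chain (defaults follow the text)."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    recruitment: RecruitmentConfig = field(default_factory=RecruitmentConfig)
    grf_threshold_n: float = 20.0
    filter_markers: bool = True
    filter_grf: bool = True
    flag_thresholds: FlagThresholds = field(default_factory=FlagThresholds)


@dataclass
class TrialResults:
    """Bundle of every per-frame quantity the pipeline computes."""

    time: np.ndarray
    pct: np.ndarray
    postures: list[Posture]
    net_loads: NetJointLoads
    constrained_dofs: list[str]
    moment_targets: np.ndarray          # (n, d)
    muscle_forces: np.ndarray           # (n, m)
    activations: np.ndarray             # (n, m)
    hcf_components: np.ndarray          # (n, 3) femur frame, BW
    hcf_world: np.ndarray               # (n, 3) N
    free_body: object
    crossing_forces: np.ndarray         # (n, m, 3) world N
    contribution: MuscleContribution
    flags: object
    events: object
    validation: object | None = None
    residual_base: np.ndarray | None = None

    @property
    def hcf_total(self) -> np.ndarray:
        return np.linalg.norm(self.hcf_components, axis=1)

    @property
    def eq1_residual_bw(self) -> float:
        """Max per-frame norm of the limb force-balance residual, in BW."""
        return float(np.max(self.contribution.closure_residual))


def _analysis_meta(model: SkeletalModel):
    a = dict(model.analysis)
    a.setdefault("hip_joint", "hip")
    a.setdefault("knee_joint", "knee")
    a.setdefault("femur_segment", "femur")
    a.setdefault("foot_segment", "foot")
    a.setdefault("anterior_axis", [1.0, 0.0, 0.0])
    if "constrained_dofs" not in a:
        dofs = []
        for seg in model.topological_order():
            j = model.joint_of_child(seg)
            if j is None:
                continue
            if any(muscle_spans_joint(model, m, j.name) for m in model.muscles):
                dofs.extend(j.dof_names)
        a["constrained_dofs"] = dofs
    return a


def _filtered_trial(model, trial: GaitTrial, settings: AnalysisSettings) -> GaitTrial:
    rate = trial.rate
    markers = trial.markers
    if settings.filter_markers:
        markers = {nm: lowpass_zero_phase(tr, settings.filter, rate)
                   for nm, tr in trial.markers.items()}
    grf = trial.grf
    if settings.filter_grf:
        from .kinematics import GrfRecord

        grf = [GrfRecord(
            name=r.name,
            force=lowpass_zero_phase(r.force, settings.filter, rate),
            cop=r.cop,
            free_moment=lowpass_zero_phase(r.free_moment, settings.filter, rate),
            target_segment=r.target_segment,
        ) for r in trial.grf]
    return GaitTrial(time=trial.time, markers=markers, grf=grf,
                     measured_hcf=trial.measured_hcf, events=dict(trial.events))


def _load_set(model, trial: GaitTrial, threshold: float) -> ExternalLoadSet:
    """Assign each plate to its target foot when loaded above the threshold."""
    frames = []
    for i in range(trial.n_frames):
        loads = []
        for rec in trial.grf:
            if rec.target_segment and rec.target_segment in model.segments:
                if rec.force[i, 2] > threshold:
                    loads.append(ExternalLoad(
                        segment=rec.target_segment,
                        force=rec.force[i].copy(),
                        point=rec.cop[i].copy(),
                        free_moment=rec.free_moment[i].copy(),
                    ))
        frames.append(loads)
    return ExternalLoadSet(frames=frames)


def _moment_targets(model, postures, net_loads: NetJointLoads, dof_names):
    """Generalized net moments on the constrained dofs, per frame."""
    all_names = model.dof_names
    idx = [all_names.index(d) for d in dof_names]
    joint_of = {}
    for seg in model.topological_order():
        j = model.joint_of_child(seg)
        if j is None:
            continue
        sl = model.joint_dof_slice(j.name)
        for k in range(sl.start, sl.stop):
            joint_of[k] = (j.name, k - sl.start)
    out = np.zeros((len(postures), len(idx)))
    for i in range(len(postures)):
        for c, k in enumerate(idx):
            jname, comp = joint_of[k]
            out[i, c] = np.real(net_loads.frames[i][jname].generalized[comp])
    return out


def analyze_trial(model: SkeletalModel, trial: GaitTrial,
                  settings: AnalysisSettings | None = None) -> TrialResults:
    """Run the full analysis chain on one trial (in memory)."""
    settings = settings or AnalysisSettings()
    meta = _analysis_meta(model)
    rate = trial.rate
    ftrial = _filtered_trial(model, trial, settings)

    # events from the plate assigned to the analyzed foot
    foot_plate = next((r for r in ftrial.grf if r.target_segment == meta["foot_segment"]),
                      None)
    events = None
    if foot_plate is not None:
        events = detect_gait_events(ftrial.time, foot_plate.force[:, 2],
                                    settings.grf_threshold_n)

    postures = solve_trial_ik(model, ftrial)
    postures = differentiate_postures(postures, rate)

    load_set = _load_set(model, ftrial, settings.grf_threshold_n)
    net_loads = inverse_dynamics(model, postures, load_set)

    dof_names = list(meta["constrained_dofs"])
    tau = _moment_targets(model, postures, net_loads, dof_names)
    dof_idx = [model.dof_names.index(d) for d in dof_names]
    strengths = np.array([m.strength for m in model.muscles])

    n, m = len(postures), len(model.muscles)
    forces = np.zeros((n, m))
    acts = np.zeros((n, m))
    for i, post in enumerate(postures):
        R = np.zeros((len(dof_idx), m))
        for c, mus in enumerate(model.muscles):
            for r, d in enumerate(dof_idx):
                R[r, c] = moment_arm(model, post, mus, d)
        try:
            state = solve_recruitment(tau[i], R, strengths, settings.recruitment)
        except Exception as exc:
            raise PipelineError(f"recruitment failed at frame {i}: {exc}") from exc
        forces[i] = state.forces
        acts[i] = state.activations

    hip = meta["hip_joint"]
    fb = limb_free_body(model, postures, load_set, hip)
    femur = femur_frame_axes(model, hip, meta["knee_joint"],
                             anterior_local=np.asarray(meta["anterior_axis"], float))
    hcf_comp = np.zeros((n, 3))
    hcf_world = np.zeros((n, 3))
    crossing = np.zeros((n, m, 3))
    from .model import forward_kinematics

    for i, post in enumerate(postures):
        kin = forward_kinematics(model, post)
        cf = hip_crossing_forces(model, post, forces[i], hip, kin=kin)
        for c, v in enumerate(cf):
            if v is not None:
                crossing[i, c] = v
        from .recruitment import MuscleState

        state = MuscleState(forces=forces[i], activations=acts[i],
                            multipliers=np.zeros(len(dof_idx)), kkt_residual=0.0)
        jcf = joint_contact_force(
            model, post, state,
            np.vstack([fb.f_inertial[i], fb.f_gravity[i], fb.grf_sum[i]]),
            femur, hip, meta["femur_segment"], kin=kin,
        )
        hcf_comp[i] = jcf.components
        hcf_world[i] = jcf.world

    # per-muscle moment contributions on the constrained dofs
    moment_contrib = np.zeros((n, len(dof_idx), m))
    for i, post in enumerate(postures):
        for c, mus in enumerate(model.muscles):
            if forces[i, c] == 0.0:
                continue
            for r, d in enumerate(dof_idx):
                moment_contrib[i, r, c] = forces[i, c] * moment_arm(model, post, mus, d)

    bw = model.body_weight
    contrib = decompose_hcf(
        element_names=[mu.name for mu in model.muscles],
        groups_of={mu.name: mu.group for mu in model.muscles},
        crossing_forces=crossing,
        hcf_world=hcf_world,
        free_body=fb,
        moment_contrib=moment_contrib,
        dof_names=dof_names,
    )
    contrib.closure_residual = contrib.closure_residual / bw  # report in BW

    span = trial.time[-1] - trial.time[0]
    pct = 100.0 * (trial.time - trial.time[0]) / span
    stance_mask = events.in_stance(pct) if events is not None else np.ones(n, bool)
    flags = flag_suspect_muscles(contrib, tau, pct, stance_mask,
                                 settings.flag_thresholds)

    validation = None
    if trial.measured_hcf is not None and events is not None:
        validation = rmse_report(hcf_comp, trial.measured_hcf, trial.time, events)

    base = None
    if net_loads.base_residual is not None:
        base = np.array(net_loads.base_residual)

    return TrialResults(
        time=trial.time, pct=pct, postures=postures, net_loads=net_loads,
        constrained_dofs=dof_names, moment_targets=tau,
        muscle_forces=forces, activations=acts,
        hcf_components=hcf_comp, hcf_world=hcf_world,
        free_body=fb, crossing_forces=crossing, contribution=contrib,
        flags=flags, events=events, validation=validation, residual_base=base,
    )


# ---------------------------------------------------------------------------
# file-based stages
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Paths and settings of a file-based pipeline run."""

    model_path: str
    markers_path: str
    grf_path: str
    out_dir: str
    measured_hcf_path: str | None = None
    seed: int = 0
    settings: AnalysisSettings = field(default_factory=AnalysisSettings)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        base = os.path.dirname(os.path.abspath(path))

        def absp(p):
            return p if p is None or os.path.isabs(p) else os.path.join(base, p)

        settings = AnalysisSettings()
        if "filter_cutoff_hz" in doc:
            settings.filter.cutoff = float(doc["filter_cutoff_hz"])
        if "recruitment_exponent" in doc:
            settings.recruitment.exponent = float(doc["recruitment_exponent"])
        if "grf_threshold_n" in doc:
            settings.grf_threshold_n = float(doc["grf_threshold_n"])
        return cls(
            model_path=absp(doc["model"]),
            markers_path=absp(doc["markers"]),
            grf_path=absp(doc["grf"]),
            out_dir=absp(doc.get("out_dir", "out")),
            measured_hcf_path=absp(doc.get("measured_hcf")),
            seed=int(doc.get("seed", 0)),
            settings=settings,
        )

    def config_hash(self) -> str:
        blob = json.dumps({
            "model": os.path.basename(self.model_path),
            "markers": os.path.basename(self.markers_path),
            "grf": os.path.basename(self.grf_path),
            "seed": self.seed,
            "cutoff": self.settings.filter.cutoff,
            "exponent": self.settings.recruitment.exponent,
            "grf_threshold": self.settings.grf_threshold_n,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _ctx(cfg: PipelineConfig):
    model = load_model(cfg.model_path)
    os.makedirs(cfg.out_dir, exist_ok=True)
    return model


def stage_ik(cfg: PipelineConfig):
    """Filter the trial and solve per-frame inverse kinematics → q.csv."""
    model = _ctx(cfg)
    trial = hio.read_trial(cfg.markers_path, cfg.grf_path, cfg.measured_hcf_path)
    ftrial = _filtered_trial(model, trial, cfg.settings)
    postures = solve_trial_ik(model, ftrial)
    Q = np.array([p.q for p in postures])
    hio.write_q_csv(os.path.join(cfg.out_dir, "q.csv"), ftrial.time, Q, model.dof_names)
    hio.write_grf_csv(os.path.join(cfg.out_dir, "grf_filtered.csv"), ftrial.time, ftrial.grf)
    return ["q.csv", "grf_filtered.csv"]


def _read_state(cfg, model):
    t, Q, names = hio.read_q_csv(os.path.join(cfg.out_dir, "q.csv"))
    if names != model.dof_names:
        raise PipelineError("q.csv dof names do not match the model")
    rate = 1.0 / (t[1] - t[0])
    postures = differentiate_postures(
        [Posture(q=Q[i], time=float(t[i])) for i in range(len(t))], rate)
    t2, grf = hio.read_grf_csv(os.path.join(cfg.out_dir, "grf_filtered.csv"))
    trial = GaitTrial(time=t, markers={}, grf=grf)
    return t, postures, trial


def stage_id(cfg: PipelineConfig):
    """Inverse dynamics from q.csv → net generalized moments + free body."""
    model = _ctx(cfg)
    t, postures, trial = _read_state(cfg, model)
    meta = _analysis_meta(model)
    load_set = _load_set(model, trial, cfg.settings.grf_threshold_n)
    net = inverse_dynamics(model, postures, load_set)
    dofs = list(meta["constrained_dofs"])
    tau = _moment_targets(model, postures, net, dofs)
    pd.DataFrame(tau, columns=dofs).assign(time_s=t).to_csv(
        os.path.join(cfg.out_dir, "net_moments.csv"), index=False, float_format="%.17g")
    fb = limb_free_body(model, postures, load_set, meta["hip_joint"])
    hio.write_freebody_csv(os.path.join(cfg.out_dir, "freebody.csv"), t, fb)
    if net.base_residual is not None:
        pd.DataFrame(np.array(net.base_residual),
                     columns=["fx", "fy", "fz", "mx", "my", "mz"]).assign(time_s=t).to_csv(
            os.path.join(cfg.out_dir, "base_residual.csv"), index=False,
            float_format="%.17g")
    return ["net_moments.csv", "freebody.csv", "base_residual.csv"]


def stage_recruit(cfg: PipelineConfig):
    """Solve muscle recruitment and the hip contact force → forces, hcf.csv."""
    model = _ctx(cfg)
    t, postures, trial = _read_state(cfg, model)
    meta = _analysis_meta(model)
    df = pd.read_csv(os.path.join(cfg.out_dir, "net_moments.csv"))
    dofs = [c for c in df.columns if c != "time_s"]
    tau = df[dofs].to_numpy()
    dof_idx = [model.dof_names.index(d) for d in dofs]
    strengths = np.array([m.strength for m in model.muscles])
    n, m = len(postures), len(model.muscles)
    forces = np.zeros((n, m))
    acts = np.zeros((n, m))
    for i, post in enumerate(postures):
        R = np.zeros((len(dof_idx), m))
        for c, mus in enumerate(model.muscles):
            for r, d in enumerate(dof_idx):
                R[r, c] = moment_arm(model, post, mus, d)
        try:
            st = solve_recruitment(tau[i], R, strengths, cfg.settings.recruitment)
        except Exception as exc:
            raise PipelineError(f"recruitment failed at frame {i}: {exc}") from exc
        forces[i], acts[i] = st.forces, st.activations
    names = [mu.name for mu in model.muscles]
    pd.DataFrame(forces, columns=names).assign(time_s=t).to_csv(
        os.path.join(cfg.out_dir, "muscle_forces.csv"), index=False, float_format="%.17g")
    pd.DataFrame(acts, columns=names).assign(time_s=t).to_csv(
        os.path.join(cfg.out_dir, "activations.csv"), index=False, float_format="%.17g")

    _, fb = t, hio.read_freebody_csv(os.path.join(cfg.out_dir, "freebody.csv"))[1]
    femur = femur_frame_axes(model, meta["hip_joint"], meta["knee_joint"],
                             anterior_local=np.asarray(meta["anterior_axis"], float))
    from .model import forward_kinematics
    from .recruitment import MuscleState

    hcf = np.zeros((n, 3))
    for i, post in enumerate(postures):
        kin = forward_kinematics(model, post)
        st = MuscleState(forces=forces[i], activations=acts[i],
                         multipliers=np.zeros(len(dof_idx)), kkt_residual=0.0)
        jcf = joint_contact_force(
            model, post, st,
            np.vstack([fb.f_inertial[i], fb.f_gravity[i], fb.grf_sum[i]]),
            femur, meta["hip_joint"], meta["femur_segment"], kin=kin)
        hcf[i] = jcf.components
    pct = 100.0 * (t - t[0]) / (t[-1] - t[0])
    hio.write_hcf_csv(os.path.join(cfg.out_dir, "hcf.csv"), t, pct, hcf)
    return ["muscle_forces.csv", "activations.csv", "hcf.csv"]


def stage_decompose(cfg: PipelineConfig):
    """Per-muscle HCF decomposition → contributions.csv (+ closure check)."""
    model = _ctx(cfg)
    t, postures, trial = _read_state(cfg, model)
    meta = _analysis_meta(model)
    names = [mu.name for mu in model.muscles]
    forces = pd.read_csv(os.path.join(cfg.out_dir, "muscle_forces.csv"))[names].to_numpy()
    _, fb = t, hio.read_freebody_csv(os.path.join(cfg.out_dir, "freebody.csv"))[1]
    dfm = pd.read_csv(os.path.join(cfg.out_dir, "net_moments.csv"))
    dofs = [c for c in dfm.columns if c != "time_s"]
    dof_idx = [model.dof_names.index(d) for d in dofs]
    n, m = forces.shape
    crossing = np.zeros((n, m, 3))
    moment_contrib = np.zeros((n, len(dofs), m))
    hcf_world = np.zeros((n, 3))
    from .model import forward_kinematics

    for i, post in enumerate(postures):
        kin = forward_kinematics(model, post)
        cf = hip_crossing_forces(model, post, forces[i], meta["hip_joint"], kin=kin)
        for c, v in enumerate(cf):
            if v is not None:
                crossing[i, c] = v
        for c, mus in enumerate(model.muscles):
            if forces[i, c] == 0:
                continue
            for r, d in enumerate(dof_idx):
                moment_contrib[i, r, c] = forces[i, c] * moment_arm(model, post, mus, d)
        hcf_world[i] = -(fb.f_inertial[i] + fb.f_gravity[i] + fb.grf_sum[i]
                         + crossing[i].sum(axis=0))
    contrib = decompose_hcf(
        element_names=names,
        groups_of={mu.name: mu.group for mu in model.muscles},
        crossing_forces=crossing, hcf_world=hcf_world, free_body=fb,
        moment_contrib=moment_contrib, dof_names=dofs)
    bw = model.body_weight
    pct = 100.0 * (t - t[0]) / (t[-1] - t[0])
    rows = []
    for g in sorted(contrib.groups):
        gf = contrib.group_force(g) / bw
        for i in range(n):
            rows.append({"pct_gc": pct[i], "group": g,
                         "Fx_BW": gf[i, 0], "Fy_BW": gf[i, 1], "Fz_BW": gf[i, 2]})
    pd.DataFrame(rows).to_csv(os.path.join(cfg.out_dir, "contributions.csv"),
                              index=False, float_format="%.17g")
    rows = []
    for g in sorted(contrib.groups):
        gm = contrib.group_moment(g)
        for i in range(n):
            for r, d in enumerate(dofs):
                rows.append({"pct_gc": pct[i], "group": g, "dof": d,
                             "moment_Nm": gm[i, r]})
    pd.DataFrame(rows).to_csv(os.path.join(cfg.out_dir, "contribution_moments.csv"),
                              index=False, float_format="%.17g")
    with open(os.path.join(cfg.out_dir, "closure.json"), "w") as fh:
        json.dump({"max_eq1_residual_bw": float(np.max(contrib.closure_residual) / bw)},
                  fh, indent=2)
    return ["contributions.csv", "contribution_moments.csv", "closure.json"]


def stage_flag(cfg: PipelineConfig):
    """Apply the suspect-geometry criteria → flags.json."""
    model = _ctx(cfg)
    t, postures, trial = _read_state(cfg, model)
    meta = _analysis_meta(model)
    names = [mu.name for mu in model.muscles]
    forces = pd.read_csv(os.path.join(cfg.out_dir, "muscle_forces.csv"))[names].to_numpy()
    dfm = pd.read_csv(os.path.join(cfg.out_dir, "net_moments.csv"))
    dofs = [c for c in dfm.columns if c != "time_s"]
    tau = dfm[dofs].to_numpy()
    dof_idx = [model.dof_names.index(d) for d in dofs]
    _, fb = t, hio.read_freebody_csv(os.path.join(cfg.out_dir, "freebody.csv"))[1]
    n, m = forces.shape
    crossing = np.zeros((n, m, 3))
    moment_contrib = np.zeros((n, len(dofs), m))
    from .model import forward_kinematics

    for i, post in enumerate(postures):
        kin = forward_kinematics(model, post)
        cf = hip_crossing_forces(model, post, forces[i], meta["hip_joint"], kin=kin)
        for c, v in enumerate(cf):
            if v is not None:
                crossing[i, c] = v
        for c, mus in enumerate(model.muscles):
            if forces[i, c] == 0:
                continue
            for r, d in enumerate(dof_idx):
                moment_contrib[i, r, c] = forces[i, c] * moment_arm(model, post, mus, d)
    hcf_world = -(fb.f_inertial + fb.f_gravity + fb.grf_sum + crossing.sum(axis=1))
    contrib = decompose_hcf(
        element_names=names,
        groups_of={mu.name: mu.group for mu in model.muscles},
        crossing_forces=crossing, hcf_world=hcf_world, free_body=fb,
        moment_contrib=moment_contrib, dof_names=dofs)
    foot_plate = next((r for r in trial.grf if r.target_segment == meta["foot_segment"]),
                      None)
    pct = 100.0 * (t - t[0]) / (t[-1] - t[0])
    if foot_plate is not None:
        ev = detect_gait_events(t, foot_plate.force[:, 2], cfg.settings.grf_threshold_n)
        stance = ev.in_stance(pct)
    else:
        stance = np.ones(len(t), bool)
    report = flag_suspect_muscles(contrib, tau, pct, stance, cfg.settings.flag_thresholds)
    doc = {
        "criterion_a": report.criterion_a,
        "criterion_b": [asdict(e) for e in report.criterion_b],
        "summary": report.summary(),
    }
    with open(os.path.join(cfg.out_dir, "flags.json"), "w") as fh:
        json.dump(doc, fh, indent=2)
    return ["flags.json"]


def stage_validate(cfg: PipelineConfig):
    """Compare predicted vs measured HCF → validation.json (skipped w/o data)."""
    model = _ctx(cfg)
    meta = _analysis_meta(model)
    if cfg.measured_hcf_path is None or not os.path.exists(cfg.measured_hcf_path):
        with open(os.path.join(cfg.out_dir, "validation.json"), "w") as fh:
            json.dump({"skipped": "no measured HCF provided"}, fh, indent=2)
        return ["validation.json"]
    dfh = pd.read_csv(os.path.join(cfg.out_dir, "hcf.csv"))
    t = dfh["time_s"].to_numpy()
    pred = dfh[["AP_BW", "ML_BW", "PD_BW"]].to_numpy()
    _, meas = hio.read_hcf_csv(cfg.measured_hcf_path)
    t2, grf = hio.read_grf_csv(os.path.join(cfg.out_dir, "grf_filtered.csv"))
    foot_plate = next((r for r in grf if r.target_segment == meta["foot_segment"]), None)
    if foot_plate is None:
        raise PipelineError("no plate assigned to the analyzed foot")
    ev = detect_gait_events(t2, foot_plate.force[:, 2], cfg.settings.grf_threshold_n)
    rep = rmse_report(pred, meas, t, ev)
    with open(os.path.join(cfg.out_dir, "validation.json"), "w") as fh:
        json.dump(rep.as_dict(), fh, indent=2)
    return ["validation.json"]


STAGES = {
    "ik": stage_ik,
    "id": stage_id,
    "recruit": stage_recruit,
    "decompose": stage_decompose,
    "flag": stage_flag,
    "validate": stage_validate,
}


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order and write a manifest with content hashes."""
    import hipdyn

    outputs = []
    for name, fn in STAGES.items():
        try:
            outputs.extend(fn(cfg))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    manifest = {
        "package_version": getattr(hipdyn, "__version__", "0"),
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "outputs": {
            name: _sha256(os.path.join(cfg.out_dir, name))
            for name in sorted(set(outputs))
            if os.path.exists(os.path.join(cfg.out_dir, name))
        },
    }
    with open(os.path.join(cfg.out_dir, "closure.json")) as fh:
        manifest["max_eq1_residual_bw"] = json.load(fh)["max_eq1_residual_bw"]
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
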