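"""Per-muscle decomposition of the hip contact force and geometry flagging.

Each muscle element crossing the hip contributes F_i = f_i u_i (force
magnitude times line of action) to the muscle term of the limb force balance,
so MF_hip = Σ_i F_i exactly; the inertial, gravitational and ground-reaction
terms do not depend on muscle geometry, which makes F_i the element's whole
contribution to the hip contact force. Elements are aggregated per actuator
group for reporting.

Muscles are flagged as anatomically suspect when
(a) their contact-force contribution is large while their joint-moment
    contribution is small on every dof, or
(b) their moment contribution exceeds the overall net joint moment (same
    sign, larger magnitude) for a sustained part of the cycle —
both indicators that a line of action is geometrically wrong rather than
physiologically meaningful (e.g. knee flexors with no knee lever arm forcing
huge forces, and hence spurious hip loading, during swing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MuscleContribution",
    "FlagThresholds",
    "FlagReport",
    "decompose_hcf",
    "flag_suspect_muscles",
]


@dataclass
class MuscleContribution:
    """Per-frame, per-element hip force contributions and moment contributions."""

    element_names: list[str]
    groups: dict[str, list[int]]              # group -> element indices
    forces_world: np.ndarray                  # (n, m, 3) N : F_i = f_i u_i
    mf_hip: np.ndarray                        # (n, 3) N : sum over elements
    moment_contrib: np.ndarray                # (n, d, m) N*m : f_i * arm
    dof_names: list[str]
    closure_residual: np.ndarray              # (n,) N : Eq-1A residual norm

    def group_force(self, group: str) -> np.ndarray:
        return self.forces_world[:, self.groups[group], :].sum(axis=1)

    def group_moment(self, group: str) -> np.ndarray:
        return self.moment_contrib[:, :, self.groups[group]].sum(axis=2)


def decompose_hcf(element_names, groups_of, crossing_forces, hcf_world,
                  free_body, moment_contrib, dof_names) -> MuscleContribution:
    """Assemble the per-muscle decomposition and verify the force balance.

    ``crossing_forces``: (n, m, 3) world force vectors f_i u_i (zero rows for
    elements not crossing the hip). The closure residual reported per frame is
    ``‖HCF + F_inertial + F_gravity + GRF + Σ F_i‖`` recomputed from the
    stored terms — by construction of the contact force it should vanish to
    machine precision.
    """
    F = np.asarray(crossing_forces, float)
    n, m, _ = F.shape
    if len(element_names) != m:
        raise ValueError("element name count does not match force array")
    mf = F.sum(axis=1)
    resid = np.linalg.norm(
        np.asarray(hcf_world, float)
        + free_body.f_inertial + free_body.f_gravity + free_body.grf_sum + mf,
        axis=1,
    )
    groups: dict[str, list[int]] = {}
    for i, nm in enumerate(element_names):
        groups.setdefault(groups_of[nm], []).append(i)
    return MuscleContribution(
        element_names=list(element_names),
        groups=groups,
        forces_world=F,
        mf_hip=mf,
        moment_contrib=np.asarray(moment_contrib, float),
        dof_names=list(dof_names),
        closure_residual=resid,
    )


@dataclass
class FlagThresholds:
    """Criteria thresholds (repo defaults; the criteria themselves are
    qualitative — 'high contact-force share, low moment share' and 'moment
    contribution above the net moment').

    criterion (a): group peak |F_i| ≥ ``hcf_share`` of the peak total HCF
    while its moment share stays ≤ ``moment_share_floor`` on every dof.
    criterion (b): |group moment| > |net moment| with matching sign for at
    least ``min_episode_pct`` of the cycle, evaluated per dof, and exceeding
    it by at least ``min_excess_ratio`` at the episode peak (mild transient
    co-contraction is normal in a polynomial-criterion solution; a sustained
    multiple of the net moment is the anatomical red flag). Frames where the
    net moment is small — below ``net_moment_floor`` (N*m) or below
    ``net_moment_rel_floor`` times that dof's cycle-peak net moment — are
    ignored: exceeding a vanishing net moment carries no anatomical signal.
    """

    hcf_share: float = 0.15
    moment_share_floor: float = 0.05
    min_episode_pct: float = 5.0
    net_moment_floor: float = 5.0
    net_moment_rel_floor: float = 0.05
    min_excess_ratio: float = 2.0


@dataclass
class FlagEpisode:
    group: str
    dof: str
    start_pct: float
    end_pct: float
    peak_excess_ratio: float
    phase: str                         # "stance" | "swing" | "mixed"


@dataclass
class FlagReport:
    criterion_a: list[dict] = field(default_factory=list)
    criterion_b: list[FlagEpisode] = field(default_factory=list)

    @property
    def flagged_groups(self) -> set[str]:
        return {e["group"] for e in self.criterion_a} | {e.group for e in self.criterion_b}

    def summary(self) -> str:
        lines = []
        for e in self.criterion_a:
            lines.append(
                f"[a] {e['group']}: HCF share {e['hcf_share']:.2f} with moment share "
                f"<= {e['max_moment_share']:.3f} on every dof"
            )
        for e in self.criterion_b:
            lines.append(
                f"[b] {e.group} on {e.dof}: contribution exceeds net moment "
                f"{e.start_pct:.0f}-{e.end_pct:.0f}% ({e.phase}), "
                f"peak ratio {e.peak_excess_ratio:.2f}"
            )
        return "\n".join(lines) if lines else "no muscles flagged"


def flag_suspect_muscles(contrib: MuscleContribution, net_moments: np.ndarray,
                         pct: np.ndarray, stance_mask: np.ndarray,
                         thresholds: FlagThresholds | None = None) -> FlagReport:
    """Flag actuator groups with disproportionate or super-net contributions.

    ``net_moments``: (n, d) generalized net joint moments on the same dofs as
    ``contrib.moment_contrib``. Flagging is monotone in the thresholds:
    loosening any threshold can only add flags.
    """
    th = thresholds or FlagThresholds()
    pct = np.asarray(pct, float)
    net = np.asarray(net_moments, float)
    n, d, m = contrib.moment_contrib.shape
    report = FlagReport()

    # share scale: peak magnitude of the total muscle term MF_hip (the part
    # of the contact force that muscle geometry can influence)
    total_hcf_peak = float(np.max(np.linalg.norm(contrib.mf_hip, axis=1)))
    if total_hcf_peak <= 0:
        return report

    for group in sorted(contrib.groups):
        gF = contrib.group_force(group)
        gM = contrib.group_moment(group)            # (n, d)
        peak_share = float(np.max(np.linalg.norm(gF, axis=1)) / total_hcf_peak)

        # criterion (a): large force share, small moment share on every dof
        moment_shares = []
        for k in range(d):
            denom = max(float(np.max(np.abs(net[:, k]))), th.net_moment_floor)
            moment_shares.append(float(np.max(np.abs(gM[:, k]))) / denom)
        if peak_share >= th.hcf_share and max(moment_shares) <= th.moment_share_floor:
            report.criterion_a.append({
                "group": group,
                "hcf_share": peak_share,
                "max_moment_share": max(moment_shares),
            })

        # criterion (b): sustained super-net same-sign moment contribution
        for k in range(d):
            floor = max(th.net_moment_floor,
                        th.net_moment_rel_floor * float(np.max(np.abs(net[:, k]))))
            exceed = (
                (np.abs(gM[:, k]) > np.abs(net[:, k]))
                & (np.sign(gM[:, k]) == np.sign(net[:, k]))
                & (np.abs(net[:, k]) > floor)
            )
            for i0, i1 in _runs(exceed):
                span = pct[i1 - 1] - pct[i0]
                if span + (pct[1] - pct[0]) < th.min_episode_pct:
                    continue
                sl = slice(i0, i1)
                ratio = float(np.max(np.abs(gM[sl, k]) / np.abs(net[sl, k])))
                if ratio < th.min_excess_ratio:
                    continue
                in_st = stance_mask[sl]
                phase = "stance" if in_st.all() else ("swing" if not in_st.any() else "mixed")
                report.criterion_b.append(FlagEpisode(
                    group=group, dof=contrib.dof_names[k],
                    start_pct=float(pct[i0]), end_pct=float(pct[i1 - 1]),
                    peak_excess_ratio=ratio, phase=phase,
                ))
    return report


def _runs(mask):
    """(start, stop) index pairs of contiguous True runs."""
    out = []
    i = 0
    mask = np.asarray(mask, bool)
    while i < len(mask):
        if mask[i]:
            j = i
            while j < len(mask) and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out
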