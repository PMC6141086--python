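"""Readers and writers for the trial and result file formats.

Markers travel as TRC (tab-separated, the standard motion-capture exchange
text format) or long CSV; ground reaction forces, postures, muscle states and
hip contact forces as CSV via pandas. All values are written with full float
precision so a write/read round trip is exact and pipeline stages can be
composed through files without drift.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dynamics import LimbFreeBodyState
from .kinematics import GaitTrial, GrfRecord

__all__ = [
    "write_trc",
    "read_trc",
    "write_grf_csv",
    "read_grf_csv",
    "write_hcf_csv",
    "read_hcf_csv",
    "write_q_csv",
    "read_q_csv",
    "write_trial",
    "read_trial",
]

_FMT = "%.17g"


# ---------------------------------------------------------------------------
# TRC markers
# ---------------------------------------------------------------------------

def write_trc(path, time: np.ndarray, markers: dict[str, np.ndarray], units: str = "m"):
    names = list(markers)
    n = len(time)
    rate = (n - 1) / (time[-1] - time[0]) if n > 1 else 0.0
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{rate:.6f}\t{rate:.6f}\t{n}\t{len(names)}\t{units}\t"
                 f"{rate:.6f}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t\t\n")
        fh.write("\t\t" + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(names)))
                 + "\n")
        fh.write("\n")
        for i in range(n):
            row = [str(i + 1), _FMT % time[i]]
            for nm in names:
                row.extend(_FMT % v if np.isfinite(v) else "" for v in markers[nm][i])
            fh.write("\t".join(row) + "\n")


def read_trc(path):
    """Returns ``(time, markers)``; blank coordinate cells become NaN."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    hdr = lines[3].rstrip("\t").split("\t")
    names = [h for h in hdr[2:] if h]
    data_lines = [ln for ln in lines[5:] if ln.strip()]
    n = len(data_lines)
    time = np.zeros(n)
    markers = {nm: np.full((n, 3), np.nan) for nm in names}
    for i, ln in enumerate(data_lines):
        cells = ln.split("\t")
        time[i] = float(cells[1])
        for k, nm in enumerate(names):
            for c in range(3):
                cell = cells[2 + 3 * k + c] if 2 + 3 * k + c < len(cells) else ""
                if cell.strip():
                    markers[nm][i, c] = float(cell)
    return time, markers


# ---------------------------------------------------------------------------
# GRF / HCF / posture CSV
# ---------------------------------------------------------------------------

def write_grf_csv(path, time: np.ndarray, records: list[GrfRecord]):
    rows = []
    for rec in records:
        for i in range(len(time)):
            rows.append({
                "time_s": time[i], "plate": rec.name,
                "fx_n": rec.force[i, 0], "fy_n": rec.force[i, 1], "fz_n": rec.force[i, 2],
                "copx_m": rec.cop[i, 0], "copy_m": rec.cop[i, 1], "copz_m": rec.cop[i, 2],
                "mx_nm": rec.free_moment[i, 0], "my_nm": rec.free_moment[i, 1],
                "mz_nm": rec.free_moment[i, 2],
                "target_segment": rec.target_segment or "",
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FMT)


def read_grf_csv(path) -> tuple[np.ndarray, list[GrfRecord]]:
    df = pd.read_csv(path, keep_default_na=False)
    records = []
    time = None
    for plate, g in df.groupby("plate", sort=False):
        g = g.sort_values("time_s")
        time = g["time_s"].to_numpy()
        tgt = str(g["target_segment"].iloc[0]) or None
        records.append(GrfRecord(
            name=str(plate),
            force=g[["fx_n", "fy_n", "fz_n"]].to_numpy(),
            cop=g[["copx_m", "copy_m", "copz_m"]].to_numpy(),
            free_moment=g[["mx_nm", "my_nm", "mz_nm"]].to_numpy(),
            target_segment=tgt,
        ))
    return time, records


def write_hcf_csv(path, time, pct, components, total=None):
    comp = np.asarray(components, float)
    if total is None:
        total = np.linalg.norm(comp, axis=1)
    pd.DataFrame({
        "time_s": time, "pct_gait_cycle": pct,
        "AP_BW": comp[:, 0], "ML_BW": comp[:, 1], "PD_BW": comp[:, 2],
        "total_BW": total,
    }).to_csv(path, index=False, float_format=_FMT)


def read_hcf_csv(path):
    df = pd.read_csv(path)
    cols = [c for c in ("AP_BW", "ML_BW", "PD_BW") if c in df.columns]
    if len(cols) != 3:
        # tolerate a plain time + three-component layout (measured exports)
        num = df.select_dtypes("number")
        cols = [c for c in num.columns if c.lower() not in ("time_s", "time", "pct_gait_cycle")][:3]
    return df["time_s"].to_numpy(), df[cols].to_numpy()


def write_q_csv(path, time, Q, dof_names):
    df = pd.DataFrame(Q, columns=dof_names)
    df.insert(0, "time_s", time)
    df.to_csv(path, index=False, float_format=_FMT)


def read_q_csv(path):
    df = pd.read_csv(path)
    time = df.pop("time_s").to_numpy()
    return time, df.to_numpy(), list(df.columns)


def write_freebody_csv(path, time, fb: LimbFreeBodyState):
    pd.DataFrame({
        "time_s": time,
        "fi_x": fb.f_inertial[:, 0], "fi_y": fb.f_inertial[:, 1], "fi_z": fb.f_inertial[:, 2],
        "fg_x": fb.f_gravity[:, 0], "fg_y": fb.f_gravity[:, 1], "fg_z": fb.f_gravity[:, 2],
        "grf_x": fb.grf_sum[:, 0], "grf_y": fb.grf_sum[:, 1], "grf_z": fb.grf_sum[:, 2],
    }).to_csv(path, index=False, float_format=_FMT)


def read_freebody_csv(path):
    df = pd.read_csv(path)
    return df["time_s"].to_numpy(), LimbFreeBodyState(
        f_inertial=df[["fi_x", "fi_y", "fi_z"]].to_numpy(),
        f_gravity=df[["fg_x", "fg_y", "fg_z"]].to_numpy(),
        grf_sum=df[["grf_x", "grf_y", "grf_z"]].to_numpy(),
    )


# ---------------------------------------------------------------------------
# whole-trial convenience wrappers
# ---------------------------------------------------------------------------

def write_trial(dirpath, trial: GaitTrial, prefix: str = "trial"):
    """Write a GaitTrial as TRC + GRF CSV (+ measured HCF CSV if present)."""
    import os

    trc = os.path.join(dirpath, f"{prefix}_markers.trc")
    grf = os.path.join(dirpath, f"{prefix}_grf.csv")
    write_trc(trc, trial.time, trial.markers)
    write_grf_csv(grf, trial.time, trial.grf)
    paths = {"markers": trc, "grf": grf}
    if trial.measured_hcf is not None:
        hcf = os.path.join(dirpath, f"{prefix}_measured_hcf.csv")
        span = trial.time[-1] - trial.time[0]
        pct = 100.0 * (trial.time - trial.time[0]) / span
        write_hcf_csv(hcf, trial.time, pct, trial.measured_hcf)
        paths["measured_hcf"] = hcf
    return paths


def read_trial(markers_path, grf_path, measured_hcf_path=None) -> GaitTrial:
    time, markers = read_trc(markers_path)
    t2, grf = read_grf_csv(grf_path)
    if len(t2) != len(time) or np.max(np.abs(t2 - time)) > 1e-9:
        raise ValueError("marker and GRF time bases differ")
    measured = None
    if measured_hcf_path is not None:
        t3, measured = read_hcf_csv(measured_hcf_path)
    return GaitTrial(time=time, markers=markers, grf=grf, measured_hcf=measured)
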