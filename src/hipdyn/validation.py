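"""Validation metrics: gait events, RMSE reports, activation on-off timing.

Predicted and measured hip contact forces are compared on a common 0–100%
gait-cycle grid (101 points, monotone cubic resampling): RMSE over the whole
cycle for the antero-posterior, medio-lateral and proximo-distal components
and for the total force (the Euclidean norm of the three), the total-force
RMSE split into stance and swing, and the two stance peaks (loading ~0–30%,
terminal ~30–60% windows). Muscle activity is reduced to on-off intervals by
thresholding with debouncing and compared against reference timing windows
(e.g. published EMG timing for hip-replacement patients).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "ValidationError",
    "GaitEvents",
    "ValidationReport",
    "ActivationTiming",
    "detect_gait_events",
    "resample_to_cycle",
    "rmse_report",
    "activation_onoff",
    "compare_timing",
]


class ValidationError(RuntimeError):
    pass


@dataclass
class GaitEvents:
    """Stance/swing split of one normalized gait cycle (percent of cycle)."""

    stance_pct: tuple[float, float]      # [start, end) in % cycle
    cycle_time: tuple[float, float]      # (t_start, t_end) s

    def in_stance(self, pct):
        lo, hi = self.stance_pct
        return (pct >= lo) & (pct < hi)


def detect_gait_events(time: np.ndarray, vertical_grf: np.ndarray,
                       threshold: float = 20.0) -> GaitEvents:
    """Stance interval from a vertical GRF threshold crossing.

    Stance is where the analyzed foot's vertical force exceeds ``threshold``
    (N). The cycle is normalized heel-strike to heel-strike: a trial covering
    exactly one cycle may start in stance at its first sample.
    """
    f = np.asarray(vertical_grf, float)
    time = np.asarray(time, float)
    above = f > threshold
    if not above.any():
        raise ValidationError(f"vertical GRF never exceeds {threshold} N; no events")
    if not (~above).any():
        raise ValidationError("vertical GRF never drops below threshold; no swing phase")
    i_on = int(np.argmax(above))
    i_off = i_on + int(np.argmax(~above[i_on:]))
    t0, t1 = time[0], time[-1]
    span = t1 - t0
    stance = (100.0 * (time[i_on] - t0) / span, 100.0 * (time[i_off] - t0) / span)
    return GaitEvents(stance_pct=stance, cycle_time=(float(t0), float(t1)))


def resample_to_cycle(time: np.ndarray, series: np.ndarray, n_points: int = 101) -> np.ndarray:
    """Monotone cubic resampling onto the 0–100% cycle grid."""
    time = np.asarray(time, float)
    series = np.asarray(series, float)
    pct = 100.0 * (time - time[0]) / (time[-1] - time[0])
    grid = np.linspace(0.0, 100.0, n_points)
    if series.ndim == 1:
        return PchipInterpolator(pct, series)(grid)
    return np.column_stack([PchipInterpolator(pct, series[:, k])(grid)
                            for k in range(series.shape[1])])


def _rmse(a, b):
    return float(np.sqrt(np.mean(np.square(np.asarray(a) - np.asarray(b)))))


@dataclass
class ValidationReport:
    rmse_total: float
    rmse_stance: float
    rmse_swing: float
    rmse_components: dict[str, float]          # AP / ML / PD
    first_peak: dict[str, float]               # predicted / measured / error
    second_peak: dict[str, float]
    error_series: np.ndarray                   # per-grid-point total error
    grid_pct: np.ndarray

    def as_dict(self):
        return {
            "rmse_total_bw": self.rmse_total,
            "rmse_stance_bw": self.rmse_stance,
            "rmse_swing_bw": self.rmse_swing,
            "rmse_ap_bw": self.rmse_components["AP"],
            "rmse_ml_bw": self.rmse_components["ML"],
            "rmse_pd_bw": self.rmse_components["PD"],
            "first_peak": self.first_peak,
            "second_peak": self.second_peak,
        }


def _window_peak(mag, grid, lo, hi):
    """Largest interior local maximum of ``mag`` inside [lo, hi] % cycle."""
    sel = (grid >= lo) & (grid <= hi)
    idx = np.where(sel)[0]
    if idx.size == 0:          # coarse grid: no sample falls in the window
        idx = np.arange(len(grid))
    best, best_val = None, -np.inf
    for i in idx:
        if 0 < i < len(mag) - 1 and mag[i] >= mag[i - 1] and mag[i] >= mag[i + 1]:
            if mag[i] > best_val:
                best, best_val = i, mag[i]
    if best is None:  # monotone in window: take the max
        best = idx[np.argmax(mag[idx])]
    return int(best)


def rmse_report(predicted: np.ndarray, measured: np.ndarray, time: np.ndarray,
                events: GaitEvents, n_points: int = 101,
                peak_windows=((0.0, 30.0), (30.0, 60.0))) -> ValidationReport:
    """Compare predicted vs measured HCF components (n×3, BW) over one cycle."""
    pred = resample_to_cycle(time, np.asarray(predicted, float), n_points)
    meas = resample_to_cycle(time, np.asarray(measured, float), n_points)
    if pred.shape != meas.shape:
        raise ValidationError(f"series shapes differ after resampling: "
                              f"{pred.shape} vs {meas.shape}")
    grid = np.linspace(0.0, 100.0, n_points)
    mag_p = np.linalg.norm(pred, axis=1)
    mag_m = np.linalg.norm(meas, axis=1)
    stance = events.in_stance(grid)
    comp_names = ("AP", "ML", "PD")
    comps = {nm: _rmse(pred[:, k], meas[:, k]) for k, nm in enumerate(comp_names)}
    i1 = _window_peak(mag_m, grid, *peak_windows[0])
    i2 = _window_peak(mag_m, grid, *peak_windows[1])

    def peak(i):
        return {
            "pct": float(grid[i]),
            "predicted_bw": float(mag_p[i]),
            "measured_bw": float(mag_m[i]),
            "error_bw": float(mag_p[i] - mag_m[i]),
        }

    return ValidationReport(
        rmse_total=_rmse(mag_p, mag_m),
        rmse_stance=_rmse(mag_p[stance], mag_m[stance]),
        rmse_swing=_rmse(mag_p[~stance], mag_m[~stance]),
        rmse_components=comps,
        first_peak=peak(i1),
        second_peak=peak(i2),
        error_series=mag_p - mag_m,
        grid_pct=grid,
    )


# ---------------------------------------------------------------------------
# activation on-off timing
# ---------------------------------------------------------------------------

def activation_onoff(pct: np.ndarray, activation: np.ndarray,
                     on_threshold: float | None = None,
                     threshold_fraction: float = 0.1,
                     debounce_pct: float = 3.0) -> list[tuple[float, float]]:
    """On intervals (% gait cycle) of one muscle's activation series.

    ``on`` is activation above the threshold (absolute value, or
    ``threshold_fraction`` of the cycle maximum when not given), with runs —
    on or off — shorter than ``debounce_pct`` of the cycle merged away.
    """
    a = np.asarray(activation, float)
    pct = np.asarray(pct, float)
    if on_threshold is None:
        mx = a.max() if a.size else 0.0
        if mx <= 0:
            return []
        on_threshold = threshold_fraction * mx
    on = a > on_threshold
    if not on.any():
        return []
    # run-length pass with debouncing
    step = np.mean(np.diff(pct)) if len(pct) > 1 else 1.0
    min_run = max(1, int(round(debounce_pct / step)))
    runs = []
    i = 0
    while i < len(on):
        j = i
        while j < len(on) and on[j] == on[i]:
            j += 1
        runs.append([bool(on[i]), i, j])
        i = j
    # absorb short runs into neighbours (interior only)
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for k, (state, i0, i1) in enumerate(runs):
            if 0 < k < len(runs) - 1 and (i1 - i0) < min_run:
                runs[k - 1][2] = runs[k + 1][2]
                del runs[k:k + 2]
                changed = True
                break
    out = []
    for state, i0, i1 in runs:
        if state and (i1 - i0) >= min_run:
            out.append((float(pct[i0]), float(pct[min(i1, len(pct) - 1)])))
    return out


@dataclass
class ActivationTiming:
    """Per-muscle comparison of predicted on intervals vs reference windows."""

    muscle: str
    predicted: list[tuple[float, float]]
    reference: list[tuple[float, float]]
    matches: list[dict] = field(default_factory=list)
    jaccard: float = 0.0


def _interval_overlap(a, b):
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def compare_timing(muscle: str, predicted: list[tuple[float, float]],
                   reference: list[tuple[float, float]]) -> ActivationTiming:
    """Match predicted on-intervals to reference windows by maximal overlap.

    Jaccard is the cycle-wide intersection over union of the two interval
    sets; per-match onset/offset errors are predicted minus reference, in %
    of the gait cycle.
    """
    grid = np.linspace(0.0, 100.0, 1001)

    def cover(ints):
        m = np.zeros(len(grid), bool)
        for lo, hi in ints:
            m |= (grid >= lo) & (grid <= hi)
        return m

    p, r = cover(predicted), cover(reference)
    union = np.count_nonzero(p | r)
    jac = float(np.count_nonzero(p & r) / union) if union else 1.0
    matches = []
    for ref in reference:
        best, best_ov = None, 0.0
        for pred in predicted:
            ov = _interval_overlap(pred, ref)
            if ov > best_ov:
                best, best_ov = pred, ov
        if best is not None:
            matches.append({
                "reference": ref,
                "predicted": best,
                "onset_error_pct": best[0] - ref[0],
                "offset_error_pct": best[1] - ref[1],
                "overlap_pct": best_ov,
            })
    return ActivationTiming(muscle=muscle, predicted=list(predicted),
                            reference=list(reference), matches=matches, jaccard=jac)
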