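"""Summary quantities from experiment records.

Turns a raw record into the numbers one quotes from a stall measurement:
the initial stress (mean over the first 30 min after insertion), the
stalling stress (mean over the trailing plateau), the time to stall, a
dissipation flag with a fitted exponential decay timescale, the elongation
speed of a tissue front, and Welch two-sample comparisons of cell-speed
cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from tifm import units
from tifm.calibration_control import ExperimentRecord

INITIAL_WINDOW_S = 1800.0  # the "shortly after insertion" window


@dataclass
class StallMetrics:
    initial_stress_Pa: float
    stall_stress_Pa: float | None
    time_to_stall_min: float | None
    dissipation: bool
    decay_timescale_h: float | None
    warning: str | None = None


@dataclass
class GroupComparison:
    mean_a: float
    mean_b: float
    dispersion_a: float
    dispersion_b: float
    dispersion: str  # "sd" | "sem"
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int


def stress_trace(record: ExperimentRecord, k: float, area_um2: float) -> pd.Series:
    """σ(t) in Pa from the record's deflection column; indexed by time (s)."""
    if "deflection_um" not in record.data or "time_s" not in record.data:
        raise ValueError("record lacks deflection/time columns")
    d = record.data
    sigma = units.PA_PER_NN_UM2 * units.force_nN(k, 1.0) * d["deflection_um"] / area_um2
    out = pd.Series(sigma.to_numpy(), index=d["time_s"].to_numpy(), name="sigma_Pa")
    out.attrs["k_N_per_m"] = k
    out.attrs["area_um2"] = area_um2
    return out


def stall_metrics(
    sigma: pd.Series,
    stall_window_min: float = 30.0,
    rate_threshold_Pa_per_min: float = 0.2,
    smooth_samples: int = 5,
    dissipation_drop: float = 0.20,
) -> StallMetrics:
    """Initial/stall stress and dissipation from a σ(t) trace (index: s).

    The trace is smoothed with a centered moving average first. A trace that
    ends more than ``dissipation_drop`` below its (smoothed) peak is treated
    as dissipating: the stall stress is the plateau mean over the window
    ending at the peak, and an exponential decay is fitted to the declining
    segment. Otherwise the plateau is the trailing ``stall_window_min``
    minutes, accepted when the regression slope of σ over that window is
    below the rate threshold; a trace still ramping at the end reports no
    stall with a warning. Time-to-stall is when the smoothed trace first
    reaches 95 % of the plateau level.
    """
    t = np.asarray(sigma.index, float)
    y = np.asarray(sigma.to_numpy(), float)
    if t[-1] - t[0] < INITIAL_WINDOW_S:
        raise ValueError("trace must span at least the first 30 min")
    initial = float(np.mean(y[t - t[0] <= INITIAL_WINDOW_S]))

    ys = pd.Series(y).rolling(smooth_samples, center=True,
                              min_periods=1).mean().to_numpy()
    peak_idx = int(np.argmax(ys))
    dissipation = ys[-1] < (1.0 - dissipation_drop) * ys[peak_idx]

    def _time_to_stall(level: float) -> float:
        hit = np.flatnonzero(ys >= 0.95 * level)
        i0 = hit[0] if len(hit) else peak_idx
        return float((t[i0] - t[0]) / 60.0)

    if dissipation:
        in_peak = (t >= t[peak_idx] - stall_window_min * 60.0) & (t <= t[peak_idx])
        stall = float(np.mean(ys[in_peak]))
        tau_h = _fit_decay_timescale(t, ys, peak_idx)
        return StallMetrics(initial, stall, _time_to_stall(stall), True, tau_h)

    tail = t >= t[-1] - stall_window_min * 60.0
    slope = np.polyfit(t[tail] / 60.0, ys[tail], 1)[0]  # Pa per min
    if abs(slope) >= rate_threshold_Pa_per_min:
        return StallMetrics(initial, None, None, False, None,
                            warning="no plateau found")
    stall = float(np.mean(ys[tail]))
    return StallMetrics(initial, stall, _time_to_stall(stall), False, None)


def _fit_decay_timescale(t: np.ndarray, ys: np.ndarray, peak_idx: int
                         ) -> float | None:
    """Exponential timescale (h) of the declining segment after the peak.

    The fit starts where the trace has dropped to 80 % of the peak — the
    immediate post-peak shoulder still carries the mechanical relaxation of
    the probe and would bias the timescale upward.
    """
    below = np.flatnonzero(ys[peak_idx:] <= 0.8 * ys[peak_idx])
    start = peak_idx + (below[0] if len(below) else 0)
    if start >= len(t) - 3:
        start = peak_idx
    tt = (t[start:] - t[start]) / units.S_PER_H
    yy = ys[start:]
    if np.any(yy <= 0) or len(tt) < 4:
        return None
    try:
        popt, _ = optimize.curve_fit(
            lambda x, a, tau: a * np.exp(-x / tau),
            tt, yy, p0=(yy[0], max(tt[-1] / 2.0, 0.1)), maxfev=5000,
        )
        return float(popt[1])
    except RuntimeError:
        return None


def elongation_speed(front_positions: pd.Series | np.ndarray,
                     times_s: np.ndarray | None = None) -> float:
    """Least-squares slope of front position vs time, in µm/h."""
    if isinstance(front_positions, pd.Series):
        t = np.asarray(front_positions.index, float)
        x = front_positions.to_numpy(dtype=float)
    else:
        x = np.asarray(front_positions, float)
        t = np.asarray(times_s, float)
    if len(x) < 2:
        raise ValueError("need ≥ 2 samples")
    if np.ptp(t) == 0:
        raise ValueError("degenerate time axis")
    slope = np.polyfit(t, x, 1)[0]  # µm/s
    return float(units.um_per_s_to_um_per_h(slope))


def compare_groups(
    samples_a, samples_b, dispersion: str = "sd"
) -> GroupComparison:
    """Welch unpaired two-tailed t-test between two cohorts.

    Dispersion is reported as s.d. or s.e.m. per the caller's choice. Two
    zero-variance groups with equal means return t = 0, p = 1 by convention.
    """
    a = np.asarray(samples_a, float)
    b = np.asarray(samples_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n ≥ 2")
    if dispersion not in ("sd", "sem"):
        raise ValueError("dispersion must be 'sd' or 'sem'")
    sd_a, sd_b = np.std(a, ddof=1), np.std(b, ddof=1)
    if sd_a == 0 and sd_b == 0:
        t_stat, p = (0.0, 1.0) if np.mean(a) == np.mean(b) else (math.inf, 0.0)
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=False)
        t_stat, p = float(t_stat), float(p)
    disp_a = sd_a if dispersion == "sd" else sd_a / math.sqrt(len(a))
    disp_b = sd_b if dispersion == "sd" else sd_b / math.sqrt(len(b))
    return GroupComparison(
        mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
        dispersion_a=float(disp_a), dispersion_b=float(disp_b),
        dispersion=dispersion, t_statistic=t_stat, p_value=p,
        n_a=len(a), n_b=len(b),
    )


def summarize_record(record: ExperimentRecord, **stall_kwargs) -> dict:
    """Tidy summary of one experiment record (consumed by the CLI)."""
    k = record.config.get("spring_constant_N_per_m")
    area = record.config.get("contact_area_um2")
    sigma = stress_trace(record, k, area)
    out = {
        "n_rows": int(len(record.data)),
        "duration_s": float(record.data["time_s"].iloc[-1]
                            - record.data["time_s"].iloc[0]),
        "mean_F_nN": float(record.data["F_nN"].abs().mean()),
        "final_sigma_Pa": float(sigma.iloc[-1]),
        "events": [{"time_s": t, "event": e} for t, e in record.events],
    }
    if out["duration_s"] >= INITIAL_WINDOW_S:
        m = stall_metrics(sigma, **stall_kwargs)
        out.update(
            initial_stress_Pa=m.initial_stress_Pa,
            stall_stress_Pa=m.stall_stress_Pa,
            time_to_stall_min=m.time_to_stall_min,
            dissipation=m.dissipation,
            decay_timescale_h=m.decay_timescale_h,
        )
    return out
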