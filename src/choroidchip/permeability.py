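"""Barrier-permeability kinetics from fluorescence filling curves.

When a fluorescent tracer is perfused through the endothelial channel, each
chip channel (MVEC, stromal, RPE) fills with a sigmoidal intensity-vs-time
curve. The barrier readout is relative: after min/max normalization of each
channel's mean-ROI trace, a sigmoid is fitted to find the time at which half
of the plateau intensity is reached (an EC50 read as a *time*, t50), and the
lag between two channels' t50 values measures how tight the barrier between
them is — a positive lag means the target channel fills later, i.e. a
tighter barrier. No absolute permeability coefficient is computed; the chip
geometry is not designed for that.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "KineticTrace",
    "FitResult",
    "RelativePermeability",
    "extract_roi_trace",
    "normalize_trace",
    "fit_t50",
    "relative_permeability",
    "read_traces_csv",
    "write_traces_csv",
]

#: Slack allowed on normalized values (noise may under/overshoot [0, 1]).
NORMALIZED_EPS = 0.5


@dataclass
class KineticTrace:
    """A time-stamped intensity series for one chip channel."""

    times_s: np.ndarray
    values: np.ndarray
    channel_id: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times_s.shape != self.values.shape or self.times_s.ndim != 1:
            raise ValueError("times and values must be matching 1D arrays")
        if len(self.times_s) >= 2 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass
class FitResult:
    """Outcome of the sigmoid fit; ``t50_s`` is valid only when converged."""

    t50_s: float
    slope: float
    fit_quality: float  # root-mean-square residual
    converged: bool
    channel_id: str = ""


@dataclass
class RelativePermeability:
    """Lag between two channels' half-filling times, in seconds."""

    lag_s: float
    source_channel: str = ""
    target_channel: str = ""
    molecule_label: str = ""


def extract_roi_trace(
    image_series: np.ndarray,
    times_s: np.ndarray,
    roi_center_xy: tuple[float, float],
    roi_radius_px: float,
    channel_id: str = "",
) -> KineticTrace:
    """Mean intensity over a circular ROI for every frame.

    ``image_series`` has shape (t, y, x); the first frame is typically the
    pre-perfusion reference whose level defines the background floor that
    min/max normalization later removes. A pixel belongs to the ROI when its
    center lies within ``roi_radius_px`` of the ROI center.
    """
    series = np.asarray(image_series)
    if series.ndim != 3:
        raise ValueError("image series must be (t, y, x)")
    ny, nx = series.shape[1:]
    cx, cy = roi_center_xy
    r = float(roi_radius_px)
    if not (r <= cx <= nx - 1 - r and r <= cy <= ny - 1 - r):
        raise ValueError(
            f"ROI center {roi_center_xy} radius {r} extends outside the "
            f"{nx}x{ny} image"
        )
    yy, xx = np.mgrid[0:ny, 0:nx]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    values = series[:, mask].mean(axis=1)
    return KineticTrace(times_s=times_s, values=values, channel_id=channel_id)


def normalize_trace(trace: KineticTrace) -> KineticTrace:
    """Min/max normalization: minimum (background) -> 0, maximum -> 1."""
    vmin = float(trace.values.min())
    vmax = float(trace.values.max())
    if vmax <= vmin:
        raise ValueError(f"flat trace (min = max = {vmin}): no signal to normalize")
    return KineticTrace(
        times_s=trace.times_s.copy(),
        values=(trace.values - vmin) / (vmax - vmin),
        channel_id=trace.channel_id,
        normalized=True,
    )


def _sigmoid_fixed(t, t50, h):
    t = np.asarray(t, dtype=np.float64)
    out = np.zeros_like(t)
    pos = t > 0
    with np.errstate(over="ignore"):
        out[pos] = 1.0 / (1.0 + (t50 / t[pos]) ** h)
    return out


def _sigmoid_free(t, t50, h, floor, ceil):
    return floor + (ceil - floor) * _sigmoid_fixed(t, t50, h)


def _initial_t50(times, values):
    """First upward crossing of 0.5, by linear interpolation."""
    above = np.nonzero(values >= 0.5)[0]
    if len(above) == 0 or above[0] == 0:
        return float(times[len(times) // 2])
    i = above[0]
    t0, t1 = times[i - 1], times[i]
    v0, v1 = values[i - 1], values[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (0.5 - v0) * (t1 - t0) / (v1 - v0))


def fit_t50(trace: KineticTrace, free_asymptotes: bool = False) -> FitResult:
    """Fit ``response(t) = 1 / (1 + (t50/t)^h)`` to a normalized trace.

    The floor and ceiling are fixed at 0 and 1 (the data are normalized);
    ``free_asymptotes`` switches to the 4-parameter variant. The fit is
    ordinary least squares; t50 starts at the first 0.5 crossing and the
    slope at 1. A fit is reported as converged only when the optimizer
    succeeded and the fitted t50 lies within the sampled time range.
    """
    if not trace.normalized:
        raise ValueError("fit_t50 expects a normalized trace; call normalize_trace first")
    if len(trace) < 8:
        raise ValueError(f"need >= 8 samples to fit, got {len(trace)}")
    if trace.values.min() < -NORMALIZED_EPS or trace.values.max() > 1 + NORMALIZED_EPS:
        raise ValueError("normalized trace values far outside [0, 1]")
    times, values = trace.times_s, trace.values
    t_lo = max(times[0], 1e-9)
    p0_t50 = min(max(_initial_t50(times, values), t_lo), times[-1])
    try:
        if free_asymptotes:
            popt, _ = curve_fit(
                _sigmoid_free,
                times,
                values,
                p0=(p0_t50, 1.0, 0.0, 1.0),
                bounds=((t_lo, 1e-3, -1.0, 0.0), (np.inf, 100.0, 1.0, 2.0)),
                maxfev=20000,
            )
            t50, h = float(popt[0]), float(popt[1])
            resid = values - _sigmoid_free(times, *popt)
        else:
            popt, _ = curve_fit(
                _sigmoid_fixed,
                times,
                values,
                p0=(p0_t50, 1.0),
                bounds=((t_lo, 1e-3), (np.inf, 100.0)),
                maxfev=20000,
            )
            t50, h = float(popt[0]), float(popt[1])
            resid = values - _sigmoid_fixed(times, *popt)
    except (RuntimeError, ValueError):
        return FitResult(
            t50_s=float("nan"), slope=float("nan"), fit_quality=float("inf"),
            converged=False, channel_id=trace.channel_id,
        )
    rms = float(np.sqrt(np.mean(resid**2)))
    converged = bool(times[0] <= t50 <= times[-1])
    return FitResult(
        t50_s=t50 if converged else float("nan"),
        slope=h,
        fit_quality=rms,
        converged=converged,
        channel_id=trace.channel_id,
    )


def relative_permeability(
    fit_source: FitResult, fit_target: FitResult, molecule_label: str = ""
) -> RelativePermeability:
    """Lag time = t50(target) − t50(source); positive = tighter barrier."""
    if not (fit_source.converged and fit_target.converged):
        bad = [f.channel_id or "?" for f in (fit_source, fit_target) if not f.converged]
        raise ValueError(f"unconverged fit(s) for channel(s): {', '.join(bad)}")
    return RelativePermeability(
        lag_s=fit_target.t50_s - fit_source.t50_s,
        source_channel=fit_source.channel_id,
        target_channel=fit_target.channel_id,
        molecule_label=molecule_label,
    )


# ---- CSV I/O -----------------------------------------------------------


def write_traces_csv(traces: list[KineticTrace], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "value", "channel"])
        for tr in traces:
            for t, v in zip(tr.times_s, tr.values):
                w.writerow([f"{t:.6g}", f"{v:.9g}", tr.channel_id])


def read_traces_csv(path) -> dict[str, KineticTrace]:
    """Read long-format trace CSV (columns: time_s, value, channel)."""
    data: dict[str, list[tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            data.setdefault(row["channel"], []).append(
                (float(row["time_s"]), float(row["value"]))
            )
    out = {}
    for channel, rows in data.items():
        rows.sort(key=lambda r: r[0])
        times = np.array([r[0] for r in rows])
        values = np.array([r[1] for r in rows])
        out[channel] = KineticTrace(times_s=times, values=values, channel_id=channel)
    return out
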