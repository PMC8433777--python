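"""Chromatogram container, baseline correction, integration and peak detection.

Traces are stored on their native (possibly non-uniform) time grid; every
operation works directly on that grid.  Integration is trapezoidal with
linear interpolation of the signal at window edges, which makes it exact for
piecewise-linear traces and exactly additive over adjacent windows.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import BoundsError, DomainError, NoPeakError

__all__ = [
    "Chromatogram",
    "Peak",
    "baseline_correct",
    "integrate",
    "detect_main_peak",
    "read_chromatogram_csv",
    "write_chromatogram_csv",
]


@dataclass
class Chromatogram:
    """A detector trace: strictly increasing times (min) vs. response (RI units).

    ``meta`` carries run metadata (flow rate, injection volume, dilution
    factor, sample label); a dilution factor below 1 is rejected.
    """

    time: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.signal.shape:
            raise DomainError("time and signal must be 1-D arrays of equal length")
        if self.time.size < 2:
            raise DomainError("a chromatogram needs at least two samples")
        if not np.all(np.diff(self.time) > 0):
            raise DomainError("time must be strictly increasing")
        dil = self.meta.get("dilution_factor")
        if dil is not None and dil < 1:
            raise DomainError("dilution factor must be >= 1")

    @property
    def t_min(self) -> float:
        return float(self.time[0])

    @property
    def t_max(self) -> float:
        return float(self.time[-1])

    def signal_at(self, t):
        """Signal linearly interpolated at arbitrary times inside the trace."""
        return np.interp(t, self.time, self.signal)


@dataclass(frozen=True)
class Peak:
    """One detected peak: bounds and apex (min), area (signal·min), height."""

    t_start: float
    t_apex: float
    t_end: float
    area: float
    height: float

    def __post_init__(self) -> None:
        if not (self.t_start < self.t_apex < self.t_end):
            raise DomainError("peak bounds must bracket the apex")


def _check_window(chrom: Chromatogram, t_a: float, t_b: float) -> None:
    if t_a >= t_b:
        raise BoundsError(f"empty or reversed window [{t_a}, {t_b}]")
    if t_a < chrom.t_min - 1e-12 or t_b > chrom.t_max + 1e-12:
        raise BoundsError(
            f"window [{t_a}, {t_b}] outside trace [{chrom.t_min}, {chrom.t_max}]"
        )


def baseline_correct(
    chrom: Chromatogram,
    window: tuple[float, float],
    endpoint_avg_min: float = 0.0,
) -> Chromatogram:
    """Subtract the straight line joining the signal at the window endpoints.

    The whole trace is corrected; with the default point anchors the signal
    becomes exactly zero at both window endpoints, and the operation is
    idempotent for a fixed window.

    On noisy traces a single-sample anchor tilts the baseline by the noise at
    the two endpoints; ``endpoint_avg_min`` > 0 instead anchors the line at
    the mean signal over that many minutes just inside each endpoint, which
    suppresses the anchor noise by the square root of the samples averaged.
    """
    t_a, t_b = window
    _check_window(chrom, t_a, t_b)
    if endpoint_avg_min > 0:
        e = min(endpoint_avg_min, (t_b - t_a) / 4)
        mask_a = (chrom.time >= t_a) & (chrom.time <= t_a + e)
        mask_b = (chrom.time >= t_b - e) & (chrom.time <= t_b)
        x_a, y_a = chrom.time[mask_a].mean(), chrom.signal[mask_a].mean()
        x_b, y_b = chrom.time[mask_b].mean(), chrom.signal[mask_b].mean()
    else:
        x_a, y_a = t_a, chrom.signal_at(t_a)
        x_b, y_b = t_b, chrom.signal_at(t_b)
    slope = (y_b - y_a) / (x_b - x_a)
    baseline = y_a + slope * (chrom.time - x_a)
    return replace(chrom, signal=chrom.signal - baseline, meta=dict(chrom.meta))


def cumulative_area(chrom: Chromatogram, t):
    """Running trapezoidal integral of the signal from the trace start to ``t``.

    ``t`` may be a scalar or array anywhere inside the trace; values at
    arbitrary positions use the linearly interpolated signal, so
    ``cumulative_area(b) - cumulative_area(a)`` is the exact trapezoid area of
    the piecewise-linear trace over [a, b].
    """
    t = np.asarray(t, dtype=float)
    time, sig = chrom.time, chrom.signal
    # cumulative integral at the native sample points
    seg = 0.5 * (sig[1:] + sig[:-1]) * np.diff(time)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    idx = np.clip(np.searchsorted(time, t, side="right") - 1, 0, time.size - 2)
    t_k = time[idx]
    s_k = sig[idx]
    s_t = chrom.signal_at(t)
    return cum[idx] + 0.5 * (s_k + s_t) * (t - t_k)


def integrate(chrom: Chromatogram, t_a: float, t_b: float) -> float:
    """Trapezoidal area (signal·min) over [t_a, t_b].

    Window edges are linearly interpolated between samples; areas are additive
    over adjacent windows.
    """
    _check_window(chrom, t_a, t_b)
    f = cumulative_area(chrom, np.array([t_a, t_b]))
    return float(f[1] - f[0])


def _threshold_crossing(time, signal, i_apex, thr, direction):
    """Time of the nearest crossing of ``thr`` walking from the apex outwards."""
    n = time.size
    i = i_apex
    while True:
        j = i + direction
        if j < 0 or j >= n:
            return float(time[i] if 0 <= i < n else time[0 if direction < 0 else -1])
        if signal[j] <= thr:
            # linear interpolation between samples i (above) and j (at/below)
            if signal[i] == signal[j]:
                return float(time[j])
            frac = (signal[i] - thr) / (signal[i] - signal[j])
            return float(time[i] + frac * (time[j] - time[i]))
        i = j


def detect_main_peak(
    chrom: Chromatogram, threshold_frac: float = 0.005, smooth_min: float = 0.0
) -> Peak:
    """Locate the tallest peak of a baseline-corrected trace.

    The apex is the global maximum; the bounds are the nearest times on either
    side where the signal falls to ``threshold_frac`` of the apex height
    (linearly interpolated), or the trace ends if it never does.

    With ``smooth_min`` > 0 the apex and bounds are located on a boxcar-
    smoothed copy of the trace (window of that many minutes), which keeps
    single noisy baseline samples from triggering the threshold crossing
    early; the reported height and area always come from the raw trace.
    """
    if not 0 < threshold_frac < 1:
        raise DomainError("threshold_frac must lie in (0, 1)")
    loc = chrom.signal
    if smooth_min > 0:
        dt = float(np.median(np.diff(chrom.time)))
        w = max(1, int(round(smooth_min / dt)) | 1)
        loc = np.convolve(chrom.signal, np.ones(w) / w, mode="same")
    i_apex = int(np.argmax(loc))
    height = float(chrom.signal[i_apex])
    if loc[i_apex] <= 0 or height <= 0:
        raise NoPeakError("trace has no positive signal")
    thr = threshold_frac * float(loc[i_apex])
    t_start = _threshold_crossing(chrom.time, loc, i_apex, thr, -1)
    t_end = _threshold_crossing(chrom.time, loc, i_apex, thr, +1)
    area = integrate(chrom, t_start, t_end)
    if area <= 0:
        raise NoPeakError("detected window carries no positive area")
    return Peak(
        t_start=t_start,
        t_apex=float(chrom.time[i_apex]),
        t_end=t_end,
        area=area,
        height=height,
    )


# ---------------------------------------------------------------------------
# CSV dialect: header `time_min,signal`, metadata as leading `# key: value`
# comment lines.

_META_NUMERIC = {"flow_ml_min", "injection_volume_ul", "dilution_factor"}


def read_chromatogram_csv(path) -> Chromatogram:
    text = Path(path).read_text()
    meta: dict = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            key = key.strip()
            value = value.strip()
            meta[key] = float(value) if key in _META_NUMERIC else value
        elif line.strip():
            body_lines.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body_lines)))
    if not {"time_min", "signal"} <= set(df.columns):
        raise DomainError("chromatogram CSV must have columns time_min,signal")
    return Chromatogram(df["time_min"].to_numpy(), df["signal"].to_numpy(), meta)


def write_chromatogram_csv(chrom: Chromatogram, path) -> None:
    lines = [f"# {k}: {v}" for k, v in chrom.meta.items()]
    lines.append("time_min,signal")
    lines.extend(f"{t:.6g},{s:.10g}" for t, s in zip(chrom.time, chrom.signal))
    Path(path).write_text("\n".join(lines) + "\n")
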