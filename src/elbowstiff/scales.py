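"""Repetition segmentation, normalized movement patterns and functional scales.

A trial consists of repeated flexion+extension cycles paced by a metronome;
each cycle spans two beats (one flexion, one extension), i.e. ``2*60/tempo``
seconds.  Segments are overlaid on a common 0--100 % phase grid to produce
mean ± std movement patterns, and the area under the stiffness signal within
each cycle is the per-repetition summary statistic.

Across conditions the summary follows two empirical "functional scales":

* tempo sweep:  ``Stiffness(tempo) = a * tempo**b``   (power law),
* load sweep:   ``Stiffness(weight) = a * exp(b * weight)``  (exponential),

both fitted by nonlinear least squares with analytic log/semilog
initializers, which makes the fits exact on noiseless model data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .errors import DataError, ParameterError

__all__ = [
    "NormalizedPattern",
    "ScaleFit",
    "segment_repetitions",
    "normalize_overlay",
    "stiffness_area",
    "fit_power_scale",
    "fit_exp_scale",
    "plot_pattern",
]

PHASE_POINTS = 101


@dataclass
class NormalizedPattern:
    """Pointwise mean ± std of time-normalized repetition segments."""

    phase: np.ndarray   # 0..100 %
    mean: np.ndarray
    std: np.ndarray
    n_repetitions: int


@dataclass(frozen=True)
class ScaleFit:
    """Fitted functional scale ``a * x**b`` (power) or ``a * exp(b*x)`` (exponential)."""

    form: str   # "power" | "exponential"
    a: float
    b: float
    rss: float

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.form == "power":
            return self.a * x**self.b
        return self.a * np.exp(self.b * x)


def segment_repetitions(time, values, tempo: float, method: str = "metronome",
                        ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a trace into one-cycle (flexion+extension) segments.

    ``metronome`` slices at integer multiples of the cycle period
    ``2*60/tempo`` s; ``onset`` detects cycle starts from the angle signal
    (threshold up-crossing backtracked to the preceding local minimum).
    """
    if tempo <= 0:
        raise ParameterError("tempo must be > 0 bpm")
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    period = 2.0 * 60.0 / tempo
    duration = time[-1] - time[0]
    if duration < period:
        raise DataError(f"trace ({duration:.2f}s) shorter than one cycle ({period:.2f}s)")

    if method == "metronome":
        n_cycles = int(np.floor(duration / period + 1e-9))
        bounds = time[0] + period * np.arange(n_cycles + 1)
        idx = np.searchsorted(time, bounds - 1e-12)
    elif method == "onset":
        idx = _onset_boundaries(time, values, period)
    else:
        raise ParameterError(f"unknown segmentation method {method!r}")

    segments = []
    for k in range(len(idx) - 1):
        lo, hi = idx[k], min(idx[k + 1] + 1, len(time))
        if hi - lo >= 2:
            segments.append((time[lo:hi], values[lo:hi]))
    return segments


def _onset_boundaries(time, values, period: float) -> np.ndarray:
    """Cycle boundaries from threshold up-crossings of the signal.

    Each sufficiently separated up-crossing of a 30 %-of-range threshold is
    backtracked along the strictly rising flank to the sample where the rise
    starts.  On a signal that rests at baseline between movements this
    recovers the true onset sample; on signals with passive drift between
    movements (the forward model rebounds toward its passive equilibrium
    after each extension) the boundary lands at the preceding local minimum
    instead, and the threshold sits above the rebound level.
    """
    vmin, vmax = float(np.min(values)), float(np.max(values))
    thr = vmin + 0.30 * (vmax - vmin)
    atol = 1e-9 * (vmax - vmin)
    above = values >= thr
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    dt = float(np.median(np.diff(time)))
    min_gap = max(1, int(0.5 * period / dt))
    starts: list[int] = []
    last = -min_gap
    for c in crossings:
        if c - last < min_gap:
            continue
        onset = int(c)
        while onset > 0 and values[onset - 1] < values[onset] - atol:
            onset -= 1
        starts.append(onset)
        last = c
    if not starts:
        raise DataError("no movement onsets detected")
    n_after_last = int(round(period / dt))
    starts.append(min(len(time) - 1, starts[-1] + n_after_last))
    return np.asarray(starts)


def normalize_overlay(segments, n_points: int = PHASE_POINTS) -> NormalizedPattern:
    """Resample each segment to the phase grid and take pointwise mean/std."""
    if len(segments) == 0:
        raise DataError("need at least one segment")
    grid = np.linspace(0.0, 100.0, n_points)
    resampled = []
    for t, v in segments:
        phase = 100.0 * (t - t[0]) / (t[-1] - t[0])
        resampled.append(np.interp(grid, phase, v))
    stack = np.vstack(resampled)
    return NormalizedPattern(phase=grid, mean=stack.mean(axis=0),
                             std=stack.std(axis=0), n_repetitions=len(segments))


def stiffness_area(time, stiffness) -> float:
    """Area under the stiffness signal over a segment [N·m·s/rad]."""
    time = np.asarray(time, dtype=float)
    stiffness = np.asarray(stiffness, dtype=float)
    if time.size == 0:
        raise DataError("empty segment")
    return float(np.trapezoid(stiffness, time))


def plot_pattern(pattern: NormalizedPattern, ax=None, *, label: str | None = None,
                 ylabel: str = ""):
    """Mean ± std movement pattern over the 0--100 % phase grid.

    Returns the matplotlib axes; writes nothing to disk.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(pattern.phase, pattern.mean - pattern.std,
                    pattern.mean + pattern.std, alpha=0.3)
    ax.plot(pattern.phase, pattern.mean, lw=2, label=label)
    ax.set_xlabel("movement phase [%]")
    if ylabel:
        ax.set_ylabel(ylabel)
    if label:
        ax.legend()
    return ax


def _fit(x, values, model, p0, form: str) -> ScaleFit:
    with warnings.catch_warnings():
        # two-point fits are exact; their singular covariance is irrelevant
        warnings.simplefilter("ignore", OptimizeWarning)
        popt, _ = curve_fit(model, x, values, p0=p0, maxfev=20000)
    rss = float(np.sum((values - model(x, *popt)) ** 2))
    return ScaleFit(form=form, a=float(popt[0]), b=float(popt[1]), rss=rss)


def fit_power_scale(tempos, values) -> ScaleFit:
    """Least-squares fit of ``a * tempo**b`` (log-log linear initializer)."""
    tempos = np.asarray(tempos, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(np.unique(tempos)) < 2:
        raise DataError("need at least two distinct tempos")
    if np.any(tempos <= 0) or np.any(values <= 0):
        raise DataError("power-scale fit requires positive tempos and values")
    b0, loga0 = np.polyfit(np.log(tempos), np.log(values), 1)
    return _fit(tempos, values, lambda t, a, b: a * t**b, (np.exp(loga0), b0), "power")


def fit_exp_scale(weights, values) -> ScaleFit:
    """Least-squares fit of ``a * exp(b * weight)`` (semilog initializer)."""
    weights = np.asarray(weights, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(np.unique(weights)) < 2:
        raise DataError("need at least two distinct weights")
    if np.any(values <= 0):
        raise DataError("exponential-scale fit requires positive values")
    b0, loga0 = np.polyfit(weights, np.log(values), 1)
    return _fit(weights, values, lambda w, a, b: a * np.exp(b * w),
                (np.exp(loga0), b0), "exponential")
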