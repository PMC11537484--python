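"""Response quantifications: sinusoid-fit error, adaptation gain ratio,
time-to-peak, stimulus-response trajectory loop area, variance explained,
and stimulus/residual power spectra."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .cascade import Trace

__all__ = [
    "SinusoidFit",
    "best_fit_sinusoid",
    "gain_ratio",
    "time_to_peak",
    "loop_area",
    "variance_explained",
    "residual_spectra",
]


@dataclass(frozen=True)
class SinusoidFit:
    """Least-squares sinusoid at a known frequency: amplitude, phase (rad),
    offset, and the residual MSE normalized by the trace variance."""

    frequency: float
    amplitude: float
    phase: float
    offset: float
    mse: float


def best_fit_sinusoid(trace: Trace, freq: float) -> SinusoidFit:
    """Fit ``offset + amplitude*sin(2*pi*freq*t + phase)`` by linear least
    squares on a sin/cos/constant basis.

    The returned ``mse`` is the mean squared residual divided by the trace
    variance, so it is independent of response contrast and units.  Requires
    at least two full periods.
    """
    y = np.asarray(trace.values, dtype=float)
    t = trace.times
    if trace.duration < 2.0 / freq:
        raise ValueError(
            f"trace ({trace.duration:.3g} s) must span >= 2 periods of {freq} Hz"
        )
    w = 2.0 * np.pi * freq * t
    A = np.column_stack([np.sin(w), np.cos(w), np.ones_like(w)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    a, b, c = coef
    resid = y - A @ coef
    var = np.var(y)
    if var == 0:
        mse = 0.0
    else:
        mse = float(np.mean(resid ** 2) / var)
    return SinusoidFit(
        frequency=freq,
        amplitude=float(np.hypot(a, b)),
        phase=float(np.arctan2(b, a)),
        offset=float(c),
        mse=mse,
    )


def _window_amplitude(values: np.ndarray, dt: float, t0: float, window: float,
                      baseline_window: float) -> float:
    i0 = int(round(t0 / dt))
    i1 = int(round((t0 + window) / dt))
    ib = int(round((t0 - baseline_window) / dt))
    if ib < 0 or i1 > len(values):
        raise ValueError("analysis window extends outside the trace")
    baseline = float(np.mean(values[ib:i0])) if i0 > ib else float(values[i0])
    seg = values[i0:i1] - baseline
    return float(np.max(np.abs(seg)))


def gain_ratio(response: Trace, flash_time_pre: float, flash_time_during: float,
               window: float, baseline_window: float = 0.1) -> float:
    """Adaptation index: flash-response amplitude during a light step divided
    by the amplitude before the step.

    Amplitudes are baseline-subtracted peak absolute deviations within
    ``window`` seconds of each flash time; the baseline is the mean over
    ``baseline_window`` seconds immediately preceding each flash.  A ratio
    of 1 means no adaptation.
    """
    if flash_time_pre + window > flash_time_during:
        raise ValueError("flash analysis windows overlap")
    v = np.asarray(response.values, dtype=float)
    a_pre = _window_amplitude(v, response.dt, flash_time_pre, window, baseline_window)
    a_during = _window_amplitude(v, response.dt, flash_time_during, window, baseline_window)
    if a_pre == 0:
        raise ValueError("pre-step flash amplitude is zero; gain ratio undefined")
    return a_during / a_pre


def _refine_peak(values: np.ndarray, idx: int) -> float:
    """Sub-sample extremum location by quadratic interpolation around idx."""
    if idx <= 0 or idx >= len(values) - 1:
        return float(idx)
    y0, y1, y2 = values[idx - 1], values[idx], values[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(idx)
    return idx + 0.5 * (y0 - y2) / denom


def time_to_peak(response: Trace, onset: float = 0.0,
                 baseline_window: float = 0.1) -> float:
    """Time (s) from ``onset`` to the extremum of the response, with
    quadratic sub-sample refinement.

    The baseline is estimated from the ``baseline_window`` seconds preceding
    onset (or the first sample if the onset is at the trace start).  Raises
    if the post-onset trace is monotone (no interior extremum).
    """
    v = np.asarray(response.values, dtype=float)
    dt = response.dt
    i_on = int(round(onset / dt))
    if not (0 <= i_on < len(v) - 2):
        raise ValueError("onset outside trace")
    ib = max(0, i_on - int(round(baseline_window / dt)))
    baseline = float(np.mean(v[ib:i_on])) if i_on > ib else float(v[i_on])
    dev = v[i_on:] - baseline
    idx = int(np.argmax(np.abs(dev)))
    if idx == 0 or idx == len(dev) - 1:
        raise ValueError("no interior extremum after onset (monotone response?)")
    return _refine_peak(dev, idx) * dt


def loop_area(stimulus_cycle: Trace, response_cycle: Trace) -> float:
    """Area enclosed by the (stimulus, response) trajectory over one period.

    Both axes are normalized to unit peak-to-peak range so the area is
    dimensionless and contrast-independent; the magnitude of the shoelace
    area of the closed polygon is returned.  Zero means the response is a
    static function of the stimulus (the trajectory retraces itself).
    """
    x = np.asarray(stimulus_cycle.values, dtype=float)
    y = np.asarray(response_cycle.values, dtype=float)
    if len(x) != len(y):
        raise ValueError("stimulus and response cycles must have equal length")
    rx = np.ptp(x)
    ry = np.ptp(y)
    if rx == 0 or ry == 0:
        raise ValueError("degenerate (zero peak-to-peak) axis in loop_area")
    x = x / rx
    y = y / ry
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return float(abs(area))


def variance_explained(measured: Trace | np.ndarray, predicted: Trace | np.ndarray) -> float:
    """Fraction of variance explained, 1 - SSE/SST (alias of the fitting
    module's goodness-of-fit; kept here for estimation accuracy reports)."""
    from .fitting import fraction_variance
    return fraction_variance(measured, predicted)


def residual_spectra(stimulus: Trace, estimate: Trace,
                     nperseg: int | None = None,
                     threshold: float = 0.5, sustain_bins: int = 3):
    """Welch power spectra of a stimulus and of the residual
    (stimulus - estimate), plus the frequency where they converge.

    Returns ``(freqs, stim_power, resid_power, convergence_freq)``.  The
    convergence frequency is the lowest frequency at which the residual
    power is at least ``threshold`` of the stimulus power for
    ``sustain_bins`` consecutive bins (None if never reached): below it the
    estimate tracks the stimulus, above it estimation has failed.
    """
    s = np.asarray(stimulus.values, dtype=float)
    e = np.asarray(estimate.values, dtype=float)
    if len(s) != len(e):
        raise ValueError("stimulus and estimate must have equal length")
    fs = 1.0 / stimulus.dt
    if nperseg is None:
        nperseg = min(len(s), max(256, len(s) // 8))
    freqs, p_stim = signal.welch(s - np.mean(s), fs=fs, nperseg=nperseg)
    _, p_resid = signal.welch((s - e) - np.mean(s - e), fs=fs, nperseg=nperseg)
    conv = None
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p_stim > 0, p_resid / p_stim, np.inf)
    above = ratio >= threshold
    # skip the DC bin
    for i in range(1, len(above) - sustain_bins + 1):
        if np.all(above[i:i + sustain_bins]):
            conv = float(freqs[i])
            break
    return freqs, p_stim, p_resid, conv
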