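"""Small-signal linear filter model of the photocurrent.

At a fixed mean light level the cascade responds linearly to low-contrast
modulations, and the impulse response is well described by the parametric
filter

    L(t) = alpha * (t/tau_R)^3 / (1 + (t/tau_R)^3) * exp(-t/tau_D)

where the cubed sigmoid sets the rise (rising time constant ``tau_R``) and
the exponential sets the decay (damping time constant ``tau_D``).  The filter is fit to the full model's response to low-contrast
Gaussian noise about the mean; convolving it with the stimulus deviation
gives the "linear target" responses used by the light-adaptation clamp —
how the photoreceptor would respond if it did not adapt.

Sign convention: increments in light reduce the current magnitude, so the
linear response is baseline - (L * dStim) * dt with alpha > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.signal import fftconvolve

from .cascade import (
    CascadeParams,
    DarkOperatingPoint,
    Trace,
    default_dt,
    flash_response,
    simulate_current,
    steady_state,
)

__all__ = ["LinearFilterParams", "eval_filter", "filter_kernel",
           "fit_linear_model", "linear_response"]


@dataclass(frozen=True)
class LinearFilterParams:
    """Fitted filter parameters, tagged with the adapting mean they were fit
    at.  ``alpha`` maps R*/s to pA (times seconds, via the convolution);
    time constants in seconds."""

    alpha: float
    tau_R: float
    tau_D: float
    mean_level: float
    cell_type: str = "primate_cone"

    def __post_init__(self):
        if self.tau_R <= 0 or self.tau_D <= 0:
            raise ValueError("time constants must be positive")

    def scaled(self, scale: float) -> "LinearFilterParams":
        """Filter with both time constants multiplied by ``scale`` (used to
        slow or speed target response kinetics)."""
        if scale <= 0:
            raise ValueError("scale must be positive")
        return replace(self, tau_R=self.tau_R * scale, tau_D=self.tau_D * scale)


def eval_filter(lfp: LinearFilterParams, t: np.ndarray | float) -> np.ndarray | float:
    """Evaluate L(t); zero at t=0 and decaying to zero at large t."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("filter is causal; t must be nonnegative")
    x = (t_arr / lfp.tau_R) ** 3
    out = lfp.alpha * x / (1.0 + x) * np.exp(-t_arr / lfp.tau_D)
    return out if np.ndim(t) else float(out)


def _kernel_duration(lfp: LinearFilterParams) -> float:
    # tail decays as exp(-t/tau_R); 12 time constants is far below tolerance
    return 12.0 * max(lfp.tau_R, lfp.tau_D)


def filter_kernel(lfp: LinearFilterParams, dt: float,
                  duration: float | None = None) -> np.ndarray:
    if duration is None:
        duration = _kernel_duration(lfp)
    t = np.arange(int(round(duration / dt))) * dt
    return np.asarray(eval_filter(lfp, t))


def linear_response(lfp: LinearFilterParams, stimulus: Trace,
                    baseline_current: float) -> Trace:
    """Convolve the filter with the stimulus deviation from the mean level.

    Output = baseline - (L * (Stim - mean)) * dt, so light increments reduce
    the current magnitude.  A constant stimulus at the mean returns the
    baseline; a sinusoid returns a (phase-shifted) sinusoid.
    """
    dev = np.asarray(stimulus.values, dtype=float) - lfp.mean_level
    kern = filter_kernel(lfp, stimulus.dt)
    resp = fftconvolve(dev, kern)[: len(dev)] * stimulus.dt
    return Trace(stimulus.dt, baseline_current - resp, "pA")


def _noise_stimulus(mean_level: float, contrast: float, duration: float,
                    dt: float, seed: int, pad: float) -> tuple[np.ndarray, int]:
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    n_pad = int(round(pad / dt))
    noise = rng.normal(mean_level, contrast * mean_level, n)
    stim = np.concatenate([np.full(n_pad, mean_level), noise])
    np.clip(stim, 0.0, None, out=stim)
    return stim, n_pad


def fit_linear_model(params: CascadeParams, dark: DarkOperatingPoint,
                     mean_level: float, contrast: float = 0.05,
                     duration: float | None = None, seed: int = 2024,
                     *, dt: float | None = None) -> LinearFilterParams:
    """Fit the parametric filter to the full model's low-contrast response.

    Simulates the cascade driven by Gaussian noise (SD = contrast * mean)
    about ``mean_level`` and least-squares fits the convolution of L with
    the stimulus deviation to the baseline-subtracted current.  ``alpha`` is
    profiled out analytically each iteration; tau_R and tau_D are optimized
    in log space by Nelder-Mead started from the model's dim-flash
    time-to-peak.
    """
    if not (0 < contrast <= 0.2):
        raise ValueError("contrast must be in (0, 0.2] (low-contrast regime)")
    if mean_level <= 0:
        raise ValueError("mean_level must be positive")
    if dt is None:
        dt = default_dt(params.cell_type)
    if duration is None:
        duration = 30.0 if "cone" in params.cell_type else 60.0

    ss = steady_state(params, dark, mean_level)
    pad = 0.5 if "cone" in params.cell_type else 2.0
    stim, n_pad = _noise_stimulus(mean_level, contrast, duration, dt, seed, pad)
    current = simulate_current(params, dark, Trace(dt, stim, "R*/s"), initial=ss)
    dev_stim = stim[n_pad:] - mean_level
    # response deviation, sign-flipped so the filter is positive-going
    target = ss[5] - current[n_pad:]

    # initial guess: time-to-peak of a dim flash at this mean
    _, ttp = flash_response(params, dark, mean_level,
                            flash_strength=0.01 * mean_level, dt=dt)
    t0 = max(ttp, 5 * dt)
    n_burn = None  # set per-eval from kernel length

    def predict(tau_r, tau_d):
        lfp = LinearFilterParams(1.0, tau_r, tau_d, mean_level, params.cell_type)
        kern = filter_kernel(lfp, dt)
        return fftconvolve(dev_stim, kern)[: len(dev_stim)] * dt, len(kern)

    def objective(logtaus):
        tau_r, tau_d = np.exp(logtaus)
        pred, nk = predict(tau_r, tau_d)
        burn = min(nk, len(pred) // 4)
        p, y = pred[burn:], target[burn:]
        pp = float(p @ p)
        if pp == 0 or not np.isfinite(pp):
            return np.inf
        alpha = float(p @ y) / pp
        resid = y - alpha * p
        return float(resid @ resid) / len(y)

    x0 = np.log([t0 / 2.0, t0 / 2.0])
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-14, "maxiter": 600})
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"linear-filter fit failed to converge: {res.message}")
    tau_r, tau_d = np.exp(res.x)
    pred, nk = predict(tau_r, tau_d)
    burn = min(nk, len(pred) // 4)
    p, y = pred[burn:], target[burn:]
    alpha = float(p @ y) / float(p @ p)
    return LinearFilterParams(alpha=alpha, tau_R=float(tau_r), tau_D=float(tau_d),
                              mean_level=mean_level, cell_type=params.cell_type)
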