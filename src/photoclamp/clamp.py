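"""Light-adaptation clamp: stimulus design by model inversion.

The clamp makes the nonlinear cascade produce a chosen target response.  A
target (typically the output of the small-signal linear model, i.e. the
response the photoreceptor would give if it did not adapt) is pushed through
the inverse model to find the stimulus that elicits it; forward simulation
of that modified stimulus then verifies the design.  Because light
intensities cannot be negative, stimuli whose mathematical estimate dips
below zero are clipped at zero and the clipped fraction reported: clipping
is the physical feasibility limit of the method (it is what bounds how much
responses can be sped up).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cascade import (
    CascadeParams,
    DarkOperatingPoint,
    Trace,
    default_dt,
    simulate,
    steady_state,
)
from .inversion import InversionSettings, invert_current
from .linear import LinearFilterParams, linear_response
from .metrics import time_to_peak

__all__ = [
    "ClampResult",
    "InfeasibleTargetError",
    "design_clamp",
    "design_step_flash_clamp",
    "design_kinetics_clamp",
    "sinusoid_stimulus",
    "step_flash_stimulus",
    "flash_stimulus",
]


class InfeasibleTargetError(ValueError):
    """The target response cannot be produced by any light stimulus (it
    would require nonpositive current, i.e. negative cGMP)."""


@dataclass
class ClampResult:
    """Outcome of a clamp design.

    ``achieved_response`` is the forward simulation of the (clipped)
    modified stimulus; when nothing was clipped it matches the target to
    inversion tolerance.  ``annotations`` carries protocol timing and
    derived quantities (flash times, time-to-peak predictions, ...).
    """

    original_stimulus: Trace
    target_response: Trace
    modified_stimulus: Trace
    achieved_response: Trace
    clipped_fraction: float
    feasible: bool
    annotations: dict = field(default_factory=dict)


def _check_target_positive(target: Trace):
    v = target.values
    if np.any(v <= 0):
        t_bad = float(np.flatnonzero(v <= 0)[0] * target.dt)
        raise InfeasibleTargetError(
            f"target current becomes nonpositive at t={t_bad:.6g} s; "
            "no light stimulus can produce it"
        )


def design_clamp(original_stimulus: Trace, params: CascadeParams,
                 dark: DarkOperatingPoint, lfp: LinearFilterParams,
                 settings: InversionSettings | None = None) -> ClampResult:
    """Core clamp: linear target from the original stimulus, inversion,
    clipping, and verification by forward simulation.

    The original stimulus is assumed to start at (and adapt around) the
    filter's mean level, which fixes the baseline current and the initial
    state of the verification simulation.
    """
    ss = steady_state(params, dark, lfp.mean_level)
    baseline = float(ss[5])
    target = linear_response(lfp, original_stimulus, baseline)
    _check_target_positive(target)
    estimate = invert_current(target, params, dark, settings)
    clipped = estimate.values < 0
    clipped_fraction = float(np.mean(clipped))
    modified = Trace(estimate.dt, np.clip(estimate.values, 0.0, None), "R*/s")
    achieved = simulate(params, dark, modified, initial=ss).I
    return ClampResult(
        original_stimulus=original_stimulus,
        target_response=target,
        modified_stimulus=modified,
        achieved_response=achieved,
        clipped_fraction=clipped_fraction,
        feasible=clipped_fraction == 0.0,
    )


# ---------------------------------------------------------------------------
# protocol builders

def sinusoid_stimulus(mean: float, contrast: float, freq: float,
                      duration: float, dt: float) -> Trace:
    """mean * (1 + contrast * sin(2 pi f t)); starts at the mean."""
    if not (0 <= contrast <= 1):
        raise ValueError("contrast must be in [0, 1] for a nonnegative sinusoid")
    t = np.arange(int(round(duration / dt))) * dt
    return Trace(dt, mean * (1.0 + contrast * np.sin(2 * np.pi * freq * t)), "R*/s")


def step_flash_stimulus(pre_level: float, step_level: float,
                        flash_strength: float, flash_times: tuple,
                        step_window: tuple, total_time: float, dt: float,
                        flash_duration: float = 0.01) -> Trace:
    """Step between two mean levels with identical superimposed flashes.

    ``flash_strength`` is in R* per flash (delivered as a rectangular
    increment of ``flash_duration`` seconds)."""
    n = int(round(total_time / dt))
    stim = np.full(n, float(pre_level))
    i_on, i_off = (int(round(t / dt)) for t in step_window)
    stim[i_on:i_off] = step_level
    n_fl = max(1, int(round(flash_duration / dt)))
    for t_f in flash_times:
        i_f = int(round(t_f / dt))
        stim[i_f:i_f + n_fl] += flash_strength / (n_fl * dt)
    return Trace(dt, stim, "R*/s")


def flash_stimulus(background: float, flash_strength: float, onset: float,
                   total_time: float, dt: float,
                   flash_duration: float = 0.01) -> Trace:
    n = int(round(total_time / dt))
    stim = np.full(n, float(background))
    i_f = int(round(onset / dt))
    n_fl = max(1, int(round(flash_duration / dt)))
    stim[i_f:i_f + n_fl] += flash_strength / (n_fl * dt)
    return Trace(dt, stim, "R*/s")


def size_step_flash_protocol(params: CascadeParams, dark: DarkOperatingPoint,
                             lfp: LinearFilterParams,
                             flash_dip: float = 0.05,
                             step_dip: float = 0.40) -> dict:
    """Choose step level and flash strength from the linear gain.

    Sizes the protocol so the linear target stays well inside the positive
    current range: the flash transiently dips the target by ``flash_dip`` of
    the baseline current and the sustained step decrement is ``step_dip`` of
    it.  With the defaults the step produces roughly a twofold gain change
    in the full model, mirroring the adaptation the clamp is meant to
    negate.  Returns ``{"pre_level", "step_level", "flash_strength"}``.
    """
    from .linear import filter_kernel

    dt = default_dt(params.cell_type)
    baseline = float(steady_state(params, dark, lfp.mean_level)[5])
    kern = filter_kernel(lfp, dt)
    flash_strength = flash_dip * baseline / float(kern.max())
    step_increment = step_dip * baseline / float(kern.sum() * dt)
    return {
        "pre_level": lfp.mean_level,
        "step_level": lfp.mean_level + step_increment,
        "flash_strength": flash_strength,
    }


def _default_step_times(cell_type: str):
    # cones settle within tens of ms; rods are ~10x slower
    if "cone" in cell_type:
        return dict(step_window=(1.0, 3.0), flash_times=(0.5, 2.0), total_time=4.0)
    return dict(step_window=(4.0, 12.0), flash_times=(2.0, 8.0), total_time=16.0)


def design_step_flash_clamp(pre_level: float, step_level: float,
                            flash_strength: float,
                            flash_times: tuple | None,
                            params: CascadeParams, dark: DarkOperatingPoint,
                            lfp: LinearFilterParams,
                            *, step_window: tuple | None = None,
                            total_time: float | None = None,
                            flash_duration: float = 0.01,
                            dt: float | None = None) -> ClampResult:
    """Clamp that negates adaptation to a change in mean light level.

    The original stimulus delivers identical flashes before and during a
    step; adaptation in the full model shrinks the during-step flash
    response.  The linear target has equal flash responses by construction,
    so the modified stimulus restores a gain ratio of 1.  The linear filter
    fit at the pre-step mean is used throughout.
    """
    if pre_level < 0 or step_level < 0:
        raise ValueError("light levels must be nonnegative")
    if dt is None:
        dt = default_dt(params.cell_type)
    defaults = _default_step_times(params.cell_type)
    step_window = step_window or defaults["step_window"]
    total_time = total_time or defaults["total_time"]
    flash_times = flash_times or defaults["flash_times"]
    original = step_flash_stimulus(pre_level, step_level, flash_strength,
                                   flash_times, step_window, total_time, dt,
                                   flash_duration)
    result = design_clamp(original, params, dark, lfp)
    result.annotations.update(
        flash_times=tuple(flash_times), step_window=tuple(step_window),
        flash_duration=flash_duration,
    )
    return result


def design_kinetics_clamp(flash_stim: Trace, scale: float,
                          params: CascadeParams, dark: DarkOperatingPoint,
                          lfp: LinearFilterParams,
                          flash_onset: float = 0.0) -> ClampResult:
    """Clamp that reshapes flash-response kinetics by a factor ``scale``.

    The target is the linear flash response with both filter time constants
    multiplied by ``scale`` (>1 slows, <1 speeds).  Speeding requires a
    stimulus decrement that cannot exceed 100% contrast, so sped designs may
    clip at zero light; the clipping report quantifies how far the achieved
    response can follow the target.  Annotations carry the time-to-peak of
    the response to the original flash, of the target, and of the achieved
    response (all measured from ``flash_onset``).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    result = design_clamp(flash_stim, params, dark,
                          lfp.scaled(scale) if scale != 1.0 else lfp)
    ss_current = float(steady_state(params, dark, lfp.mean_level)[5])
    original_response = simulate(params, dark, flash_stim,
                                 initial=steady_state(params, dark, lfp.mean_level)).I
    ttp_original = time_to_peak(original_response, onset=flash_onset)
    ttp_target = time_to_peak(result.target_response, onset=flash_onset)
    ttp_achieved = time_to_peak(result.achieved_response, onset=flash_onset)
    result.annotations.update(
        scale=scale,
        baseline_current=ss_current,
        time_to_peak_original=ttp_original,
        time_to_peak_target=ttp_target,
        time_to_peak_achieved=ttp_achieved,
        predicted_change=ttp_target - ttp_original,
        achieved_change=ttp_achieved - ttp_original,
    )
    if not result.feasible and scale < 1:
        # diagnostic: how much of the requested speeding was achieved
        if result.annotations["predicted_change"] != 0:
            result.annotations["achieved_fraction"] = (
                result.annotations["achieved_change"]
                / result.annotations["predicted_change"]
            )
    return result
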