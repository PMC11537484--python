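"""Stimulus protocol generators and synthetic recordings.

These reproduce the stimulus families used to constrain and test the
cascade model — flash families, steps with superimposed flashes, the
variable-mean noise stimulus (Gaussian noise whose mean steps periodically
over up to 30-fold), and sinusoids — plus noisy synthetic "recordings" for
parameter-recovery experiments.  All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cascade import (
    CascadeParams,
    DarkOperatingPoint,
    Trace,
    default_dt,
    simulate_current,
)

__all__ = [
    "ProtocolSpec",
    "make_variable_mean_noise",
    "make_flash_family",
    "make_synthetic_recording",
    "default_mean_levels",
]

_PROTOCOL_KINDS = ("flash_family", "step_with_flashes", "variable_mean_noise",
                   "sinusoid")


@dataclass
class ProtocolSpec:
    """A stimulus protocol: kind tag, per-kind parameters, seed, and dt."""

    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0
    dt: float = 1e-3

    def __post_init__(self):
        if self.kind not in _PROTOCOL_KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def default_mean_levels(cell_type: str, n_levels: int = 5,
                        fold_range: float = 30.0):
    """Mean intensities for the variable-mean noise stimulus: ``n_levels``
    log-spaced levels spanning ``fold_range`` (up to 30-fold), centred on
    the regimes the two receptor classes operate in."""
    top = 30000.0 if "cone" in cell_type else 75.0
    return list(np.geomspace(top / fold_range, top, n_levels))


def make_variable_mean_noise(mean_levels, segment_dur: float, contrast: float,
                             dt: float, seed: int = 0,
                             shuffle: bool = True) -> Trace:
    """Gaussian noise with periodic changes in mean intensity.

    Each segment is ``segment_dur`` seconds of Gaussian noise with
    SD = contrast * mean about its mean level, truncated at zero.  Segment
    order is shuffled (seeded) so mean changes are unpredictable.
    """
    levels = np.asarray(list(mean_levels), dtype=float)
    if np.any(levels <= 0):
        raise ValueError("mean levels must be positive")
    if not (0 <= contrast < 1):
        raise ValueError("contrast must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if shuffle:
        levels = rng.permutation(levels)
    n_seg = int(round(segment_dur / dt))
    parts = []
    for mu in levels:
        seg = rng.normal(mu, contrast * mu, n_seg) if contrast > 0 else np.full(n_seg, mu)
        parts.append(seg)
    values = np.clip(np.concatenate(parts), 0.0, None)
    values[0] = levels[0]  # start exactly at the first mean
    return Trace(dt, values, "R*/s")


def make_flash_family(base_strength: float = 3.0, n_flashes: int = 6,
                      spacing_factor: float = 2.0, background: float = 0.0,
                      dt: float = 1e-3, inter_flash: float = 3.0,
                      flash_duration: float = 0.01, pre_time: float = 0.5):
    """Family of brief flashes, each ``spacing_factor`` times brighter than
    the last (default: weakest ~3 R*, doubling).

    Returns ``(trace, annotations)`` where annotations is a list of
    ``(onset_time_s, strength_R*)`` tuples.
    """
    if n_flashes < 1:
        raise ValueError("need at least one flash")
    strengths = [base_strength * spacing_factor ** i for i in range(n_flashes)]
    n_total = int(round((pre_time + n_flashes * inter_flash) / dt))
    stim = np.full(n_total, float(background))
    n_fl = max(1, int(round(flash_duration / dt)))
    annotations = []
    for i, s in enumerate(strengths):
        t_on = pre_time + i * inter_flash
        i_on = int(round(t_on / dt))
        stim[i_on:i_on + n_fl] += s / (n_fl * dt)
        annotations.append((t_on, s))
    return Trace(dt, stim, "R*/s"), annotations


def make_synthetic_recording(protocol: ProtocolSpec, params: CascadeParams,
                             dark: DarkOperatingPoint, noise_sd: float = 0.0,
                             seed: int | None = None):
    """Simulate a noisy recording of the cascade's response to a protocol.

    Returns ``(stimulus, response)`` traces; the response is the forward
    simulation plus additive white Gaussian current noise of SD
    ``noise_sd`` pA.  The noise seed defaults to the protocol seed + 1.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    stimulus = _realize(protocol)
    current = simulate_current(params, dark, stimulus)
    if noise_sd > 0:
        rng = np.random.default_rng(protocol.seed + 1 if seed is None else seed)
        current = current + rng.normal(0.0, noise_sd, len(current))
    return stimulus, Trace(stimulus.dt, current, "pA")


def _realize(protocol: ProtocolSpec) -> Trace:
    p = dict(protocol.parameters)
    if protocol.kind == "variable_mean_noise":
        return make_variable_mean_noise(
            p.get("mean_levels", default_mean_levels("mouse_rod")),
            p.get("segment_dur", 5.0), p.get("contrast", 0.5),
            protocol.dt, protocol.seed,
        )
    if protocol.kind == "flash_family":
        trace, _ = make_flash_family(
            p.get("base_strength", 3.0), p.get("n_flashes", 6),
            p.get("spacing_factor", 2.0), p.get("background", 0.0),
            protocol.dt,
        )
        return trace
    if protocol.kind == "sinusoid":
        from .clamp import sinusoid_stimulus
        return sinusoid_stimulus(p["mean"], p.get("contrast", 1.0),
                                 p.get("freq", 2.0), p.get("duration", 4.0),
                                 protocol.dt)
    if protocol.kind == "step_with_flashes":
        from .clamp import step_flash_stimulus
        return step_flash_stimulus(
            p["pre_level"], p["step_level"], p.get("flash_strength", 0.0),
            p.get("flash_times", ()), p["step_window"], p["total_time"],
            protocol.dt,
        )
    raise ValueError(f"unknown protocol kind {protocol.kind!r}")
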