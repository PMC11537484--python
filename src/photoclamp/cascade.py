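"""Forward biochemical model of the rod/cone phototransduction cascade.

The cascade converts a light stimulus (isomerization rate, R*/s) into an
outer-segment current (pA) through six coupled variables:

    dR/dt = gamma * Stim - sigma * R        (opsin activity)
    dP/dt = R - phi * P + eta               (phosphodiesterase activity)
    dG/dt = S - P * G                       (cGMP concentration)
    I     = k * G**n                        (cGMP-gated current)
    dC/dt = q * I - beta * C                (calcium concentration)
    S     = S_max / (1 + (C / K_GC)**m)     (cyclase synthesis rate)

``q`` and ``S_max`` are not free: they are pinned by the requirement that
darkness (Stim = 0) is a fixed point with the measured dark current, which
gives ``q = beta * C_D / I_D`` and
``S_max = G_D * (eta / phi) * (1 + (C_D / K_GC)**m)``.

The model current is a positive magnitude; recording conventions report dark
currents as negative, and all constructors accept either sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.optimize import brentq

__all__ = [
    "CELL_TYPES",
    "CascadeParams",
    "DarkOperatingPoint",
    "Trace",
    "StateTrace",
    "consensus_params",
    "default_dark_current",
    "default_dt",
    "dark_operating_point",
    "steady_state",
    "simulate",
    "flash_response",
]

CELL_TYPES = ("primate_cone", "mouse_cone", "primate_rod", "mouse_rod")

# Best-fit consensus parameter values per photoreceptor type.  sigma and phi
# (opsin and PDE decay rates) are interchangeable in their effect on the
# output and are tied; k, n, m and C_D are fixed from prior measurements,
# beta is fixed for rods and free for cones.
_CONSENSUS = {
    #               sigma    eta    beta  K_GC  gamma
    "primate_cone": (22.0, 2000.0,  9.00, 0.5, 10.0),
    "mouse_cone":   (9.74,  761.0,  2.64, 0.4, 10.0),
    "primate_rod":  (7.07,   2.53, 25.00, 0.5,  4.2),
    "mouse_rod":    (7.66,   1.62, 25.00, 0.4,  8.0),
}

# Representative dark-current magnitudes (pA), mid-range of the measured
# spans (240-428 primate cone, 41-80 mouse cone, 19-37 primate rod,
# 16-24 mouse rod).  Response kinetics are independent of this choice; only
# absolute amplitudes scale with it.
_DEFAULT_DARK_CURRENT = {
    "primate_cone": 300.0,
    "mouse_cone": 60.0,
    "primate_rod": 28.0,
    "mouse_rod": 20.0,
}

# Reference integration steps: 0.1 ms for cones, 1 ms for rods.
_DEFAULT_DT = {
    "primate_cone": 1e-4,
    "mouse_cone": 1e-4,
    "primate_rod": 1e-3,
    "mouse_rod": 1e-3,
}


@dataclass(frozen=True)
class CascadeParams:
    """The eleven biochemical parameters of the cascade plus a cell-type tag.

    Rates are s^-1; ``k`` is pA*uM^-n; ``K_GC`` and ``C_D`` are uM;
    ``gamma``, ``n`` and ``m`` are unitless.
    """

    gamma: float
    sigma: float
    phi: float
    eta: float
    k: float
    n: float
    m: float
    beta: float
    K_GC: float
    C_D: float
    cell_type: str = "primate_cone"

    def __post_init__(self):
        for name in ("gamma", "sigma", "phi", "eta", "k", "beta", "K_GC", "C_D"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.n < 1 or self.m < 1:
            raise ValueError("cooperativities n and m must be >= 1")

    def replace(self, **kw) -> "CascadeParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class DarkOperatingPoint:
    """Dark fixed point of the cascade and the derived constants.

    ``I_D``: dark current magnitude (pA); ``G_D``: dark cGMP (uM);
    ``P_D``: dark PDE activity (s^-1); ``q``: current-to-calcium conversion
    (uM s^-1 pA^-1); ``S_max``: maximal cyclase rate (uM s^-1).
    """

    I_D: float
    G_D: float
    P_D: float
    q: float
    S_max: float


@dataclass
class Trace:
    """Uniformly sampled time series: sample interval ``dt`` (s), values,
    and a units label (``R*/s``, ``pA``, ``uM``, ``s^-1``, ``mV``, ``a.u.``)."""

    dt: float
    values: np.ndarray
    units: str = "a.u."

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not (self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite samples")
        if self.units == "R*/s" and np.any(self.values < 0):
            raise ValueError("stimulus traces (R*/s) must be nonnegative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt

    @property
    def duration(self) -> float:
        return len(self.values) * self.dt

    def copy(self) -> "Trace":
        return Trace(self.dt, self.values.copy(), self.units)


@dataclass
class StateTrace:
    """All six cascade variables over time, sharing dt and length."""

    R: Trace
    P: Trace
    G: Trace
    S: Trace
    C: Trace
    I: Trace

    @property
    def dt(self) -> float:
        return self.I.dt


def consensus_params(cell_type: str) -> CascadeParams:
    """Return the consensus parameter set for one of the four supported
    photoreceptor types."""
    if cell_type not in _CONSENSUS:
        raise ValueError(
            f"unsupported cell type {cell_type!r}; expected one of {CELL_TYPES}"
        )
    sigma, eta, beta, kgc, gamma = _CONSENSUS[cell_type]
    return CascadeParams(
        gamma=gamma, sigma=sigma, phi=sigma, eta=eta,
        k=0.01, n=3.0, m=4.0, beta=beta, K_GC=kgc, C_D=1.0,
        cell_type=cell_type,
    )


def default_dark_current(cell_type: str) -> float:
    return _DEFAULT_DARK_CURRENT[cell_type]


def default_dt(cell_type: str) -> float:
    return _DEFAULT_DT[cell_type]


def dark_operating_point(params: CascadeParams, dark_current: float) -> DarkOperatingPoint:
    """Derive the dark fixed point from a measured dark current.

    ``dark_current`` may be given in recording convention (negative); its
    magnitude is used.  G_D = (I_D/k)^(1/n); P_D = eta/phi;
    q = beta*C_D/I_D; S_max = G_D*(eta/phi)*(1+(C_D/K_GC)^m).
    """
    i_d = abs(float(dark_current))
    if not (i_d > 0 and np.isfinite(i_d)):
        raise ValueError(f"dark current must be nonzero and finite, got {dark_current!r}")
    g_d = (i_d / params.k) ** (1.0 / params.n)
    p_d = params.eta / params.phi
    q = params.beta * params.C_D / i_d
    s_max = g_d * p_d * (1.0 + (params.C_D / params.K_GC) ** params.m)
    return DarkOperatingPoint(I_D=i_d, G_D=g_d, P_D=p_d, q=q, S_max=s_max)


def _state_vector(params: CascadeParams, dark: DarkOperatingPoint,
                  r: float, p: float, g: float, c: float) -> np.ndarray:
    i = params.k * g ** params.n
    s = dark.S_max / (1.0 + (c / params.K_GC) ** params.m)
    return np.array([r, p, g, s, c, i])


def steady_state(params: CascadeParams, dark: DarkOperatingPoint,
                 background: float) -> np.ndarray:
    """Fixed point (R, P, G, S, C, I) under constant ``background`` R*/s.

    At background 0 this is the dark state.  For positive backgrounds the
    cGMP level is found by root-finding; the fixed point is unique because
    synthesis falls and hydrolysis rises monotonically with G.
    """
    if background < 0:
        raise ValueError("background must be nonnegative")
    r = params.gamma * background / params.sigma
    p = (r + params.eta) / params.phi
    if background == 0:
        return _state_vector(params, dark, 0.0, dark.P_D, dark.G_D, params.C_D)

    def resid(g):
        c = dark.q * params.k * g ** params.n / params.beta
        s = dark.S_max / (1.0 + (c / params.K_GC) ** params.m)
        return s - p * g

    lo, hi = 1e-12, dark.G_D
    if resid(hi) > 0:  # can only happen for pathological parameters
        while resid(hi) > 0:
            hi *= 2.0
            if hi > 1e9:
                raise RuntimeError(
                    f"steady-state root not bracketed at background={background}"
                )
    g = brentq(resid, lo, hi, xtol=1e-14, rtol=1e-15)
    c = dark.q * params.k * g ** params.n / params.beta
    return _state_vector(params, dark, r, p, g, c)


@njit(cache=False)
def _euler_kernel(stim, dt, gamma, sigma, phi, eta, k, n, m, beta, kgc,
                  q, smax, r0, p0, g0, c0):  # pragma: no cover - jit
    N = stim.shape[0]
    R = np.empty(N)
    P = np.empty(N)
    G = np.empty(N)
    S = np.empty(N)
    C = np.empty(N)
    I = np.empty(N)
    r, p, g, c = r0, p0, g0, c0
    for i in range(N):
        s = smax / (1.0 + (c / kgc) ** m)
        cur = k * g ** n
        R[i] = r
        P[i] = p
        G[i] = g
        S[i] = s
        C[i] = c
        I[i] = cur
        r_new = r + dt * (gamma * stim[i] - sigma * r)
        p_new = p + dt * (r - phi * p + eta)
        g_new = g + dt * (s - p * g)
        c_new = c + dt * (q * cur - beta * c)
        r, p, g, c = r_new, p_new, g_new, c_new
    return R, P, G, S, C, I


def _rk4_kernel(stim, dt, pr, dark, y0):
    """Classical Runge-Kutta integration (convergence cross-check).

    The stimulus is held constant over each step (zero-order hold), matching
    the Euler reference.
    """
    gamma, sigma, phi, eta = pr.gamma, pr.sigma, pr.phi, pr.eta
    k, n, m, beta, kgc = pr.k, pr.n, pr.m, pr.beta, pr.K_GC
    q, smax = dark.q, dark.S_max

    def deriv(y, u):
        r, p, g, c = y
        s = smax / (1.0 + (c / kgc) ** m)
        cur = k * g ** n
        return np.array([
            gamma * u - sigma * r,
            r - phi * p + eta,
            s - p * g,
            q * cur - beta * c,
        ])

    N = len(stim)
    out = np.empty((N, 4))
    y = np.asarray(y0, dtype=float)
    for i in range(N):
        out[i] = y
        u = stim[i]
        k1 = deriv(y, u)
        k2 = deriv(y + 0.5 * dt * k1, u)
        k3 = deriv(y + 0.5 * dt * k2, u)
        k4 = deriv(y + dt * k3, u)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return out


def simulate(params: CascadeParams, dark: DarkOperatingPoint, stimulus: Trace,
             initial: np.ndarray | None = None, method: str = "euler") -> StateTrace:
    """Integrate the cascade over a stimulus trace.

    ``initial`` is a 6-element state vector (R, P, G, S, C, I), e.g. from
    :func:`steady_state`; by default the model is equilibrated at the first
    stimulus sample.  The reference scheme is forward Euler at the trace's
    own dt (0.1 ms for cones, 1 ms for rods by convention); ``method="rk4"``
    provides an independent higher-order check.
    """
    stim = np.asarray(stimulus.values, dtype=float)
    if np.any(stim < 0):
        raise ValueError("stimulus must be nonnegative (R*/s)")
    if initial is None:
        initial = steady_state(params, dark, float(stim[0]))
    r0, p0, g0, _, c0, _ = (float(v) for v in initial)
    dt = stimulus.dt
    if method == "euler":
        R, P, G, S, C, I = _euler_kernel(
            stim, dt, params.gamma, params.sigma, params.phi, params.eta,
            params.k, params.n, params.m, params.beta, params.K_GC,
            dark.q, dark.S_max, r0, p0, g0, c0,
        )
    elif method == "rk4":
        Y = _rk4_kernel(stim, dt, params, dark, (r0, p0, g0, c0))
        R, P, G, C = Y[:, 0], Y[:, 1], Y[:, 2], Y[:, 3]
        S = dark.S_max / (1.0 + (C / params.K_GC) ** params.m)
        I = params.k * G ** params.n
    else:
        raise ValueError(f"unknown integration method {method!r}")
    if not np.all(np.isfinite(I)):
        bad = int(np.flatnonzero(~np.isfinite(I))[0])
        raise FloatingPointError(
            f"integration became non-finite at t={bad * dt:.6g} s; "
            "reduce dt or check parameters"
        )
    mk = lambda v, u: Trace(dt, v, u)
    return StateTrace(
        R=mk(R, "s^-1"), P=mk(P, "s^-1"), G=mk(G, "uM"),
        S=mk(S, "uM/s"), C=mk(C, "uM"), I=mk(I, "pA"),
    )


def simulate_current(params: CascadeParams, dark: DarkOperatingPoint,
                     stimulus: Trace, initial: np.ndarray | None = None) -> np.ndarray:
    """Fast path returning only the current array (used by the fitters)."""
    stim = np.asarray(stimulus.values, dtype=float)
    if initial is None:
        initial = steady_state(params, dark, float(stim[0]))
    r0, p0, g0, _, c0, _ = (float(v) for v in initial)
    _, _, _, _, _, I = _euler_kernel(
        stim, stimulus.dt, params.gamma, params.sigma, params.phi, params.eta,
        params.k, params.n, params.m, params.beta, params.K_GC,
        dark.q, dark.S_max, r0, p0, g0, c0,
    )
    return I


def flash_response(params: CascadeParams, dark: DarkOperatingPoint,
                   background: float, flash_strength: float,
                   flash_duration: float | None = None,
                   *, dt: float | None = None, pre_time: float = 0.2,
                   total_time: float | None = None):
    """Baseline-subtracted response to a rectangular flash on a background.

    ``flash_strength`` is in R* per flash (integrated isomerizations); the
    flash is delivered as a rectangular increment of duration
    ``flash_duration`` (default: one sample) starting at ``pre_time`` from
    the adapted steady state.  Returns ``(response, time_to_peak)`` where the
    response Trace starts at flash onset and time_to_peak is the time from
    onset to the response extremum.

    Raises ValueError for a zero-strength flash (time-to-peak undefined).
    """
    if flash_strength < 0 or background < 0:
        raise ValueError("flash strength and background must be nonnegative")
    if dt is None:
        dt = default_dt(params.cell_type)
    if flash_duration is None:
        flash_duration = dt
    if flash_duration < dt:
        raise ValueError("flash duration must be at least one time step")
    if total_time is None:
        total_time = 1.0 if "cone" in params.cell_type else 4.0
    n_pre = int(round(pre_time / dt))
    n_flash = max(1, int(round(flash_duration / dt)))
    n_total = int(round(total_time / dt))
    stim = np.full(n_total, float(background))
    stim[n_pre:n_pre + n_flash] += flash_strength / (n_flash * dt)
    ss = steady_state(params, dark, background)
    states = simulate(params, dark, Trace(dt, stim, "R*/s"), initial=ss)
    resp = states.I.values[n_pre:] - ss[5]
    if flash_strength == 0 or np.allclose(resp, 0.0):
        raise ValueError("flat response: time-to-peak undefined for zero flash")
    from .metrics import _refine_peak
    ipk = int(np.argmax(np.abs(resp)))
    t_peak = _refine_peak(resp, ipk) * dt
    return Trace(dt, resp, "pA"), t_peak
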