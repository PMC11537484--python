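"""Parameter estimation for the cascade model, statsmodels-style.

:class:`PhototransductionModel` holds stimulus/response recordings from one
or more cells; ``fit()`` minimizes the mean-squared error between simulated
and measured currents by Nelder-Mead simplex over the free parameters and
returns a :class:`PhototransductionResults` carrying the estimates,
goodness of fit, MSE-doubling sensitivity ranges and the sloppy-model
Hessian eigenanalysis.

Fitting conventions, mirroring how such models are constrained in practice:

* the dark cGMP of each cell is pinned by its measured dark current, never
  fit;
* the opsin and PDE decay rates (sigma, phi) are interchangeable and tied;
* free parameters are sigma, eta, K_GC (plus beta for cones; it is fixed
  from prior measurements for rods), with the overall gain gamma free per
  cell to absorb sensitivity differences;
* parameters are optimized in log space, which enforces positivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .cascade import (
    CascadeParams,
    DarkOperatingPoint,
    Trace,
    dark_operating_point,
    simulate_current,
)

__all__ = [
    "CellData",
    "FitSpec",
    "PhototransductionModel",
    "PhototransductionResults",
    "HessianResult",
    "fraction_variance",
    "fit_cell",
    "fit_consensus",
    "finite_difference_hessian",
]

_ROD_FREE = ("sigma", "eta", "K_GC")
_CONE_FREE = ("sigma", "eta", "K_GC", "beta")


def fraction_variance(measured, predicted) -> float:
    """Goodness of fit: 1 - SSE/SST.  1 for a perfect fit, 0 for predicting
    the mean, negative for worse than the mean."""
    m = np.asarray(getattr(measured, "values", measured), dtype=float)
    p = np.asarray(getattr(predicted, "values", predicted), dtype=float)
    if m.shape != p.shape:
        raise ValueError("measured and predicted must have equal length")
    sst = float(np.sum((m - m.mean()) ** 2))
    if sst == 0:
        raise ValueError("measured trace has zero variance; fraction undefined")
    sse = float(np.sum((m - p) ** 2))
    return 1.0 - sse / sst


@dataclass
class CellData:
    """One cell's recordings: paired stimulus/response traces and the
    measured dark current (either sign accepted)."""

    stimuli: list
    responses: list
    dark_current: float

    def __post_init__(self):
        if len(self.stimuli) != len(self.responses) or not self.stimuli:
            raise ValueError("need >= 1 paired stimulus/response traces")
        for s, r in zip(self.stimuli, self.responses):
            if len(s) != len(r) or s.dt != r.dt:
                raise ValueError("stimulus/response pair mismatched in dt or length")


@dataclass(frozen=True)
class FitSpec:
    """Which parameters are free.  ``shared_params`` are tied across cells;
    gamma is always free per cell.  Defaults follow the cell type: beta is
    free for cones only."""

    shared_params: tuple = ()
    tie_sigma_phi: bool = True

    @staticmethod
    def for_cell_type(cell_type: str) -> "FitSpec":
        free = _CONE_FREE if "cone" in cell_type else _ROD_FREE
        return FitSpec(shared_params=free)


@dataclass
class HessianResult:
    """Finite-difference Hessian of the cost at the optimum, symmetrized
    and eigendecomposed.  Large eigenvalues mark stiff parameter
    combinations, small ones sloppy combinations."""

    H: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    param_names: tuple
    steps: np.ndarray


def finite_difference_hessian(cost, theta: np.ndarray, rel_step: float = 0.01,
                              param_names: tuple | None = None) -> HessianResult:
    """Central-difference Hessian of ``cost`` at ``theta``.

    Steps are ``rel_step`` times each parameter magnitude (``rel_step``
    itself where a parameter is zero).  The result is symmetrized; its
    eigenvalues are sorted in decreasing order.
    """
    theta = np.asarray(theta, dtype=float)
    p = len(theta)
    h = np.where(theta != 0, rel_step * np.abs(theta), rel_step)
    H = np.empty((p, p))
    f0 = cost(theta)
    if not np.isfinite(f0):
        raise ValueError("cost not finite at the expansion point")
    e = np.eye(p)
    for i in range(p):
        fp = cost(theta + h[i] * e[i])
        fm = cost(theta - h[i] * e[i])
        H[i, i] = (fp - 2.0 * f0 + fm) / h[i] ** 2
        for j in range(i + 1, p):
            fpp = cost(theta + h[i] * e[i] + h[j] * e[j])
            fpm = cost(theta + h[i] * e[i] - h[j] * e[j])
            fmp = cost(theta - h[i] * e[i] + h[j] * e[j])
            fmm = cost(theta - h[i] * e[i] - h[j] * e[j])
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    if not np.all(np.isfinite(H)):
        bad = np.argwhere(~np.isfinite(H))[0]
        raise FloatingPointError(f"non-finite Hessian entry at {tuple(bad)}")
    H = 0.5 * (H + H.T)
    w, v = np.linalg.eigh(H)
    order = np.argsort(w)[::-1]
    if param_names is None:
        param_names = tuple(f"theta{i}" for i in range(p))
    return HessianResult(H=H, eigenvalues=w[order], eigenvectors=v[:, order],
                         param_names=tuple(param_names), steps=h)


class PhototransductionModel:
    """Cascade model bound to data from one or more cells of a type.

    Parameters
    ----------
    cells : list of CellData
    base_params : CascadeParams
        Template providing the fixed parameters (k, n, m, C_D, and beta for
        rods) and the cell type.
    spec : FitSpec, optional
        Free-parameter layout; defaults to the cell type's convention.
    """

    def __init__(self, cells, base_params: CascadeParams,
                 spec: FitSpec | None = None):
        if not cells:
            raise ValueError("need at least one cell")
        self.cells = list(cells)
        self.base_params = base_params
        self.spec = spec or FitSpec.for_cell_type(base_params.cell_type)
        self.shared_names = tuple(self.spec.shared_params)
        self.param_names = self.shared_names + tuple(
            f"gamma_{i}" for i in range(len(self.cells))
        )
        if "beta" in self.shared_names and "rod" in base_params.cell_type:
            raise ValueError("beta is fixed for rods, it cannot be free")

    # -- parameter packing ---------------------------------------------------

    def _unpack(self, theta_log: np.ndarray):
        theta = np.exp(theta_log)
        shared = dict(zip(self.shared_names, theta[: len(self.shared_names)]))
        if self.spec.tie_sigma_phi and "sigma" in shared:
            shared["phi"] = shared["sigma"]
        gammas = theta[len(self.shared_names):]
        return shared, gammas

    def _pack(self, params: CascadeParams, gammas) -> np.ndarray:
        vals = [getattr(params, n) for n in self.shared_names]
        return np.log(np.concatenate([vals, np.asarray(gammas, dtype=float)]))

    def _cell_params(self, shared: dict, gamma: float) -> CascadeParams:
        return self.base_params.replace(gamma=float(gamma), **shared)

    # -- objective -----------------------------------------------------------

    def mse(self, theta_log: np.ndarray) -> float:
        """Mean-squared error pooled over all samples of all stimuli of all
        cells (uniform per-sample weighting)."""
        shared, gammas = self._unpack(theta_log)
        sse = 0.0
        n = 0
        for cell, gamma in zip(self.cells, gammas):
            try:
                p = self._cell_params(shared, gamma)
                dark = dark_operating_point(p, cell.dark_current)
                for stim, resp in zip(cell.stimuli, cell.responses):
                    pred = simulate_current(p, dark, stim)
                    if not np.all(np.isfinite(pred)):
                        return np.inf
                    sse += float(np.sum((resp.values - pred) ** 2))
                    n += len(pred)
            except (ValueError, FloatingPointError, RuntimeError):
                return np.inf
        return sse / n

    def predict(self, theta_log: np.ndarray):
        """Simulated currents for every (cell, stimulus) pair."""
        shared, gammas = self._unpack(theta_log)
        out = []
        for cell, gamma in zip(self.cells, gammas):
            p = self._cell_params(shared, gamma)
            dark = dark_operating_point(p, cell.dark_current)
            out.append([
                Trace(s.dt, simulate_current(p, dark, s), "pA")
                for s in cell.stimuli
            ])
        return out

    # -- fitting -------------------------------------------------------------

    def fit(self, start_params: CascadeParams | None = None,
            start_gammas=None, restarts: int = 2, maxiter: int = 2000,
            seed: int = 0) -> "PhototransductionResults":
        """Nelder-Mead simplex minimization of the pooled MSE in log space.

        ``restarts`` additional runs resume from the incumbent optimum with
        a freshly initialized simplex, guarding against premature collapse.
        """
        if start_params is None:
            start_params = self.base_params
        if start_gammas is None:
            start_gammas = [start_params.gamma] * len(self.cells)
        x = self._pack(start_params, start_gammas)
        best = None
        for _ in range(restarts + 1):
            res = minimize(self.mse, x, method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-12,
                                    "maxiter": maxiter, "maxfev": maxiter})
            if best is None or res.fun < best.fun:
                best = res
            x = best.x
        shared, gammas = self._unpack(best.x)
        params = self._cell_params(shared, gammas[0])
        # pooled fraction of variance
        sst = sum(
            float(np.sum((r.values - np.mean(r.values)) ** 2))
            for c in self.cells for r in c.responses
        )
        n = sum(len(r) for c in self.cells for r in c.responses)
        fv = 1.0 - best.fun * n / sst if sst > 0 else np.nan
        return PhototransductionResults(
            model=self, params=params, per_cell_gamma=np.asarray(gammas),
            theta_log=best.x, mse_value=float(best.fun),
            fraction_variance=fv, nit=int(best.nit), nfev=int(best.nfev),
            converged=bool(best.success),
        )


@dataclass
class PhototransductionResults:
    """Fit results: shared parameter estimates (in ``params``), per-cell
    gains, objective value and diagnostics."""

    model: PhototransductionModel
    params: CascadeParams
    per_cell_gamma: np.ndarray
    theta_log: np.ndarray
    mse_value: float
    fraction_variance: float
    nit: int
    nfev: int
    converged: bool

    def cell_params(self, i: int) -> CascadeParams:
        return self.params.replace(gamma=float(self.per_cell_gamma[i]))

    def sensitivity_range(self, param_name: str, factor: float = 2.0,
                          span: float = 50.0, tol: float = 1e-3):
        """Parameter interval over which the MSE stays below ``factor``
        times its optimal value, all other parameters held fixed.

        Each side is located by bisection on a log grid out to
        ``span``-fold; an unreached side is returned as None (open bound).
        Returns ``(lower, upper)``.
        """
        names = self.model.param_names
        if param_name not in names:
            raise ValueError(f"{param_name!r} not a free parameter ({names})")
        idx = names.index(param_name)
        x_opt = self.theta_log.copy()
        m_opt = self.mse_value
        target = factor * m_opt

        def mse_at(logv):
            x = x_opt.copy()
            x[idx] = logv
            return self.model.mse(x)

        out = []
        for sign in (-1.0, 1.0):
            far = x_opt[idx] + sign * np.log(span)
            if mse_at(far) < target:
                out.append(None)
                continue
            lo, hi = x_opt[idx], far
            while abs(hi - lo) > tol:
                mid = 0.5 * (lo + hi)
                if mse_at(mid) < target:
                    lo = mid
                else:
                    hi = mid
            out.append(float(np.exp(0.5 * (lo + hi))))
        return tuple(out)

    def sloppy_hessian(self, rel_step: float = 0.01) -> HessianResult:
        """Finite-difference Hessian of the MSE over the natural (not log)
        free parameters at the optimum."""
        theta = np.exp(self.theta_log)

        def cost(th):
            if np.any(th <= 0):
                return np.inf
            return self.model.mse(np.log(th))

        return finite_difference_hessian(cost, theta, rel_step,
                                         param_names=self.model.param_names)

    def summary(self) -> str:
        lines = [
            "Phototransduction cascade fit",
            "=" * 46,
            f"cell type:          {self.params.cell_type}",
            f"cells:              {len(self.model.cells)}",
            f"MSE:                {self.mse_value:.6g} pA^2",
            f"fraction variance:  {self.fraction_variance:.4f}",
            f"iterations/evals:   {self.nit}/{self.nfev}",
            "-" * 46,
        ]
        for name in self.model.shared_names:
            lines.append(f"{name:>10s} = {getattr(self.params, name):.4g}")
        if self.model.spec.tie_sigma_phi:
            lines.append(f"{'phi':>10s} = {self.params.phi:.4g} (tied to sigma)")
        for i, g in enumerate(self.per_cell_gamma):
            lines.append(f"{f'gamma[{i}]':>10s} = {g:.4g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# spec-level conveniences

def fit_cell(stimuli, responses, dark_current, init: CascadeParams,
             **fit_kw) -> PhototransductionResults:
    """Fit one cell's free parameters (including its gamma)."""
    cell = CellData(list(stimuli), list(responses), dark_current)
    return PhototransductionModel([cell], init).fit(start_params=init, **fit_kw)


def fit_consensus(cells, init: CascadeParams, **fit_kw) -> PhototransductionResults:
    """Joint fit across cells: shared kinetics/feedback parameters, dark
    cGMP pinned per cell by its dark current, gamma free per cell."""
    return PhototransductionModel(list(cells), init).fit(start_params=init, **fit_kw)
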