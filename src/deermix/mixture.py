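"""Gaussian-component time-domain fitting of DEER traces.

This is the quantitative heart of the package: a measured (or simulated)
trace V(t) is fit directly in the time domain with a model built from a
small number of Gaussian distance components,

    F(t) = amp * [(1 - lambda) + lambda * sum_i w_i (K N_i)(t)] * B(t),

where N_i is a Gaussian distance component (mean <R>_i, width sigma_i)
truncated to the distance grid, K the powder-averaged dipolar kernel,
lambda the modulation depth and B an optional stretched-exponential
background.  Goodness of fit is judged by the reduced chi-square

    chi2_nu = 1/(N - q) * sum_i [V(t_i) - F(t_i)]^2 / s_i^2,

with N points, q free parameters and per-point noise s_i; values below
about 2 indicate a good fit.

Three entry points:

- :func:`fit_gaussians` -- general 1-3 component fit with per-parameter
  fix/free control (bounded trust-region least squares, seeded
  multi-start).
- :func:`two_state_fit` -- the docked/undocked population decomposition:
  both components held fixed, only the undocked fraction (plus modulation
  depth and amplitude nuisance) varied.
- :func:`lincomb_fit` -- model-free cross-check fitting a trace as a
  linear combination of two measured/simulated basis traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls

from .forward import DeerTrace, DistanceDistribution, DistanceGrid, build_kernel
from .inversion import estimate_noise
from .synthetic import GaussianComponent, gaussian_distribution

__all__ = [
    "FitResult",
    "TwoStateResult",
    "chi2_reduced",
    "fit_gaussians",
    "two_state_fit",
    "lincomb_fit",
]

_SIGMA_BOUNDS = (0.3, 25.0)
_LAMBDA_BOUNDS = (0.01, 0.99)
_AMP_BOUNDS = (0.8, 1.2)


@dataclass
class FitResult:
    """Fitted model trace with parameter estimates and goodness of fit."""

    model: np.ndarray
    params: dict[str, float]
    stderr: dict[str, float]
    q: int
    chi2_nu: float
    converged: bool
    distribution: DistanceDistribution | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class TwoStateResult:
    """Undocked-fraction decomposition against fixed docked/undocked components."""

    fraction_undocked: float
    stderr: float
    chi2_nu: float
    lambda_mod: float
    docked: GaussianComponent
    undocked: GaussianComponent
    fit: FitResult

    @property
    def percent_undocked(self) -> float:
        return 100.0 * self.fraction_undocked


def _noise(trace: DeerTrace, noise_sd: float | None, estimate: bool) -> float:
    if noise_sd is not None:
        return float(noise_sd)
    if trace.noise_sd is not None:
        return float(trace.noise_sd)
    if not estimate:
        raise ValueError("trace has no noise level and estimation is disabled")
    return estimate_noise(trace)


def chi2_reduced(
    trace: DeerTrace,
    model: np.ndarray,
    q: int,
    noise_sd: float | None = None,
    estimate: bool = True,
) -> float:
    """Reduced chi-square of ``model`` against the trace, with q free parameters."""
    model = np.asarray(model, dtype=float)
    if model.shape != trace.signal.shape:
        raise ValueError("model and trace must share the time axis")
    n = trace.n
    if n <= q:
        raise ValueError("need more points than free parameters")
    s = _noise(trace, noise_sd, estimate)
    return float(np.sum((trace.signal - model) ** 2) / s**2 / (n - q))


class _ParamSet:
    """Ordered fixed/free parameter bookkeeping for the trust-region solver."""

    def __init__(self):
        self.names: list[str] = []
        self.values: dict[str, float] = {}
        self.free: dict[str, bool] = {}
        self.bounds: dict[str, tuple[float, float]] = {}

    def add(self, name, value, free, lo, hi):
        self.names.append(name)
        self.values[name] = float(np.clip(value, lo, hi)) if free else float(value)
        self.free[name] = free
        self.bounds[name] = (lo, hi)

    @property
    def free_names(self):
        return [n for n in self.names if self.free[n]]

    def vector(self, overrides=None):
        vals = dict(self.values)
        if overrides:
            vals.update(overrides)
        return np.array(
            [np.clip(vals[n], *self.bounds[n]) for n in self.free_names]
        )

    def lo_hi(self):
        lo = np.array([self.bounds[n][0] for n in self.free_names])
        hi = np.array([self.bounds[n][1] for n in self.free_names])
        return lo, hi

    def full(self, x):
        out = dict(self.values)
        out.update(zip(self.free_names, x))
        return out


def _mixture_density(grid, params, n_components):
    weights = []
    remaining = 1.0
    for i in range(1, n_components):
        w = params[f"frac{i}"]
        weights.append(w)
        remaining -= w
    weights.append(max(remaining, 0.0))
    p = np.zeros(grid.n)
    for i, w in enumerate(weights, start=1):
        comp = GaussianComponent(params[f"mean{i}"], params[f"sigma{i}"])
        p = p + w * gaussian_distribution(comp, grid).density
    return p


def fit_gaussians(
    trace: DeerTrace,
    n_components: int = 1,
    grid: DistanceGrid | None = None,
    fix: dict[str, float] | None = None,
    lambda_mod: float | None = None,
    bg_rate: float | None = None,
    bg_dim: float = 3.0,
    noise_sd: float | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Weighted nonlinear least-squares Gaussian-mixture fit of a raw trace.

    Parameters named ``mean1, sigma1, ..., frac1, ...`` may be fixed through
    ``fix``; ``lambda_mod`` fixes the modulation depth (free by default) and
    ``bg_rate`` fixes the background rate (held at 0 by default, i.e. no
    background is fitted unless a value or ``fix={'bg_rate': ...}`` frees it
    explicitly via np.nan).  Multi-start: ``n_starts`` seeded initial points;
    the lowest reduced chi-square wins, ties broken by the lowest first
    fraction.
    """
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    grid = grid or DistanceGrid.default()
    fix = dict(fix or {})
    s = _noise(trace, noise_sd, estimate=True)
    K = build_kernel(trace.times, grid)
    bg_free = bg_rate is not None and np.isnan(bg_rate)

    ps = _ParamSet()
    r_lo, r_hi = float(grid.r[0]), float(grid.r[-1])
    span = r_hi - r_lo
    for i in range(1, n_components + 1):
        m0 = r_lo + (i - 0.5) / n_components * span
        ps.add(f"mean{i}", fix.get(f"mean{i}", m0), f"mean{i}" not in fix, r_lo, r_hi)
        ps.add(f"sigma{i}", fix.get(f"sigma{i}", 5.0), f"sigma{i}" not in fix, *_SIGMA_BOUNDS)
    for i in range(1, n_components):
        ps.add(f"frac{i}", fix.get(f"frac{i}", 1.0 / n_components), f"frac{i}" not in fix, 0.0, 1.0)
    lam0 = float(np.clip(1.0 - np.min(trace.signal), *_LAMBDA_BOUNDS))
    ps.add("lambda", lambda_mod if lambda_mod is not None else lam0, lambda_mod is None, *_LAMBDA_BOUNDS)
    ps.add("bg_rate", 0.0 if bg_rate is None or bg_free else bg_rate, bg_free, 0.0, 10.0)
    ps.add("amp", 1.0, True, *_AMP_BOUNDS)

    t = trace.times
    v = trace.signal

    def model_of(params):
        p = _mixture_density(grid, params, n_components)
        form = K @ p
        bg = np.exp(-params["bg_rate"] * t ** (bg_dim / 3.0))
        return params["amp"] * ((1.0 - params["lambda"]) + params["lambda"] * form) * bg

    def residuals(x):
        return (model_of(ps.full(x)) - v) / s

    rng = np.random.default_rng(seed)
    starts = [ps.vector()]
    for _ in range(max(n_starts - 1, 0)):
        jitter = {}
        for i in range(1, n_components + 1):
            jitter[f"mean{i}"] = rng.uniform(r_lo + 0.05 * span, r_hi - 0.05 * span)
            jitter[f"sigma{i}"] = rng.uniform(1.0, 12.0)
        for i in range(1, n_components):
            jitter[f"frac{i}"] = rng.uniform(0.0, 1.0)
        jitter["lambda"] = rng.uniform(0.1, 0.6)
        starts.append(ps.vector({k: val for k, val in jitter.items() if ps.free.get(k, False)}))

    lo, hi = ps.lo_hi()
    q = len(ps.free_names)
    best = None
    any_success = False
    for x0 in starts:
        res = least_squares(residuals, x0, bounds=(lo, hi), method="trf", x_scale="jac")
        any_success = any_success or res.success
        chi2 = chi2_reduced(trace, model_of(ps.full(res.x)), q, noise_sd=s)
        frac_key = tuple(
            res.x[ps.free_names.index(f"frac{i}")]
            for i in range(1, n_components)
            if f"frac{i}" in ps.free_names
        )
        key = (round(chi2, 10), frac_key)
        if best is None or key < best[0]:
            best = (key, res, chi2)

    _, res, chi2 = best
    params = ps.full(res.x)

    # 1-sigma uncertainties from the weighted Jacobian, scaled by chi2_nu
    stderr = {name: 0.0 for name in ps.names}
    try:
        jtj = res.jac.T @ res.jac
        cov = chi2 * np.linalg.pinv(jtj)
        for name, var in zip(ps.free_names, np.diag(cov)):
            stderr[name] = float(np.sqrt(max(var, 0.0)))
    except np.linalg.LinAlgError:
        pass

    dist = DistanceDistribution.from_unnormalized(grid, _mixture_density(grid, params, n_components))
    return FitResult(
        model=model_of(params),
        params=params,
        stderr=stderr,
        q=q,
        chi2_nu=chi2,
        converged=any_success,
        distribution=dist,
        meta={"n_components": n_components, "noise_sd": s},
    )


def two_state_fit(
    trace: DeerTrace,
    docked: GaussianComponent,
    undocked: GaussianComponent,
    grid: DistanceGrid | None = None,
    lambda_mod: float | None = None,
    noise_sd: float | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> TwoStateResult:
    """Fixed-component two-state population fit.

    The docked and undocked components' <R> and sigma are held fixed; only
    the undocked fraction a (bounded to [0, 1]) plus the modulation depth
    and an amplitude nuisance are varied.  The uncertainty on a comes from
    the chi2-scaled Jacobian covariance.
    """
    if (docked.mean, docked.sigma) == (undocked.mean, undocked.sigma):
        raise ValueError("docked and undocked components are identical; the fraction is not identifiable")
    fit = fit_gaussians(
        trace,
        n_components=2,
        grid=grid,
        fix={
            "mean1": undocked.mean,
            "sigma1": undocked.sigma,
            "mean2": docked.mean,
            "sigma2": docked.sigma,
        },
        lambda_mod=lambda_mod,
        noise_sd=noise_sd,
        n_starts=n_starts,
        seed=seed,
    )
    return TwoStateResult(
        fraction_undocked=float(fit.params["frac1"]),
        stderr=float(fit.stderr["frac1"]),
        chi2_nu=fit.chi2_nu,
        lambda_mod=float(fit.params["lambda"]),
        docked=docked,
        undocked=undocked,
        fit=fit,
    )


def lincomb_fit(
    target: DeerTrace,
    basis_undocked: DeerTrace,
    basis_docked: DeerTrace,
    noise_sd: float | None = None,
) -> tuple[float, FitResult]:
    """Fit a trace as c * [a * V_undocked + (1 - a) * V_docked].

    The basis traces are linearly interpolated onto the target time axis.
    The nonnegative linear problem in (c*a, c*(1-a)) is solved exactly;
    a is their normalized first coefficient.  Returns (a, FitResult) with
    q = 2 free parameters (a and the overall amplitude c).
    """
    vu = np.interp(target.times, basis_undocked.times, basis_undocked.signal)
    vd = np.interp(target.times, basis_docked.times, basis_docked.signal)
    if np.allclose(vu, vd, rtol=1e-10, atol=1e-12):
        raise ValueError("basis traces are identical; the fraction is not identifiable")
    A = np.column_stack([vu, vd])
    coef, _ = nnls(A, target.signal)
    total = coef.sum()
    if total <= 0:
        raise ValueError("degenerate linear-combination fit (zero amplitude)")
    a = float(coef[0] / total)
    model = A @ coef
    s = _noise(target, noise_sd, estimate=True)
    chi2 = chi2_reduced(target, model, q=2, noise_sd=s)

    # variance of a via the linear model covariance, scaled by chi2_nu
    try:
        cov = chi2 * s**2 * np.linalg.pinv(A.T @ A)
        grad = np.array([coef[1], -coef[0]]) / total**2
        var_a = float(grad @ cov @ grad)
    except np.linalg.LinAlgError:
        var_a = 0.0

    result = FitResult(
        model=model,
        params={"a": a, "c": float(total)},
        stderr={"a": float(np.sqrt(max(var_a, 0.0))), "c": 0.0},
        q=2,
        chi2_nu=chi2,
        converged=True,
        meta={"noise_sd": s},
    )
    return a, result
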