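"""Parameter estimation for the growth and batch-fermentation models.

Two layers:

* growth-rate-versus-substrate regression — the classical Monod fit
  mu(S) = theta1*S/(theta2+S) by sum-of-squares minimization (Nelder-Mead
  simplex from a double-reciprocal start), and its Haldane extension with
  the S^2/K_I substrate-inhibition term for data spanning inhibitory
  substrate levels;
* full time-course estimation — weighted least squares between an observed
  batch trajectory and the ODE simulation, minimized over any named subset
  of the kinetic parameters by simplex search or sampled by DRAM MCMC with
  a Gaussian likelihood and conjugate error-variance chain.

Residuals are weighted per variable by the observed range by default, so
glucose (order 100 g/L) does not drown out biomass (order 1 g/L).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from .bayes_mcmc import McmcChain, McmcConfig, UniformPrior, chain_diagnostics, dram_sample
from .ferm_kinetics import (
    FermentationState,
    KineticParams,
    SimulationError,
    TimeCourse,
    simulate_batch,
)

__all__ = [
    "GrowthRatePoint",
    "MonodFit",
    "TimeCourseFitSpec",
    "TimeCourseFit",
    "fit_monod",
    "fit_haldane",
    "ssq_timecourse",
    "fit_timecourse",
    "fit_diagnostics",
]

#: default box constraints: rates (1/h) and concentrations (g/L)
DEFAULT_RATE_BOUNDS = (1e-6, 10.0)
DEFAULT_CONC_BOUNDS = (1e-3, 1e4)

_RATE_PARAMS = {"mu_m", "K_d", "m_S", "beta_Ba", "beta_Aa"}


@dataclass(frozen=True)
class GrowthRatePoint:
    """One (substrate, observed specific growth rate) observation."""

    S: float        #: substrate concentration, g/L
    mu_obs: float   #: observed specific growth rate, 1/h

    def __post_init__(self) -> None:
        if self.S < 0 or self.mu_obs < 0:
            raise ValueError("S and mu_obs must be nonnegative")


@dataclass
class MonodFit:
    """Result of a growth-law sum-of-squares fit."""

    theta1: float           #: fitted maximum growth rate, 1/h
    theta2: float           #: fitted saturation constant, g/L
    ssq: float              #: minimized sum of squares
    n_points: int
    n_params: int = 2
    converged: bool = True
    theta3: float | None = None  #: substrate-inhibition constant K_I (Haldane only)

    def predict(self, S: np.ndarray) -> np.ndarray:
        S = np.asarray(S, dtype=float)
        if self.theta3 is None:
            return self.theta1 * S / (self.theta2 + S)
        return self.theta1 * S / (S + self.theta2 + S**2 / self.theta3)


def _double_reciprocal_start(data: Sequence[GrowthRatePoint]) -> tuple[float, float]:
    # Lineweaver-Burk: 1/mu = 1/theta1 + (theta2/theta1) * (1/S)
    pts = [(p.S, p.mu_obs) for p in data if p.S > 0 and p.mu_obs > 0]
    if len(pts) < 2:
        raise ValueError("need >= 2 points with positive S and mu for the start")
    inv_s = np.array([1.0 / s for s, _ in pts])
    inv_mu = np.array([1.0 / m for _, m in pts])
    slope, intercept = np.polyfit(inv_s, inv_mu, 1)
    if intercept <= 0:  # noisy data can flip the sign; fall back to crude start
        theta1 = max(m for _, m in pts) * 1.2
        theta2 = float(np.median([s for s, _ in pts]))
    else:
        theta1 = 1.0 / intercept
        theta2 = max(slope / intercept, 1e-3)
    return float(theta1), float(theta2)


def _validate_growth_data(data: Sequence[GrowthRatePoint]) -> None:
    if len(data) < 3:
        raise ValueError("need at least 3 observations")
    if len({p.S for p in data}) < 2:
        raise ValueError("need at least 2 distinct substrate levels")
    if all(p.mu_obs == 0 for p in data):
        raise ValueError("all observed growth rates are zero; nothing to fit")


def fit_monod(
    data: Sequence[GrowthRatePoint],
    start: tuple[float, float] | None = None,
) -> MonodFit:
    """Fit mu(S) = theta1*S/(theta2+S) by Nelder-Mead on the sum of squares.

    theta1 is the maximum growth rate (1/h), theta2 the half-saturation
    constant (g/L). Default start comes from the double-reciprocal
    (1/mu vs 1/S) linearization. Appropriate for data at low, non-inhibitory
    substrate levels where the inhibition term is negligible.
    """
    _validate_growth_data(data)
    s = np.array([p.S for p in data])
    y = np.array([p.mu_obs for p in data])
    if start is None:
        start = _double_reciprocal_start(data)

    def ssq(theta: np.ndarray) -> float:
        t1, t2 = theta
        if t1 <= 0 or t2 <= 0:
            return 1e300
        r = y - t1 * s / (t2 + s)
        return float(r @ r)

    res = optimize.minimize(
        ssq, x0=list(start), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 10_000},
    )
    if not res.success:
        warnings.warn(f"Monod fit did not converge: {res.message}", stacklevel=2)
    return MonodFit(
        theta1=float(res.x[0]), theta2=float(res.x[1]),
        ssq=float(res.fun), n_points=len(data), n_params=2,
        converged=bool(res.success),
    )


def fit_haldane(
    data: Sequence[GrowthRatePoint],
    start: tuple[float, float, float] | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> MonodFit:
    """Fit the substrate-inhibition growth law mu(S) = mu_m*S/(S+K_S+S^2/K_I).

    Three parameters (theta1=mu_m, theta2=K_S, theta3=K_I) by Nelder-Mead
    sum-of-squares minimization with a documented default of `n_starts`
    jittered restarts (the Haldane surface is mildly multimodal when high-S
    coverage is thin). Needs data spanning inhibitory substrate levels for
    K_I to be identified.
    """
    _validate_growth_data(data)
    s = np.array([p.S for p in data])
    y = np.array([p.mu_obs for p in data])
    if start is None:
        t1, t2 = _double_reciprocal_start(data)
        # crude K_I start: optimum of the empirical curve at S_opt = sqrt(K_S*K_I)
        s_peak = float(s[np.argmax(y)])
        t3 = max(s_peak**2 / max(t2, 1e-3), 10.0)
        start = (t1, t2, t3)

    def ssq(theta: np.ndarray) -> float:
        t1, t2, t3 = theta
        if t1 <= 0 or t2 <= 0 or t3 <= 0:
            return 1e300
        r = y - t1 * s / (s + t2 + s**2 / t3)
        return float(r @ r)

    rng = np.random.default_rng(seed)
    best = None
    x0 = np.asarray(start, dtype=float)
    for k in range(max(n_starts, 1)):
        trial = x0 if k == 0 else x0 * np.exp(rng.normal(0, 0.3, size=3))
        res = optimize.minimize(
            ssq, x0=trial, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20_000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return MonodFit(
        theta1=float(best.x[0]), theta2=float(best.x[1]), theta3=float(best.x[2]),
        ssq=float(best.fun), n_points=len(data), n_params=3,
        converged=bool(best.success),
    )


@dataclass
class TimeCourseFitSpec:
    """Which kinetic parameters to estimate, their bounds, and the rest.

    `free_params` are estimated; everything else is pinned at `fixed`
    (default: the packaged parameter set). Bounds default to [1e-6, 10] for
    rates and [1e-3, 1e4] for concentration-like parameters.
    """

    free_params: list[str]
    initial_state: FermentationState
    fixed: KineticParams = field(default_factory=KineticParams)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    weights: dict[str, float] | None = None  #: per-variable residual weights

    def __post_init__(self) -> None:
        valid = set(KineticParams.__dataclass_fields__)
        unknown = set(self.free_params) - valid
        if unknown:
            raise ValueError(f"unknown kinetic parameters: {sorted(unknown)}")
        if len(set(self.free_params)) != len(self.free_params):
            raise ValueError("free_params contains duplicates")
        for name in self.free_params:
            if name not in self.bounds:
                self.bounds[name] = (
                    DEFAULT_RATE_BOUNDS if name in _RATE_PARAMS else DEFAULT_CONC_BOUNDS
                )
        for name, (lo, hi) in self.bounds.items():
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"bad bounds for {name}: ({lo}, {hi})")

    def build_params(self, theta: np.ndarray) -> KineticParams:
        return self.fixed.replace(**dict(zip(self.free_params, map(float, theta))))

    def start_vector(self) -> np.ndarray:
        out = []
        for name in self.free_params:
            v = getattr(self.fixed, name)
            lo, hi = self.bounds[name]
            out.append(min(max(v, lo), hi))
        return np.array(out)


_VARS = ("X", "S", "P_Ba", "P_Aa")


def _default_weights(obs: np.ndarray) -> np.ndarray:
    # inverse squared observed range per variable; constant columns get weight 0
    rng_ = obs.max(axis=0) - obs.min(axis=0)
    w = np.zeros(obs.shape[1])
    nz = rng_ > 0
    w[nz] = 1.0 / rng_[nz] ** 2
    return w


def ssq_timecourse(
    params: KineticParams,
    observed: TimeCourse,
    weights: dict[str, float] | None = None,
    *,
    inhibition: str = "total",
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> float:
    """Weighted residual sum of squares between observation and simulation.

    Simulates from the observed initial state at the observed times; weights
    are per variable (keys X, S, P_Ba, P_Aa), defaulting to inverse squared
    observed range. Simulation failure returns +inf (optimizer-safe).
    """
    if len(observed.states) == 0:
        raise ValueError("observed time course is empty")
    times = observed.times
    obs = observed.as_array()
    if weights is None:
        w = _default_weights(obs)
    else:
        w = np.array([weights.get(v, 0.0) for v in _VARS])
    try:
        sim = simulate_batch(
            params, observed.initial, t_end=float(times[-1]), t_eval=times,
            inhibition=inhibition, rtol=rtol, atol=atol,
        )
    except (SimulationError, ValueError):
        return math.inf
    resid = obs - sim.as_array()
    return float(np.sum(w * resid**2))


@dataclass
class TimeCourseFit:
    """Fitted kinetic parameters with objective value and optional chain."""

    params: KineticParams
    free_params: list[str]
    estimates: dict[str, float]
    ssq: float
    method: str
    converged: bool
    at_bounds: list[str]            #: free parameters within 1% of a bound
    chain: McmcChain | None = None
    diagnostics: dict | None = None


def fit_timecourse(
    observed: TimeCourse,
    spec: TimeCourseFitSpec,
    method: Literal["simplex", "mcmc"] = "simplex",
    mcmc_config: McmcConfig | None = None,
    seed: int = 0,
) -> TimeCourseFit:
    """Estimate the free kinetic parameters from a batch time course.

    "simplex" minimizes the weighted SSQ by Nelder-Mead inside the bounds
    (out-of-bounds proposals rejected with +inf). "mcmc" runs DRAM with a
    Gaussian likelihood on the same weighted residuals, a flat prior on the
    bounds box, and the conjugate error-variance chain; the point estimate
    is the posterior mean. Parameters ending within 1% of a bound are
    listed in `at_bounds` as a convergence warning.
    """
    names = spec.free_params
    if not names:
        ss = ssq_timecourse(spec.fixed, observed, spec.weights)
        return TimeCourseFit(
            params=spec.fixed, free_params=[], estimates={}, ssq=ss,
            method=method, converged=True, at_bounds=[],
        )
    lo = np.array([spec.bounds[n][0] for n in names])
    hi = np.array([spec.bounds[n][1] for n in names])

    def objective(theta: np.ndarray) -> float:
        if np.any(theta < lo) or np.any(theta > hi):
            return math.inf
        try:
            p = spec.build_params(theta)
        except ValueError:
            return math.inf
        return ssq_timecourse(p, observed, spec.weights)

    x0 = spec.start_vector()

    if method == "simplex":
        res = optimize.minimize(
            objective, x0=x0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 20_000},
        )
        theta = np.clip(res.x, lo, hi)
        fit_params = spec.build_params(theta)
        est = dict(zip(names, map(float, theta)))
        at_bounds = _near_bounds(theta, lo, hi, names)
        return TimeCourseFit(
            params=fit_params, free_params=list(names), estimates=est,
            ssq=float(res.fun), method="simplex",
            converged=bool(res.success), at_bounds=at_bounds,
        )

    if method != "mcmc":
        raise ValueError(f"unknown method {method!r}")

    n_obs = observed.as_array().size
    cfg = mcmc_config or McmcConfig(
        n_steps=4000, n_params=len(names), adapt_start=200,
        adapt_interval=100, seed=seed,
        init_cov=np.diag((0.05 * np.maximum(np.abs(x0), 1e-3)) ** 2),
    )
    if cfg.n_params != len(names):
        raise ValueError("mcmc_config.n_params must match the number of free parameters")
    prior = UniformPrior(lower=lo, upper=hi)
    chain = dram_sample(
        None, prior, cfg, x0, ssq_fn=objective, n_obs=n_obs, param_names=names,
    )
    diag = chain_diagnostics(chain)
    theta = chain.post_burn().mean(axis=0)
    theta = np.clip(theta, lo, hi)
    fit_params = spec.build_params(theta)
    est = dict(zip(names, map(float, theta)))
    return TimeCourseFit(
        params=fit_params, free_params=list(names), estimates=est,
        ssq=ssq_timecourse(fit_params, observed, spec.weights),
        method="mcmc", converged=not chain.all_rejected,
        at_bounds=_near_bounds(theta, lo, hi, names),
        chain=chain, diagnostics=diag,
    )


def _near_bounds(
    theta: np.ndarray, lo: np.ndarray, hi: np.ndarray, names: Sequence[str]
) -> list[str]:
    span = hi - lo
    near = (theta - lo < 0.01 * span) | (hi - theta < 0.01 * span)
    return [n for n, flag in zip(names, near) if flag]


def fit_diagnostics(
    fit: MonodFit | TimeCourseFit,
    data: Sequence[GrowthRatePoint] | TimeCourse | None = None,
    step_frac: float = 1e-4,
) -> dict:
    """Residual and curvature-based uncertainty report for a completed fit.

    Reports S_R (residual SSQ), n, p, the residual mean square S_R/(n-p),
    and approximate 95% confidence intervals from a finite-difference
    estimate of the objective curvature: cov(theta) ~ 2*s^2*H^{-1} for a
    least-squares objective. Zero-residual fits give degenerate intervals.
    """
    if isinstance(fit, MonodFit):
        if data is None:
            raise ValueError("pass the fitted growth-rate data for diagnostics")
        s = np.array([p.S for p in data])
        y = np.array([p.mu_obs for p in data])
        names = ["theta1", "theta2"] + (["theta3"] if fit.theta3 is not None else [])
        est = np.array([fit.theta1, fit.theta2] + ([fit.theta3] if fit.theta3 is not None else []))

        def objective(theta: np.ndarray) -> float:
            if fit.theta3 is None:
                pred = theta[0] * s / (theta[1] + s)
            else:
                pred = theta[0] * s / (s + theta[1] + s**2 / theta[2])
            r = y - pred
            return float(r @ r)

        n = fit.n_points
        ssq = fit.ssq
    else:
        if data is None:
            raise ValueError("pass the observed TimeCourse for diagnostics")
        names = fit.free_params
        est = np.array([fit.estimates[k] for k in names])
        spec_fixed = fit.params

        def objective(theta: np.ndarray) -> float:
            p = spec_fixed.replace(**dict(zip(names, map(float, theta))))
            return ssq_timecourse(p, data)

        n = data.as_array().size
        ssq = fit.ssq

    p = len(names)
    if n <= p:
        raise ValueError(f"need n > p for diagnostics (n={n}, p={p})")
    s2 = ssq / (n - p)
    if ssq == 0.0:
        ci = {k: (float(v), float(v)) for k, v in zip(names, est)}
        se = {k: 0.0 for k in names}
    else:
        hess = _fd_hessian(objective, est, step_frac)
        try:
            cov = 2.0 * s2 * np.linalg.inv(hess)
            diag = np.diag(cov)
            se_v = np.sqrt(np.clip(diag, 0, None))
        except np.linalg.LinAlgError:
            se_v = np.full(p, np.nan)
        se = dict(zip(names, map(float, se_v)))
        ci = {
            k: (float(v - 1.96 * se[k]), float(v + 1.96 * se[k]))
            for k, v in zip(names, est)
        }
    return {
        "S_R": ssq,
        "n": n,
        "p": p,
        "residual_mean_square": s2,
        "estimates": dict(zip(names, map(float, est))),
        "se": se,
        "ci95": ci,
    }


def _fd_hessian(f, x: np.ndarray, step_frac: float) -> np.ndarray:
    p = len(x)
    h = step_frac * np.maximum(np.abs(x), 1e-8)
    hess = np.empty((p, p))
    f0 = f(x)
    for a in range(p):
        for b in range(a, p):
            if a == b:
                xp = x.copy(); xp[a] += h[a]
                xm = x.copy(); xm[a] -= h[a]
                hess[a, a] = (f(xp) - 2 * f0 + f(xm)) / h[a] ** 2
            else:
                xpp = x.copy(); xpp[[a, b]] += [h[a], h[b]]
                xpm = x.copy(); xpm[a] += h[a]; xpm[b] -= h[b]
                xmp = x.copy(); xmp[a] -= h[a]; xmp[b] += h[b]
                xmm = x.copy(); xmm[[a, b]] -= [h[a], h[b]]
                hess[a, b] = hess[b, a] = (
                    f(xpp) - f(xpm) - f(xmp) + f(xmm)
                ) / (4 * h[a] * h[b])
    return hess
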