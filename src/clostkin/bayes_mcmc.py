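"""Delayed-rejection adaptive Metropolis (DRAM) sampling with an error-variance chain.

A random-walk Metropolis sampler with two standard add-ons:

* adaptation — the Gaussian proposal covariance is periodically re-estimated
  from the accumulated chain history, scaled by 2.38^2 / d with a small
  diagonal regularizer;
* delayed rejection — after a first-stage rejection, a second, narrower
  proposal (covariance shrunk by dr_scale^2) is tried, with the two-stage
  acceptance ratio that preserves detailed balance.

For Gaussian observation models the observation variance sigma^2 is not a
chain parameter: it is Gibbs-sampled each sweep from its conjugate
scaled-inverse-chi-square full conditional given the current residual sum
of squares, producing the `s2chain` alongside the parameter chain.
Posterior predictive envelopes evaluate a model function over random chain
subsets and report pointwise central quantile bands.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "McmcConfig",
    "McmcChain",
    "UniformPrior",
    "PredictiveEnvelope",
    "dram_sample",
    "predictive_envelope",
    "chain_diagnostics",
    "replicate_chains",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class McmcConfig:
    """Sampler settings.

    adapt_start/adapt_interval control covariance adaptation (set
    ``adapt=False`` for a fixed proposal); ``use_dr=False`` disables the
    second proposal stage, reducing the sampler to plain Metropolis.
    error_prior_n0/error_prior_s20 are the weight and scale of the
    scaled-inverse-chi-square prior on the observation variance; s20=None
    defaults to the initial residual mean square.
    """

    n_steps: int
    n_params: int
    adapt_start: int = 1000
    adapt_interval: int = 100
    dr_scale: float = 0.2
    init_cov: np.ndarray | float | None = None
    seed: int = 0
    error_prior_n0: float = 1.0
    error_prior_s20: float | None = None
    adapt: bool = True
    use_dr: bool = True
    burn_in: float = 0.2

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not 0 < self.dr_scale < 1:
            raise ValueError("dr_scale must be in (0, 1)")
        if self.adapt_start < 1:
            raise ValueError("adapt_start must be >= 1")
        if not 0 <= self.burn_in < 1:
            raise ValueError("burn_in must be in [0, 1)")

    def initial_cov(self) -> np.ndarray:
        d = self.n_params
        c = self.init_cov
        if c is None:
            return np.eye(d)
        if np.isscalar(c):
            return float(c) * np.eye(d)
        c = np.asarray(c, dtype=float)
        if c.ndim == 1:
            return np.diag(c)
        return c.copy()

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        if isinstance(d["init_cov"], np.ndarray):
            d["init_cov"] = d["init_cov"].tolist()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "McmcConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class UniformPrior:
    """Flat prior on a box; log-density 0 inside, -inf outside."""

    lower: np.ndarray
    upper: np.ndarray

    def logpdf(self, theta: np.ndarray) -> float:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        th = np.asarray(theta, dtype=float)
        return 0.0 if np.all((th >= lo) & (th <= hi)) else -np.inf


@dataclass
class McmcChain:
    """Parameter chain, error-variance chain and acceptance bookkeeping."""

    samples: np.ndarray          #: (n_steps, n_params) parameter draws
    s2chain: np.ndarray          #: (n_steps,) observation-variance draws
    logpost: np.ndarray          #: per-step log-posterior (at current s2)
    accept_stage1: int
    accept_stage2: int
    n_stage2_tried: int
    config: McmcConfig
    param_names: list[str] = field(default_factory=list)
    all_rejected: bool = False   #: flagged when no proposal was ever accepted

    def __post_init__(self) -> None:
        if not self.param_names:
            self.param_names = [f"p{i}" for i in range(self.samples.shape[1])]
        if np.any(self.s2chain <= 0):
            raise ValueError("s2chain must be strictly positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    def __len__(self) -> int:
        return self.samples.shape[0]

    def post_burn(self, burn_in: float | None = None) -> np.ndarray:
        frac = self.config.burn_in if burn_in is None else burn_in
        start = int(frac * len(self))
        return self.samples[start:]

    def to_csv(self, path: str | Path) -> None:
        """One row per step: named parameter columns plus `s2`."""
        df = pd.DataFrame(self.samples, columns=self.param_names)
        df["s2"] = self.s2chain
        df.to_csv(path, index=False)
        sidecar = Path(path).with_suffix(".json")
        cfg = asdict(self.config)
        if isinstance(cfg["init_cov"], np.ndarray):
            cfg["init_cov"] = cfg["init_cov"].tolist()
        sidecar.write_text(json.dumps({
            "config": cfg,
            "accept_stage1": self.accept_stage1,
            "accept_stage2": self.accept_stage2,
            "n_stage2_tried": self.n_stage2_tried,
            "all_rejected": self.all_rejected,
            "param_names": self.param_names,
        }, indent=2))


def _mahalanobis(diff: np.ndarray, cov_inv: np.ndarray) -> float:
    return float(diff @ cov_inv @ diff)


def dram_sample(
    log_likelihood: Callable[[np.ndarray], float] | None,
    prior,
    config: McmcConfig,
    init: np.ndarray,
    *,
    ssq_fn: Callable[[np.ndarray], float] | None = None,
    n_obs: int | None = None,
    param_names: Sequence[str] | None = None,
) -> McmcChain:
    """Run the DRAM chain.

    Two target modes:

    * Gaussian observation model — pass ``ssq_fn`` (residual sum of squares
      as a function of the parameters) and ``n_obs``. The log-likelihood is
      -0.5 * (SS/sigma^2 + n*log(2*pi*sigma^2)) and sigma^2 is Gibbs-updated
      each sweep from (n0*s20 + SS) / chi2(n0 + n).
    * generic — pass ``log_likelihood`` directly; the s2chain is held at the
      prior scale (no residual structure to update from).

    A log-likelihood evaluating to NaN is treated as -inf (rejection).
    `prior` needs a ``logpdf(theta) -> float`` method returning -inf outside
    support. The chain is bit-reproducible for a fixed config.seed.
    """
    gaussian_mode = ssq_fn is not None
    if gaussian_mode and n_obs is None:
        raise ValueError("n_obs is required with ssq_fn")
    if not gaussian_mode and log_likelihood is None:
        raise ValueError("pass either log_likelihood or ssq_fn")

    d = config.n_params
    init = np.asarray(init, dtype=float)
    if init.shape != (d,):
        raise ValueError(f"init must have shape ({d},)")
    if not np.isfinite(prior.logpdf(init)):
        raise ValueError("init must lie inside the prior support")

    rng = np.random.default_rng(config.seed)
    n0 = config.error_prior_n0

    if gaussian_mode:
        ss_cur = float(ssq_fn(init))
        if not math.isfinite(ss_cur):
            raise ValueError("ssq_fn must be finite at init")
        s20 = config.error_prior_s20
        if s20 is None:
            s20 = ss_cur / max(n_obs - d, 1)
        if s20 <= 0:
            s20 = 1.0
        s2 = s20

        def loglik_at(ss: float) -> float:
            return -0.5 * (ss / s2 + n_obs * (_LOG_2PI + math.log(s2)))

        def evaluate(theta: np.ndarray) -> tuple[float, float]:
            ss = float(ssq_fn(theta))
            if math.isnan(ss):
                return math.inf, -math.inf
            return ss, loglik_at(ss)

        ll_cur = loglik_at(ss_cur)
    else:
        s20 = config.error_prior_s20 if config.error_prior_s20 else 1.0
        s2 = s20
        ss_cur = math.nan

        def evaluate(theta: np.ndarray) -> tuple[float, float]:
            ll = float(log_likelihood(theta))
            if math.isnan(ll):
                ll = -math.inf
            return math.nan, ll

        ll_cur = evaluate(init)[1]
        if not math.isfinite(ll_cur):
            raise ValueError("log_likelihood must be finite at init")

    lp_cur = prior.logpdf(init)
    x = init.copy()

    cov = config.initial_cov()
    chol = np.linalg.cholesky(cov)
    cov_inv = np.linalg.inv(cov)

    samples = np.empty((config.n_steps, d))
    s2chain = np.empty(config.n_steps)
    logpost = np.empty(config.n_steps)
    acc1 = acc2 = tried2 = 0

    def posterior(lp: float, ll: float) -> float:
        return lp + ll if math.isfinite(lp) and math.isfinite(ll) else -math.inf

    post_cur = posterior(lp_cur, ll_cur)

    for step in range(config.n_steps):
        # ---- stage 1 proposal
        z1 = rng.standard_normal(d)
        y1 = x + chol @ z1
        lp1 = prior.logpdf(y1)
        if math.isfinite(lp1):
            ss1, ll1 = evaluate(y1)
        else:
            ss1, ll1 = math.inf, -math.inf
        post1 = posterior(lp1, ll1)
        log_a1 = post1 - post_cur
        u1 = rng.random()
        if math.log(u1) < log_a1:
            x, lp_cur, ll_cur, ss_cur, post_cur = y1, lp1, ll1, ss1, post1
            acc1 += 1
        elif config.use_dr:
            # ---- stage 2: narrower proposal, DR acceptance ratio
            tried2 += 1
            z2 = rng.standard_normal(d)
            y2 = x + config.dr_scale * (chol @ z2)
            lp2 = prior.logpdf(y2)
            if math.isfinite(lp2):
                ss2, ll2 = evaluate(y2)
            else:
                ss2, ll2 = math.inf, -math.inf
            post2 = posterior(lp2, ll2)
            u2 = rng.random()
            if math.isfinite(post2):
                # alpha(y2 -> y1): stage-1 ratio seen from y2
                log_a1_from_y2 = post1 - post2
                # q1 ratio: both proposals measured under the stage-1 kernel
                q_num = -0.5 * _mahalanobis(y1 - y2, cov_inv)
                q_den = -0.5 * _mahalanobis(y1 - x, cov_inv)
                log_num = post2 + q_num + _log1m_exp_min0(log_a1_from_y2)
                log_den = post_cur + q_den + _log1m_exp_min0(log_a1)
                log_a2 = log_num - log_den
                if math.log(u2) < log_a2:
                    x, lp_cur, ll_cur, ss_cur, post_cur = y2, lp2, ll2, ss2, post2
                    acc2 += 1

        # ---- conjugate error-variance sweep
        if gaussian_mode:
            shape = n0 + n_obs
            scale = n0 * s20 + ss_cur
            g = rng.chisquare(shape)
            s2 = scale / g
            ll_cur = loglik_at(ss_cur)
            post_cur = posterior(lp_cur, ll_cur)

        samples[step] = x
        s2chain[step] = s2
        logpost[step] = post_cur

        # ---- adaptation from the accumulated history
        if (
            config.adapt
            and step + 1 >= config.adapt_start
            and (step + 1 - config.adapt_start) % config.adapt_interval == 0
        ):
            hist = samples[: step + 1]
            emp = np.cov(hist, rowvar=False)
            emp = np.atleast_2d(emp)
            cand = (2.38**2 / d) * emp + 1e-10 * np.eye(d)
            try:
                chol_new = np.linalg.cholesky(cand)
            except np.linalg.LinAlgError:
                pass  # keep previous proposal; singular history
            else:
                cov, chol = cand, chol_new
                cov_inv = np.linalg.inv(cov)

    return McmcChain(
        samples=samples,
        s2chain=s2chain,
        logpost=logpost,
        accept_stage1=acc1,
        accept_stage2=acc2,
        n_stage2_tried=tried2,
        config=config,
        param_names=list(param_names) if param_names else [],
        all_rejected=(acc1 + acc2 == 0),
    )


def _log1m_exp_min0(log_a: float) -> float:
    """log(1 - min(1, exp(log_a))), with -inf when the move is sure."""
    if log_a >= 0:
        return -math.inf
    return math.log1p(-math.exp(log_a)) if log_a > -700 else 0.0


@dataclass
class PredictiveEnvelope:
    """Pointwise posterior (or posterior-predictive) quantile bands."""

    grid: np.ndarray
    median: np.ndarray
    quantile_bands: dict[float, tuple[np.ndarray, np.ndarray]]  #: level -> (lower, upper)

    def __post_init__(self) -> None:
        levels = sorted(self.quantile_bands)
        for narrow, wide in zip(levels, levels[1:]):
            lo_n, hi_n = self.quantile_bands[narrow]
            lo_w, hi_w = self.quantile_bands[wide]
            if np.any(lo_w > lo_n + 1e-12) or np.any(hi_w < hi_n - 1e-12):
                raise ValueError("quantile bands are not nested")


def predictive_envelope(
    chain: McmcChain,
    model_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
    grid: Sequence[float],
    levels: Sequence[float] = (0.5, 0.9, 0.95, 0.99),
    n_draws: int = 500,
    include_observation_noise: bool = False,
    burn_in: float | None = None,
    seed: int = 0,
) -> PredictiveEnvelope:
    """Central quantile bands of model_fn(theta, grid) over chain draws.

    Rows are drawn without replacement from the post-burn-in chain; with
    ``include_observation_noise`` Gaussian noise with variance from the
    matching s2chain rows is added before taking quantiles (posterior
    predictive rather than posterior bands).
    """
    if len(chain) == 0:
        raise ValueError("chain is empty")
    if not all(0 < lv < 1 for lv in levels):
        raise ValueError("levels must lie in (0, 1)")
    grid = np.asarray(grid, dtype=float)
    frac = chain.config.burn_in if burn_in is None else burn_in
    start = int(frac * len(chain))
    kept = chain.samples[start:]
    s2_kept = chain.s2chain[start:]
    if n_draws > len(kept):
        warnings.warn(
            f"n_draws={n_draws} exceeds post-burn-in chain length {len(kept)}; capped",
            stacklevel=2,
        )
        n_draws = len(kept)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(kept), size=n_draws, replace=False)
    preds = np.empty((n_draws, grid.size))
    for j, row in enumerate(idx):
        preds[j] = np.asarray(model_fn(kept[row], grid), dtype=float)
    if include_observation_noise:
        preds = preds + rng.standard_normal(preds.shape) * np.sqrt(s2_kept[idx])[:, None]
    bands: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for lv in levels:
        lo = np.quantile(preds, (1 - lv) / 2, axis=0)
        hi = np.quantile(preds, 1 - (1 - lv) / 2, axis=0)
        bands[float(lv)] = (lo, hi)
    return PredictiveEnvelope(
        grid=grid,
        median=np.quantile(preds, 0.5, axis=0),
        quantile_bands=bands,
    )


def _ess(x: np.ndarray) -> float:
    """Effective sample size via Geyer's initial positive sequence."""
    n = len(x)
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0:
        return float(n)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    tau = 1.0
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k]
        if pair < 0:
            break
        tau += 2 * pair
    return float(n / max(tau, 1.0))


def chain_diagnostics(chain: McmcChain, burn_in: float | None = None) -> dict:
    """Posterior summaries and acceptance bookkeeping.

    Per-parameter mean, sd, central 95% credible interval and an effective
    sample size estimate, over the post-burn-in chain; acceptance rates by
    proposal stage over the full run.
    """
    frac = chain.config.burn_in if burn_in is None else burn_in
    if not 0 <= frac < 1:
        raise ValueError("burn_in must be in [0, 1)")
    kept = chain.post_burn(frac)
    if len(kept) == 0:
        raise ValueError("no post-burn-in samples")
    s2_kept = chain.s2chain[int(frac * len(chain)):]
    n = len(chain)
    params = {}
    for j, name in enumerate(chain.param_names):
        col = kept[:, j]
        params[name] = {
            "mean": float(col.mean()),
            "sd": float(col.std(ddof=1)) if len(col) > 1 else 0.0,
            "ci_2.5": float(np.quantile(col, 0.025)),
            "ci_97.5": float(np.quantile(col, 0.975)),
            "ess": _ess(col),
        }
    return {
        "params": params,
        "s2_mean": float(s2_kept.mean()),
        "error_sd_mean": float(np.sqrt(s2_kept).mean()),
        "accept_rate_stage1": chain.accept_stage1 / n,
        "accept_rate_stage2": chain.accept_stage2 / n,
        "accept_rate_total": (chain.accept_stage1 + chain.accept_stage2) / n,
        "n_post_burn": len(kept),
    }


def replicate_chains(
    n_replicates: int,
    base_seed: int,
    run_one: Callable[[int], McmcChain],
) -> list[McmcChain]:
    """Replicate-run helper: run_one(seed) for seeds base_seed..base_seed+R-1.

    Off by default everywhere; useful for stability checks across many
    independent chains.
    """
    return [run_one(base_seed + r) for r in range(n_replicates)]
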