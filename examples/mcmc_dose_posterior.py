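"""Bayesian dose-lethality fit with DRAM and a posterior survival envelope.

Samples (beta0, beta1) of the binomial-logistic lethality model by
delayed-rejection adaptive Metropolis (50,000 steps), then builds nested
50/90/95/99% posterior bands for the survival curve over dose.
"""

import numpy as np

from clostkin.bayes_mcmc import (
    McmcConfig,
    UniformPrior,
    chain_diagnostics,
    dram_sample,
    predictive_envelope,
)
from clostkin.dose_response import LogisticParams, binomial_loglik, fit_mle
from clostkin.synthetic_data import load_fixture

table = load_fixture("table2")["Q36-8"]
mle = fit_mle(table)


def loglik(theta):
    return binomial_loglik(LogisticParams(*theta), table)


config = McmcConfig(
    n_steps=50_000, n_params=2, adapt_start=1000, adapt_interval=100,
    init_cov=np.diag([4.0, 1.0]), seed=20,
)
prior = UniformPrior(lower=np.array([-200.0, 0.0]), upper=np.array([0.0, 120.0]))
chain = dram_sample(loglik, prior, config,
                    np.array([mle.params.beta0, mle.params.beta1]),
                    param_names=["beta0", "beta1"])

diag = chain_diagnostics(chain)
for name, p in diag["params"].items():
    print(f"{name}: posterior mean {p['mean']:8.2f} +- {p['sd']:.2f} "
          f"(95% CI {p['ci_2.5']:.2f} to {p['ci_97.5']:.2f}, ESS {p['ess']:.0f})")
print(f"acceptance: stage 1 {diag['accept_rate_stage1']:.2f}, "
      f"stage 2 {diag['accept_rate_stage2']:.2f} "
      "(the narrower second-stage proposal rescues part of the rejections)")

dose_grid = np.linspace(50, 80, 7)
env = predictive_envelope(
    chain,
    lambda th, g: 1.0 - 1.0 / (1.0 + np.exp(-(th[0] + th[1] * np.log10(g)))),
    grid=dose_grid, levels=(0.5, 0.9, 0.95, 0.99), n_draws=2000, seed=1,
)
lo95, hi95 = env.quantile_bands[0.95]
print("\nposterior survival curve (median and 95% band):")
for d, med, lo, hi in zip(dose_grid, env.median, lo95, hi95):
    print(f"  {d:4.0f} Gy: {med:.3f}  [{lo:.3f}, {hi:.3f}]")
print("bands at the four levels are nested at every dose by construction.")
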