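# clostkin

Modeling tools for improving butyric-acid production by *Clostridium
tyrobutyricum* through heavy-ion irradiation mutagenesis: a dose–lethality
model for the irradiation step, screening arithmetic for picking improved
mutants, and a batch-fermentation kinetic model — with least-squares and
Bayesian (DRAM MCMC) parameter estimation — for the fermentation itself.

The package is aimed at bioprocess and strain-engineering groups who need
to (i) choose an irradiation dose from colony survival tables, (ii) call
"positive" mutants from acid-productivity screens, and (iii) simulate and
fit batch fermentations of the selected strains.

## Models

**Dose–lethality.** Colonies irradiated at dose *d* (Gy) die independently
with probability *p(x)*, where *x* = log₁₀ *d* and

&nbsp;&nbsp;&nbsp;&nbsp;logit *p*(*x*) = β₀ + β₁·*x*,

so per-dose dead counts are binomial. The fit maximizes the exact binomial
likelihood; a DRAM chain gives posterior bands for the survival curve
*1 − p(x)*.

**Mutant screening.** δ = R_butyric / R_acetic; a colony is a *positive*
mutant when δ strictly exceeds the wild-type baseline 3.05. Screening rates
are R_M/T = 100·M/T and R_P/T = 100·P/T. MTT viability: survival =
2^(−T_delay/T_doubling).

**Batch kinetics.** Four states — biomass X (g/L DCW), glucose S, butyrate
P_Ba, acetate P_Aa (g/L) — with

- growth: dX/dt = (μ − K_d)·X,
  μ = μ_m·S/(S + K_S + S²/K_I) · (1 − P/P_d)^i, P = P_Ba + P_Aa;
- Luedeking–Piret formation: dP_j/dt = α_j·(dX/dt)⁺ + β_j·X;
- substrate balance: −dS/dt = (dX/dt)⁺/Y_X + (dP_Ba/dt)/Y_Ba +
  (dP_Aa/dt)/Y_Aa + m_S·X.

The Haldane term makes growth maximal at S* = √(K_S·K_I); the
(1 − P/P_d)^i factor shuts growth down as total acid approaches P_d.
Free parameters are estimated from time courses by weighted least squares
(Nelder–Mead) or by DRAM MCMC with a conjugate error-variance chain
(`s2chain`), and posterior predictive envelopes summarize fit uncertainty.

## Worked example

```bash
python examples/simulate_reference_batch.py
```

```
growth optimum: S_opt = sqrt(K_S*K_I) = 25.59 g/L glucose, mu(S_opt) = 0.423 1/h
     t_h     X_gL     S_gL  butyrate_gL  acetate_gL
   0.000    0.100  180.000        0.000       0.000
  20.000    3.879  157.909       13.420       3.136
  60.000    5.618  134.920       29.197       4.592
 120.000    4.882  114.219       44.716       4.592

at 120 h: butyrate 44.7 g/L vs acetate 4.6 g/L (ratio 9.7) - the batch is butyrate-dominated
total acid 49.3 g/L approaches the critical P_d = 53.8 g/L, which is what shuts growth down
stoichiometric ceiling: 0.489 g butyrate per g glucose (0.667 for acetate)
```

Biomass peaks near 5.6 g/L around 50–60 h, then declines at the death rate
K_d once accumulated acid suppresses growth; butyrate keeps forming through
the non-growth-associated β_Ba·X term while acetate (β_Aa = 0) stops with
growth.

Other capabilities, one script each under `examples/`:

- `fit_dose_lethality.py` — binomial-logistic fits of the packaged
  survival tables (pooled LD50 ≈ 59.7 Gy);
- `mcmc_dose_posterior.py` — 50,000-step DRAM posterior for (β₀, β₁) and
  nested 50/90/95/99% survival-curve bands;
- `screen_mutants.py` — δ ratios, positive/negative calls, screening rates
  and the printed-table mismatch log;
- `fit_growth_law.py` — Monod and Haldane growth-law fits with residual
  diagnostics;
- `fit_batch_timecourse.py` — least-squares and DRAM recovery of (μ_m,
  P_d) from a noisy synthetic batch.

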