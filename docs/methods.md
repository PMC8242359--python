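# Methods

This note records the modeling assumptions, numerical choices and known
limitations behind the package, in the order data flows through a strain
improvement campaign: irradiation dose–response, mutant screening, batch
kinetics, and parameter estimation.

## Dose–lethality model

Per-dose dead-colony counts are treated as independent binomials with
lethality probability logit⁻¹(β₀ + β₁·x). The covariate is x = log₁₀(dose),
matching how survival tables report "log of irradiation dose"; a raw-dose
covariate is available via `fit_mle(..., covariate="dose")`. The likelihood
includes the binomial coefficient, and the same convention is used in the
reported −2 log L, so likelihood values are comparable across tools (they
match statsmodels' GLM binomial log-likelihood; the test suite asserts
this).

Fitting maximizes the exact binomial log-likelihood with Nelder–Mead from
an ordinary-least-squares start on continuity-corrected empirical logits
((k+0.5)/(n+1)); the correction is used *only* for initialization — all
rows, including 0% and 100% survival rows, enter the likelihood unchanged.
This start is robust to the separation-prone all-die row at 80 Gy. Complete
separation is detected (all fitted probabilities pinned to 0/1) and
flagged, not raised, since the parameters are then boundary-chasing but the
fitted curve is still usable for interpolation.

Reported survival proportions are rounded half-up to 4 decimals, the
convention of the source tables. Fitting each sample separately is the
default; `pool_tables` merges counts dose-by-dose for a pooled fit.

A historical diagnostic note: a published deviance-style figure of −40.28
for this model family cannot be a deviance (those are nonnegative) and the
underlying data are unstated; the package reports −2 log L as a diagnostic
and treats no external likelihood value as a verification point.

## Screening arithmetic

δ = R_butyric/R_acetic is reported rounded half-up to 2 decimals (raw value
retained on `ScreeningRecord.delta_raw`); the positive call uses strict
inequality against the wild-type δ = 3.05 — ties are negative. Group
counts P, M, T are data (table footers), not re-derived from per-row
calls, because the grouping that produced them is not reconstructible from
the printed ratios. Rates are reported half-up to 1 decimal with a
`rounding="truncate"` option, because published screens sometimes print
truncated rates (24/409 = 5.87% appearing as 5.8%). Printed ratios that
disagree with their own row's productivities are surfaced by
`delta_mismatch_log` and never silently corrected.

## Batch kinetic model

States: X (g/L DCW), S (g/L glucose), P_Ba, P_Aa (g/L acids); time in
hours. Model structure and default parameter values (the packaged
`table4_params.yaml`):

| symbol | meaning | default | units |
|---|---|---|---|
| μ_m | maximum specific growth rate | 0.48 | 1/h |
| K_S | substrate saturation constant | 1.71 | g/L |
| K_I | substrate inhibition constant | 383 | g/L |
| P_d | critical total-acid concentration | 53.8 | g/L |
| i | product-inhibition exponent | 5.32 | – |
| K_d | specific death rate | 0.0027 | 1/h |
| α_Ba, α_Aa | growth-associated formation | 3.12, 0.83 | g/g DCW |
| β_Ba, β_Aa | non-growth formation | 0.049, 0 | g/g DCW/h |
| Y_X, Y_Ba, Y_Aa | substrate-balance yield factors | 0.812, 0.973, 0.997 | g/g |
| m_S | maintenance coefficient | 0.015 | 1/h |

Modeling decisions where the source material was ambiguous or open:

- **P in the inhibition factor is total acid** P_Ba + P_Aa, with P_d the
  critical *total*; the alternative literal reading (butyrate-only
  inhibition) is available via `inhibition="butyrate"`.
- **The inhibition base is clamped at zero** before exponentiation: i =
  5.32 is non-integer, so a negative base is undefined; physically, growth
  is simply zero beyond P_d.
- **Death is a net rate**: dX/dt = (μ − K_d)X at all times, the simplest
  reading of a constant specific death rate.
- **Only the positive part of dX/dt** drives Luedeking–Piret formation and
  the substrate balance: biomass decay neither synthesizes product nor
  returns glucose.
- **β_Aa defaults to 0** (acetate formation purely growth-associated); the
  source table leaves it unreported. Overridable like every parameter.
- **X₀ is never published** for the reference batches; simulations of that
  scenario use 0.1 g/L DCW, a typical anaerobic inoculum, and state it
  explicitly.
- OD600 ↔ DCW conversion: 0.412 g/L per OD unit (`OD_TO_DCW_G_PER_L`).

The Haldane optimum is S* = √(K_S·K_I) = 25.59 g/L with the default
constants, where μ(S*) = μ_m/(1 + 2√(K_S/K_I)) = 0.423 1/h. Source prose
quotes "approximately 50 g/L" for the same optimum; both numbers are
surfaced by `haldane_optimum` users and the discrepancy is deliberately not
reconciled.

**Stoichiometric ceilings.** From glucose → butyrate + 2H₂ + 2CO₂ and
glucose + 2H₂O → 2 acetate + 4H₂ + 2CO₂, the theoretical mass yields are
0.489 and 0.667 g/g (IUPAC atomic masses). Note a structural inconsistency
of the fitted parameter set: with Y_Ba = 0.973 the simulated reference
batch converts glucose to butyrate at ≈0.68 g/g, above the 0.489
thermodynamic ceiling. The yield factors in the substrate balance are
fitted bookkeeping constants, not stoichiometric limits; the package's
yield-bound test therefore checks the balance-implied bound
ΔP_Ba ≤ Y_Ba·(−ΔS) (a genuine solver-consistency check), while the 0.489
figure is validated as pure stoichiometry.

**Numerics.** Integration uses `scipy.integrate.solve_ivp` (LSODA by
default) at rtol 1e−8 / atol 1e−10 (configurable); outputs are clipped of
negative round-off below atol. The vector field is made continuous at
glucose exhaustion: non-growth production and maintenance ramp linearly to
zero over a 1e−4 g/L substrate boundary layer (far below assay detection;
the equations are exact for S ≥ 1e−4). Without the ramp the discontinuity
at S = 0 collapses the step size and stalls integration for parameter sets
that exhaust glucose mid-run. The adaptive solution is tested against an
independent fixed-step RK4 integration at h = 0.01 h (0.5% agreement on
the reference scenario), and the substrate balance is closed by an
independent trapezoid integral to 1%.

## Parameter estimation

**Growth-law regression.** `fit_monod` fits μ(S) = θ₁S/(θ₂+S) by
Nelder–Mead on the sum of squares from a double-reciprocal (1/μ vs 1/S)
start; it is meant for low-substrate designs (≈5–25 g/L) where inhibition
is negligible. `fit_haldane` adds the S²/K_I term for designs spanning
inhibitory substrate levels, with a documented default of 5 jittered
restarts. θ₁/θ₂ follow the regression convention (θ₁ = maximum rate, θ₂ =
saturation constant); an occasionally-seen mapping of θ₁, θ₂ onto K_S, K_I
is treated as an erratum. `fit_diagnostics` reports S_R, n, p, the
residual mean square S_R/(n−p) and curvature-based (finite-difference
Hessian) 95% confidence intervals; published S_R-style values without
their underlying data are treated as format examples only.

**Time-course fitting.** Residuals are weighted per variable by the
inverse squared observed range, so glucose (order 100 g/L) does not drown
biomass (order 1 g/L); weights are overridable. Bounds default to
[1e−6, 10] for rates and [1e−3, 1e4] for concentration-like parameters.
Simplex mode rejects out-of-bounds proposals with +∞; estimates within 1%
of a bound are reported as convergence warnings. MCMC mode wraps the same
weighted SSQ in a Gaussian likelihood with the conjugate error-variance
machinery below and reports posterior means.

## DRAM sampler

Random-walk Metropolis with two standard extensions, matching common DRAM
practice: (a) *adaptation* — from `adapt_start` (default 1,000 for
dose-response-sized problems, 200 for kinetics fits) and every
`adapt_interval` = 100 steps, the proposal covariance is re-estimated from
the full chain history, scaled by 2.38²/d plus a 1e−10 diagonal
regularizer; (b) *delayed rejection* — after a first-stage rejection, a
second proposal with covariance shrunk by dr_scale² (dr_scale = 1/5) is
tried with the two-stage acceptance ratio that preserves detailed balance.
Default chain lengths: 50,000 (dose–response), 4,000 (kinetics). Burn-in
default is 20%. With adaptation and delayed rejection disabled the sampler
reduces exactly to plain Metropolis (regression-tested against an
independently coded chain on the same RNG stream).

For Gaussian observation models the observation variance is Gibbs-drawn
each sweep from its scaled-inverse-χ² full conditional,
σ² ~ (n₀s₀² + SS(θ))/χ²(n₀+n), with a weak default prior (n₀ = 1, s₀² =
initial residual mean square); this `s2chain` feeds posterior-predictive
envelopes. Envelopes evaluate the model on rows drawn without replacement
from the post-burn-in chain and report central quantile bands (default
50/90/95/99%), which are nested by construction; with
`include_observation_noise` Gaussian noise at the matching s2chain draw is
added first. A NaN log-likelihood is treated as −∞ (rejection), never an
exception. All seeds are explicit; fixed seed ⇒ bit-identical chains. An
ambiguous published instruction to "repeat each dimension 500 times" is
exposed only as the optional `replicate_chains` helper, off by default.

## Synthetic data and what the tests show

`generate_survival_table` draws binomial dead counts under the logistic
dose model at the reference design (seven doses 50–80 Gy, ≈6,000 colonies
per dose). `generate_timecourse` overlays observation noise on the ODE
solution; the default is 2% multiplicative Gaussian per variable and time
point — typical OD/HPLC precision, stated explicitly wherever used —
clamped at zero. Zero sigma returns the exact simulation.

The generators produce data that satisfy the models' assumptions exactly
(independent binomials; i.i.d. multiplicative noise on an exact ODE
trajectory). Passing recovery tests therefore demonstrate estimator
correctness and identifiability under the stated conditions, not
robustness to real-data pathologies: lag phases, pH drift,
autocorrelated assay error, undissociated-acid speciation and gas-phase
effects are all outside the generator and the model. The recovery
experiments use 10 seeded replicates, 12 substrate levels (1–150 g/L) for
the growth law and 13 sampling times over 120 h for the batch — sizes at
which the estimators are well-conditioned and the full suite runs in
seconds.

## Packaged reference tables

Three small fixtures ship with the package: per-dose survival counts for
three irradiated samples, the 17-row screening table with footer counts
(P = 24, M = 81, T = 409), and the kinetic parameter set above. Fixtures
are transcribed verbatim, with two caveats surfaced in code and logs: one
survival row (sample H51-8, 55 Gy) prints its survivor count in the lethal
column — the fixture stores the self-consistent lethal count 2,070 and
keeps the printed proportion for validation — and two screening rows print
δ values inconsistent with their own productivities (flagged by
`delta_mismatch_log`, kept verbatim).

## Known limitations

- The kinetic model has no lag phase; early-time predictions overstate
  activity for cultures with significant adaptation time.
- K_I (and to a lesser degree K_S) is weakly identified unless the design
  spans well past the Haldane optimum; fits report curvature-based
  intervals that honestly widen in that case.
- The ODE parameter set is a point estimate; no hierarchical/batch-effect
  structure is modeled.
- Single-chain ESS is the only convergence diagnostic; no multi-chain
  R-hat (out of scope).
- pH dynamics, acid speciation (pK_a ≈ 4.8–4.9), gas transfer, fed-batch
  and continuous operation are out of scope.
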