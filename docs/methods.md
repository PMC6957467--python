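# Methods

This note documents the statistical model, the inference algorithm, the
synthetic-data generator, and the numerical and design choices behind
`anomort`, in enough detail to judge what the passing test suite does and
does not establish.

## The exposure metric

The anomaly of unit *i* (county or state) in calendar month *m* of year
*y* is `a = T[i,m,y] − (1/Y) Σ_y' T[i,m,y']`, the deviation from that
unit-month's mean over the analysis years. By construction the anomaly
series of every unit-month sums to zero over the years used to form the
baseline (enforced to 1e−9 in tests), and a warm-but-stable location has
smaller anomalies than a cooler but more variable one. County anomalies
are aggregated to states as `Σ_c w_c a_c / Σ_c w_c`.

Choices the metric leaves open, and what this package does:

* **Aggregation weights** — total (all-stratum) county population,
  interpolated monthly, rather than stratum-specific weights. Exposure is
  a property of where people live, not of their demographic cell, and
  monthly interpolation keeps the weights consistent with the population
  denominators used elsewhere.
* **Monthly population** — annual counts are anchored to July and
  interpolated linearly between anchors; months before the first or after
  the last July are extrapolated linearly from the nearest two anchors
  (anchors are reproduced exactly; a single-year series falls back to a
  constant with a warning).
* **Percentile definition** — all empirical quantiles (the 90th-percentile
  extreme measures, credible intervals) use the linear-interpolation
  order-statistic estimator.
* **Month-length adjustment** — the exceedance-day and episode counts are
  normalised to a 30-day month (× 30/n_days), so Februaries and
  31-day months are comparable.
* **Missing temperature values** are a hard error with the offending
  unit-months listed; the metric assumes a complete field (reanalysis-like
  input) and silent imputation would corrupt the baselines.
* **Gridded input** is accepted as anything `pandas`/`xarray` can deliver
  as a long (unit, date, temp) table; the tested path is long-format CSV.

## The model

Deaths in one analysis stratum (injury type × sex × age group) follow

```
deaths[s,t] ~ Poisson(exp(η[s,t]) · population[s,t])
η[s,t] = (α0 + β0 x_t) + (α_s + β_s x_t) + (α_m + β_m x_t)
       + ζ[s,m] + ψ[s,m] x_t + ν_t + γ_m a[s,t] + ε[s,t]
```

with `m = month(t)` and `x_t` the overall month index centred at the
series midpoint (units: months). Centring is our choice — it removes the
strong prior correlation between intercept and slope without changing the
model.

Priors: `α_s`, `β_s` are BYM (ICAR structured + iid unstructured, separate
precisions); `α_m`, `β_m` and `γ_m` are cyclic first-order random walks
(December adjacent to January); `ζ`, `ψ` are iid Gaussian (type-I
space–time interactions, one precision per block); `ν_t` is an RW1 over
overall time; `ε[s,t]` is iid Gaussian overdispersion. Every precision has
a Gamma(shape 1, rate 0.001) hyperprior — equivalently a log-gamma prior
on the log precision. The common slope has a N(0, 1000) prior; the flat
intercept prior is implemented as N(0, 1e6) for numerical regularity
(configurable).

**Identifiability.** Random-walk, state and interaction blocks are
constrained to sum to zero. The constraint is imposed by
reparameterisation: a block of size n is represented by n−1 free
coordinates z with x = Az, A = [I; −1ᵀ], so every represented value obeys
the constraint exactly — there are no soft constraints anywhere, and no
residual translation invariance remains against the global intercept.
Intercept and slope random-walk blocks carry separate precisions.

**The anomaly coefficients γ_m are deliberately *not* constrained.** Their
cyclic RW1 prior is improper in the constant direction, but that direction
is identified by the likelihood (it is the average anomaly effect, the
scientifically central quantity); a sum-to-zero constraint would force the
average effect to zero and make a warm-year scenario meaningless. The RW1
precision smooths only the month-to-month differences.

## Inference

The sampler is Metropolis-within-Gibbs on the exact posterior:

1. **Precisions.** Given the latent field, each block precision has an
   exact Gamma full conditional, `τ_b | x ~ Gamma(1 + r_b/2,
   0.001 + xᵀR_b x/2)` with r_b the block's structure rank; these are
   redrawn exactly every iteration.
2. **Latent field.** Given the precisions, the latent conditional is
   log-concave. Its Laplace (Gaussian) approximation is maintained by a
   damped-Newton recursion — two Newton steps per iteration from the
   previous *reference* mode, a deterministic function of the precision
   history, never of the current latent state — and the field is updated
   by a preconditioned Crank–Nicolson Metropolis step around that
   Gaussian: `x* = x̂ + α(x − x̂) + √(1−α²)·n`, `n ~ N(0, Q⁻¹)`. Because
   proposal and acceptance use the same reference Gaussian, the acceptance
   ratio is exactly the exact-to-Gaussian density ratio, and the kernel
   targets the exact conditional regardless of how good the Gaussian is.
   The retention α is adapted during warmup towards an acceptance of 0.35
   and frozen afterwards; in practice the Gaussian reference is so close
   that α adapts to ≈0 (independence proposals) with acceptance 0.5–0.8.

The observation-level overdispersion block is eliminated analytically
through a diagonal Schur complement, so each Newton step costs one
Cholesky of the structural block (~700 × 700 at the 20-state scale) plus a
sparse normal-equations product; a dense BLAS path is used when
`N·p²` is small.

**Draws and intervals.** 5,000 posterior draws by default; retained
iterations are thinned (or recycled when fewer were kept) to exactly the
requested count. Credible intervals are empirical 2.5th–97.5th percentiles
(linear interpolation).

**Diagnostics and convergence rule.** Split-chain R-hat is computed for
the monitored parameters — the fixed effects and every γ_m — and the mean
latent acceptance probability is tracked; R-hat above 1.01 (or acceptance
below 0.05) raises by default. Hyperparameter R-hats are reported but not
gated: weakly identified interaction/slope precisions mix slowly along
their prior-dominated plateaus without measurably affecting the monitored
posteriors, and gating on them would reject fits whose inferential targets
are fully converged. Simulation batches (e.g. the coverage study) run with
`on_nonconvergence="warn"` and record the diagnostics instead, since a
borderline R-hat on one replicate of fifty is sampling noise, not a
modelling failure.

**Fixed-precision path.** With every precision fixed there is no Gibbs
loop: draws come from the Laplace Gaussian, and for low-dimensional latent
instances (≤ 40 by default) they are importance-resampled against the
exact joint density, making the draws exact up to Monte-Carlo noise. On a
3-state × 24-month Poisson GLM this path agrees with an exhaustive
61³-point grid posterior to ~5e−4 on the log scale (tested bound 0.02),
and the resampling effective sample size is essentially the draw count.

## The synthetic-data generator

The generator is the package's study stand-in and defines the conditions
under which everything is validated:

* **Spatial structure** — a rook-adjacency lattice (default 4 × 5 = 20
  states; 48-state, 38-year generation uses the same code) in place of the
  contiguous-state contiguity graph.
* **Anomalies** — independent Gaussians per state-month with
  month-specific SDs tapering from 2.5 °C (December/January) to 0.6 °C
  (August/September), re-centred so each state-month's long-term mean is
  exactly zero, matching the metric's construction. Anomalies are treated
  as observed covariates, hence no spatial correlation by default (an
  ICAR-correlated option exists).
* **Latents** — every random-effect block is drawn from its constrained
  prior (Cholesky of the reduced structure matrix). Default scales:
  state/seasonal intercept SDs 0.1, interaction SD 0.05, overdispersion SD
  0.05, slope-block SDs 10⁻⁴–5·10⁻⁴ per month of overall time, RW1
  increment SD 0.01 — fields of a size that neither drowns nor trivialises
  the anomaly signal.
* **Fixed effects** — baseline rate 10⁻⁴ deaths per person-month
  (α0 = log 10⁻⁴, roughly tens of deaths per state-month at the default
  10⁶ population), trend β0 = log(0.8)/120 (a 20% decline per decade).
* **Anomaly effect** — γ_m follows a smooth seasonal curve,
  0.01 + 0.03·sin(2π(m−4)/12), ranging −0.02 to +0.04 per °C with its
  summer peak; magnitudes of a few percent per °C are the realistic order
  for injury-mortality associations.

What the generator does **not** emulate: real injury epidemiology
magnitudes beyond order of magnitude, age/sex heterogeneity (one stratum
by default), reporting artefacts, spatially correlated anomalies, or
non-linear temperature effects. Passing tests therefore demonstrate that
the estimator recovers the model's own truth at realistic signal-to-noise
— internal validity — not that any particular real-world estimate is
correct.

## Validation problem sizes

Parameter recovery runs at 20 states × 120 months with 1,500 retained
draws; interval coverage uses 50 replicates of a 5-state × 60-month null;
the grid-oracle comparison uses 3 states × 24 months; the full-scale
anomaly-metric summary uses 48 states × 38 years. These sizes keep each
check to minutes on a single CPU while leaving the per-month anomaly
coefficients well identified (posterior SDs 0.003–0.012 per °C at the
recovery scale).

## Other design decisions

* **Scenario arithmetic** — the excess relative risk is `exp(γ_m Δ) − 1`,
  so multiplying observed counts by it yields *additional* deaths; this is
  the only reading under which month-coefficients that are negative (falls
  in winter, say) produce the expected net declines. Reference-year counts
  enter as fixed constants; all aggregations are computed within draw
  before percentiles are taken, so interval endpoints respect the joint
  posterior. National ERRs applied to state-month counts and summed are
  arithmetically identical to pooling first.
* **Age standardisation** — direct standardisation against the US 2000
  standard population collapsed to the ten analysis age groups (0–4,
  ten-year groups to 84, 85+), configurable; monthly rates are annualised
  (×12) so monthly and annual groupings share a scale.
* **ICD mapping** — configuration-driven, revision chosen per record year
  (9th before 1999, 10th from 1999). The shipped default uses standard
  external-cause groupings (ICD-10: V01–V99 transport, W00–W19 falls,
  W65–W74 drownings, X60–X84+Y87 suicide, X85–Y09 assault; ICD-9:
  E800–E848, E880–E888, E910, E950–E959, E960–E969); other injury codes
  fall to "other", which is computed but excluded from modelling by
  default; non-injury codes are excluded with a logged count.
* **Degenerate inputs** — all-zero death series, zero aggregation weights,
  incomplete state×month grids, negative counts and non-positive
  populations are hard errors with the offending records named.

## Known limitations

* The latent update is exact but its efficiency rests on the Laplace
  reference being close; for extremely sparse counts (many empty cells)
  acceptance would drop and longer chains would be needed.
* Hyperparameter posteriors for weakly identified precisions (notably the
  interaction-slope block) are prior-dominated and mix slowly; their
  marginals should be read with that in mind.
* Anomalies are treated as error-free covariates; exposure measurement
  error is not propagated.
* The scenario is the stylised uniform-anomaly year only — no
  climate-model trajectories, and no Poisson uncertainty on reference-year
  counts.
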