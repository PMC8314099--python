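# Methods

## The model

`cptrend` fits non-linear mixed models to unbalanced longitudinal panels of
quarterly consumption rates (the motivating use case is antibiotic
consumption in the community, in DDD per 1000 inhabitants per day, observed
across countries). For country *i* at quarter *t<sub>ij</sub>* the observed
value is modelled as

Y<sub>ij</sub> = (β₀ + b<sub>0i</sub>) + (β₁ + b<sub>1i</sub>) t<sub>ij</sub>
  + Σ<sub>k=1..K</sub> (β<sub>k+1</sub> + b<sub>(k+1)i</sub>) (t<sub>ij</sub> − C<sub>k</sub>)₊
  + (β₀ˢ + b<sub>0i</sub>ˢ + β₁ˢ t<sub>ij</sub>) sin(ω t<sub>ij</sub> + δ) + ε<sub>ij</sub>

where x₊ = max(x, 0) is the hinge basis (so the piecewise-linear trend is
continuous at each change-point), ω = 2π/T with T = 4 quarters per year is a
fixed known constant — not a sampled parameter — and the C<sub>k</sub> are K
*common* change-points shared by all countries, with data-driven locations
C₁ < C₂ < … < C<sub>K</sub>. Random effects b<sub>i</sub> are independent
mean-zero Gaussians with component-specific variances (a diagonal
covariance; no cross-component correlation is modelled), and
ε<sub>ij</sub> ~ N(0, σ²<sub>ε</sub>) i.i.d. K = 0 reduces to a plain
linear-trend-plus-seasonality model.

Assumptions worth keeping in mind: Gaussian errors with constant variance on
the raw consumption scale; time enters on the raw 1..T<sub>max</sub> quarter
scale (no centering); the seasonal amplitude β₀ˢ + b<sub>0i</sub>ˢ + β₁ˢ·t is
unconstrained in sign (a negative amplitude is mathematically a phase flip);
the likelihood is *conditional* on the random effects — the marginal,
integrated-over-b form is never used as the model's likelihood. Missing
quarters are represented by absent records and contribute nothing, so
unbalanced panels need no imputation.

## Priors

All regression coefficients (β₀, β₁, each β<sub>k+1</sub>, β₀ˢ, β₁ˢ, δ) get
independent Normal(0, 1000) priors — mean 0, **variance** 1000 (the
equivalent precision is 0.001). C₁ is Uniform(1, T<sub>max</sub>) over the
whole time range; each subsequent C<sub>k</sub> is
Uniform(C<sub>k−1</sub>, T<sub>max</sub>), which fixes the ordering and
prevents label switching. Every variance component gets IGamma(0.001, 0.001)
in the shape–rate convention (x ~ IGamma(α, β) iff 1/x ~ Gamma(α, rate β),
so 1/x has mean α/β). `cp_upper` defaults to the largest observed time index
rather than a hard-coded 84, so panels of other lengths work unchanged.

The phase shift δ shares the vague normal prior and is not wrapped to
(−π, π]; the aliasing δ ↔ δ + 2π is accepted because the posterior
concentrates far inside one period whenever seasonality is present.

## Sampler

A Metropolis-within-Gibbs kernel, chosen because conditional on (C, δ) the
mean is linear in every coefficient:

* **Fixed-effect block** — one joint Gaussian draw. When random effects are
  being sampled, they are *integrated out* of this draw (each country
  contributes through its marginal covariance σ²I + Z D Zᵀ, handled with the
  Woodbury identity on small q×q matrices) and then redrawn conditionally;
  the pair is one exact blocked draw from the joint full conditional of
  (β, b). This partial collapsing matters: the plain alternation β | b,
  b | β leaves the nearly-flat direction β₀ + mean(b₀) (and likewise for the
  amplitude) mixing so slowly that effective sample sizes collapse to single
  digits. With clamped or absent random effects the plain conditional draw
  is used.
* **Per-country random effects** — Gaussian full conditionals.
* **Variance components** — inverse-gamma full conditionals.
* **δ and each C<sub>k</sub>** — random-walk Metropolis. Change-point
  proposals violating the ordered support are rejected through the prior;
  proposals leaving fewer than two distinct observed time points on either
  side are also rejected (the likelihood is nearly flat there, and the guard
  prevents boundary sticking). Because the ordered-uniform prior density of
  C<sub>k+1</sub> depends on C<sub>k</sub>, the Metropolis ratio uses the
  joint change-point prior, not just the moved coordinate's factor.

Proposal scales adapt toward ~30% acceptance in batches of 50 during
burn-in only, then freeze (continuing adaptation would break detailed
balance for the retained draws). Initialization is deterministic —
coefficients 0, variances 1, δ = 0, change-points at equally spaced
positions in the support — plus a small seed-controlled jitter that
differentiates chains. Chains run sequentially from independent spawned
seed streams; a fixed seed gives bit-identical draws.

The recommended production protocol is 2 chains × 110 000 iterations,
burn-in 10 000, thinning to every 5th draw. The validation suite and the
acceptance script use scaled-down protocols (2 × 8 000, burn-in 2 000,
thin 2 for the recovery fits; 2 × 20 000 for the zero-data prior-recovery
run; 2 × 2 000 for the 20 coverage replicates), sizes chosen as the
smallest at which the corresponding checks are statistically informative.

An empty panel is explicitly supported: the likelihood is identically one
and the sampler draws from the prior, which is how prior recovery is
validated (mean of C₁ ≈ 42.5, variance of β₀ ≈ 1000).

Convergence is operationalized as split r-hat ≤ 1.1 (plus effective sample
sizes) on all fixed effects, change-points and variance components,
computed by arviz; the threshold is configurable. Random effects are not
individually monitored.

## Model selection

DIC = D̄ + penalty with the *conditional* deviance D = −2 log L(y | θ, b).
D(θ̄) plugs in the componentwise posterior mean of everything sampled,
random effects included — the convention of hierarchical Gibbs software;
whether to condition on or marginalize over the random effects is a genuine
choice, and the conditional form is used and documented here. Both
penalties are always reported: pD = D̄ − D(θ̄) and pV = Var(deviance)/2
(useful because pD is not invariant to reparameterization and can go
negative). Selection takes the smallest DIC(pD) among converged fits by
default (`select_by="pv"` switches); non-converged fits stay visible in the
comparison table but are never selected — fitting more change-points than
the data contain typically manifests exactly as non-convergence.
Posterior means of change-points are plain means of the retained draws.

## Calendar convention

Time index 1 is the origin quarter (default 1997 Q1). A fractional index —
e.g. an estimated change-point at 44.529 — is mapped to the quarter it falls
*within*, i.e. floor(t): 44.529 → 2007 Q4, 29.028 → 2004 Q1,
48.839 → 2008 Q4. Rounding would misplace estimates with fractional part
above one half (round(44.529) = 45 → 2008 Q1).

## Synthetic panels

The generator draws from exactly the model above, so parameter-recovery
experiments are well-posed. Defaults describe a 25-country, 84-quarter
panel in the magnitude regime of community antibiotic consumption:
intercept 18.0, slope −0.017/quarter, two change-points at quarters 29 and
49 (integer-rounded for clean bookkeeping) with slope changes +0.054 and
−0.051, amplitude 3.8 shrinking by 0.012/quarter, phase 0.399, random
intercept variance 40.7, residual variance 1.65. Three missingness motifs
mimic how surveillance networks accumulate data, all completely at random
given the country's pattern class:

* late entry — with probability 0.4 a country loses an initial block of
  Uniform{1..40} quarters;
* intermittent gaps — each remaining cell is dropped independently with
  probability 0.05;
* right truncation — with probability 0.2 a country loses a terminal block
  of Uniform{1..12} quarters (up to three most recent years; the block
  length is the package's choice, as only the affected fraction is pinned
  down by the motivating data description).

What the generator does **not** emulate: non-random (informative)
missingness, autocorrelated residuals, heteroscedasticity, reporting-system
level shifts, or country-specific change-point locations. Passing
recovery tests therefore demonstrates correctness of the inference
machinery under the model's own assumptions, not robustness of the model to
real surveillance data's violations of them.

Because the model is Gaussian, small means can yield negative simulated
values; they are *retained* by default (the fitted model is Gaussian too,
and truncation would bias recovery experiments) behind an explicit
`allow_negative` container flag. `clip_negative=True` exists for display.
`load_panel` rejects negative values unless told otherwise, since real
consumption rates cannot be negative.

## Numerical choices

* Random-effect prior log-densities are computed on z-scored residuals so
  that astronomically large variance draws from the vague inverse-gamma
  tail cannot overflow to −∞ spuriously.
* Inverse-gamma sampling re-draws on gamma-variate underflow to zero
  (relevant only for the near-improper IGamma(0.001, 0.001) with no data).
* The fixed-effect and random-effect Gaussian draws use Cholesky
  factorizations of the posterior precision; the N(0, 1000) prior acts as a
  ridge, keeping the precision positive definite even when hinge columns
  are nearly collinear (a change-point proposal close to the data boundary).
* A fit with K change-points requires at least 2(K+1) distinct observed
  time points; otherwise the sampler refuses to start and advises fewer
  change-points.
* Ties/degenerate inputs: duplicate (country, quarter) records are a
  validation error; an empty panel is valid input (prior sampling).

## Validation design

The test suite validates the sampler against independent oracles rather
than against its own output: closed-form conjugate posteriors on clamped
sub-models (normal mean, inverse-gamma variance, and the collapsed marginal
with random intercepts), prior moments on zero-data runs, brute-force
per-point likelihood and prior density sums via scipy.stats, and a
re-evaluation oracle for D̄. The credible-interval coverage check runs 20
seeded replicates and requires ≥ 90 of the 100 (parameter × replicate)
95%-interval checks to cover the generating values; the aggregate count is
used because demanding ≥ 18/20 per parameter would fail ~8% of the time
per parameter by chance at nominal coverage.

## Known limitations

* K is fixed per fit; the number of change-points is chosen by DIC across
  fits, not sampled (no reversible jump).
* Random-effect covariances are diagonal; no correlation between a
  country's intercept and slope deviations.
* DIC is computed in conditional form only; absolute DIC values are
  dataset-specific and comparable only across models fitted to the same
  records.
* The phase-shift prior is non-wrapped; fits to panels with essentially no
  seasonality can wander across 2π aliases (harmless for the seasonal
  amplitude and predictions, visible in δ's trace).
* Single-country analyses should clamp the random effects
  (`fixed_params={"random_effects": 0.0}`) since country deviations are
  then redundant.
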