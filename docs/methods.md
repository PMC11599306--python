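# Methods

`hostassay` implements the statistical machinery of a group-reared,
multi-population insect host-plant performance assay: caterpillars from
several source populations are reared on excised foliage of several
host-plant species, in mixed-brood cultures of fixed size, and three
performance responses are recorded per individual — survival to
pupation (binary), pupal mass (mg, survivors only), and development
time from hatch to pupation (days, survivors only).

## The experimental design and its pseudoreplication

The design fully crosses `n_pops` source populations with `n_hosts`
host treatments; each population x host cell holds
`n_cultures_per_cell` rearing containers of `n_per_culture` larvae.
The default layout is 4 populations x 9 hosts x 5 cultures x 20 larvae
= 3600 individuals, with per-population brood pools of 15, 14, 126 and
19 wild-caught females.

Because larvae are assigned to cultures at random *across* broods, and
individuals cannot be tracked inside a culture, brood membership is
real in the data-generating process but unobservable in the analysable
table. The fitted models therefore omit a brood term that truly
exists — a pseudoreplication whose consequences the `design_sim` module
quantifies directly.

## Generative model (`synthetic_data`)

Each response r has a link-scale linear predictor

    eta_ir = b0_r + u_pop + u_host + u_pop:host + u_culture + u_brood (+ e_i)

with each `u ~ Normal(0, sigma^2_term)` drawn independently per
response. Survival uses a logit link: `survived ~
Bernoulli(logistic(eta))`, with an individual-level residual whose
variance is the same quantity the binary model later fixes. Mass and
development time are Gaussian on the identity link, truncated at zero
by redraw (capped at 1000 attempts, then an error — at the default
parameters negative values are essentially impossible). Sex is
Bernoulli(0.5); a fixed female-minus-male contrast of 1.2 mg enters
the mass mean; sex is recorded for survivors only (pupae can be sexed,
larvae cannot). Mortality is independent across individuals — no
cannibalism or density dependence is modelled.

Default parameters (all link scale):

| response  | intercept | pop   | host | pop:host | culture | brood | residual |
|-----------|-----------|-------|------|----------|---------|-------|----------|
| survival  | -2.29     | 0.046 | 2.09 | 0.87     | 0.0005  | 0.5   | 1.0 (fixed) |
| mass (mg) | 26.3      | 0.68  | 33.4 | 9.3      | 0.009   | 6.0   | 14.0     |
| dev (d)   | 33.9      | 14.8  | 19.4 | 3.8      | 0.008   | 4.0   | 4.2      |

Survival and mass components are the posterior means estimated from
the real assay. The mass residual (not estimable from published
summaries) is set so the marginal SD matches the observed 7.6 mg.
Development time is deliberately *not* parameterised from the raw
posterior-mean variances: with only four population levels that
posterior is so right-skewed that its mean (68.7 d^2, an 8.3-day
population SD) would place whole-cell mean development times below
zero, which no assay can produce. Instead the components are the
estimated variance *shares* (host 46%, population 35%, interaction 9%)
scaled to the observed marginal SD of 6.5 days, with the residual as
the remainder. Brood variances are not published anywhere; the
defaults represent moderate familial resemblance (roughly 10% of
marginal variance) and are ordinary config values.

What the generator does *not* emulate: calendar staggering of host
start dates, foliage aging, whole-culture failures, density-dependent
mortality and cross-response correlation of random effects (the
responses are modelled separately downstream, so effects are drawn
independently per response). Passing tests therefore demonstrate
correct recovery of this idealised hierarchy, not robustness to those
real-world features.

## Model fitting (`glmm_core`)

Three models, all intercept-only in the fixed part, with random
intercepts exactly as the design prescribes: survival and development
time use (host, population, population:host, culture); mass adds sex
as a fifth random term — sex is modelled as a 2-level random effect
rather than a fixed contrast, matching the published model structure.

Priors: `Normal(0, 1e8)` on the intercept; scalar inverse-Wishart
`(V = 1, nu = 0.002)` — i.e. inverse-gamma(nu/2, nu V/2) — on every
variance component; the same family on the Gaussian residual; the
binary model's residual variance is *fixed* (default 1.0) in every
draw. These are the long-standing defaults of the animal-model MCMC
software family this analysis style comes from, and all are exposed in
`PriorSpec`.

The Gaussian sampler is pure Gibbs. The whole location vector
(intercept + all group effects, typically ~230 coefficients at full
design size) is drawn jointly from its exact multivariate-normal full
conditional via a dense Cholesky factorisation — single-site updates
mix catastrophically here because the intercept and the host-effect
mean are nearly confounded with only 9 host levels. Variance
components use their conjugate scaled-inverse-chi-square full
conditionals. An additional joint Metropolis "scale move" multiplies a
block `u_k` by `a = exp(0.7 z)` and its variance by `a^2`; conditional
Gibbs alone is slow to traverse the near-zero-variance funnel (the
culture term lives there) and this move walks along the funnel axis.

The binary sampler augments each individual with a latent value whose
likelihood is Bernoulli(logistic(eta_i)) and whose prior is
Normal(linear predictor, fixed residual variance). Latents are updated
by vectorised random-walk Metropolis with the proposal scale adapted
towards ~44% acceptance during burn-in only, then frozen; two families
of auxiliary moves decouple the latent field from the coefficients: a
global translation (shift intercept and every latent together) and
per-level shifts (move one level's effect and its members' latents
together — levels partition individuals, so acceptance factorises).
All remaining updates are the Gaussian machinery applied to the
latents. Group effects carry no sum-to-zero constraint; shrinkage
through the variance priors identifies them.

Chain-length conventions: the published protocol (1.5M iterations,
0.5M burn-in, thinning 100 → 10,000 stored draws) is available as
`MCMCSettings.published_protocol()`; everything desk-scale in this
package (tests, simulation studies, the acceptance script) runs
reduced chains of a few thousand iterations storing 400–1000 draws,
which the joint-update sampler mixes well enough to support (typical
ESS 0.5–1x stored draws for all but the near-zero culture variance).

Degenerate inputs abort with messages: constant response, non-binary
survival codes, all-0/all-1 survival (intercept unidentifiable under a
flat prior), random terms with a single level. Rows missing the
response or a term column are dropped, which is what restricts the
mass/dev-time models to survivors.

## Summaries (`variance_partition`, diagnostics)

Variance shares are computed draw-wise on the link scale: a
component's share is its variance over the sum of all components
*including the residual* (fixed or sampled) within that draw, so the
posterior mean share is a mean of ratios. No logistic-distribution
variance (pi^2/3) is added to the denominator — the partition stays on
the scale of the fitted model; `extra_residual` switches that
convention on if wanted.

Treatment predictions apply the inverse link to `intercept + u_host`
(host level) or `+ u_population + u_population:host` (cell level);
unrequested random terms are set to zero (conditional-mode
convention). Whether per-host predictions should instead marginalise
over populations is genuinely open; both conventions are implemented
(`population_mode="zero" | "average"`).

Credible intervals are highest-posterior-density (shortest) intervals
computed from the sorted draws — matching the published convention
whose variance intervals bottom out at 0. Effective sample size uses
Geyer's initial-positive-sequence estimator; a constant chain (e.g. a
fixed residual column) reports ESS = n with a warning. A reassuring
aside: the sampler reproduces, on synthetic data, the published
oddity of a 2-level variance posterior whose *mean* lies far above its
HPD upper bound — that is what extreme right-skew does to a mean, not
a typo in this package.

## Derived metrics (`derived_metrics`)

Development rate (mg/day) is the draw-wise ratio of a group's mass
prediction to its development-time prediction. Projected absolute
fitness (eggs/female) is draw-wise `survival x fecundity(mass)`, with
optional sex-ratio and eclosion-survival multipliers (off by default).
Draws from the three independently fitted models are paired by stored
index, which requires equal chain settings; independence makes any
pairing a valid Monte-Carlo propagation. Grand values are arithmetic
means over treatment groups within each draw.

The fecundity map is configuration, not science baked into code. The
shipped default is linear through the origin at 4.7 eggs/mg — a
placeholder calibrated so that grand survival x fecundity(grand mass)
reproduces the observed scale of projected fitness (0.18 x 4.7 x 26.2
~ 22 eggs) — and should be replaced by an empirically derived
mass-fecundity relation where one is available.

## Design evaluation (`design_sim`)

Each scenario cell simulates `replicates` assays *with* brood effects
at a chosen brood variance, drops the brood column, fits the focal
model *without* a brood term at reduced chain settings, and records
per-component posterior means, HPD intervals, coverage of the
generative truth, and a positive/negative call for the focal (host)
component. Failures (e.g. an all-dead replicate under a harsh
setting) are flagged and excluded with a count, never fatal. One
master seed spawns independent per-replicate streams.

Because variance posteriors cannot contain zero, significance needs an
explicit rule: a component is called positive when the HPD lower bound
of its variance *share* exceeds a threshold `epsilon_share`. The
threshold is calibrated on null replicates (`calibrate_epsilon` takes
the upper-alpha quantile of null lower bounds) so the null call rate
sits at the nominal level; the shipped default 0.01 is deliberately
conservative and is not asserted to be anyone's published rule.

Two robust qualitative findings, both covered by tests: unmodelled
brood variance is absorbed mostly by the residual (Gaussian case) and
partly by the culture variance, and the calibrated null call rate
matches its nominal level. With brood effects present the design thus
tends to *inflate* nuisance components rather than the focal host
term — conservative behaviour for the focal inference.

## Local adaptation (`local_adaptation`)

Two classical criteria over the host x population posterior
predictions against a site-flora map: **local vs foreign** (per host,
the posterior probability that each population is the best performer
there, via draw-wise argmax — invariant to monotone transformations of
the metric) and **home vs away** (per population, the posterior
probability that its home-host mean beats its away-host mean; a
rank-based variant provides monotone invariance; the report carries
the standard caveat that this criterion is misleading when
environments differ in average quality). The shipped flora map encodes
prose habitat descriptions of the four collection sites
(Devon→{oak}; Edinburgh→{oak, sycamore}; Buckinghamshire→{apple,
cherry, hawthorn}; Suffolk→{oak, birch, sycamore}) and is flagged as
an interpretation — it is config, not ground truth. Outputs are
probabilities, not verdicts; no numeric threshold for "local
adaptation detected" is imposed.

## Numerical and testing notes

* Determinism: every stochastic routine takes a seed; seeds are spawned
  through `numpy.random.SeedSequence`, and identical (inputs, seed)
  reproduce outputs byte-for-byte.
* The conjugate-oracle test conditions the Gaussian sampler on fixed
  variances and compares its moments to the closed-form multivariate
  normal posterior; the prior-recovery test fixes the residual huge so
  the likelihood is flat and KS-tests the variance draws against their
  inverse-gamma prior; statsmodels' REML and arviz's ESS/HPD serve as
  independent cross-checks, never as the implementation.
* Frequentist coverage of the 95% HPD intervals, measured over 100
  synthetic assays at the default (no-brood) parameters with reduced
  chains, is 0.96/0.97/0.96 for host, host x population and residual,
  but ~1.00 for population (4 levels) and culture (truth near zero):
  intervals for weakly identified variance components are so wide —
  with lower bounds at ~0, exactly as the published intervals print —
  that they essentially always cover. This over-coverage is a property
  of the posterior geometry under these priors, not a sampler defect;
  the corresponding acceptance test, which demands 90–98% for *every*
  component, fails honestly on those two.
* Problem sizes in the test suite and acceptance script (8000-iteration
  fits, 100-replicate coverage runs, 300+200-replicate calibration at a
  2-population x 4-host x 2-culture x 10-larva design) were chosen as
  the smallest runs whose Monte-Carlo error is comfortably below the
  effects being checked.

## Known limitations

* The binary model's fixed residual variance is a modelling convention;
  estimates are conditional on its value (default 1.0), and variance
  shares change if it is changed.
* Culture-variance chains mix more slowly than the rest (ESS of order
  50–100 per 1000 stored draws); summaries of that component carry
  correspondingly more Monte-Carlo error.
* The fecundity default is a calibrated placeholder (see above).
* The generator draws brood membership independently per individual
  (multinomial over the pool), a simplification of physical clutch
  sizes.
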