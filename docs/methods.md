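# Methods

`leksim` is a virtual-ecologist framework for lek-count monitoring of a
declining prairie grouse population: it simulates the true demographic
process, overlays a lek-attendance and detection observation process, fits
two Bayesian trend models to the simulated counts, and measures how far the
estimated long-term growth rate and abundance sit from the simulated truth.

## Process model (individual-based simulation)

Each of `n_sites` independent sites carries integer head counts in four
classes: {female, male} × {second-year SY, after-second-year ASY}.  A year
advances through reproduction → annual mortality → aging.  Lek attendance
is *not* part of the process model; it only filters what observers can see.

Vital rates are parameterized by literature means and SDs (Kansas lesser
prairie-chicken estimates; see `default_vital_rates()`).  Each site-year
independently realizes one value per rate from a truncated normal
(probabilities to [0, 1], clutch sizes to [0, ∞); zero-SD rates stay at
their mean).  All individuals at a site share the realized rates within a
year while their fates remain independent Bernoulli trials, drawn as
binomials per class.  Drawing rates per site-year (rather than fixing them
per site or per run) is deliberate: rate draws held constant over 25 years
let occasional sites realize a super-critical growth rate and explode,
which contradicts the universal collapse to fewer than 10 pooled birds that
the study design requires.

Fecundity per female of age class *j* follows the two-attempt chain

    F_j = [NP·C1·S1_j + (1 − S1_j)·R·C2·S2_j] · cs · js · 0.5 · h

(NP nesting propensity, C1/C2 clutch sizes, S1/S2 age-specific nest
success, R renesting probability, cs chick survival to 60 d, js juvenile
survival to the next breeding season, h per-egg hatchability, 0.5 offspring
sex ratio).  Note that NP weights only the first-nest term: the renesting
pathway is conditioned on first-nest failure alone.  The stage-wise
simulator draws the first-nest success lottery for every female, applies
propensity among successes, and offers renesting to all failures, so its
expectation equals F_j exactly.  Realized clutch sizes are rounded
half-up to integers per site-year (bias < 2% at clutch ≈ 10.8 eggs; the
simulator-vs-closed-form test allows for it explicitly).

Recruits carry first-year survival inside F_j, so they do not additionally
pass through annual mortality in their birth year; they appear at the next
pre-breeding census as SY birds.  Females survive with the product of
breeding- and non-breeding-season survival; males with the adult male rate.
At table means the female multiplier (survival + fecundity) is ≈ 0.72, so
the population declines to pseudo-extinction within the 25-year horizon;
about 99.2% of site-simulations at the default initialization (50 F + 50 M
at 60:40 ASY:SY) are fully extinct by year 25.

## Observation model

Each year a site's attending abundance `N_LEK` is drawn by thinning the
census: per-class attendance probabilities realize with truncated-normal
noise (SD 0.1), then each individual attends independently.  Three regimes:
perfect (everyone), fixed age-sex rates (SY males 0.60, ASY males 0.80,
females 0.30), and density-based, where all males attend with
γ = min(1, K/N_males) for lek carrying capacity K = 25 males (females keep
0.30; females are excluded from N_males).  Attendance is annual — `N_LEK`
is held fixed across the two survey occasions of a year, so within-year
closure holds in the simulated data by construction.

Each occasion then records `Binomial(N_LEK, p)` birds.  Detection regimes:
perfect, fixed (0.25 / 0.375 / 0.5), Uniform(0.25, 0.75) drawn per site,
per year, or per site-year, and a linear trend 0.75 − 0.03·(t − 1) clamped
at 0.25.  Thirteen scenarios combine these regimes; the "N" variants mark
that the counts are analyzed with the N-mixture model (the simulated data
are identical).

Random streams are split per (simulation, site) between process and
observation, so scenarios sharing a master seed have bit-identical true
trajectories and differ only in observation — attendance/detection effects
are therefore never confounded with process noise.

## Estimators

Both models share the latent multiplicative-growth process

    N[i,t] = N[i,t−1]·λ[i,t],   λ[i,t] ~ Gamma(r, β),
    r = λ̄²/σ_λ²,  β = λ̄/σ_λ²,

so the growth multipliers have mean λ̄ and SD σ_λ, with priors
λ̄ ~ Gamma(0.10, 0.10) and σ_λ ~ Gamma(3, 1) and all sites fitted jointly.
The **state-space** model observes the per-site-year maximum of the two
occasion counts as `y ~ Poisson(N)` — no detection correction.  The
**N-mixture** model observes both occasions as `y_j ~ Binomial(X, p)` with
integer latent `X ~ Poisson(N)` and a Beta(1, 1) prior on detection p.
`λ̄_sim` is the plain mean of the λ̄ draws over all kept iterations.

**Initial-abundance prior.**  N[i,1] gets a scale-invariant log-uniform
prior on [10⁻³, U], U = 10·(max count + 1) (`init_upper_factor`).  A flat
Uniform(0, U) prior is untenable for the two-occasion N-mixture: along the
ridge where all abundances scale up and p scales down, flat-prior volume
grows with the scale and overwhelms the likelihood's identification of p,
so the posterior piles up against U with p near the corresponding floor (we
measured the likelihood penalty at ~90 log units against a prior-volume
gain of ~I·log s).  The log-uniform prior removes the volume term; detection
recovery on self-generated data is then unbiased with nominal coverage.

**Detection structure.**  The fully saturated per-site-year Beta(1, 1)
detection is weakly identified with two occasions; the default is one
shared p, with `p_structure ∈ {shared, by_year, by_site_year}` available.
Under `by_year` the fits reproduce the qualitative pathologies the
saturated model shows on these data: detection underestimated in the early
years and abundance correspondingly overestimated, before both settle.

**Sampler.**  No probabilistic-programming backend is used; sampling is a
vectorized Metropolis-within-Gibbs engine (`leksim._gibbs`) on θ = log N:

- checkerboard random-walk updates of the year columns (odd/even columns
  are conditionally independent given the other parity), adapted by
  Robbins–Monro during warmup to 44% acceptance;
- per-site level shifts and trend tilts, plus a global trend tilt, which
  mix the site scale and λ̄ directions that single-cell moves traverse
  slowly;
- scalar log-random-walk updates of (λ̄, σ_λ) given the sufficient
  statistics of the λ field, eight repetitions per sweep;
- an occasional prior-independence rejuvenation move proposing
  (λ̄, σ_λ, all λ) from the prior — with data it is almost always rejected;
  with no data it makes the sampler reproduce the prior exactly, which the
  test suite checks by PIT uniformity (the Gamma(0.10, 0.10) prior has
  extreme mass near zero; log-space Gamma draws via the shape-boost
  identity keep those trajectories representable);
- for the N-mixture, a collapsed block built on the bivariate-Poisson
  representation of two binomial-thinned occasions
  (y₁ = A + C, y₂ = B + C with A, B ~ Pois(Np(1−p)), C ~ Pois(Np²)):
  Metropolis updates of p on the logit scale and of the joint
  abundance/detection scale (translate all θ, counter-move p so N·p is
  preserved) under the X-marginalized likelihood, followed by an exact
  conditional redraw of X (Gumbel-max draw of the shared component C plus a
  Poisson remainder).  Collapsing X is what removes the detection/abundance
  ridge that defeats cellwise samplers on this model.

Defaults are 3 chains of 2,000 warmup + 2,000 kept sweeps; convergence is
flagged (as a `ConvergenceWarning`, never silently) when the rank-normalized
split R-hat of λ̄ or σ_λ exceeds 1.05 (computed via ArviZ when ≥ 2 chains
are run).  Posterior correctness is established by parameter-recovery tests
on data simulated from the models themselves: 95% intervals for λ̄, σ_λ and
p cover the generating values in ≥ 18/20 seeded replicates, and the no-data
posterior matches the prior.

## Evaluation

The true long-term growth rate of one simulation is the averaged geometric
mean of site-level annual ratios: per site, the product of
N[i,t]/N[i,t−1] over consecutive-year ratios with positive numerator and
denominator, taken to the power 1/(number of included ratios), then
averaged over sites.  Ratios touching extinct years are log-undefined and
excluded; a site with no valid ratio is dropped with a logged warning.  The
root makes λ̄_true an annual rate commensurate with λ̄_sim (the bare-product
variant is available via `annualize=False` but collapses toward zero over
24 transitions).  Bias is θ_s = λ̄_sim,s − λ̄_true,s per simulation,
summarized by its mean and empirical 2.5%/97.5% quantiles.  Abundance
overlap is assessed on pooled totals: the first year whose 95% credible
interval for Σᵢ N[i,t] contains the true pooled abundance.

A generic `sensitivity_sweep` reruns simulate + fit over a grid of
detection probability p or lek carrying capacity K and reports λ̄_sim, θ and
the finite-difference sensitivity.

## Problem sizes

The demographic results (extinction frequency, pseudo-extinction) are
computed at the full study scale: 100 simulations × 300 sites × 25 years.
Estimator-dependent results use a reduced design that preserves the
qualitative structure — 20 simulations × 100 sites × 25 years with
shortened chains (state-space: 1 chain, 500 + 500 sweeps; N-mixture:
1 chain, 400 + 400) — chosen as the package's desk-scale defaults for the
scenario study; the test suite's grid fixtures run slightly shorter chains
still, and recovery tests use 2 chains of 800 + 800.  Modal overlap years
and pooled growth-rate quantiles were checked to be insensitive to doubling
the chain lengths.

## What the generator does and does not emulate

The generator reproduces the study conditions: demographic stochasticity at
the individual level, environmental noise through per-site-year rate
draws, availability bias through lek attendance, and detection error
through binomial thinning.  It does not include movement between sites or
leks, density dependence in vital rates, individual heterogeneity or
heredity, observer covariates, or lek-level detection failure (a whole lek
missed).  Passing tests therefore say nothing about those processes in real
surveys; in particular, real lek counts confound temporary emigration with
detection in ways the closed two-occasion design here deliberately
excludes.

## Known limitations

- The site-extinction frequency is slightly higher (~99.2%) than the
  published 98.5%; with the printed vital rates the residual depends on
  unpublished details of the original simulation code.  The same vitality
  gap shifts the bias baseline: the uncorrected growth estimate tracks the
  arithmetic mean of the annual multipliers while λ̄_true is a geometric
  mean, and the faster, noisier crashes here widen that gap to ≈ +0.03
  even under perfect detection, so the bias ordering across scenarios is
  reproduced more cleanly than its absolute zero point.
- λ̄ cannot represent true extinction (Gamma multipliers are positive), so
  fits to all-zero tails shrink toward the shared decline rate rather than
  crashing to zero.
- The N-mixture sampler is specialized to exactly two occasions (the
  bivariate-Poisson collapse); more occasions would need the multivariate
  generalization.
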