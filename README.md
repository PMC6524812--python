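# leksim

Virtual-ecologist evaluation of lek-count monitoring for declining grouse
populations.

Male-based lek surveys are the standard way to monitor lekking species such
as the lesser prairie-chicken (*Tympanuchus pallidicinctus*), yet the
demographic processes that drive population change act mostly through
female survival and reproduction. `leksim` asks whether lek counts can
recover the true long-term population growth rate when lek attendance and
detection are imperfect. It does so by simulating everything: an
individual-based demographic model generates the true populations, an
observation layer converts them into repeated lek counts under thirteen
attendance × detection scenarios, and two Bayesian models — the ones a
field program would use — are fitted to the simulated counts and judged
against the simulated truth.

The package is aimed at quantitative ecologists evaluating monitoring
designs, and at anyone who needs a transparent, reproducible testbed for
N-mixture and state-space trend estimation on count data.

## The model in brief

**Process.** Each site holds {female, male} × {SY, ASY} head counts,
initialized at 50 + 50 birds (60:40 ASY:SY). A year runs reproduction →
mortality → aging with literature vital rates realized per site-year
(truncated-normal noise). Fecundity per female of age class *j* is

    F_j = [NP·C1·S1_j + (1 − S1_j)·R·C2·S2_j] · cs · js · 0.5 · h

with NP nesting propensity, C1/C2 clutch sizes, S1/S2 nest success, R the
renesting probability, cs/js chick and juvenile survival, h hatchability.
At the default rates the population declines to pseudo-extinction within 25
years.

**Observation.** A year's attending birds N_LEK are a thinned census (SY
males 0.60, ASY males 0.80, females 0.30, or density-based male attendance
γ = min(1, K/N_males) with lek carrying capacity K = 25), and each of two
occasions records Binomial(N_LEK, p) birds under fixed, random, or trending
detection p.

**Estimation.** Both estimators share the latent growth process
N_{i,t} = N_{i,t−1} λ_{i,t}, λ_{i,t} ~ Gamma(r, β) with r = λ̄²/σ_λ²,
β = λ̄/σ_λ² and priors λ̄ ~ Gamma(0.10, 0.10), σ_λ ~ Gamma(3, 1). The
state-space model observes max counts as y ~ Poisson(N); the N-mixture
model observes both occasions as y_j ~ Binomial(X, p), X ~ Poisson(N),
p ~ Beta(1, 1). Sampling is a purpose-built vectorized
Metropolis-within-Gibbs engine (see `docs/methods.md`). Bias is
θ_s = λ̄_sim − λ̄_true, with λ̄_true the averaged geometric mean of the true
annual growth ratios.

## Worked example

Simulate the fixed-detection scenario (p = 0.5, age-sex attendance) at a
reduced scale, fit the state-space model, and compare against truth:

```python
import leksim as lk
from leksim.estimators import MCMCSettings

cfg = lk.scenario_config(7, n_sims=1, n_sites=100, n_years=25, master_seed=42)
result = lk.run_scenario(cfg)
post = lk.fit_state_space(result.max_counts[0],
                          MCMCSettings(chains=2, warmup=600, draws=600, seed=0))
lt = lk.lambda_true(result.true_total[0])
lo, hi = post.credible_interval("lambda_bar")
print(f"lambda_true            = {lt:.3f}")
print(f"lambda_sim (posterior) = {post.lambda_bar_sim:.3f}  95% CI ({lo:.3f}, {hi:.3f})")
print(f"bias theta             = {lk.bias(post.lambda_bar_sim, lt):+.3f}")
```

prints

```
lambda_true            = 0.680
lambda_sim (posterior) = 0.726  95% CI (0.715, 0.737)
bias theta             = +0.045
```

The population truly shrinks about 32% per year (λ̄_true = 0.68). The
uncorrected lek-count fit also sees a collapsing population (λ̄ well below
1) but overestimates the growth rate by +0.045: detection below 1 hides
part of the decline. This is the study's central effect, and the scenario
grid quantifies it under every attendance/detection regime.

The same pipeline is scriptable from the shell:

```sh
leksim simulate --scenario 7 --sims 1 --sites 100 --years 25 --seed 42 --out run/
leksim fit --model statespace --counts run/counts.csv --simulation 1 --out fit.json
leksim evaluate --truth run/truth.csv --counts run/counts.csv --out eval.json
leksim reproduce --scenarios 1-13 --sims 20 --sites 100 --seed 7 --out bias.csv
```

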