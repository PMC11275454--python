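# dynocc — seasonal habitat use from camera-trap data

`dynocc` fits Bayesian **dynamic (multi-season) occupancy models** to
monthly camera-trap detection histories, for ecologists who want to ask
*when* a species uses a site, not just whether it does: seasonal range
expansion and contraction, and how colonization and desertion of sites
respond to covariates such as elevation and rural human population
density, all while correcting for imperfect detection.

## Model

Detection histories follow a robust design — months (secondary periods)
nested in alternating summer/winter seasons (primary periods).  The latent
*use* state z of site *i* in season *t* evolves as

    z[i,1] ~ Bernoulli(ψ[i,1])
    z[i,t] ~ Bernoulli( z[i,t−1]·(1 − ε[i,t−1]) + (1 − z[i,t−1])·γ[i,t−1] )

with colonization probability γ and desertion probability ε, and monthly
detections follow

    y[i,j,t] ~ Bernoulli( z[i,t] · p*[i,j,t] ),    p* = 1 − (1 − p)^days

where `days` is the camera's active days that month (so p is a daily
detection probability).  ψ, γ, ε and p are logit-linear in site and season
covariates with a random area intercept; three fixed model variants differ
in the γ/ε formula (`additive`: season + elevation + popden;
`interaction_popden`: season × popden; `interaction_elevation`: season ×
elevation).  Priors are logistic(0,1) on intercepts, N(0,1) on slopes and
half-normal scales for the random effects.  The likelihood is marginalized
over z by a forward recursion; latent states are recovered by
forward-filter backward-sampling.  Posterior sampling uses an adaptive
Metropolis sampler with curvature-seeded proposals and interweaving moves
for the hierarchical block, with split R-hat convergence checks
(threshold 1.1), and model
adequacy is assessed by posterior-predictive χ² checks of the closed
(detection) and open (transition) parts — Bayesian p-value
Pr(χ²_rep > χ²_obs) near 0.5 and lack-of-fit ratio χ²_obs/χ²_rep near 1
indicate an adequate model.  See `docs/methods.md` for the full account.

## Worked example

Simulate a small survey from the model's own generative process, fit the
additive variant, and check convergence and fit:

```python
import dynocc as dc
from dynocc.inference import McmcConfig

scenario = dc.default_scenarios()["reduced"]     # 40 sites, 4 areas, 6 seasons
dataset, truth = dc.simulate(scenario, seed=7)

config = McmcConfig(n_chains=3, n_iter=60_000, n_burnin=30_000, thin=6, seed=1)
samples = dc.fit(scenario.spec, dataset, mcmc=config)
report = dc.diagnose(samples)
print(f"converged: {report.converged} (max R-hat {report.max_rhat:.3f})")

rows = ["gamma_int", "gamma_season[winter]", "eps_int", "eps_season[winter]"]
print(dc.summarize(samples).loc[rows].round(2))

gof = dc.posterior_predictive_gof(samples, scenario.spec, dataset, rng=0, n_draws=250)
print(f"Bpv closed = {gof.bpv_closed:.2f}, Bpv open = {gof.bpv_open:.2f}")

use = dc.proportion_used(samples, scenario.spec, dataset, rng=0, n_draws=300)
for s, lab, m, lo, hi in zip(use.season, use.label, use.mean, use.lo, use.hi):
    print(f"season {s} ({lab}): {m:.2f} [{lo:.2f}, {hi:.2f}]")
```

Output (a few minutes on one core):

```
40 sites, 6 seasons, 30 months
converged: True (max R-hat 1.081)
                      mean    sd    lo    hi  excludes_zero
parameter
gamma_int            -0.92  0.52 -1.93  0.16          False
gamma_season[winter]  1.85  0.51  0.92  2.91           True
eps_int              -0.66  0.40 -1.51  0.11          False
eps_season[winter]   -1.60  0.56 -2.71 -0.55           True
Bpv closed = 0.24, Bpv open = 0.60
season 1 (summer): 0.48 [0.47, 0.50]
season 2 (winter): 0.38 [0.33, 0.47]
season 3 (summer): 0.83 [0.82, 0.85]
season 4 (winter): 0.61 [0.57, 0.65]
season 5 (summer): 0.83 [0.82, 0.85]
season 6 (winter): 0.55 [0.47, 0.62]
```

The season contrasts recover the generating signal (true values +2.5 and
−1.5): colonization is higher into summer (`gamma_season[winter]` is the
winter-origin contrast) and desertion lower, both flagged as excluding
zero; the proportion of sites used alternates in a summer-high sawtooth;
and the posterior-predictive p-values fall in the mid-range, as they
should when the fitted model is the generating one.

The same pipeline is available from the shell:

```bash
dynocc simulate --scenario strong_seasonality --seed 1 --out data/
dynocc fit --data data/ --model additive --seed 1 --out fit/
dynocc gof --fit fit/ --data data/ --out gof.json
dynocc predict --fit fit/ --data data/ --what use --out use.csv
```

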