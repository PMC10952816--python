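# msam — hierarchical multi-species N-mixture abundance models

`msam` estimates the breeding abundance of a species community from
repeated count surveys in which individuals are detected imperfectly. It
was built for floodplain amphibian monitoring — egg-mass and larval counts
at waterbodies along a hydrological connectivity gradient — but applies to
any repeated-count community survey with site and survey covariates.

## The model

Counts of species *i* at site *j* on survey *k* follow an N-mixture
hierarchy with community-level shrinkage across species:

    N_ij  ~ Poisson(λ_ij),    log λ_ij  = β0_i + β1_i Area_j + β2_i x1_j + β3_i x2_j + ε_j
    C_ijk ~ Binomial(N_ij, p_ijk),  logit p_ijk = α0_i + α1_i Days_jk + α2_i Temp_jk
    β_ci  ~ Normal(μ_λc, σ_λc²),    α_di ~ Normal(μ_βd, σ_βd²),   ε_j ~ Normal(0, σ_ε²)

The latent abundance `N_ij` is separated from detectability `p_ijk` by the
repeat surveys; the community distributions (`μ`, `σ`) pool information so
rare species borrow strength from common ones; `ε_j` absorbs site-level
overdispersion. Site covariates are z-scored composites: sampled area
(log10) plus first principal components of habitat-structure, chemistry,
hydrology and landscape blocks, each PC sign-anchored (e.g. positive
hydrology scores = disconnected waterbodies). Fitting is by a built-in
Metropolis-within-Gibbs sampler with the discrete latent N sampled exactly
from its truncated full conditional; candidate covariate sets are ranked by
WAIC; fit is checked with a Freeman–Tukey posterior predictive p-value.
See `docs/methods.md` for the full account.

## Worked example

Simulate a community from the model's own hierarchy, fit it, and summarise
the community response:

```python
from dataclasses import replace
from msam import CommunityAbundanceModel, McmcConfig
from msam.experiments import calibration_scenario
from msam.simulate import simulate_dataset

sim = simulate_dataset(replace(calibration_scenario(), seed=5))
model = CommunityAbundanceModel.from_simulation(sim)
res = model.fit(McmcConfig(n_chains=2, n_iter=12_000, n_burnin=4_000,
                           thin=10, seed=42))
print(res.summary().loc[["mu_lambda[x1]", "mu_lambda[x2]", "mu_beta[temp]"]]
      .round(3).to_string())
print("max R-hat:", res.rhat_table().max().round(3))
print("Freeman-Tukey p:", res.ppc(seed=0).bayesian_p)
```

prints (truth: x1 effect +0.8, x2 effect −0.4, temperature effect +0.8):

```
                Mean     SD  2.5th  97.5th  important  important_90
parameter
mu_lambda[x1]  0.755  0.189  0.379   1.144       True          True
mu_lambda[x2] -0.238  0.193 -0.618   0.138      False         False
mu_beta[temp]  0.543  0.234  0.079   1.031       True          True
max R-hat: 1.051
Freeman-Tukey p: 0.513125
```

Every 95% credible interval covers its generating value; the positive x1
and temperature effects are flagged important (interval excludes 0) while
the weaker x2 effect is not resolved at this sample size; all parameters
pass the R̂ < 1.1 convergence rule; and the posterior predictive p-value
sits mid-range (no lack of fit).

The packaged 30-site floodplain survey table ships with the package:

```sh
$ msam table1
sites: 30
Bufbuf larvae detected at 11 sites
Hylarb larvae detected at 4 sites
Pelcom larvae detected at 6 sites
Randal egg_mass detected at 20 sites
Randal larvae detected at 4 sites
% days connected: mean 36.3, SD 35.7, range 0-100
large fish richness: mean 4.5, SD 2.5, range 0-8
fish vs connectivity r = 0.703
ephemeral sites: 5
```

A full pipeline run (simulate → prepare → fit nine candidate models →
WAIC ranking → summaries, curves, convergence report, manifest):

```sh
msam all -c examples/demo_config.yaml -o demo_out
```

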