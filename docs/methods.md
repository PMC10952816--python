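# Methods

## The model

`msam` fits a hierarchical multi-species N-mixture model to repeated count
surveys of a breeding community. For species *i* at site *j* on survey *k*:

```
N_ij   ~ Poisson(lambda_ij)
log lambda_ij = b_0i + b_1i Area_j + b_2i x1_j + b_3i x2_j + eps_j
C_ijk  ~ Binomial(N_ij, p_ijk)
logit p_ijk   = a_0i + a_1i Days_jk + a_2i Temp_jk
```

`N_ij` is the true (latent) abundance, `C_ijk` the observed count, and
`p_ijk` the per-individual detection probability. Site covariates are
z-scored; sampled area (log10, z-scored) is always included to absorb
survey-effort differences, plus at most two further site covariates per
candidate model. Detection is driven by days since 1 February (breeding
phenology) and water temperature (activity). `eps_j ~ Normal(0, sigma_eps^2)`
is a shared site-level overdispersion term on log abundance: one draw per
site, common to all species, the literal reading of its subscript.

Species coefficients are exchangeable draws from community distributions,
`b_ci ~ Normal(mu_lambda_c, sigma_lambda_c^2)` and likewise for detection —
the "borrowing strength" device that stabilises estimates for rarely
observed species.

### Priors

* Community means: Normal with location −1 (intercepts) or +1 (slopes) and
  scale 5. The scale's meaning is ambiguous across MCMC engines, so it is
  interpreted as a **variance** by default (sd ≈ 2.236) with a
  `{variance|sd|precision}` switch on `PriorSpec`.
* Community sds: Uniform(0.01, 0.5).
* `sigma_eps`: Uniform(0, 1); the uniform prior is placed on the sd of the
  overdispersion term, not on `eps_j` itself.

These are weak on the z-scored design scale. Note the Uniform(0.01, 0.5)
support is a genuine modelling constraint: a community whose species differ
by more than ±0.5 in a standardized coefficient cannot be represented.

## Covariate preparation

Raw site variables come in four blocks (habitat structure, water chemistry,
hydrology, landscape). Each block is reduced to its first principal
component; the per-site PC1 score is the composite gradient entering the
abundance predictor. Conventions:

* PCA is of the **correlation** matrix by default (blocks mix units such as
  % cover and µS/cm); `PrepConfig.scale_pca=False` switches to covariance.
* PC orientation is pinned by a per-block **anchor**: hydrology is oriented
  so `pct_connected` loads negative (positive scores = disconnected,
  isolated waterbodies) and landscape so forest cover loads negative
  (positive scores = agricultural surroundings). Anchors are configurable.
* PC1 scores are re-z-scored before entering the model so their coefficient
  scale matches the other covariates.
* Missing water-chemistry readings are mean-imputed before the PCA.
* Area and nearest-neighbour distance are log10-transformed, then z-scored.
* Days and Temp are z-scored jointly over all site × survey cells.
* Pairs of prepared covariates with |r| ≥ 0.7 are reported by the
  correlation screen (the conventional collinearity alarm).

## Sampler

Fitting is Metropolis-within-Gibbs with explicit data augmentation of the
discrete latent abundances:

1. `N_ij` is drawn **exactly** from its full conditional on the truncated
   support `[max_k C_ijk, K_trunc]` by Gumbel-max sampling over a
   log-weight table. The count-dependent part of the table is precomputed
   once; per iteration only the term linear in N changes.
2. Species detection and abundance coefficient vectors: one joint
   random-walk Metropolis proposal per species (species are conditionally
   independent, so acceptance is vectorised across species).
3. `eps_j`: per-site Metropolis, vectorised across sites.
4. Community means: exact conjugate normal Gibbs updates.
5. Community sds and `sigma_eps`: Metropolis on the log scale (Jacobian
   included) with the uniform supports enforced by rejection.

Proposal scales adapt multiplicatively toward ~30% acceptance during
burn-in only, so the post-burn-in kernel is fixed. Each chain has its own
`numpy` Generator spawned from the user seed; runs are bitwise
reproducible.

Numerical choices:

* `K_trunc` defaults to `max(100, 5 × max observed count)` per cell. Under
  weak detection (p of a few percent) the latent N can exceed any multiple
  of the observed counts, so every fit runs a truncation-doubling
  sensitivity check on the marginal likelihood at the final draw and logs a
  warning when it shifts by more than 1e-6; set `McmcConfig.k_trunc`
  explicitly in that regime.
* Initialisation: `N = max count + 1`, coefficients at the hyper-prior
  locations, sds at the middles of their uniform supports; jittered
  re-initialisation (bounded attempts) if the log posterior is not finite.
* Defaults are desk-scale (3 chains × 20,000 iterations, 5,000 burn-in,
  thin 5); `McmcConfig.paper_scale()` provides the long production preset
  (800,000 kept after 50,000 burn-in, thin 5).
* Convergence: split-chain potential scale reduction factor per scalar
  parameter; R̂ < 1.1 is the acceptance rule, and `compare_models` flags
  (but still reports) fits with R̂ ≥ 1.1 on more than 5% of parameters.

The N-marginalised cell likelihood (`marginal_loglik_cell`, a log-sum-exp
over the truncated support) exists independently of the sampler; the two
routes are cross-checked against enumeration oracles in the tests.

## Model comparison and fit assessment

WAIC = −2(lppd − p_WAIC) with the variance-form penalty (sample variance,
n−1 denominator). The pointwise unit is a (species, site) cell whose counts
across surveys enter jointly with the latent N marginalised out —
conditioning on the sampled N would understate predictive uncertainty. The
alternative `conditional_observation` unit (per survey observation, N from
the draw) is available as a switch. Candidate models are ranked ascending;
ties break by specification order with a logged warning.

Fit is checked with a Bayesian p-value on the Freeman–Tukey discrepancy
`T = Σ (√C − √e)²` with `e = N·p` per draw (the conditional expectation
given the augmented latent state). Replicates are drawn
`C_rep ~ Binomial(N, p)` per kept draw; `p_B = Pr(T_rep ≥ T_obs)` with ties
counting toward p. Values near 0.5 indicate acceptable fit; p < 0.1 is the
conventional lack-of-fit flag.

## Synthetic data

`msam.simulate` draws data from exactly the hierarchy above with all truth
returned. Site covariates are independent standard normals (then
empirically z-scored, matching the design scale of a real analysis); survey
dates follow evenly spaced occasions with ±10-day jitter and temperatures
warm through the season. `scenario_paper_like()` echoes the motivating
floodplain study's scale — 4 species, 30 sites, 3 surveys, community
hyper-parameters at the reported posterior means, detection around 1–15% —
and is the stress regime for the truncation machinery.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring waterbodies, temporal dynamics between surveys beyond the
covariates, species interactions, unmodelled detection heterogeneity, and
zero inflation. Passing recovery tests therefore show the estimator is
correct *under the model's own assumptions*; they cannot show robustness to
the ways real floodplain data violate them.

Dry-site surveys are stored as observed zeros by default (`dry_flag`
marks them); `dry_as_missing=True` removes them from the detection
likelihood instead.

## Validation experiments (run by tests and `scripts/acceptance.py`)

Problem sizes were chosen so the whole battery runs on a laptop-class single
core:

* **Likelihood oracles** — 50 randomised cells: `marginal_loglik_cell` and
  `latent_N_conditional` agree with direct enumeration to 1e-10.
* **Exact toy posterior** — 1 species, 3 sites, 2 surveys, K_trunc = 15,
  hypers held fixed: MCMC frequencies of N match quadrature-plus-enumeration
  within 3 batch-means Monte-Carlo SEs (60,000 iterations).
* **Parameter recovery** — 20 replicates of 8 species × 150 sites × 4
  surveys (moderate effects, detection ≈ 0.4, all sds inside prior support;
  1 chain, 1,200 iterations, 400 burn-in, thin 2): the seven community
  hyper-means are recovered with mean absolute error ≤ 0.3 and ≥ 90%
  coverage of the nominal 95% intervals.
* **Model selection sanity** — 20 replicates of study-scale data with a
  strong x1 effect (community mean 2.0) and a null x2: WAIC must rank the
  x1 model above the decoy in ≥ 18 of 20.
* **PPC calibration** — 20 well-specified study-scale fits: the
  Freeman–Tukey p lies in [0.05, 0.95] in ≥ 18 of 20; multiplying observed
  counts by 100 against an unchanged fit must push p below 0.1.

The motivating study's own fitted tables (WAIC values, hyper-parameter and
species-coefficient estimates) are **not** reproducible here: its raw counts
are unreleased, and MCMC at that scale is a production run, not a test.

## Known limitations

* Short adaptive random-walk chains mix slowly for species intercepts when
  sites are few; the desk-scale defaults (not the experiment lengths) are
  the recommended minimum for real analyses.
* The Uniform(0.01, 0.5) sd prior truncates hard; posteriors for community
  sds often pile up near 0.5 (visible in the motivating study's own tables).
* WAIC between models with different truncation bounds is comparable only
  because the bound is data-determined and shared; fixing `k_trunc`
  manually for one model in a comparison is not supported.
* `compare_models` refits every candidate from scratch; there is no
  draw-reuse across specifications.
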