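"""The hierarchical multi-species N-mixture model: likelihood, priors, fitting.

Model structure, for species i, site j, survey k::

    N_ij  ~ Poisson(lambda_ij),   log lambda_ij = x_j' b_i + eps_j
    C_ijk ~ Binomial(N_ij, p_ijk), logit p_ijk  = w_jk' a_i
    b_ic  ~ Normal(mu_lambda_c, sigma_lambda_c^2)   (community distributions)
    a_id  ~ Normal(mu_beta_d,  sigma_beta_d^2)
    eps_j ~ Normal(0, sigma_eps^2)

x_j holds an intercept plus up to three z-scored site covariates (sampled
area always first); w_jk holds an intercept plus the two survey covariates
(days since 1 February, water temperature), z-scored.

Hyper-priors: normal on the community means (location -1 for intercepts,
+1 for slopes, scale 5 — interpreted as a variance by default, switchable),
Uniform(0.01, 0.5) on the community sds, Uniform(0, 1) on sigma_eps.

Fitting is Metropolis-within-Gibbs with the discrete latent abundances
sampled exactly from their full conditionals on a truncated support
(data augmentation).  :func:`marginal_loglik_cell` provides the
N-marginalised likelihood independently of the sampler; it backs WAIC and
the enumeration oracle tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import norm, uniform

from .exceptions import ValidationError
from .prep import PreparedCovariates
from .simulate import CommunityHyperParams, OverdispersionTerms, SpeciesParams
from .survey import SurveyDataset

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "McmcConfig",
    "CommunityAbundanceModel",
    "abundance_mean",
    "detection_prob",
    "marginal_loglik_cell",
    "latent_N_conditional",
    "log_prior",
    "default_k_trunc",
    "run_mcmc",
]

DETECTION_COVARIATES = ("days", "temp")


@dataclass
class ModelSpec:
    """Which site covariates enter the abundance predictor.

    At most three abundance covariates in total, with sampled area first
    whenever any are present (area adjusts for survey effort).  The two
    detection covariates are fixed as (days, temp).  An empty covariate list
    gives an intercept-only abundance model, used for reduced/diagnostic
    fits.  ``overdispersion`` switches the site random effect eps_j.
    """

    abundance_covariates: tuple[str, ...] = ("area",)
    name: str = ""
    overdispersion: bool = True

    def __post_init__(self) -> None:
        self.abundance_covariates = tuple(self.abundance_covariates)
        if len(self.abundance_covariates) > 3:
            raise ValidationError("at most 3 abundance covariates are allowed")
        if self.abundance_covariates and self.abundance_covariates[0] != "area":
            raise ValidationError("sampled area must be the first abundance covariate")
        if not self.name:
            self.name = "+".join(("intercept",) + self.abundance_covariates)

    @property
    def abundance_names(self) -> tuple[str, ...]:
        return ("intercept",) + self.abundance_covariates

    @property
    def detection_names(self) -> tuple[str, ...]:
        return ("intercept",) + DETECTION_COVARIATES


@dataclass
class PriorSpec:
    """Hyper-priors for the community-level parameters.

    ``scale`` is the spread of the normal prior on community means; its
    meaning is governed by ``scale_interpretation`` ({'variance', 'sd',
    'precision'}, default 'variance', so scale 5 means sd sqrt(5)).
    """

    intercept_loc: float = -1.0
    slope_loc: float = 1.0
    scale: float = 5.0
    scale_interpretation: str = "variance"
    sigma_bounds: tuple[float, float] = (0.01, 0.5)
    sigma_eps_bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.scale_interpretation not in ("variance", "sd", "precision"):
            raise ValidationError("scale_interpretation must be variance|sd|precision")
        if self.scale <= 0:
            raise ValidationError("prior scale must be positive")
        for lo, hi in (self.sigma_bounds, self.sigma_eps_bounds):
            if not lo < hi:
                raise ValidationError("uniform prior bounds must be ordered")

    @property
    def mean_prior_sd(self) -> float:
        if self.scale_interpretation == "variance":
            return math.sqrt(self.scale)
        if self.scale_interpretation == "sd":
            return self.scale
        return 1.0 / math.sqrt(self.scale)

    def mean_prior_loc(self, position: str) -> float:
        return self.intercept_loc if position == "intercept" else self.slope_loc


@dataclass
class McmcConfig:
    """Sampler settings.  Defaults are desk-scale; :meth:`paper_scale` gives
    the long production preset (3 chains, 800,000 kept iterations after a
    50,000 burn-in, thinned by 5)."""

    n_chains: int = 3
    n_iter: int = 20_000
    n_burnin: int = 5_000
    thin: int = 5
    seed: int = 0
    k_trunc: int | None = None       # None -> max(100, 5 * max count) per cell
    target_accept: float = 0.3
    adapt: bool = True
    fixed_hypers: CommunityHyperParams | None = None
    fixed_sigma_eps: float | None = None
    max_init_attempts: int = 10

    def __post_init__(self) -> None:
        if self.n_iter <= self.n_burnin:
            raise ValidationError("n_iter must exceed n_burnin")
        if self.thin < 1 or self.n_chains < 1:
            raise ValidationError("thin and n_chains must be >= 1")

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "McmcConfig":
        return cls(n_chains=3, n_iter=850_000, n_burnin=50_000, thin=5, seed=seed)


# ---------------------------------------------------------------------------
# Likelihood primitives
# ---------------------------------------------------------------------------

def abundance_mean(params: SpeciesParams, covs: Sequence[float], eps_j: float = 0.0) -> float:
    """Expected abundance lambda = exp(b0 + b' covs + eps_j).

    `covs` are the covariate values matching the species' non-intercept
    abundance coefficients.
    """
    covs = np.asarray(covs, float)
    b = params.abundance
    if covs.size != b.size - 1:
        raise ValidationError(f"expected {b.size - 1} covariate values, got {covs.size}")
    eta = float(b[0] + b[1:] @ covs + eps_j)
    if eta > 700:
        raise OverflowError("log abundance too large to exponentiate")
    return math.exp(eta)


def detection_prob(params: SpeciesParams, days: float, temp: float) -> float:
    """Per-individual detection probability, inverse-logit of a0+a1*days+a2*temp."""
    a = params.detection
    return float(expit(a[0] + a[1] * days + a[2] * temp))


def _cell_log_weights(counts_k, lam: float, p_k, k_trunc: int):
    """log Poisson(N|lam) + sum_k log Binomial(c_k|N, p_k) over the support
    N = max(counts) .. k_trunc (unnormalised; shared by the marginal
    likelihood and the latent-N conditional)."""
    c = np.asarray(counts_k)
    p = np.asarray(p_k, float)
    if np.any(c < 0) or np.any(c != np.floor(c)):
        raise ValidationError("counts must be non-negative integers")
    c = c.astype(np.int64)
    if c.shape != p.shape:
        raise ValidationError("counts and detection probabilities must align")
    cmax = int(c.max()) if c.size else 0
    if k_trunc < cmax:
        raise ValidationError(f"k_trunc={k_trunc} below max observed count {cmax}")
    if not lam > 0:
        raise ValidationError("lambda must be positive")
    N = np.arange(cmax, k_trunc + 1)
    logw = N * math.log(lam) - lam - gammaln(N + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log(p)
        log1mp = np.log1p(-p)
    for k in range(c.size):
        ck = c[k]
        # binomial log pmf; p=0 and p=1 edges handled exactly
        if p[k] == 0.0:
            term = np.where(ck == 0, 0.0, -np.inf) * np.ones_like(N, dtype=float)
        elif p[k] == 1.0:
            term = np.where(N == ck, 0.0, -np.inf)
        else:
            term = (gammaln(N + 1) - gammaln(N - ck + 1) - gammaln(ck + 1)
                    + ck * logp[k] + (N - ck) * log1mp[k])
        logw = logw + term
    return N, logw


def marginal_loglik_cell(counts_k, lam: float, p_k, k_trunc: int) -> float:
    """Log-likelihood of one (species, site) cell's counts across surveys,
    with the latent abundance summed out over N = max(counts) .. k_trunc.

    Computed in log space (log-sum-exp); exact at the truncation level.
    """
    _, logw = _cell_log_weights(counts_k, lam, p_k, k_trunc)
    return float(logsumexp(logw))


def latent_N_conditional(counts_k, lam: float, p_k, k_trunc: int) -> np.ndarray:
    """Normalised full conditional of the latent abundance N for one cell,
    over the support max(counts) .. k_trunc (sums to 1)."""
    _, logw = _cell_log_weights(counts_k, lam, p_k, k_trunc)
    w = np.exp(logw - logsumexp(logw))
    return w / w.sum()


def log_prior(hyper: CommunityHyperParams, species: Sequence[SpeciesParams],
              od: OverdispersionTerms | None, priors: PriorSpec) -> float:
    """Joint log prior density of hypers, species coefficients and
    overdispersion terms; -inf outside the uniform supports."""
    ml, sl, mb, sb = hyper.arrays()
    lo, hi = priors.sigma_bounds
    if np.any(sl < lo) or np.any(sl > hi) or np.any(sb < lo) or np.any(sb > hi):
        return -np.inf
    s0 = priors.mean_prior_sd
    locs_l = np.array([priors.mean_prior_loc(n) for n in hyper.abundance_names])
    locs_b = np.array([priors.mean_prior_loc(n) for n in hyper.detection_names])
    total = float(norm.logpdf(ml, locs_l, s0).sum() + norm.logpdf(mb, locs_b, s0).sum())
    total += float(uniform.logpdf(sl, lo, hi - lo).sum()
                   + uniform.logpdf(sb, lo, hi - lo).sum())
    for sp in species:
        total += float(norm.logpdf(sp.abundance, ml, sl).sum())
        total += float(norm.logpdf(sp.detection, mb, sb).sum())
    if od is not None:
        elo, ehi = priors.sigma_eps_bounds
        if not (elo < od.sigma_eps <= ehi):
            return -np.inf
        total += float(uniform.logpdf(od.sigma_eps, elo, ehi - elo))
        total += float(norm.logpdf(od.eps, 0.0, od.sigma_eps).sum())
    return total


def default_k_trunc(counts: np.ndarray, floor: int = 100, factor: int = 5) -> np.ndarray:
    """Per-cell truncation bound for the latent abundance support:
    max(floor, factor * max observed count at that species-site)."""
    cmax = counts.max(axis=-1)
    return np.maximum(floor, factor * cmax).astype(np.int64)


# ---------------------------------------------------------------------------
# Model object
# ---------------------------------------------------------------------------

class CommunityAbundanceModel:
    """Hierarchical community N-mixture model bound to a dataset.

    Parameters
    ----------
    dataset : SurveyDataset
        Repeated counts, one slice per species.
    covariates : PreparedCovariates
        Standardised site and survey covariates (z-scores).
    spec : ModelSpec, optional
        Abundance covariate set; defaults to area only.
    priors : PriorSpec, optional
    dry_as_missing : bool
        If True, surveys flagged dry are removed from the detection
        likelihood instead of entering as observed zero counts (the
        default treats them as zeros).
    """

    def __init__(self, dataset: SurveyDataset, covariates: PreparedCovariates,
                 spec: ModelSpec | None = None, priors: PriorSpec | None = None,
                 dry_as_missing: bool = False):
        self.dataset = dataset
        self.covariates = covariates
        self.spec = spec or ModelSpec()
        self.priors = priors or PriorSpec()
        self.dry_as_missing = dry_as_missing
        if dataset.site_ids != covariates.site_ids:
            raise ValidationError("dataset and covariates disagree on site ids")
        if covariates.days_z is None or covariates.temp_z is None:
            raise ValidationError("prepared covariates lack the survey-level days/temp z-scores")

        self.X = covariates.design_matrix(self.spec.abundance_covariates)  # (J, P)
        J, K = dataset.days.shape
        self.W = np.stack([np.ones((J, K)), covariates.days_z, covariates.temp_z],
                          axis=-1)                                          # (J, K, 3)
        self.counts = dataset.counts                                        # (S, J, K)
        self.survey_mask = (~dataset.dry_flag if dry_as_missing
                            else np.ones((J, K), dtype=bool))

    @classmethod
    def from_simulation(cls, sim, spec: ModelSpec | None = None, **kwargs):
        """Bind the model to a :class:`~msam.simulate.SimulatedCommunity`,
        defaulting the covariate set to the one that generated the data."""
        if spec is None:
            names = tuple(sim.config.hyper.abundance_names[1:])
            spec = ModelSpec(abundance_covariates=names)
        return cls(sim.dataset, sim.covariates, spec=spec, **kwargs)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    def fit(self, mcmc: McmcConfig | None = None):
        """Run the Metropolis-within-Gibbs sampler; returns a
        :class:`~msam.results.CommunityAbundanceResults`."""
        from .sampler import sample_posterior
        mcmc = mcmc or McmcConfig()
        posterior = sample_posterior(self, mcmc)
        from .results import CommunityAbundanceResults
        return CommunityAbundanceResults(self, posterior, mcmc)


def run_mcmc(dataset: SurveyDataset, prepared: PreparedCovariates,
             spec: ModelSpec, priors: PriorSpec | None = None,
             mcmc: McmcConfig | None = None):
    """Functional entry point: build the model and fit it."""
    return CommunityAbundanceModel(dataset, prepared, spec, priors).fit(mcmc)
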