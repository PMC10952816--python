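"""Posterior containers, summaries and response curves."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostics import rhat
from .exceptions import ValidationError

__all__ = [
    "CommunityPosterior",
    "CommunityAbundanceResults",
    "ResponseCurve",
    "summarize_posterior",
]


@dataclass
class CommunityPosterior:
    """Chain-indexed MCMC draws of every model quantity.

    All arrays are indexed (chain, draw, ...).  ``b`` are species abundance
    coefficients (chain, draw, species, position), ``a`` species detection
    coefficients; hyper-parameters and the overdispersion terms follow the
    same convention.  ``N`` holds the sampled latent abundances.
    """

    species_ids: list[str]
    site_ids: list[str]
    abundance_names: tuple[str, ...]
    detection_names: tuple[str, ...]
    b: np.ndarray
    a: np.ndarray
    mu_lambda: np.ndarray
    sigma_lambda: np.ndarray
    mu_beta: np.ndarray
    sigma_beta: np.ndarray
    eps: np.ndarray
    sigma_eps: np.ndarray
    N: np.ndarray
    log_posterior: np.ndarray
    accept_rates: list[dict] = field(default_factory=list)
    k_trunc_check: float = 0.0
    overdispersion: bool = True

    @classmethod
    def from_chains(cls, model, chains) -> "CommunityPosterior":
        stack = {f: np.stack([getattr(c, f) for c in chains])
                 for f in ("b", "a", "mu_lambda", "sigma_lambda", "mu_beta",
                           "sigma_beta", "eps", "sigma_eps", "N", "log_posterior")}
        return cls(
            species_ids=model.dataset.species_ids,
            site_ids=model.dataset.site_ids,
            abundance_names=model.spec.abundance_names,
            detection_names=model.spec.detection_names,
            accept_rates=[c.accept_rates for c in chains],
            overdispersion=model.spec.overdispersion,
            **stack,
        )

    @property
    def n_chains(self) -> int:
        return self.b.shape[0]

    @property
    def n_draws(self) -> int:
        return self.b.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws of one quantity with chains concatenated along axis 0."""
        arr = getattr(self, name)
        return arr.reshape((-1,) + arr.shape[2:])

    def scalar_params(self):
        """Yield (name, (chain, draw) array) for every scalar parameter
        reported in summaries: hyper-parameters, species coefficients and
        sigma_eps."""
        for i, nm in enumerate(self.abundance_names):
            yield f"mu_lambda[{nm}]", self.mu_lambda[:, :, i]
        for i, nm in enumerate(self.abundance_names):
            yield f"sigma_lambda[{nm}]", self.sigma_lambda[:, :, i]
        for i, nm in enumerate(self.detection_names):
            yield f"mu_beta[{nm}]", self.mu_beta[:, :, i]
        for i, nm in enumerate(self.detection_names):
            yield f"sigma_beta[{nm}]", self.sigma_beta[:, :, i]
        for s, sp in enumerate(self.species_ids):
            for i, nm in enumerate(self.abundance_names):
                yield f"b[{sp},{nm}]", self.b[:, :, s, i]
            for i, nm in enumerate(self.detection_names):
                yield f"a[{sp},{nm}]", self.a[:, :, s, i]
        if self.overdispersion:
            yield "sigma_eps", self.sigma_eps

    def to_dataframe(self) -> pd.DataFrame:
        """Long (chain, draw, parameter, value) table of all scalar params."""
        frames = []
        for name, arr in self.scalar_params():
            c, d = np.meshgrid(np.arange(arr.shape[0]), np.arange(arr.shape[1]),
                               indexing="ij")
            frames.append(pd.DataFrame({
                "chain": c.ravel(), "draw": d.ravel(),
                "parameter": name, "value": arr.ravel(),
            }))
        return pd.concat(frames, ignore_index=True)


def summarize_posterior(posterior: CommunityPosterior) -> pd.DataFrame:
    """Posterior summary table: pooled-chain mean, sd (n-1 denominator) and
    the 2.5th/97.5th percentiles per scalar parameter, plus an ``important``
    flag marking 95% intervals that exclude zero (and a softer 90% flag)."""
    rows = []
    for name, arr in posterior.scalar_params():
        x = arr.ravel()
        if x.size < 2:
            raise ValidationError("summaries need at least 2 kept draws")
        q025, q975 = np.quantile(x, [0.025, 0.975])
        q05, q95 = np.quantile(x, [0.05, 0.95])
        rows.append({
            "parameter": name,
            "Mean": float(x.mean()),
            "SD": float(x.std(ddof=1)),
            "2.5th": float(q025),
            "97.5th": float(q975),
            "important": bool(q025 > 0 or q975 < 0),
            "important_90": bool(q05 > 0 or q95 < 0),
        })
    if not rows:
        raise ValidationError("empty posterior")
    return pd.DataFrame(rows).set_index("parameter")


@dataclass
class ResponseCurve:
    """Posterior expected abundance along one covariate, others held at 0."""

    covariate: str
    grid: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: str
    species: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate_value": self.grid, "mean": self.mean,
            "q2.5": self.lower, "q97.5": self.upper,
        })


class CommunityAbundanceResults:
    """Fit results: posterior draws plus summary, diagnostic, assessment and
    prediction methods (statsmodels-style Results object)."""

    def __init__(self, model, posterior: CommunityPosterior, mcmc):
        self.model = model
        self.posterior = posterior
        self.mcmc = mcmc

    # -- summaries ----------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        return summarize_posterior(self.posterior)

    def rhat_table(self) -> pd.Series:
        """Split-chain R-hat per scalar parameter (needs >= 2 chains)."""
        vals = {name: rhat(list(arr)) for name, arr in self.posterior.scalar_params()}
        return pd.Series(vals, name="rhat")

    def converged(self, threshold: float = 1.1, tolerate_frac: float = 0.05) -> bool:
        r = self.rhat_table()
        return float((r >= threshold).mean()) <= tolerate_frac

    # -- assessment ---------------------------------------------------------
    def waic(self, unit: str = "marginal_site_species"):
        from .assess import pointwise_log_density, waic
        ld = pointwise_log_density(self.posterior, self.model.dataset,
                                   self.model.covariates, self.model.spec,
                                   unit=unit, survey_mask=self.model.survey_mask)
        return waic(ld, unit=unit)

    def ppc(self, seed: int = 0):
        from .assess import freeman_tukey_ppc
        return freeman_tukey_ppc(self.posterior, self.model.dataset,
                                 self.model.covariates, self.model.spec,
                                 seed=seed, survey_mask=self.model.survey_mask)

    # -- prediction ---------------------------------------------------------
    def response_curve(self, covariate: str, grid, level: str = "community",
                       species: str | None = None) -> ResponseCurve:
        """Expected abundance versus one covariate, the other covariates at
        their z-score mean (0) and the overdispersion term at 0.

        ``level='community'`` uses the community hyper-means; ``'species'``
        uses that species' own coefficients.  Per grid point the posterior
        mean and 2.5/97.5 percentiles over draws are returned.
        """
        post = self.posterior
        names = post.abundance_names
        if covariate not in names[1:]:
            raise KeyError(f"covariate {covariate!r} not in model ({names[1:]})")
        ci = names.index(covariate)
        grid = np.asarray(grid, dtype=float)
        if level == "community":
            b0 = post.pooled("mu_lambda")[:, 0]
            bc = post.pooled("mu_lambda")[:, ci]
        elif level == "species":
            if species is None or species not in post.species_ids:
                raise KeyError(f"unknown species {species!r}")
            s = post.species_ids.index(species)
            b0 = post.pooled("b")[:, s, 0]
            bc = post.pooled("b")[:, s, ci]
        else:
            raise ValidationError("level must be 'community' or 'species'")
        lam = np.exp(b0[:, None] + bc[:, None] * grid[None, :])   # (draws, grid)
        lo, hi = np.quantile(lam, [0.025, 0.975], axis=0)
        return ResponseCurve(covariate=covariate, grid=grid,
                             mean=lam.mean(axis=0), lower=lo, upper=hi,
                             level=level, species=species)
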