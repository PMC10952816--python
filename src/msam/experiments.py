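"""Simulation experiments: parameter recovery, model-selection sanity,
posterior-predictive calibration, and an exact-enumeration check of the
sampler on a toy model.

These are the package's self-validation studies.  Raw field counts for the
motivating floodplain study are not publicly deposited, so fitted numbers
from that study cannot be recomputed; instead these experiments verify the
machinery against data simulated from the very hierarchy the model assumes,
where the truth is known.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import binom, norm, poisson

from .model import (CommunityAbundanceModel, McmcConfig, ModelSpec)
from .simulate import CommunityHyperParams, SimulationConfig, simulate_dataset

__all__ = [
    "recovery_scenario",
    "selection_scenario",
    "calibration_scenario",
    "run_recovery",
    "run_model_selection",
    "run_ppc_calibration",
    "toy_posterior_comparison",
]

HYPER_MEAN_NAMES = (
    "mu_lambda[intercept]", "mu_lambda[area]", "mu_lambda[x1]", "mu_lambda[x2]",
    "mu_beta[intercept]", "mu_beta[days]", "mu_beta[temp]",
)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def recovery_scenario(seed: int = 0) -> SimulationConfig:
    """Community of 8 species at 150 sites with 4 surveys: moderate covariate
    effects and detection around 0.4, the regime the model is designed for.
    Community sds sit inside the Uniform(0.01, 0.5) hyper-prior support so
    recovery and coverage are well defined."""
    hyper = CommunityHyperParams(
        mu_lambda={"intercept": 0.3, "area": 0.5, "x1": 0.8, "x2": -0.4},
        sigma_lambda={k: 0.25 for k in ("intercept", "area", "x1", "x2")},
        mu_beta={"intercept": -0.35, "days": 0.2, "temp": 0.8},
        sigma_beta={k: 0.25 for k in ("intercept", "days", "temp")},
    )
    return SimulationConfig(n_species=8, n_sites=150, n_surveys=4,
                            hyper=hyper, sigma_eps=0.3, seed=seed)


def selection_scenario(seed: int = 0) -> SimulationConfig:
    """Study-scale data (4 species, 30 sites, 3 surveys) generated with a
    strong x1 effect (community mean 2.0) and a null x2."""
    hyper = CommunityHyperParams(
        mu_lambda={"intercept": 0.3, "area": 0.5, "x1": 2.0, "x2": 0.0},
        sigma_lambda={"intercept": 0.25, "area": 0.25, "x1": 0.3, "x2": 0.05},
        mu_beta={"intercept": -0.35, "days": 0.2, "temp": 0.8},
        sigma_beta={k: 0.25 for k in ("intercept", "days", "temp")},
    )
    return SimulationConfig(n_species=4, n_sites=30, n_surveys=3,
                            hyper=hyper, sigma_eps=0.3, seed=seed)


def calibration_scenario(seed: int = 0) -> SimulationConfig:
    """Study-scale, well-specified data for posterior-predictive calibration."""
    hyper = CommunityHyperParams(
        mu_lambda={"intercept": 0.3, "area": 0.5, "x1": 0.8, "x2": -0.4},
        sigma_lambda={k: 0.25 for k in ("intercept", "area", "x1", "x2")},
        mu_beta={"intercept": -0.35, "days": 0.2, "temp": 0.8},
        sigma_beta={k: 0.25 for k in ("intercept", "days", "temp")},
    )
    return SimulationConfig(n_species=4, n_sites=30, n_surveys=3,
                            hyper=hyper, sigma_eps=0.3, seed=seed)


@dataclass
class RecoveryResult:
    names: tuple[str, ...]
    truth: np.ndarray                 # (7,)
    post_means: np.ndarray            # (reps, 7)
    covered: np.ndarray               # (reps, 7) bool

    @property
    def mae(self) -> np.ndarray:
        """Mean absolute error of the posterior means, per hyper-mean."""
        return np.abs(self.post_means - self.truth).mean(axis=0)

    @property
    def coverage(self) -> float:
        """Fraction of nominal-95% intervals containing the truth."""
        return float(self.covered.mean())


def run_recovery(n_replicates: int = 20, seed: int = 1,
                 n_iter: int = 1200, n_burnin: int = 400,
                 thin: int = 2) -> RecoveryResult:
    """Fit the model to `n_replicates` datasets drawn from
    :func:`recovery_scenario`; summarise error and interval coverage of the
    seven community hyper-means."""
    seeds = _child_seeds(seed, 2 * n_replicates)
    base = recovery_scenario()
    truth = np.array(list(base.hyper.mu_lambda.values())
                     + list(base.hyper.mu_beta.values()))
    means = np.empty((n_replicates, truth.size))
    covered = np.empty((n_replicates, truth.size), dtype=bool)
    for r in range(n_replicates):
        sim = simulate_dataset(replace(base, seed=seeds[2 * r]))
        res = CommunityAbundanceModel.from_simulation(sim).fit(
            McmcConfig(n_chains=1, n_iter=n_iter, n_burnin=n_burnin,
                       thin=thin, seed=seeds[2 * r + 1]))
        s = res.summary()
        for i, name in enumerate(HYPER_MEAN_NAMES):
            row = s.loc[name]
            means[r, i] = row["Mean"]
            covered[r, i] = row["2.5th"] <= truth[i] <= row["97.5th"]
    return RecoveryResult(names=HYPER_MEAN_NAMES, truth=truth,
                          post_means=means, covered=covered)


def run_model_selection(n_replicates: int = 20, seed: int = 2,
                        n_iter: int = 1200, n_burnin: int = 400,
                        thin: int = 4) -> dict:
    """WAIC sanity: on data with a strong x1 effect and a null x2, does the
    x1 model outrank the x2-only decoy?  Returns the per-replicate outcome."""
    seeds = _child_seeds(seed, 2 * n_replicates)
    base = selection_scenario()
    spec_true = ModelSpec(("area", "x1"), name="area+x1")
    spec_decoy = ModelSpec(("area", "x2"), name="area+x2")
    wins = []
    for r in range(n_replicates):
        sim = simulate_dataset(replace(base, seed=seeds[2 * r]))
        mcmc = McmcConfig(n_chains=1, n_iter=n_iter, n_burnin=n_burnin,
                          thin=thin, seed=seeds[2 * r + 1])
        waics = {}
        for spec in (spec_true, spec_decoy):
            res = CommunityAbundanceModel(sim.dataset, sim.covariates,
                                          spec).fit(mcmc)
            waics[spec.name] = res.waic().waic
        wins.append(waics["area+x1"] < waics["area+x2"])
    return {"n_correct": int(np.sum(wins)), "n_replicates": n_replicates,
            "wins": wins}


def run_ppc_calibration(n_replicates: int = 20, seed: int = 3,
                        n_iter: int = 1200, n_burnin: int = 400,
                        thin: int = 4, corrupt_factor: int = 100) -> dict:
    """Freeman-Tukey calibration: for well-specified fits the Bayesian p
    should rarely be extreme; multiplying the observed counts by
    `corrupt_factor` against an unchanged fit should push p below 0.1."""
    from .survey import SurveyDataset

    seeds = _child_seeds(seed, 3 * n_replicates)
    base = calibration_scenario()
    pvals = []
    corrupted_p = None
    for r in range(n_replicates):
        sim = simulate_dataset(replace(base, seed=seeds[3 * r]))
        res = CommunityAbundanceModel.from_simulation(sim).fit(
            McmcConfig(n_chains=1, n_iter=n_iter, n_burnin=n_burnin,
                       thin=thin, seed=seeds[3 * r + 1]))
        pvals.append(res.ppc(seed=seeds[3 * r + 2]).bayesian_p)
        if r == 0:
            from .assess import freeman_tukey_ppc
            bad = SurveyDataset(
                sim.dataset.species_ids, sim.dataset.site_ids,
                sim.dataset.counts * corrupt_factor,
                sim.dataset.days, sim.dataset.water_temp, sim.dataset.dry_flag)
            corrupted_p = freeman_tukey_ppc(
                res.posterior, bad, sim.covariates, res.model.spec,
                seed=seeds[3 * r + 2]).bayesian_p
    pvals = np.asarray(pvals)
    return {
        "pvals": pvals,
        "n_calibrated": int(np.sum((pvals >= 0.05) & (pvals <= 0.95))),
        "n_replicates": n_replicates,
        "corrupted_p": float(corrupted_p),
    }


# ---------------------------------------------------------------------------
# Exact enumeration of a toy posterior
# ---------------------------------------------------------------------------

def _toy_enumeration(counts: np.ndarray, p_grid_half_width: float,
                     mu_b0: float, sd_b0: float, mu_a0: float, sd_a0: float,
                     k_trunc: int, n_grid: int) -> np.ndarray:
    """Marginal posterior P(N_j = n | data) for an intercept-only,
    single-species model, by quadrature over (b0, a0) and exact summation
    over the latent counts.  Independent of the MCMC code path: densities
    are composed directly from scipy.stats pmfs."""
    J, K = counts.shape
    b0 = np.linspace(mu_b0 - p_grid_half_width * sd_b0,
                     mu_b0 + p_grid_half_width * sd_b0, n_grid)
    a0 = np.linspace(mu_a0 - p_grid_half_width * sd_a0,
                     mu_a0 + p_grid_half_width * sd_a0, n_grid)
    lam = np.exp(b0)                              # (G,)
    p = 1.0 / (1.0 + np.exp(-a0))                 # (G,)
    Nsup = np.arange(k_trunc + 1)

    # site j, abundance n: f[j, n, gb, ga] = Pois(n|lam_gb) * prod_k Bin(c_jk|n, p_ga)
    pois = poisson.pmf(Nsup[:, None], lam[None, :])        # (n, gb)
    out = np.zeros((J, k_trunc + 1))
    like_cell = np.empty((J, k_trunc + 1, n_grid))         # over a0 grid
    for j in range(J):
        like = np.ones((k_trunc + 1, n_grid))
        for k in range(K):
            like *= binom.pmf(counts[j, k], Nsup[:, None], p[None, :])
        like_cell[j] = like
    wb = norm.pdf(b0, mu_b0, sd_b0)
    wa = norm.pdf(a0, mu_a0, sd_a0)
    # joint weight over the (b0, a0) grid: product over sites of the cell
    # marginals, times the priors
    m_cells = np.einsum("jng,nb->jbg", like_cell, pois)    # (J, gb, ga)
    logM = np.log(m_cells + 1e-300).sum(axis=0)            # (gb, ga)
    W = np.exp(logM - logM.max()) * wb[:, None] * wa[None, :]
    W /= W.sum()
    for j in range(J):
        other = logM - np.log(m_cells[j] + 1e-300)         # leave-one-out
        Wj = np.exp(other - other.max()) * wb[:, None] * wa[None, :]
        contrib = np.einsum("nb,bg,jng->jn", pois, Wj,
                            like_cell[j:j + 1])[0]
        out[j] = contrib / contrib.sum()
    return out


def toy_posterior_comparison(seed: int = 11, n_iter: int = 60_000,
                             n_burnin: int = 5_000, k_trunc: int = 15,
                             n_grid: int = 121) -> dict:
    """Stationary-distribution check on a 1-species, 3-site, 2-survey toy.

    The community hyper-parameters are held fixed so the continuous
    parameters reduce to the species intercepts (b0, a0); the exact
    posterior of each site's latent N then follows from quadrature over
    (b0, a0).  The MCMC frequencies of N are compared against it, with the
    Monte-Carlo error of each frequency estimated by batch means.
    Returns the maximum absolute deviation in units of its standard error.
    """
    from .prep import PreparedCovariates
    from .survey import SurveyDataset

    mu_b0, sd_b0 = 1.0, 0.4
    mu_a0, sd_a0 = 0.2, 0.4
    counts = np.array([[2, 1], [0, 1], [4, 3]])
    J, K = counts.shape
    days = np.zeros((J, K))
    temp = np.zeros((J, K))
    dataset = SurveyDataset(["sp1"], [f"site{j+1}" for j in range(J)],
                            counts[None, :, :], days, temp)
    prepared = PreparedCovariates(site_ids=dataset.site_ids, site={},
                                  days_z=days, temp_z=temp)
    # fixed hypers; the survey covariates are identically 0 so the slope
    # coefficients touch neither the likelihood nor the N posterior — their
    # prior width is immaterial to the comparison
    hyper = CommunityHyperParams(
        mu_lambda={"intercept": mu_b0}, sigma_lambda={"intercept": sd_b0},
        mu_beta={"intercept": mu_a0, "days": 0.0, "temp": 0.0},
        sigma_beta={"intercept": sd_a0, "days": sd_a0, "temp": sd_a0},
    )
    spec = ModelSpec((), name="toy", overdispersion=False)
    model = CommunityAbundanceModel(dataset, prepared, spec)
    res = model.fit(McmcConfig(
        n_chains=1, n_iter=n_iter, n_burnin=n_burnin, thin=1, seed=seed,
        k_trunc=k_trunc, fixed_hypers=hyper))
    Ndraws = res.posterior.pooled("N")[:, 0, :]            # (D, J)

    exact = _toy_enumeration(counts, 8.0, mu_b0, sd_b0, mu_a0, sd_a0,
                             k_trunc, n_grid)
    max_dev_se = 0.0
    n_batches = 40
    D = Ndraws.shape[0]
    bs = D // n_batches
    for j in range(J):
        for n in range(k_trunc + 1):
            ind = (Ndraws[:, j] == n).astype(float)
            freq = ind.mean()
            bmeans = ind[:bs * n_batches].reshape(n_batches, bs).mean(axis=1)
            se = bmeans.std(ddof=1) / np.sqrt(n_batches)
            se = max(se, 1.0 / D)                          # guard rare states
            max_dev_se = max(max_dev_se, abs(freq - exact[j, n]) / se)
    return {"max_dev_se": float(max_dev_se), "exact": exact,
            "n_draws": int(D)}
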