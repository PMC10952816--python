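"""Metropolis-within-Gibbs engine for the community N-mixture model.

Update cycle per iteration:

1. latent abundances N_ij drawn *exactly* from their discrete full
   conditional on the truncated support (Gumbel-max over the precomputed
   log-weight table; only the term linear in N changes between iterations,
   the count-dependent table is fixed by the data),
2. species detection coefficients a_i: adaptive random-walk Metropolis,
   one joint proposal per species,
3. species abundance coefficients b_i: same scheme against the Poisson
   likelihood of N,
4. site overdispersion eps_j: per-site Metropolis,
5. community means mu: conjugate normal Gibbs updates,
6. community sds sigma and sigma_eps: Metropolis on the log scale with the
   uniform supports enforced (proposal Jacobian included).

Proposal scales adapt toward the target acceptance rate during burn-in only,
so the post-burn-in kernel is a fixed Markov kernel.  Everything is driven
by one numpy Generator per chain, spawned from the user seed, so runs are
bitwise reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .exceptions import ConvergenceError, ValidationError
from .model import CommunityAbundanceModel, McmcConfig, default_k_trunc, marginal_loglik_cell

logger = logging.getLogger(__name__)

__all__ = ["sample_posterior", "ChainDraws"]


@dataclass
class ChainDraws:
    """Thinned post-burn-in draws from one chain (arrays indexed draw-first)."""

    b: np.ndarray            # (D, S, P) abundance coefficients
    a: np.ndarray            # (D, S, Q) detection coefficients
    mu_lambda: np.ndarray    # (D, P)
    sigma_lambda: np.ndarray # (D, P)
    mu_beta: np.ndarray      # (D, Q)
    sigma_beta: np.ndarray   # (D, Q)
    eps: np.ndarray          # (D, J)
    sigma_eps: np.ndarray    # (D,)
    N: np.ndarray            # (D, S, J)
    log_posterior: np.ndarray  # (D,)
    accept_rates: dict


def _log_sigmoid(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(log p, log (1-p)) for p = sigmoid(x), numerically stable."""
    logp = -np.logaddexp(0.0, -x)
    return logp, logp - x


def _precompute_base(counts: np.ndarray, mask: np.ndarray, k_cell: np.ndarray,
                     kmax: int) -> np.ndarray:
    """Data-only part of the latent-N log-weights: for every candidate
    abundance n, (n_surveys-1)*log n! - sum_k log (n - c_k)! with -inf outside
    the per-cell support [max count, k_cell]."""
    S, J, K = counts.shape
    G = np.arange(kmax + 1)
    gltab = gammaln(np.arange(kmax + 2).astype(float))
    nk = mask.sum(axis=1).astype(float)                      # (J,)
    base = (nk[None, None, :] - 1.0) * gltab[G + 1][:, None, None]
    base = np.broadcast_to(base, (kmax + 1, S, J)).copy()
    for k in range(K):
        d = G[:, None, None] - counts[None, :, :, k] + 1     # (kmax+1, S, J)
        site_on = mask[:, k][None, None, :]
        ok = (d >= 1) & site_on
        contrib = np.where(ok, -gltab[np.clip(d, 0, kmax + 1)], 0.0)
        contrib = np.where((d < 1) & site_on, -np.inf, contrib)
        base += contrib
    base[G[:, None, None] > k_cell[None, :, :]] = -np.inf
    return base


def sample_posterior(model: CommunityAbundanceModel, mcmc: McmcConfig):
    """Run all chains; returns a :class:`~msam.results.CommunityPosterior`."""
    from .results import CommunityPosterior

    ss = np.random.SeedSequence(mcmc.seed)
    chains = [
        _run_chain(model, mcmc, np.random.default_rng(child))
        for child in ss.spawn(mcmc.n_chains)
    ]
    post = CommunityPosterior.from_chains(model, chains)
    post.k_trunc_check = _k_trunc_sensitivity(model, chains[0], mcmc)
    if post.k_trunc_check > 1e-6:
        logger.warning(
            "doubling the latent-N truncation shifts the marginal log-likelihood "
            "by %.3g; consider a larger k_trunc", post.k_trunc_check)
    return post


def _run_chain(model: CommunityAbundanceModel, mcmc: McmcConfig,
               rng: np.random.Generator) -> ChainDraws:
    C = model.counts                          # (S, J, K)
    mask = model.survey_mask                  # (J, K)
    X, W = model.X, model.W                   # (J,P), (J,K,Q)
    S, J, K = C.shape
    P, Q = X.shape[1], W.shape[2]
    priors = model.priors
    overdisp = model.spec.overdispersion

    c_eff = np.where(mask[None, :, :], C, 0)
    max_c = c_eff.max(axis=2)                 # (S, J)
    if mcmc.k_trunc is not None:
        if mcmc.k_trunc < max_c.max():
            raise ValidationError("k_trunc below the maximum observed count")
        k_cell = np.full((S, J), int(mcmc.k_trunc), dtype=np.int64)
    else:
        k_cell = default_k_trunc(c_eff)
    kmax = int(k_cell.max())
    base = _precompute_base(c_eff, mask, k_cell, kmax)
    G = np.arange(kmax + 1)
    gltab = gammaln(np.arange(kmax + 2).astype(float))

    lo_s, hi_s = priors.sigma_bounds
    lo_e, hi_e = priors.sigma_eps_bounds
    s0 = priors.mean_prior_sd
    loc_l = np.array([priors.mean_prior_loc(n) for n in model.spec.abundance_names])
    loc_b = np.array([priors.mean_prior_loc(n) for n in model.spec.detection_names])

    fixed = mcmc.fixed_hypers
    if fixed is not None:
        mu_l = np.array([fixed.mu_lambda[n] for n in model.spec.abundance_names])
        sig_l = np.array([fixed.sigma_lambda[n] for n in model.spec.abundance_names])
        mu_b = np.array([fixed.mu_beta[n] for n in model.spec.detection_names])
        sig_b = np.array([fixed.sigma_beta[n] for n in model.spec.detection_names])
    else:
        mu_l, mu_b = loc_l.copy(), loc_b.copy()
        sig_l = np.full(P, 0.5 * (lo_s + hi_s))
        sig_b = np.full(Q, 0.5 * (lo_s + hi_s))
    sigma_eps = (mcmc.fixed_sigma_eps if mcmc.fixed_sigma_eps is not None
                 else 0.5 * (lo_e + hi_e))

    # -- initial state (re-jittered if the log posterior is not finite) -----
    for attempt in range(mcmc.max_init_attempts):
        B = np.tile(mu_l, (S, 1))
        A = np.tile(mu_b, (S, 1))
        if attempt:
            B = B + 0.1 * attempt * rng.standard_normal((S, P))
            A = A + 0.1 * attempt * rng.standard_normal((S, Q))
        eps = np.zeros(J)
        N = max_c + 1
        eta = B @ X.T + eps[None, :]
        if np.all(np.isfinite(eta)) and np.abs(eta).max() < 600:
            break
    else:
        raise ConvergenceError("could not initialise the sampler at a finite log posterior")

    # -- adaptive proposal scales -------------------------------------------
    step_a = np.full(S, 0.1)
    step_b = np.full(S, 0.1)
    step_e = np.full(J, 0.3)
    step_sl = np.full(P, 0.4)
    step_sb = np.full(Q, 0.4)
    step_se = 0.4
    adapt_rate, target = 0.08, mcmc.target_accept

    # reusable buffers for the latent-N step (the hot loop)
    work = np.empty((kmax + 1, S, J))
    gbuf = np.empty_like(work)
    G3 = G[:, None, None].astype(float)

    n_kept = -(-(mcmc.n_iter - mcmc.n_burnin) // mcmc.thin)   # ceil division
    out = {
        "b": np.empty((n_kept, S, P)), "a": np.empty((n_kept, S, Q)),
        "mu_lambda": np.empty((n_kept, P)), "sigma_lambda": np.empty((n_kept, P)),
        "mu_beta": np.empty((n_kept, Q)), "sigma_beta": np.empty((n_kept, Q)),
        "eps": np.empty((n_kept, J)), "sigma_eps": np.empty(n_kept),
        "N": np.empty((n_kept, S, J), dtype=np.int64),
        "log_posterior": np.empty(n_kept),
    }
    acc_tot = {"a": 0.0, "b": 0.0, "eps": 0.0}
    n_post = 0
    kept = 0

    maskf = mask[None, :, :]                  # broadcastable over species

    for t in range(mcmc.n_iter):
        adapting = mcmc.adapt and t < mcmc.n_burnin

        # (1) latent abundances
        eta = B @ X.T + eps[None, :]
        lp = np.einsum("jkq,sq->sjk", W, A)
        logp, log1mp = _log_sigmoid(lp)
        slogq = np.where(maskf, log1mp, 0.0).sum(axis=2)      # (S, J)
        np.multiply(G3, (eta + slogq)[None, :, :], out=work)
        work += base
        # standard Gumbel noise computed in place: -log(-log U)
        rng.random(out=gbuf)
        np.log(gbuf, out=gbuf)
        np.negative(gbuf, out=gbuf)
        np.log(gbuf, out=gbuf)
        work -= gbuf          # work + (-log(-log U))
        N = np.argmax(work, axis=0)                           # (S, J)

        # (2) detection coefficients
        ll_det = np.where(maskf, C * logp + (N[:, :, None] - C) * log1mp, 0.0).sum(axis=(1, 2))
        A2 = A + step_a[:, None] * rng.standard_normal((S, Q))
        logp2, log1mp2 = _log_sigmoid(np.einsum("jkq,sq->sjk", W, A2))
        ll_det2 = np.where(maskf, C * logp2 + (N[:, :, None] - C) * log1mp2, 0.0).sum(axis=(1, 2))
        dprior = (-0.5 * (((A2 - mu_b) / sig_b) ** 2 - ((A - mu_b) / sig_b) ** 2)).sum(axis=1)
        acc = np.log(rng.random(S)) < (ll_det2 - ll_det) + dprior
        A = np.where(acc[:, None], A2, A)
        if adapting:
            step_a *= np.exp(adapt_rate * (acc - target))
        acc_tot["a"] += acc.mean()

        # (3) abundance coefficients
        eta = B @ X.T + eps[None, :]
        with np.errstate(over="ignore"):
            ll_ab = (N * eta - np.exp(eta)).sum(axis=1)
            B2 = B + step_b[:, None] * rng.standard_normal((S, P))
            eta2 = B2 @ X.T + eps[None, :]
            ll_ab2 = (N * eta2 - np.exp(eta2)).sum(axis=1)
        dprior = (-0.5 * (((B2 - mu_l) / sig_l) ** 2 - ((B - mu_l) / sig_l) ** 2)).sum(axis=1)
        acc = np.log(rng.random(S)) < (ll_ab2 - ll_ab) + dprior
        B = np.where(acc[:, None], B2, B)
        if adapting:
            step_b *= np.exp(adapt_rate * (acc - target))
        acc_tot["b"] += acc.mean()

        # (4) site overdispersion
        if overdisp:
            eta = B @ X.T + eps[None, :]
            eps2 = eps + step_e * rng.standard_normal(J)
            eta2 = eta + (eps2 - eps)[None, :]
            with np.errstate(over="ignore"):
                dll = ((N * eta2 - np.exp(eta2)) - (N * eta - np.exp(eta))).sum(axis=0)
            dll += -0.5 * (eps2 ** 2 - eps ** 2) / sigma_eps ** 2
            acc = np.log(rng.random(J)) < dll
            eps = np.where(acc, eps2, eps)
            if adapting:
                step_e *= np.exp(adapt_rate * (acc - target))
            acc_tot["eps"] += acc.mean()

        if fixed is None:
            # (5) conjugate updates of the community means
            for vals, mus, sigs, locs in ((B, "mu_l", sig_l, loc_l),
                                          (A, "mu_b", sig_b, loc_b)):
                prec = S / sigs ** 2 + 1.0 / s0 ** 2
                mean = (vals.sum(axis=0) / sigs ** 2 + locs / s0 ** 2) / prec
                draw = mean + rng.standard_normal(vals.shape[1]) / np.sqrt(prec)
                if mus == "mu_l":
                    mu_l = draw
                else:
                    mu_b = draw

            # (6) community sds: log-scale Metropolis inside U(lo, hi)
            for which in ("l", "bdet"):
                vals, mus, sigs, steps = ((B, mu_l, sig_l, step_sl) if which == "l"
                                          else (A, mu_b, sig_b, step_sb))
                sig2 = sigs * np.exp(steps * rng.standard_normal(sigs.size))
                inside = (sig2 >= lo_s) & (sig2 <= hi_s)
                sse = ((vals - mus) ** 2).sum(axis=0)
                dll = (-S * np.log(sig2 / sigs) - 0.5 * sse * (1 / sig2 ** 2 - 1 / sigs ** 2)
                       + np.log(sig2 / sigs))          # last term: proposal Jacobian
                acc = inside & (np.log(rng.random(sigs.size)) < dll)
                sigs[:] = np.where(acc, sig2, sigs)
                if adapting:
                    steps *= np.exp(adapt_rate * (acc - target))

        # (7) sd of the overdispersion term
        if overdisp and mcmc.fixed_sigma_eps is None:
            se2 = sigma_eps * np.exp(step_se * rng.standard_normal())
            if lo_e < se2 <= hi_e:
                dll = (-J * np.log(se2 / sigma_eps)
                       - 0.5 * (eps ** 2).sum() * (1 / se2 ** 2 - 1 / sigma_eps ** 2)
                       + np.log(se2 / sigma_eps))
                if np.log(rng.random()) < dll:
                    sigma_eps = se2
                    if adapting:
                        step_se *= np.exp(adapt_rate * (1 - target))
                elif adapting:
                    step_se *= np.exp(adapt_rate * (0 - target))

        # -- store ----------------------------------------------------------
        if t >= mcmc.n_burnin and (t - mcmc.n_burnin) % mcmc.thin == 0:
            eta = B @ X.T + eps[None, :]
            lp = np.einsum("jkq,sq->sjk", W, A)
            logp, log1mp = _log_sigmoid(lp)
            ll_counts = np.where(
                maskf,
                gltab[N[:, :, None] + 1] - gltab[N[:, :, None] - c_eff + 1]
                - gltab[c_eff + 1] + c_eff * logp + (N[:, :, None] - c_eff) * log1mp,
                0.0).sum()
            ll_N = (N * eta - np.exp(eta) - gltab[N + 1]).sum()
            lprior = (
                -0.5 * (((B - mu_l) / sig_l) ** 2).sum() - S * np.log(sig_l).sum()
                - 0.5 * (((A - mu_b) / sig_b) ** 2).sum() - S * np.log(sig_b).sum()
                - 0.5 * (((mu_l - loc_l) / s0) ** 2).sum()
                - 0.5 * (((mu_b - loc_b) / s0) ** 2).sum()
            )
            if overdisp:
                lprior += -0.5 * (eps ** 2).sum() / sigma_eps ** 2 - J * np.log(sigma_eps)
            out["b"][kept] = B
            out["a"][kept] = A
            out["mu_lambda"][kept] = mu_l
            out["sigma_lambda"][kept] = sig_l
            out["mu_beta"][kept] = mu_b
            out["sigma_beta"][kept] = sig_b
            out["eps"][kept] = eps
            out["sigma_eps"][kept] = sigma_eps if overdisp else 0.0
            out["N"][kept] = N
            out["log_posterior"][kept] = ll_counts + ll_N + lprior
            kept += 1
        n_post += 1

    rates = {k: v / mcmc.n_iter for k, v in acc_tot.items()}
    logger.info("chain finished; acceptance rates %s", rates)
    return ChainDraws(accept_rates=rates, **out)


def _k_trunc_sensitivity(model: CommunityAbundanceModel, chain: ChainDraws,
                         mcmc: McmcConfig, n_cells: int = 25) -> float:
    """Absolute shift in summed marginal log-likelihood when the truncation
    bound is doubled, at the last kept draw, on a cell subsample."""
    C = model.counts
    S, J, K = C.shape
    B, A, eps = chain.b[-1], chain.a[-1], chain.eps[-1]
    eta = B @ model.X.T + eps[None, :]
    lp = np.einsum("jkq,sq->sjk", model.W, A)
    p = 1.0 / (1.0 + np.exp(-lp))
    rng = np.random.default_rng(0)
    cells = rng.choice(S * J, size=min(n_cells, S * J), replace=False)
    c_eff = np.where(model.survey_mask[None], C, 0)
    k_cell = (np.full((S, J), mcmc.k_trunc) if mcmc.k_trunc is not None
              else default_k_trunc(c_eff))
    diff = 0.0
    for cell in cells:
        s, j = divmod(int(cell), J)
        ks = model.survey_mask[j]
        if not ks.any():
            continue
        lam = float(np.exp(eta[s, j]))
        l1 = marginal_loglik_cell(c_eff[s, j, ks], lam, p[s, j, ks], int(k_cell[s, j]))
        l2 = marginal_loglik_cell(c_eff[s, j, ks], lam, p[s, j, ks], 2 * int(k_cell[s, j]))
        diff += abs(l2 - l1)
    return float(diff)
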