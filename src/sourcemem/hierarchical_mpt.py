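"""Latent-trait hierarchical Bayesian estimation of the source-item MPT.

Model
-----
Participant ``i``'s parameter vector (6 MPT probabilities) is a probit
transform of a correlated multivariate-normal latent trait:

    theta_ip = Phi(mu_p + beta_p * x_i + delta_ip),   delta_i ~ MVN(0, Sigma)

with ``Phi`` the standard normal CDF, ``mu`` the group-level means on the
probit scale, ``beta`` an optional fixed covariate effect (e.g. sex coded
0/1) and ``Sigma`` a 6x6 covariance capturing both interindividual
variability and parameter correlation.

Priors (weakly informative latent-trait defaults): ``mu_p ~ N(0, 1)``,
``beta_p ~ N(0, 1)``, and a scaled inverse-Wishart on ``Sigma``:
``Sigma = diag(lambda) Q diag(lambda)`` with ``Q ~ IW(I, df = 7)`` and
``lambda_p ~ Uniform(0, 10)``.

Sampler
-------
Metropolis-within-Gibbs.  The chain state carries the per-participant probit
values ``eta_i = mu + beta x_i + delta_i`` directly:

* ``eta_ip`` — adaptive scalar random-walk Metropolis, vectorised across
  participants (their full conditionals are independent given the rest);
* ``mu`` and ``beta`` — exact conjugate multivariate-normal Gibbs updates;
* ``Q`` — exact conjugate inverse-Wishart Gibbs update;
* ``lambda_p`` — scalar random-walk Metropolis under the uniform prior.

Proposal step sizes adapt toward ~44% acceptance during burn-in and are
frozen afterwards, keeping the post-burn-in chain a valid Markov chain.
Convergence is monitored with the split-R-hat potential scale-reduction
factor over >= 2 chains; R-hat < 1.05 is taken as converged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri

from .mpt_model import PARAM_NAMES, category_probabilities_array, moment_estimator, EstimationError
from .task_data import CohortTable

__all__ = [
    "N_PARAMS",
    "LatentTraitConfig",
    "PosteriorDraws",
    "GroupDifference",
    "probit",
    "inverse_probit",
    "split_rhat",
    "sample_posterior",
    "posterior_predictive_pvalues",
    "group_difference",
]

N_PARAMS = 6


def probit(p):
    """Phi^-1: probability scale -> latent (probit) scale."""
    return ndtri(p)


def inverse_probit(x):
    """Phi: latent (probit) scale -> probability scale."""
    return ndtr(x)


@dataclass(frozen=True)
class LatentTraitConfig:
    """MCMC settings; defaults follow the study's sampler configuration."""

    n_iter: int = 50_000
    burn_in: int = 10_000
    thin: int = 10
    n_chains: int = 2
    rhat_threshold: float = 1.05
    seed: int = 0
    mu_prior_sd: float = 1.0
    beta_prior_sd: float = 1.0
    lambda_upper: float = 10.0
    use_covariate: bool = False

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for split-R-hat")

    @property
    def draws_per_chain(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws from all chains.

    ``group_prob`` (n_draws, 6): inverse-probit-transformed group means on
    the probability scale (the quantity the study reports); ``individual_prob``
    (n_draws, n_participants, 6): per-participant parameters; ``chain``
    (n_draws,): chain index of each draw; ``mu``/``beta`` are the raw
    probit-scale group parameters.
    """

    group_prob: np.ndarray
    individual_prob: np.ndarray
    mu: np.ndarray
    beta: np.ndarray | None
    chain: np.ndarray
    rhat: np.ndarray
    converged: bool
    config: LatentTraitConfig
    participant_ids: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.group_prob.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws table: chain, draw, parameter, level, value."""
        rows = []
        for j, name in enumerate(PARAM_NAMES):
            rows.append(pd.DataFrame({
                "chain": self.chain,
                "draw": np.arange(self.n_draws),
                "parameter": name,
                "level": "group",
                "value": self.group_prob[:, j],
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class GroupDifference:
    """Posterior young-minus-older differences per parameter."""

    parameter: list[str]
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    credible: np.ndarray  # True iff the 95% interval excludes 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.parameter,
            "mean": self.mean,
            "lower": self.lower,
            "upper": self.upper,
            "credible": self.credible,
        })


def split_rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction with chain splitting.

    ``chains`` has shape (n_chains, n_draws); each chain is split in half
    before computing the between/within variance ratio.
    """
    n_chains, n = chains.shape
    half = n // 2
    if half < 2:
        return np.nan
    seqs = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, n = seqs.shape
    means = seqs.mean(axis=1)
    w = seqs.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0 if b <= 0 else np.inf
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


# ---------------------------------------------------------------------------
# sampler internals

def _multinomial_loglik(counts: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Per-participant multinomial log-likelihood.

    counts (n, 3, 3), theta (n, 6) -> (n,).  Kernel only (no multinomial
    coefficient).
    """
    probs = category_probabilities_array(theta)
    probs = np.clip(probs, 1e-300, 1.0)
    return np.einsum("ijk,ijk->i", counts, np.log(probs))


def _init_state(counts: np.ndarray, x: np.ndarray, rng: np.random.Generator):
    n = counts.shape[0]
    eta = np.empty((n, N_PARAMS))
    from .task_data import FrequencyTable
    for i in range(n):
        try:
            est = moment_estimator(FrequencyTable(counts[i])).params.as_array()
        except EstimationError:
            est = np.full(N_PARAMS, 0.5)
        eta[i] = probit(np.clip(est, 0.05, 0.95))
    eta += rng.normal(0, 0.1, size=eta.shape)
    mu = eta.mean(axis=0)
    beta = np.zeros(N_PARAMS)
    lam = np.ones(N_PARAMS)
    q = np.eye(N_PARAMS)
    return eta, mu, beta, lam, q


def _run_chain(counts: np.ndarray, x: np.ndarray, cfg: LatentTraitConfig,
               rng: np.random.Generator):
    """One MCMC chain; returns thinned post-burn-in (mu, beta, eta) draws."""
    n = counts.shape[0]
    p = N_PARAMS
    eta, mu, beta, lam, q = _init_state(counts, x, rng)
    q_inv = np.linalg.inv(q)

    def sigma_inv():
        return q_inv / np.outer(lam, lam)

    step_eta = np.full((n, p), 0.3)
    step_lam = np.full(p, 0.3)
    step_shift = np.full(p, 0.1)
    acc_eta = np.zeros((n, p))
    acc_lam = np.zeros(p)
    acc_shift = np.zeros(p)
    adapt_window = 50

    loglik = _multinomial_loglik(counts, inverse_probit(eta))

    n_keep = cfg.draws_per_chain
    out_mu = np.empty((n_keep, p))
    out_beta = np.empty((n_keep, p))
    out_eta = np.empty((n_keep, n, p))
    keep = 0

    iw_df0 = p + 1
    iw_scale0 = np.eye(p)
    mu_prec0 = 1.0 / cfg.mu_prior_sd**2
    beta_prec0 = 1.0 / cfg.beta_prior_sd**2

    for it in range(cfg.n_iter):
        s_inv = sigma_inv()
        center = mu + np.outer(x, beta)          # (n, p)

        # --- eta: per-parameter vectorised random-walk Metropolis
        delta = eta - center
        quad = np.einsum("ij,jk,ik->i", delta, s_inv, delta)
        for j in range(p):
            prop = eta.copy()
            prop[:, j] = eta[:, j] + step_eta[:, j] * rng.standard_normal(n)
            d_prop = prop - center
            quad_prop = np.einsum("ij,jk,ik->i", d_prop, s_inv, d_prop)
            ll_prop = _multinomial_loglik(counts, inverse_probit(prop))
            log_alpha = (ll_prop - loglik) - 0.5 * (quad_prop - quad)
            accept = np.log(rng.random(n)) < log_alpha
            eta[accept, j] = prop[accept, j]
            loglik = np.where(accept, ll_prop, loglik)
            quad = np.where(accept, quad_prop, quad)
            delta = eta - center
            acc_eta[:, j] += accept

        # --- joint translation: shift mu_p and every eta_ip together.  The
        # group-mean direction otherwise only moves O(step/sqrt(n)) per
        # sweep through the individual updates; this move samples it
        # directly (delta, hence the MVN prior term, is unchanged).
        for j in range(p):
            c = step_shift[j] * rng.standard_normal()
            prop = eta.copy()
            prop[:, j] += c
            ll_prop = _multinomial_loglik(counts, inverse_probit(prop))
            mu_term = -0.5 * mu_prec0 * ((mu[j] + c) ** 2 - mu[j] ** 2)
            if np.log(rng.random()) < (ll_prop - loglik).sum() + mu_term:
                eta = prop
                mu = mu.copy()
                mu[j] += c
                loglik = ll_prop
                acc_shift[j] += 1

        # --- mu: conjugate MVN update
        prec = n * s_inv + mu_prec0 * np.eye(p)
        resid = (eta - np.outer(x, beta)).sum(axis=0)
        b = s_inv @ resid
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, b)
        z = rng.standard_normal(p)
        mu = mean + np.linalg.solve(chol.T, z)

        # --- beta: conjugate MVN update (skipped without covariate)
        if cfg.use_covariate and np.any(x != 0):
            sx2 = float((x**2).sum())
            prec_b = sx2 * s_inv + beta_prec0 * np.eye(p)
            resid_b = ((eta - mu) * x[:, None]).sum(axis=0)
            bb = s_inv @ resid_b
            chol_b = np.linalg.cholesky(prec_b)
            mean_b = np.linalg.solve(prec_b, bb)
            beta = mean_b + np.linalg.solve(chol_b.T, rng.standard_normal(p))

        # --- Q: conjugate inverse-Wishart update on the scaled residuals
        center = mu + np.outer(x, beta)
        delta = eta - center
        xi = delta / lam
        scale_post = iw_scale0 + xi.T @ xi
        # symmetrise against accumulated round-off before sampling
        scale_post = 0.5 * (scale_post + scale_post.T)
        try:
            q = stats.invwishart.rvs(df=iw_df0 + n, scale=scale_post, random_state=rng)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"degenerate covariance update at iteration {it}") from exc
        q_inv = np.linalg.inv(q)

        # --- lambda: scalar Metropolis, Uniform(0, lambda_upper) prior
        for j in range(p):
            prop_l = lam[j] + step_lam[j] * rng.standard_normal()
            if not 0.0 < prop_l < cfg.lambda_upper:
                continue
            lam_prop = lam.copy()
            lam_prop[j] = prop_l
            xi_cur = delta / lam
            xi_prop = delta / lam_prop
            lp_cur = -n * np.log(lam[j]) - 0.5 * np.einsum("ij,jk,ik->", xi_cur, q_inv, xi_cur)
            lp_prop = -n * np.log(prop_l) - 0.5 * np.einsum("ij,jk,ik->", xi_prop, q_inv, xi_prop)
            if np.log(rng.random()) < lp_prop - lp_cur:
                lam = lam_prop
                acc_lam[j] += 1

        # --- adapt proposals during burn-in only
        if it < cfg.burn_in and (it + 1) % adapt_window == 0:
            rate_eta = acc_eta / adapt_window
            step_eta *= np.exp(rate_eta - 0.44)
            step_eta = np.clip(step_eta, 1e-3, 10.0)
            acc_eta[:] = 0
            rate_lam = acc_lam / adapt_window
            step_lam *= np.exp(rate_lam - 0.44)
            step_lam = np.clip(step_lam, 1e-3, 10.0)
            acc_lam[:] = 0
            rate_shift = acc_shift / adapt_window
            step_shift *= np.exp(rate_shift - 0.44)
            step_shift = np.clip(step_shift, 1e-3, 10.0)
            acc_shift[:] = 0

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and keep < n_keep:
            out_mu[keep] = mu
            out_beta[keep] = beta
            out_eta[keep] = eta
            keep += 1

    return out_mu[:keep], out_beta[:keep], out_eta[:keep]


def sample_posterior(cohort: CohortTable, config: LatentTraitConfig) -> PosteriorDraws:
    """Fit the latent-trait hierarchical MPT to a single-group cohort.

    Runs ``config.n_chains`` independent chains (seeds spawned from
    ``config.seed``), returns thinned post-burn-in draws with per-parameter
    split-R-hat.  A non-converged result (any R-hat above threshold) is
    returned and flagged, not discarded.
    """
    if len(cohort) < 2:
        raise ValueError("need >= 2 participants for hierarchical estimation")
    if len(set(g for g in cohort.groups)) > 1:
        raise ValueError("sample_posterior expects a single-group cohort")
    counts = np.stack([t.counts for t in cohort.tables]).astype(float)
    if config.use_covariate:
        if cohort.covariates is None:
            raise ValueError("use_covariate=True but cohort has no covariates")
        x = cohort.covariates
    else:
        x = np.zeros(len(cohort))

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    mus, betas, etas, chain_ids = [], [], [], []
    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        m, b, e = _run_chain(counts, x, config, rng)
        mus.append(m)
        betas.append(b)
        etas.append(e)
        chain_ids.append(np.full(m.shape[0], c))

    per_chain_group = [inverse_probit(m) for m in mus]
    n_min = min(g.shape[0] for g in per_chain_group)
    rhat = np.array([
        split_rhat(np.stack([g[:n_min, j] for g in per_chain_group]))
        for j in range(N_PARAMS)
    ])

    mu_all = np.concatenate(mus)
    return PosteriorDraws(
        group_prob=inverse_probit(mu_all),
        individual_prob=inverse_probit(np.concatenate(etas)),
        mu=mu_all,
        beta=np.concatenate(betas) if config.use_covariate else None,
        chain=np.concatenate(chain_ids),
        rhat=rhat,
        converged=bool(np.all(rhat < config.rhat_threshold)),
        config=config,
        participant_ids=list(cohort.participant_ids),
    )


def posterior_predictive_pvalues(draws: PosteriorDraws, cohort: CohortTable,
                                 max_draws: int = 1000,
                                 seed: int | None = None) -> tuple[float, float]:
    """Posterior predictive p-values for mean frequencies (T1) and covariance (T2).

    For each retained draw, a replicate cohort is simulated from the
    individual-level parameters (per-tree trial counts fixed at the observed
    ones).  T1 is the summed squared deviation between the across-participant
    mean category-frequency vector (9 cells) and its model expectation; T2
    the summed squared deviation between the across-participant 9x9
    covariance matrix of category frequencies and its model expectation
    (between-participant covariance of expected frequencies plus the average
    within-participant multinomial covariance).  p = fraction of draws with
    T(replicate) >= T(observed); values in (0.05, 0.95) indicate adequate fit.
    """
    if draws.n_draws < 100:
        raise ValueError(f"need >= 100 draws, have {draws.n_draws}")
    rng = np.random.default_rng(draws.config.seed + 1 if seed is None else seed)
    counts = np.stack([t.counts for t in cohort.tables]).astype(float)
    n, _, _ = counts.shape
    if draws.individual_prob.shape[1] != n:
        raise ValueError("draws and cohort have different participant counts")
    n_tree = counts.sum(axis=2)  # (n, 3) answered trials per tree
    obs = counts.reshape(n, 9)
    obs_mean = obs.mean(axis=0)
    obs_cov = np.cov(obs, rowvar=False)

    idx = np.arange(draws.n_draws)
    if draws.n_draws > max_draws:
        idx = rng.choice(draws.n_draws, size=max_draws, replace=False)

    t1_obs = np.empty(len(idx))
    t1_rep = np.empty(len(idx))
    t2_obs = np.empty(len(idx))
    t2_rep = np.empty(len(idx))
    for k, d in enumerate(idx):
        theta = draws.individual_prob[d]            # (n, 6)
        probs = category_probabilities_array(theta)  # (n, 3, 3)
        expected = probs * n_tree[:, :, None]        # (n, 3, 3)
        exp_flat = expected.reshape(n, 9)
        exp_mean = exp_flat.mean(axis=0)
        # model covariance: spread of expectations + mean multinomial noise
        between = np.cov(exp_flat, rowvar=False)
        within = np.zeros((9, 9))
        for tr in range(3):
            pr = probs[:, tr, :]                    # (n, 3)
            nn = n_tree[:, tr][:, None, None]
            cov_tr = nn * (pr[:, :, None] * np.eye(3) - pr[:, :, None] * pr[:, None, :])
            sl = slice(3 * tr, 3 * tr + 3)
            within[sl, sl] = cov_tr.mean(axis=0)
        exp_cov = between + within

        rep = np.empty((n, 3, 3))
        for tr in range(3):
            rep[:, tr, :] = rng.multinomial(n_tree[:, tr].astype(int), probs[:, tr, :])
        rep_flat = rep.reshape(n, 9)

        t1_obs[k] = float(((obs_mean - exp_mean) ** 2).sum())
        t1_rep[k] = float(((rep_flat.mean(axis=0) - exp_mean) ** 2).sum())
        t2_obs[k] = float(((obs_cov - exp_cov) ** 2).sum())
        t2_rep[k] = float(((np.cov(rep_flat, rowvar=False) - exp_cov) ** 2).sum())

    p_t1 = float(np.mean(t1_rep >= t1_obs))
    p_t2 = float(np.mean(t2_rep >= t2_obs))
    return p_t1, p_t2


def group_difference(draws_young: PosteriorDraws, draws_older: PosteriorDraws,
                     seed: int = 0, level: float = 0.95) -> GroupDifference:
    """Posterior distribution of young-minus-older group-mean differences.

    The two posteriors come from independent fits, so draws are paired by
    index after a seeded random shuffle of each (the pairing is arbitrary;
    shuffling removes any residual autocorrelation alignment).  If the draw
    counts differ the longer set is subsampled.  Intervals are central
    (equal-tailed).
    """
    rng = np.random.default_rng(seed)
    a = draws_young.group_prob
    b = draws_older.group_prob
    m = min(a.shape[0], b.shape[0])
    ia = rng.permutation(a.shape[0])[:m]
    ib = rng.permutation(b.shape[0])[:m]
    diff = a[ia] - b[ib]
    alpha = (1.0 - level) / 2
    lower = np.quantile(diff, alpha, axis=0)
    upper = np.quantile(diff, 1 - alpha, axis=0)
    mean = diff.mean(axis=0)
    credible = (lower > 0) | (upper < 0)
    return GroupDifference(list(PARAM_NAMES), mean, lower, upper, credible)
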