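"""Data-augmented multi-species occupancy model (MSOM) and its
Metropolis-within-Gibbs sampler.

Model
-----
For species k (observed and augmented) and site i:

    z_ik ~ Bernoulli(psi_ik)                      latent occupancy
    y_ik ~ Binomial(n_i, p_k * z_ik * w_k)        detections in n_i occasions
    logit(psi_ik) = beta_0k + sum_m beta_mk X_mi  covariate model
    w_k ~ Bernoulli(Omega)                        community membership

Species-level parameters are pooled through a community hierarchy:
beta_mk ~ Normal(mu_m, sigma_m^2) per coefficient and
logit(p_k) ~ Normal(mu_p, sigma_p^2).  Hyperpriors are
mu ~ Normal(0, 10^2), sigma ~ Uniform(0, 5), Omega ~ Beta(1, 1).
The observed K species are padded with all-zero augmented rows so the
posterior of N = sum_k w_k estimates total community richness including
species never detected.

Sampler
-------
One sweep updates, in order: z (exact Bernoulli conditional), w for
augmented species (with the species' z marginalized out, then redrawn),
Omega (conjugate Beta), species-level beta and logit(p) (random-walk
Metropolis, vectorized across species; species with w = 0 draw from
their community priors), and the community hyperparameters (conjugate
normal means; random-walk on log sigma with the Jacobian term).
Proposal scales adapt during burn-in only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import binom as _binom

from .ingest import DetectionHistory

__all__ = [
    "AugmentedData",
    "MCMCConfig",
    "PosteriorSamples",
    "augment",
    "occupancy_prob",
    "obs_loglik",
    "z_conditional_prob",
    "w_conditional_prob",
    "omega_posterior_params",
    "mu_conjugate_posterior",
    "run_mcmc",
    "derive_richness",
    "gelman_rubin",
]

MU_PRIOR_SD = 10.0
SIGMA_UPPER = 5.0


# ---------------------------------------------------------------------------
# data containers


@dataclass
class AugmentedData:
    """Observed detection matrix padded with all-zero pseudo-species.

    ``y`` is M x I with the K observed species first; ``n`` is per-site
    effort; ``X`` is the I x P design matrix *including* the leading
    intercept column of ones.
    """

    y: np.ndarray
    n: np.ndarray
    X: np.ndarray
    n_obs: int
    species: list

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        self.n = np.asarray(self.n, dtype=int)
        self.X = np.asarray(self.X, dtype=float)
        M, I = self.y.shape
        if self.n.shape != (I,) or self.X.shape[0] != I:
            raise ValueError("inconsistent dimensions")
        if np.any(self.y > self.n[None, :]) or np.any(self.y < 0):
            raise ValueError("0 <= y_ik <= n_i violated")
        if self.n_obs > M:
            raise ValueError("n_obs cannot exceed M")
        if np.any(self.y[self.n_obs:] != 0):
            raise ValueError("augmented rows must be all zero")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("X must carry a leading intercept column")

    @property
    def M(self) -> int:
        return self.y.shape[0]

    @property
    def n_sites(self) -> int:
        return self.y.shape[1]

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]


def augment(history: DetectionHistory, design=None, n_aug: int | None = None,
            columns=None) -> AugmentedData:
    """Build the augmented input from a detection history and an optional
    design matrix (default: intercept only).  ``n_aug`` defaults to the
    observed species count K, matching the usual practice of doubling
    the community."""
    K = history.n_species
    if n_aug is None:
        n_aug = K
    if n_aug < 0:
        raise ValueError("n_aug must be >= 0")
    if design is None:
        X = np.ones((history.n_sites, 1))
    else:
        if columns is not None:
            design = design.select(columns)
        if list(design.site_ids) != list(history.sites):
            raise ValueError("design matrix sites do not match history sites")
        X = np.column_stack([np.ones(history.n_sites), design.X])
    y = np.vstack([history.y, np.zeros((n_aug, history.n_sites), dtype=int)])
    species = list(history.species) + [f"aug_{j+1}" for j in range(n_aug)]
    return AugmentedData(y=y, n=history.n, X=X, n_obs=K, species=species)


@dataclass
class MCMCConfig:
    """Sampler settings.  Defaults follow common MSOM practice: three
    chains of 100k iterations, 5k burn-in, thinning by 60."""

    n_chains: int = 3
    n_iter: int = 100_000
    burn_in: int = 5_000
    thin: int = 60
    seed: int = 0
    target_accept: float = 0.35
    adapt_window: int = 50
    init_jitter: float = 0.5
    store_species: bool = True

    def __post_init__(self):
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


# ---------------------------------------------------------------------------
# elementary model quantities (unit-testable closed forms)


def occupancy_prob(beta_k: np.ndarray, x_i: np.ndarray) -> float:
    """psi = logit^-1(beta . x) with the intercept prepended in both."""
    beta_k = np.asarray(beta_k, dtype=float)
    x_i = np.asarray(x_i, dtype=float)
    if beta_k.shape[-1] != x_i.shape[-1]:
        raise ValueError("coefficient and covariate lengths differ")
    return expit(x_i @ beta_k)


def obs_loglik(y: int, n: int, p: float, z: int) -> float:
    """Binomial observation log-likelihood given occupancy state z.

    z = 1: Binomial(n, p) log-pmf at y.  z = 0: 0 for y = 0 (certain),
    -inf for y > 0 (impossible).
    """
    if y < 0 or y > n:
        raise ValueError("need 0 <= y <= n")
    if z == 0:
        return 0.0 if y == 0 else -np.inf
    return float(_binom.logpmf(y, n, p))


def _log_expit(x):
    """log(expit(x)), numerically stable."""
    return -np.logaddexp(0.0, -np.asarray(x, dtype=float))


def z_conditional_prob(psi, p, n, y, w):
    """P(z_ik = 1 | everything else), elementwise.

    For w = 1: certain when y > 0, otherwise
    psi (1-p)^n / (psi (1-p)^n + 1 - psi).
    For w = 0 the likelihood is flat (y is forced 0) and z is drawn from
    its prior Bernoulli(psi).
    """
    psi, p, n, y, w = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (psi, p, n, y, w)))
    with np.errstate(divide="ignore"):
        log_num = np.log(psi) + n * np.log1p(-p)
        log_den = np.logaddexp(log_num, np.log1p(-psi))
    prob = np.where(log_den == -np.inf, 0.0, np.exp(log_num - log_den))
    prob = np.where(y > 0, 1.0, prob)
    prob = np.where(w == 0, psi, prob)
    if np.any((y > 0) & (w == 0)):
        raise ValueError("invalid state: y > 0 with w = 0")
    return prob


def w_conditional_prob(psi_k, p_k, n, omega):
    """P(w_k = 1 | y_k = 0, Omega) with the species' z marginalized out.

    L1 = prod_i [psi_ik (1-p_k)^{n_i} + (1 - psi_ik)] is the probability
    of an all-zero row given membership; then
    P(w=1) = Omega L1 / (Omega L1 + 1 - Omega).
    """
    psi_k = np.atleast_2d(np.asarray(psi_k, dtype=float))
    n = np.asarray(n, dtype=float)
    p_k = np.asarray(p_k, dtype=float).reshape(-1, 1)
    with np.errstate(divide="ignore"):
        log_l1 = np.logaddexp(np.log(psi_k) + n[None, :] * np.log1p(-p_k),
                              np.log1p(-psi_k)).sum(axis=1)
        log_odds = logit(omega) + log_l1
    return expit(log_odds)


def omega_posterior_params(w) -> tuple[float, float]:
    """Beta(1 + sum w, 1 + M - sum w) under the Beta(1,1) prior."""
    w = np.asarray(w)
    return 1.0 + float(w.sum()), 1.0 + float(w.size - w.sum())


def mu_conjugate_posterior(values, sigma, prior_sd=MU_PRIOR_SD):
    """Posterior (mean, var) of a normal mean with known sd and
    Normal(0, prior_sd^2) prior."""
    values = np.asarray(values, dtype=float)
    prec = values.size / sigma ** 2 + 1.0 / prior_sd ** 2
    mean = (values.sum() / sigma ** 2) / prec
    return mean, 1.0 / prec


# ---------------------------------------------------------------------------
# sampler internals


class _ChainState:
    __slots__ = ("beta", "logit_p", "w", "z", "mu", "sigma", "mu_p",
                 "sigma_p", "omega")

    def __init__(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)


def _bern_loglik(z, eta):
    """Sum_i Bernoulli(z_i; expit(eta_i)) log-likelihood per species."""
    # z*log(psi) + (1-z)*log(1-psi) = z*eta - log(1+exp(eta))
    return (z * eta).sum(axis=1) - np.logaddexp(0.0, eta).sum(axis=1)


def _init_state(data: AugmentedData, cfg: MCMCConfig, rng, chain: int):
    M, I, P = data.M, data.n_sites, data.n_coef
    j = cfg.init_jitter
    mu = rng.normal(0.0, j, size=P)
    obs_rate = data.y[:data.n_obs].sum() / (data.n.sum() * max(data.n_obs, 1))
    mu_p = float(np.clip(logit(max(obs_rate, 1e-4)), -6.0, -0.5)
                 + rng.normal(0.0, j))
    sigma = np.full(P, 1.0)
    sigma_p = 1.0
    beta = mu + rng.normal(0.0, 0.1, size=(M, P))
    logit_p = mu_p + rng.normal(0.0, 0.1, size=M)
    z = ((data.y > 0) | (rng.random((M, I)) < 0.5)).astype(np.int8)
    w = np.ones(M, dtype=np.int8)
    return _ChainState(beta=beta, logit_p=logit_p, w=w, z=z, mu=mu,
                       sigma=sigma, mu_p=mu_p, sigma_p=sigma_p, omega=0.5)


def _update_z(state, data, rng):
    eta = state.beta @ data.X.T
    psi = expit(eta)
    prob = z_conditional_prob(psi, expit(state.logit_p)[:, None],
                              data.n[None, :], data.y,
                              state.w[:, None].astype(float))
    state.z = np.asarray(rng.random(psi.shape) < prob, dtype=np.int8)
    state.z[data.y > 0] = 1


def _update_w(state, data, rng):
    if data.M == data.n_obs:
        return
    aug = slice(data.n_obs, data.M)
    eta = state.beta[aug] @ data.X.T
    psi = expit(eta)
    p = expit(state.logit_p[aug])
    pw = w_conditional_prob(psi, p, data.n, state.omega)
    state.w[aug] = rng.random(pw.shape) < pw
    # redraw z for augmented species under the new w
    prob = z_conditional_prob(psi, p[:, None], data.n[None, :],
                              np.zeros_like(psi),
                              state.w[aug, None].astype(float))
    state.z[aug] = rng.random(psi.shape) < prob


def _update_omega(state, data, rng):
    a, b = omega_posterior_params(state.w)
    state.omega = rng.beta(a, b)


def _update_species(state, data, rng, scales, acc):
    M, P = data.M, data.n_coef
    w1 = state.w.astype(bool)
    # --- beta block (random-walk, per species) -----------------------------
    prop = state.beta + rng.normal(size=(M, P)) * scales["beta"][:, None]
    eta_cur = state.beta @ data.X.T
    eta_prop = prop @ data.X.T
    ll_cur = _bern_loglik(state.z, eta_cur)
    ll_prop = _bern_loglik(state.z, eta_prop)
    pr_cur = -0.5 * (((state.beta - state.mu) / state.sigma) ** 2).sum(axis=1)
    pr_prop = -0.5 * (((prop - state.mu) / state.sigma) ** 2).sum(axis=1)
    accept = np.log(rng.random(M)) < (ll_prop + pr_prop - ll_cur - pr_cur)
    take = accept & w1
    state.beta[take] = prop[take]
    acc["beta"] += np.where(w1, accept, 0)
    acc["beta_n"] += w1
    # w = 0 species: likelihood is flat -> draw from the community prior
    n0 = int((~w1).sum())
    if n0:
        state.beta[~w1] = state.mu + state.sigma * rng.normal(size=(n0, P))

    # --- detection block ----------------------------------------------------
    lp_prop = state.logit_p + rng.normal(size=M) * scales["p"]
    a_k = (state.z * data.y).sum(axis=1)
    b_k = (state.z * (data.n[None, :] - data.y)).sum(axis=1)
    def p_loglik(lp):
        return a_k * _log_expit(lp) + b_k * _log_expit(-lp)
    pr_cur = -0.5 * ((state.logit_p - state.mu_p) / state.sigma_p) ** 2
    pr_prop = -0.5 * ((lp_prop - state.mu_p) / state.sigma_p) ** 2
    accept = np.log(rng.random(M)) < (
        p_loglik(lp_prop) + pr_prop - p_loglik(state.logit_p) - pr_cur)
    take = accept & w1
    state.logit_p[take] = lp_prop[take]
    acc["p"] += np.where(w1, accept, 0)
    acc["p_n"] += w1
    if n0:
        state.logit_p[~w1] = state.mu_p + state.sigma_p * rng.normal(size=n0)


def _update_hyper(state, data, rng, scales, acc):
    M, P = data.M, data.n_coef
    # conjugate means
    for vals, sig, attr in ((state.beta, state.sigma, "mu"),):
        prec = M / sig ** 2 + 1.0 / MU_PRIOR_SD ** 2
        mean = (vals.sum(axis=0) / sig ** 2) / prec
        state.mu = mean + rng.normal(size=P) / np.sqrt(prec)
    m, v = mu_conjugate_posterior(state.logit_p, state.sigma_p)
    state.mu_p = m + rng.normal() * np.sqrt(v)

    # sigma: random-walk on log sigma, Uniform(0,5) prior, with Jacobian
    def sigma_logpost(s, ssq, count):
        out = np.where((s > 0) & (s < SIGMA_UPPER),
                       -count * np.log(s) - ssq / (2.0 * s ** 2) + np.log(s),
                       -np.inf)
        return out
    ssq = ((state.beta - state.mu) ** 2).sum(axis=0)
    s_prop = state.sigma * np.exp(rng.normal(size=P) * scales["sigma"])
    accept = np.log(rng.random(P)) < (
        sigma_logpost(s_prop, ssq, M) - sigma_logpost(state.sigma, ssq, M))
    state.sigma = np.where(accept, s_prop, state.sigma)
    acc["sigma"] += accept
    acc["sigma_n"] += 1

    ssq_p = ((state.logit_p - state.mu_p) ** 2).sum()
    sp_prop = state.sigma_p * np.exp(rng.normal() * scales["sigma_p"])
    if (np.log(rng.random())
            < sigma_logpost(np.array(sp_prop), ssq_p, M)
            - sigma_logpost(np.array(state.sigma_p), ssq_p, M)):
        state.sigma_p = sp_prop
        acc["sigma_p"] += 1
    acc["sigma_p_n"] += 1


def _adapt(scales, acc, target):
    for key in ("beta", "p", "sigma", "sigma_p"):
        n = np.maximum(acc[key + "_n"], 1)
        rate = acc[key] / n
        scales[key] = np.clip(
            scales[key] * np.exp(0.5 * (rate - target)), 1e-3, 10.0)
        acc[key] = np.zeros_like(np.asarray(acc[key], dtype=float))
        acc[key + "_n"] = np.zeros_like(np.asarray(acc[key + "_n"],
                                                   dtype=float))


def _run_chain(data: AugmentedData, cfg: MCMCConfig, chain: int,
               fix_hyper: dict | None = None):
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, chain]))
    M, I, P = data.M, data.n_sites, data.n_coef
    state = _init_state(data, cfg, rng, chain)
    if fix_hyper:
        for k, v in fix_hyper.items():
            setattr(state, k, np.asarray(v, dtype=float)
                    if np.ndim(v) else float(v))
        state.beta = state.mu + 0.1 * rng.normal(size=(M, P))
        state.logit_p = state.mu_p + 0.1 * rng.normal(size=M)
    scales = {"beta": np.full(M, 0.3), "p": np.full(M, 0.5),
              "sigma": np.full(P, 0.3), "sigma_p": 0.3}
    acc = {"beta": np.zeros(M), "beta_n": np.zeros(M),
           "p": np.zeros(M), "p_n": np.zeros(M),
           "sigma": np.zeros(P), "sigma_n": np.zeros(P),
           "sigma_p": 0.0, "sigma_p_n": 0.0}

    n_keep = (cfg.n_iter - cfg.burn_in + cfg.thin - 1) // cfg.thin
    out = {
        "omega": np.empty(n_keep),
        "mu": np.empty((n_keep, P)),
        "sigma": np.empty((n_keep, P)),
        "mu_p": np.empty(n_keep),
        "sigma_p": np.empty(n_keep),
        "N": np.empty(n_keep, dtype=int),
        "Ni": np.empty((n_keep, I), dtype=int),
    }
    if cfg.store_species:
        out["beta"] = np.empty((n_keep, M, P))
        out["logit_p"] = np.empty((n_keep, M))
        out["w"] = np.empty((n_keep, M), dtype=np.int8)

    kept = 0
    for it in range(cfg.n_iter):
        _update_z(state, data, rng)
        _update_w(state, data, rng)
        _update_omega(state, data, rng)
        _update_species(state, data, rng, scales, acc)
        if fix_hyper is None:
            _update_hyper(state, data, rng, scales, acc)
        if it < cfg.burn_in:
            if (it + 1) % cfg.adapt_window == 0:
                _adapt(scales, acc, cfg.target_accept)
        elif (it - cfg.burn_in) % cfg.thin == 0:
            out["omega"][kept] = state.omega
            out["mu"][kept] = state.mu
            out["sigma"][kept] = state.sigma
            out["mu_p"][kept] = state.mu_p
            out["sigma_p"][kept] = state.sigma_p
            out["N"][kept] = int(state.w.sum())
            out["Ni"][kept] = (state.w[:, None] * state.z).sum(axis=0)
            if cfg.store_species:
                out["beta"][kept] = state.beta
                out["logit_p"][kept] = state.logit_p
                out["w"][kept] = state.w
            kept += 1
    for k in out:
        out[k] = out[k][:kept]
    rates = {"beta": float(np.mean(acc["beta"] / np.maximum(acc["beta_n"], 1))),
             "p": float(np.mean(acc["p"] / np.maximum(acc["p_n"], 1)))}
    return out, rates


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws, stacked as (chain, draw, ...)."""

    draws: dict
    data: AugmentedData
    config: MCMCConfig
    accept_rates: list = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.draws["N"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["N"].shape[1]

    def trace(self, name: str) -> np.ndarray:
        return self.draws[name]

    def flat(self, name: str) -> np.ndarray:
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def community_psi(self) -> np.ndarray:
        """Per-draw community mean occupancy, logit^-1(mu_0)."""
        return expit(self.flat("mu")[:, 0])

    def community_p(self) -> np.ndarray:
        """Per-draw community mean detection, logit^-1(mu_p)."""
        return expit(self.flat("mu_p"))

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd, percentile CRI and R-hat for the headline
        parameters (Omega, community psi/p, hypermeans/sds, N)."""
        rows = {}
        def add(name, per_chain):
            flat = per_chain.reshape(-1)
            rows[name] = {
                "mean": flat.mean(), "sd": flat.std(ddof=1),
                "q2.5": np.percentile(flat, 2.5),
                "median": np.percentile(flat, 50),
                "q97.5": np.percentile(flat, 97.5),
                "rhat": gelman_rubin(per_chain),
            }
        add("N", self.draws["N"].astype(float))
        add("psi_community", expit(self.draws["mu"][:, :, 0]))
        add("p_community", expit(self.draws["mu_p"]))
        add("omega", self.draws["omega"])
        for j in range(self.draws["mu"].shape[-1]):
            add(f"mu[{j}]", self.draws["mu"][:, :, j])
            add(f"sigma[{j}]", self.draws["sigma"][:, :, j])
        add("mu_p", self.draws["mu_p"])
        add("sigma_p", self.draws["sigma_p"])
        return pd.DataFrame(rows).T

    def species_summary(self) -> pd.DataFrame:
        """Per observed species: posterior mean detection probability and
        site-averaged occupancy probability with 95% CRI."""
        if "beta" not in self.draws:
            raise ValueError("species draws were not stored")
        K = self.data.n_obs
        beta = self.flat("beta")[:, :K, :]
        p = expit(self.flat("logit_p")[:, :K])
        psi = expit(np.einsum("dkp,ip->dki", beta, self.data.X)).mean(axis=2)
        rows = []
        for k, sp in enumerate(self.data.species[:K]):
            rows.append({
                "species": sp,
                "p_mean": p[:, k].mean(),
                "p_lo": np.percentile(p[:, k], 2.5),
                "p_hi": np.percentile(p[:, k], 97.5),
                "psi_mean": psi[:, k].mean(),
                "psi_lo": np.percentile(psi[:, k], 2.5),
                "psi_hi": np.percentile(psi[:, k], 97.5),
            })
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        np.savez_compressed(path, **self.draws)


def run_mcmc(data: AugmentedData, cfg: MCMCConfig,
             fix_hyper: dict | None = None) -> PosteriorSamples:
    """Run ``cfg.n_chains`` independent chains and stack their draws.

    Each chain gets a distinct child seed of ``cfg.seed``; the run is
    bit-reproducible.  ``fix_hyper`` freezes community hyperparameters
    (used for validation against low-dimensional oracles).
    """
    chains, rates = [], []
    for c in range(cfg.n_chains):
        out, r = _run_chain(data, cfg, c, fix_hyper=fix_hyper)
        chains.append(out)
        rates.append(r)
    draws = {k: np.stack([c[k] for c in chains]) for k in chains[0]}
    return PosteriorSamples(draws=draws, data=data, config=cfg,
                            accept_rates=rates)


def derive_richness(samples: PosteriorSamples) -> pd.Series:
    """Posterior summary of community richness N = sum_k w_k."""
    n = samples.flat("N").astype(float)
    return pd.Series({
        "mean": n.mean(), "sd": n.std(ddof=1),
        "q2.5": np.percentile(n, 2.5), "median": np.percentile(n, 50),
        "q97.5": np.percentile(n, 97.5),
    })


def gelman_rubin(traces: np.ndarray) -> float:
    """Classic Gelman-Rubin potential scale reduction factor.

    ``traces`` is (n_chains, n_draws).  W is the mean within-chain
    variance, B/n the variance of chain means; R-hat =
    sqrt(((n-1)/n W + B/n) / W).  Returns NaN when W = 0.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2 or traces.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    m, n = traces.shape
    within = traces.var(axis=1, ddof=1).mean()
    between_over_n = traces.mean(axis=1).var(ddof=1)
    if within == 0:
        return float("nan")
    v_hat = (n - 1) / n * within + between_over_n
    return float(np.sqrt(v_hat / within))
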