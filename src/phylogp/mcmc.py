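"""Metropolis sampler for the posterior over per-site log rates and GP
hyperparameters.

The state has two blocks updated sequentially with symmetric proposals:

* the log-rate vector ``r``, proposed by Neal's underrelaxed prior-preserving
  move ``r' = sqrt(1 - eps^2) r + eps L z`` (``L`` the Cholesky factor of the
  prior covariance, ``z`` standard normal).  Because the move leaves the GP
  prior invariant, the Metropolis ratio reduces to the likelihood ratio, and
  the likelihood is read from the interpolated rate-grid cache;
* the hyperparameters ``(l, s)``, random-walked jointly on the log scale
  (with the exponential priors expressed on the natural scale, the log-scale
  move needs an explicit Jacobian term ``l s``), each acceptance triggering a
  fresh covariance build and Cholesky factorization.

The rate block is updated ``rate_updates_per_iter`` (default 50) times per
iteration and the hyper block once, since a hyper update costs a cubic-time
factorization while a rate update costs a matrix-vector product.  Both step
sizes are adapted toward a 0.25 acceptance rate during burn-in only
(Robbins–Monro), then frozen so the recorded phase satisfies detailed
balance.  Every ``thin``-th post-burn-in iteration is recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .gp_prior import (
    CovarianceBuilder,
    HyperPrior,
    NumericalError,
    gp_log_density,
    log_hyper_prior,
)
from .phylo_core import SiteLikelihoodCache

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "RateSummary",
    "propose_rates",
    "run_chain",
    "run_chains",
    "summarize",
]


@dataclass
class MCMCConfig:
    """Sampler schedule and tuning knobs.

    ``epsilon`` and ``hyper_step`` are initial step sizes; both are adapted
    during burn-in toward ``target_acceptance`` and frozen afterwards.
    """

    n_iterations: int = 20_000
    burn_in_fraction: float = 0.5
    thin: int = 10
    rate_updates_per_iter: int = 50
    epsilon: float = 0.1
    hyper_step: float = 0.5
    seed: int = 0
    target_acceptance: float = 0.25
    adapt_interval: int = 25
    n_chains: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.burn_in_fraction < 1):
            raise ValueError("burn_in_fraction must be in (0, 1)")
        if not (0 < self.epsilon <= 1):
            raise ValueError("epsilon must be in (0, 1]")
        if self.n_iterations < self.thin:
            raise ValueError("n_iterations must be >= thin")


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws of (r, l, s) from one chain."""

    log_rates: np.ndarray  # (n_draws, n_sites)
    lengthscales: np.ndarray  # (n_draws,)
    signal_sds: np.ndarray  # (n_draws,)
    acceptance: dict  # per update type: accepted/proposed, burn-in and after
    chain_id: int = 0
    final_epsilon: float = float("nan")
    final_hyper_step: float = float("nan")

    @property
    def n_draws(self) -> int:
        return self.log_rates.shape[0]

    @property
    def n_sites(self) -> int:
        return self.log_rates.shape[1]


def propose_rates(
    r: np.ndarray, chol: np.ndarray, epsilon: float, rng: np.random.Generator
) -> np.ndarray:
    """Underrelaxed prior-preserving proposal r' = sqrt(1-eps^2) r + eps L z."""
    if not (0 <= epsilon <= 1):
        raise ValueError("epsilon must be in [0, 1]")
    z = rng.standard_normal(len(r))
    return math.sqrt(1.0 - epsilon * epsilon) * r + epsilon * (chol @ z)


class _Tally:
    __slots__ = ("accepted", "proposed")

    def __init__(self) -> None:
        self.accepted = 0
        self.proposed = 0

    def hit(self, accepted: bool) -> None:
        self.proposed += 1
        self.accepted += int(accepted)

    @property
    def rate(self) -> float:
        return self.accepted / self.proposed if self.proposed else float("nan")

    def as_dict(self) -> dict:
        return {"accepted": self.accepted, "proposed": self.proposed, "rate": self.rate}


def _nn_distance(D: np.ndarray) -> float:
    """Mean nearest-neighbour distance, used for the length-scale start."""
    if D.shape[0] < 2:
        return 1.0
    off = D + np.diag(np.full(D.shape[0], np.inf))
    return float(off.min(axis=1).mean())


def run_chain(
    cache: SiteLikelihoodCache | None,
    D: np.ndarray,
    config: MCMCConfig,
    *,
    kernel: str = "matern15",
    jitter: float = 1e-6,
    prior: HyperPrior | None = None,
    fix_hypers: tuple[float, float] | None = None,
    seed: int | np.random.SeedSequence | None = None,
    chain_id: int = 0,
) -> PosteriorSamples:
    """Run one Metropolis chain and return its thinned post-burn-in draws.

    ``cache`` may be ``None`` for a likelihood-free (prior-only) run, which
    is useful for validating that the sampler reproduces its own prior.
    ``fix_hypers`` pins (length_scale, signal_sd) and disables hyper updates.
    Deterministic given the seed.
    """
    prior = prior or HyperPrior()
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if cache is not None and cache.n_sites != n:
        raise ValueError(f"cache has {cache.n_sites} sites but D is {n}x{n}")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    if fix_hypers is not None:
        length_scale, signal_sd = fix_hypers
    else:
        length_scale = 2.0 * _nn_distance(D)
        signal_sd = 1.0
    builder = CovarianceBuilder(D, kernel=kernel, jitter=jitter)
    cov = builder.build(length_scale, signal_sd)
    r = cov.chol @ rng.standard_normal(n)

    def loglik(rv: np.ndarray) -> tuple[np.ndarray, float]:
        if cache is None:
            return np.zeros(n), 0.0
        per_site = cache.interp_all(rv)
        return per_site, float(per_site.sum())

    _, cur_ll = loglik(r)
    if not np.isfinite(cur_ll):
        raise RuntimeError(
            f"non-finite log-likelihood {cur_ll} at initialization "
            f"(l={length_scale:g}, s={signal_sd:g})"
        )

    burn = int(round(config.n_iterations * config.burn_in_fraction))
    eps = config.epsilon
    hstep = config.hyper_step
    tallies = {
        "rate_burnin": _Tally(),
        "rate": _Tally(),
        "hyper_burnin": _Tally(),
        "hyper": _Tally(),
    }
    window = {"rate": _Tally(), "hyper": _Tally()}
    adapt_round = 0

    draws_r: list[np.ndarray] = []
    draws_l: list[float] = []
    draws_s: list[float] = []

    for it in range(config.n_iterations):
        in_burn = it < burn
        rate_tally = tallies["rate_burnin" if in_burn else "rate"]
        hyper_tally = tallies["hyper_burnin" if in_burn else "hyper"]

        # one batched draw of the iteration's proposal noise and uniforms
        zs = rng.standard_normal((config.rate_updates_per_iter, n))
        log_us = np.log(rng.random(config.rate_updates_per_iter))
        shrink = math.sqrt(1.0 - eps * eps)
        innovations = eps * (zs @ cov.chol.T)
        for k in range(config.rate_updates_per_iter):
            r_new = shrink * r + innovations[k]
            _, new_ll = loglik(r_new)
            accept = log_us[k] < new_ll - cur_ll
            if accept:
                r, cur_ll = r_new, new_ll
            rate_tally.hit(accept)
            if in_burn:
                window["rate"].hit(accept)

        if fix_hypers is None:
            log_l, log_s = math.log(length_scale), math.log(signal_sd)
            prop_log_l, prop_log_s = (
                np.array([log_l, log_s]) + hstep * rng.standard_normal(2)
            )
            new_l, new_s = math.exp(prop_log_l), math.exp(prop_log_s)
            accept = False
            try:
                new_cov = builder.build(new_l, new_s)
            except NumericalError:
                new_cov = None  # treat as rejected
            if new_cov is not None:
                # likelihood does not involve (l, s); Jacobian l*s from the
                # log-scale walk against natural-scale priors
                log_ratio = (
                    gp_log_density(r, new_cov)
                    - gp_log_density(r, cov)
                    + log_hyper_prior(new_l, new_s, prior)
                    - log_hyper_prior(length_scale, signal_sd, prior)
                    + (prop_log_l + prop_log_s)
                    - (log_l + log_s)
                )
                accept = math.log(rng.random()) < log_ratio
            if accept:
                length_scale, signal_sd, cov = new_l, new_s, new_cov
            hyper_tally.hit(accept)
            if in_burn:
                window["hyper"].hit(accept)

        if in_burn and (it + 1) % config.adapt_interval == 0:
            adapt_round += 1
            gain = 1.0 / math.sqrt(adapt_round)
            eps = min(1.0, max(1e-3, eps * math.exp(gain * (window["rate"].rate - config.target_acceptance))))
            if fix_hypers is None and window["hyper"].proposed:
                hstep = min(10.0, max(1e-3, hstep * math.exp(gain * (window["hyper"].rate - config.target_acceptance))))
            window = {"rate": _Tally(), "hyper": _Tally()}

        if not in_burn and (it - burn + 1) % config.thin == 0:
            draws_r.append(r.copy())
            draws_l.append(length_scale)
            draws_s.append(signal_sd)

    return PosteriorSamples(
        log_rates=np.array(draws_r).reshape(len(draws_r), n),
        lengthscales=np.array(draws_l),
        signal_sds=np.array(draws_s),
        acceptance={k: t.as_dict() for k, t in tallies.items()},
        chain_id=chain_id,
        final_epsilon=eps,
        final_hyper_step=hstep,
    )


def run_chains(
    cache: SiteLikelihoodCache | None,
    D: np.ndarray,
    config: MCMCConfig,
    **kwargs,
) -> list[PosteriorSamples]:
    """Run ``config.n_chains`` independent chains with seeds derived from
    ``config.seed`` via a SeedSequence spawn."""
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    return [
        run_chain(cache, D, config, seed=s, chain_id=i, **kwargs)
        for i, s in enumerate(seeds)
    ]


@dataclass
class RateSummary:
    """Pooled posterior summary across one or more chains."""

    mean_rate: np.ndarray  # (n_sites,) posterior mean of exp(r)
    lower: np.ndarray  # 2.5% quantile of exp(r)
    upper: np.ndarray  # 97.5% quantile of exp(r)
    median_lengthscale: float
    median_signal_sd: float
    n_draws: int
    split_rhat_lengthscale: float = float("nan")


def summarize(samples: PosteriorSamples | list[PosteriorSamples]) -> RateSummary:
    """Pool chains and summarize: per-site mean rates (mean of exp(r)),
    95% credible intervals, and median hyperparameters."""
    chains = [samples] if isinstance(samples, PosteriorSamples) else list(samples)
    if not chains:
        raise ValueError("need at least one chain")
    n_sites = {c.n_sites for c in chains}
    if len(n_sites) != 1:
        raise ValueError("chains disagree on the number of sites")
    if sum(c.n_draws for c in chains) == 0:
        raise ValueError("no post-burn-in draws to summarize")
    rates = np.exp(np.vstack([c.log_rates for c in chains]))
    ls = np.concatenate([c.lengthscales for c in chains])
    ss = np.concatenate([c.signal_sds for c in chains])

    rhat = float("nan")
    if len(chains) >= 2 and min(c.n_draws for c in chains) >= 4:
        m = min(c.n_draws for c in chains)
        per = np.array([c.lengthscales[:m] for c in chains])
        w = per.var(axis=1, ddof=1).mean()
        b = m * per.mean(axis=1).var(ddof=1)
        if w > 0:
            rhat = math.sqrt((m - 1) / m + b / (w * m))

    return RateSummary(
        mean_rate=rates.mean(axis=0),
        lower=np.quantile(rates, 0.025, axis=0),
        upper=np.quantile(rates, 0.975, axis=0),
        median_lengthscale=float(np.median(ls)),
        median_signal_sd=float(np.median(ss)),
        n_draws=rates.shape[0],
        split_rhat_lengthscale=rhat,
    )
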