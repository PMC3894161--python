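"""Gaussian-process prior over site-specific log substitution rates.

The prior treats the vector of per-site log rates as one draw from a
zero-mean Gaussian process evaluated at the residue coordinates, with the
covariance a function of pairwise C-alpha distance.  Three stationary
kernels are supported — Matérn 1.5 (default), Matérn 2.5 and the squared
exponential — all special cases of the Matérn family differing in the
smoothness of the latent rate field.  A small fixed jitter is added to the
diagonal so the Cholesky factorization stays numerically stable.

Hyperparameters: the characteristic length scale ``l`` (Å; how far spatial
correlation extends) and the signal standard deviation ``s`` (unitless;
marginal spread of log rates at a single site).  Both carry independent
exponential priors parameterized by their means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular, LinAlgError

__all__ = [
    "KERNELS",
    "CovarianceBuilder",
    "CovarianceSpec",
    "CovarianceMatrix",
    "HyperPrior",
    "NumericalError",
    "kernel_value",
    "build_covariance",
    "gp_log_density",
    "log_hyper_prior",
    "sample_prior",
]

KERNELS = ("matern15", "matern25", "squared_exponential")

_SQRT3 = math.sqrt(3.0)
_SQRT5 = math.sqrt(5.0)


class NumericalError(RuntimeError):
    """Covariance factorization failed despite the jitter."""


@dataclass
class CovarianceSpec:
    """Kernel family and hyperparameters of the GP prior."""

    kernel: str = "matern15"
    length_scale: float = 10.0  # Å
    signal_sd: float = 1.0
    jitter: float = 1e-6

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}; choose from {KERNELS}")
        if self.length_scale <= 0 or self.signal_sd <= 0 or self.jitter <= 0:
            raise ValueError("length_scale, signal_sd and jitter must be > 0")

    def replace(self, **kw) -> "CovarianceSpec":
        d = dict(kernel=self.kernel, length_scale=self.length_scale,
                 signal_sd=self.signal_sd, jitter=self.jitter)
        d.update(kw)
        return CovarianceSpec(**d)


@dataclass
class CovarianceMatrix:
    """A covariance matrix together with its lower Cholesky factor."""

    K: np.ndarray
    chol: np.ndarray  # lower triangular, K = chol @ chol.T

    @property
    def n(self) -> int:
        return self.K.shape[0]

    @property
    def log_det(self) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(self.chol))))


@dataclass
class HyperPrior:
    """Independent exponential priors on (length scale, signal sd).

    Parameterized by the exponential MEANS; the defaults (100 Å, 10) are
    weakly informative over realistic protein dimensions and realistic
    spreads of log substitution rates.
    """

    scale_l: float = 100.0  # Å
    scale_s: float = 10.0

    def __post_init__(self) -> None:
        if self.scale_l <= 0 or self.scale_s <= 0:
            raise ValueError("prior scales must be > 0")


def kernel_value(d, spec: CovarianceSpec, same_site: bool = False):
    """Covariance of log rates at distance ``d`` Å (scalar or array).

    The jitter is added only when ``same_site`` is true (diagonal entries).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    l, s2 = spec.length_scale, spec.signal_sd**2
    if spec.kernel == "matern15":
        a = _SQRT3 * d / l
        k = s2 * (1.0 + a) * np.exp(-a)
    elif spec.kernel == "matern25":
        a = _SQRT5 * d / l
        k = s2 * (1.0 + a + a * a / 3.0) * np.exp(-a)
    else:  # squared_exponential
        k = s2 * np.exp(-(d * d) / (2.0 * l * l))
    if same_site:
        k = k + spec.jitter
    return k if k.ndim else float(k)


def build_covariance(D: np.ndarray, spec: CovarianceSpec) -> CovarianceMatrix:
    """Kernel matrix over a pairwise distance matrix, jitter on the diagonal.

    Raises :class:`NumericalError` (reporting the hyperparameters) if the
    Cholesky factorization fails even with the jitter.
    """
    D = np.asarray(D, dtype=float)
    K = kernel_value(D, spec)
    K[np.diag_indices_from(K)] += spec.jitter
    try:
        L = cholesky(K, lower=True, check_finite=False)
    except LinAlgError as exc:
        raise NumericalError(
            f"Cholesky failed for kernel={spec.kernel} "
            f"l={spec.length_scale:g} s={spec.signal_sd:g} jitter={spec.jitter:g}"
        ) from exc
    return CovarianceMatrix(K, L)


class CovarianceBuilder:
    """Repeated kernel-matrix builds over one fixed distance matrix.

    Hyperparameter proposals rebuild K at every MCMC step; since the kernel
    is a pointwise function of distance, evaluating it once per *distinct*
    distance and gathering is much cheaper than evaluating it per entry
    (a regular lattice has O(n) distinct distances for n^2 entries).
    """

    def __init__(self, D: np.ndarray, kernel: str = "matern15", jitter: float = 1e-6):
        D = np.asarray(D, dtype=float)
        self.n = D.shape[0]
        self.kernel = kernel
        self.jitter = jitter
        self._uniq, self._inv = np.unique(D, return_inverse=True)
        self._diag = np.diag_indices(self.n)

    def build(self, length_scale: float, signal_sd: float) -> CovarianceMatrix:
        spec = CovarianceSpec(self.kernel, length_scale, signal_sd, self.jitter)
        kvals = kernel_value(self._uniq, spec)
        K = kvals[self._inv].reshape(self.n, self.n)
        K[self._diag] += self.jitter
        try:
            L = cholesky(K, lower=True, check_finite=False)
        except LinAlgError as exc:
            raise NumericalError(
                f"Cholesky failed for kernel={self.kernel} "
                f"l={length_scale:g} s={signal_sd:g} jitter={self.jitter:g}"
            ) from exc
        return CovarianceMatrix(K, L)


def gp_log_density(r: np.ndarray, cov: CovarianceMatrix) -> float:
    """Zero-mean multivariate normal log-density of ``r`` under ``cov``."""
    r = np.asarray(r, dtype=float)
    if r.shape != (cov.n,):
        raise ValueError(f"dimension mismatch: r has shape {r.shape}, K is {cov.n}x{cov.n}")
    z = solve_triangular(cov.chol, r, lower=True, check_finite=False)
    return float(-0.5 * z @ z - 0.5 * cov.log_det - 0.5 * cov.n * math.log(2.0 * math.pi))


def log_hyper_prior(length_scale: float, signal_sd: float, prior: HyperPrior) -> float:
    """Log density of the independent exponential hyperpriors.

    Non-positive arguments return ``-inf`` (a rejected MCMC state) rather
    than raising.
    """
    if length_scale <= 0 or signal_sd <= 0:
        return -math.inf
    return (
        -math.log(prior.scale_l) - length_scale / prior.scale_l
        - math.log(prior.scale_s) - signal_sd / prior.scale_s
    )


def sample_prior(cov: CovarianceMatrix, rng: np.random.Generator) -> np.ndarray:
    """One draw of the log-rate vector from the GP prior: L @ z."""
    return cov.chol @ rng.standard_normal(cov.n)
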