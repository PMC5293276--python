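"""Log-densities of the model building blocks.

The observation model is Poisson with multiplicative expected counts,
``o_it ~ Poisson(e_it * r_it)`` with
``log r_it = beta + u_i(j) + v_j + gamma_t + delta_jt``.  The component
priors are zero-mean exchangeable Gaussians (area, region, interaction), an
intrinsic first-order random walk for the temporal effect, an optional
intrinsic CAR for the area effect, and Gamma(1, 0.0005) hyperpriors on the
precisions (stated on the log-precision scale in the source literature as
logGamma(1, 0.0005)).
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import gammaln
from scipy.stats import poisson

from .geography import Geography
from .panel import ModelComponents

LOG_2PI = float(np.log(2.0 * np.pi))

#: default hyperprior on each precision: tau ~ Gamma(shape, rate)
HYPER_SHAPE = 1.0
HYPER_RATE = 5e-4


def log_likelihood(
    o: np.ndarray, e: np.ndarray, components: ModelComponents, geo: Geography
) -> float:
    """Poisson log-likelihood of the panel given the latent components.

    Cells with ``e = 0`` and ``o = 0`` contribute zero; an observed event in
    a zero-expectation cell is a data error.
    """
    o = np.asarray(o, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any((e == 0) & (o > 0)):
        raise ValueError("cells with o > 0 must have e > 0")
    eta = components.linear_predictor(geo.region_index)
    mu = e * np.exp(eta)
    live = e > 0
    return float(poisson.logpmf(o[live], mu[live]).sum())


def rw1_logdensity(
    gamma: np.ndarray, tau_gamma: float, *, normalized: bool = False
) -> float:
    """Intrinsic RW1 log-density of a temporal effect vector.

    ``((T-1)/2) log(tau/2pi) - (tau/2) sum_t (gamma_t - gamma_{t-1})^2``,
    improper (invariant to a level shift); identification comes from the
    sum-to-zero constraint applied at sampling time.  With
    ``normalized=True`` the generalized-determinant constant ``(1/2) log T``
    is added, making the value the exact Gaussian density on the sum-to-zero
    subspace.
    """
    g = np.asarray(gamma, dtype=float)
    T = g.size
    if T < 2:
        raise ValueError("RW1 needs T >= 2")
    if tau_gamma <= 0:
        raise ValueError("tau must be positive")
    val = 0.5 * (T - 1) * (np.log(tau_gamma) - LOG_2PI)
    val -= 0.5 * tau_gamma * float(np.sum(np.diff(g) ** 2))
    if normalized:
        val += 0.5 * np.log(T)
    return float(val)


def exchangeable_logdensity(x: np.ndarray, tau: float) -> float:
    """iid zero-mean Gaussian log-density with precision ``tau``."""
    x = np.asarray(x, dtype=float)
    if tau <= 0:
        raise ValueError("tau must be positive")
    n = x.size
    return float(0.5 * n * (np.log(tau) - LOG_2PI) - 0.5 * tau * np.sum(x**2))


def _laplacian(n: int, adjacency: np.ndarray) -> np.ndarray:
    L = np.zeros((n, n))
    for a, b in adjacency:
        L[a, a] += 1
        L[b, b] += 1
        L[a, b] -= 1
        L[b, a] -= 1
    return L


def icar_logdensity(
    x: np.ndarray,
    tau: float,
    adjacency: np.ndarray,
    *,
    normalized: bool = False,
) -> float:
    """Intrinsic CAR log-density for a spatially structured area effect.

    ``-(tau/2) sum_{i~i'} (x_i - x_{i'})^2`` over unordered neighbour pairs
    plus ``((n-1)/2) log(tau/2pi)``; rank deficiency 1 is handled by the
    sum-to-zero constraint at sampling time.  Requires a connected graph
    (multiple constraints are unsupported).  ``normalized=True`` adds half
    the log pseudo-determinant of the Laplacian, making the value exact on
    the sum-to-zero subspace.
    """
    x = np.asarray(x, dtype=float)
    if tau <= 0:
        raise ValueError("tau must be positive")
    n = x.size
    pairs = np.asarray(adjacency, dtype=int).reshape(-1, 2)
    if n > 1:
        g = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        ncomp, _ = connected_components(g, directed=False)
        if ncomp != 1:
            raise ValueError(
                "ICAR requires a connected adjacency graph "
                f"(found {ncomp} components)"
            )
    diffs = x[pairs[:, 0]] - x[pairs[:, 1]]
    val = 0.5 * (n - 1) * (np.log(tau) - LOG_2PI) - 0.5 * tau * float(
        np.sum(diffs**2)
    )
    if normalized:
        lam = np.linalg.eigvalsh(_laplacian(n, pairs))
        val += 0.5 * float(np.sum(np.log(lam[lam > 1e-9])))
    return float(val)


def log_hyperprior(
    tau: float, *, shape: float = HYPER_SHAPE, rate: float = HYPER_RATE
) -> float:
    """Gamma(shape, rate) log-density of a precision parameter (tau scale)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return float(
        shape * np.log(rate)
        - gammaln(shape)
        + (shape - 1) * np.log(tau)
        - rate * tau
    )


def log_hyperprior_logscale(
    log_tau: float, *, shape: float = HYPER_SHAPE, rate: float = HYPER_RATE
) -> float:
    """Hyperprior density on the log-precision scale (includes the Jacobian)."""
    return log_hyperprior(float(np.exp(log_tau)), shape=shape, rate=rate) + float(
        log_tau
    )
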