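"""A compact Hamiltonian Monte Carlo sampler.

Static-trajectory HMC with jittered trajectory length, dual-averaging step
size adaptation and windowed diagonal mass-matrix estimation during warmup.
The target is supplied as a callable returning the joint log-density and its
gradient; everything is plain numpy and deterministic given the RNG.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclasses.dataclass
class HmcResult:
    draws: np.ndarray          # (n_draws, dim)
    accept_rate: float
    step_size: float
    n_divergent: int


def _leapfrog(
    logp_grad: LogpGrad,
    x: np.ndarray,
    p: np.ndarray,
    grad: np.ndarray,
    eps: float,
    n_steps: int,
    inv_mass: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        x = x + eps * p * inv_mass
        lp, grad = logp_grad(x)
        if not np.isfinite(lp):
            return x, p, -np.inf, grad
        if step < n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return x, p, lp, grad


def _find_initial_step(
    logp_grad: LogpGrad,
    x: np.ndarray,
    rng: np.random.Generator,
    inv_mass: np.ndarray,
) -> float:
    """Double/halve until the single-step acceptance crosses 1/2."""
    with np.errstate(over="ignore", invalid="ignore"):
        return _find_initial_step_inner(logp_grad, x, rng, inv_mass)


def _find_initial_step_inner(
    logp_grad: LogpGrad,
    x: np.ndarray,
    rng: np.random.Generator,
    inv_mass: np.ndarray,
) -> float:
    eps = 0.1
    lp0, grad0 = logp_grad(x)
    p0 = rng.normal(size=x.size) / np.sqrt(inv_mass)
    h0 = lp0 - 0.5 * np.sum(p0**2 * inv_mass)
    _, p1, lp1, _ = _leapfrog(logp_grad, x, p0, grad0, eps, 1, inv_mass)
    h1 = lp1 - 0.5 * np.sum(p1**2 * inv_mass)
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps = eps * (2.0**direction)
        _, p1, lp1, _ = _leapfrog(logp_grad, x, p0, grad0, eps, 1, inv_mass)
        h1 = lp1 - 0.5 * np.sum(p1**2 * inv_mass) if np.isfinite(lp1) else -np.inf
        crossed = (h1 - h0) > np.log(0.5)
        if (direction == 1.0 and not crossed) or (direction == -1.0 and crossed):
            break
    return float(eps)


class _DualAveraging:
    """Nesterov dual averaging of log step size (Stan's schedule)."""

    def __init__(self, eps0: float, target: float = 0.8):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.counter = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_prob: float) -> float:
        self.counter += 1
        m = self.counter
        w = 1.0 / (m + self.t0)
        self.h_bar = (1 - w) * self.h_bar + w * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(m) / self.gamma * self.h_bar
        w2 = m**-self.kappa
        self.log_eps_bar = w2 * self.log_eps + (1 - w2) * self.log_eps_bar
        return float(np.exp(self.log_eps))


def sample_hmc(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    rng: np.random.Generator,
    n_warmup: int = 500,
    n_draws: int = 500,
    *,
    max_leapfrog: int = 32,
    target_accept: float = 0.8,
    gibbs: Callable[[np.ndarray, np.random.Generator], None] | None = None,
) -> HmcResult:
    """Run one HMC chain and return post-warmup draws.

    ``gibbs``, if given, is called after every trajectory with the current
    position and the chain RNG; it may update auxiliary blocks (e.g. draw
    conjugate precision parameters) that the ``logp_grad`` closure reads, in
    which case the cached density/gradient are refreshed — a
    Metropolis-within-Gibbs alternation.
    """
    x = np.array(x0, dtype=float)
    dim = x.size
    inv_mass = np.ones(dim)
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_initial_step(logp_grad, x, rng, inv_mass)
    da = _DualAveraging(eps, target_accept)
    draws = np.empty((n_draws, dim))
    n_accept = 0
    n_div = 0

    # mass-adaptation windows within warmup (fractions of the warmup span)
    w_lo, w_mid, w_hi = (
        int(0.25 * n_warmup),
        int(0.55 * n_warmup),
        int(0.9 * n_warmup),
    )
    window: list[np.ndarray] = []

    total = n_warmup + n_draws
    with np.errstate(over="ignore", invalid="ignore"):
        for it in range(total):
            warming = it < n_warmup
            p0 = rng.normal(size=dim) / np.sqrt(inv_mass)
            # jitter the trajectory length over the upper half of the range to
            # break resonances without wasting evaluations on tiny trajectories
            n_steps = int(rng.integers(max(1, max_leapfrog // 2), max_leapfrog + 1))
            h0 = lp - 0.5 * np.sum(p0**2 * inv_mass)
            x1, p1, lp1, grad1 = _leapfrog(logp_grad, x, p0, grad, eps, n_steps, inv_mass)
            if np.isfinite(lp1):
                h1 = lp1 - 0.5 * np.sum(p1**2 * inv_mass)
                delta_h = h1 - h0
            else:
                delta_h = -np.inf
            if delta_h < -1000.0 or not np.isfinite(delta_h):
                accept_prob = 0.0
                if not warming:
                    n_div += 1
            else:
                accept_prob = min(1.0, float(np.exp(min(delta_h, 0.0))))
            if rng.uniform() < accept_prob:
                x, lp, grad = x1, lp1, grad1
                if not warming:
                    n_accept += 1

            if gibbs is not None:
                gibbs(x, rng)
                lp, grad = logp_grad(x)

            if warming:
                eps = da.update(accept_prob)
                if w_lo <= it < w_mid or w_mid <= it < w_hi:
                    window.append(x.copy())
                if it + 1 in (w_mid, w_hi) and len(window) >= 10:
                    var = np.var(np.asarray(window), axis=0)
                    inv_mass = np.maximum(var, 1e-8)
                    window = []
                    eps = _find_initial_step(logp_grad, x, rng, inv_mass)
                    da = _DualAveraging(eps, target_accept)
                if it + 1 == n_warmup:
                    eps = float(np.exp(da.log_eps_bar))
            else:
                draws[it - n_warmup] = x

    return HmcResult(
        draws=draws,
        accept_rate=n_accept / max(n_draws, 1),
        step_size=eps,
        n_divergent=n_div,
    )
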