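"""Hierarchical Bayesian spatio-temporal Poisson model.

Counts per area and year are Poisson with offset expected counts and
log relative risk ``beta + u_i(j) + v_j + gamma_t + delta_jt``: exchangeable
Gaussian area and region effects (an intrinsic CAR variant is available for
the area level), an intrinsic RW1 temporal effect, an exchangeable
region x year interaction, and Gamma(1, 0.0005) hyperpriors on the four
precisions.

Inference alternates Hamiltonian Monte Carlo on the latent surface with
exact conjugate Gibbs draws of the precisions.  Identifiability is enforced
by construction: every random-effect block is sampled in the orthonormal
sum-to-zero (Helmert) subspace of its index set, so the reported components
satisfy mean(u) = mean(v) = mean(gamma) = mean(delta) = 0 exactly per draw
and the overall level lives in ``beta`` (flat prior).  For the intrinsic
priors (RW1, ICAR) this subspace is precisely their proper support; for the
exchangeable blocks it is the iid Gaussian law conditioned on a zero mean.
"""

from __future__ import annotations

import dataclasses
import warnings

import arviz as az
import numpy as np
import pandas as pd
from scipy.linalg import helmert

from .geography import Geography
from .hmc import sample_hmc
from .panel import CountsPanel

#: convergence gates: draws are flagged, not discarded, when violated
RHAT_MAX = 1.05
ESS_MIN = 100.0


class ConvergenceWarning(UserWarning):
    pass


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Prior structure and hyperprior parameters of the model."""

    area_prior: str = "exchangeable"  # "exchangeable" | "icar"
    include_area: bool = True
    include_region: bool = True
    include_time: bool = True
    include_interaction: bool = True
    hyper_shape: float = 1.0
    hyper_rate: float = 5e-4

    def __post_init__(self) -> None:
        if self.area_prior not in ("exchangeable", "icar"):
            raise ValueError(f"unknown area prior {self.area_prior!r}")
        if self.hyper_shape <= 0 or self.hyper_rate <= 0:
            raise ValueError("hyperprior parameters must be positive")


def _sum_zero_basis(n: int) -> np.ndarray:
    """Orthonormal basis of the sum-to-zero subspace, shape (n, n-1)."""
    return helmert(n).T


def _graph_laplacian(n: int, pairs: np.ndarray) -> np.ndarray:
    L = np.zeros((n, n))
    for a, b in pairs:
        L[a, a] += 1
        L[b, b] += 1
        L[a, b] -= 1
        L[b, a] -= 1
    return L


class _Posterior:
    """Latent-surface conditional posterior and conjugate precision updates.

    Latent parameters: ``beta`` plus one coefficient block per active
    component in its sum-to-zero basis.  Precisions are auxiliary state,
    updated by Gibbs between HMC trajectories.
    """

    def __init__(
        self,
        o: np.ndarray,
        e: np.ndarray,
        geo: Geography,
        spec: ModelSpec,
    ):
        self.o = np.asarray(o, dtype=float)
        self.e = np.asarray(e, dtype=float)
        self.live = self.e > 0
        if np.any(~self.live & (self.o > 0)):
            raise ValueError("cells with o > 0 must have e > 0")
        self.region_index = geo.region_index
        self.I, self.T = self.o.shape
        self.J = geo.n_regions
        self.spec = spec
        self.G = np.zeros((self.J, self.I))
        self.G[self.region_index, np.arange(self.I)] = 1.0

        # bases and prior quadratic-form matrices per block
        I, J, T = self.I, self.J, self.T
        pos = 0

        def take(n: int) -> slice:
            nonlocal pos
            s = slice(pos, pos + n)
            pos += n
            return s

        self.s_beta = take(1)
        self.blocks: dict[str, dict] = {}
        if spec.include_area and I > 1:
            B = _sum_zero_basis(I)
            if spec.area_prior == "icar":
                pairs = geo.adjacency_pairs()
                if pairs.size == 0:
                    raise ValueError("ICAR area prior needs an adjacency structure")
                if not geo.is_connected():
                    raise ValueError(
                        "ICAR area prior needs a connected adjacency graph"
                    )
                Lfull = _graph_laplacian(I, pairs)
                M = B.T @ Lfull @ B
            else:
                M, Lfull = None, None  # identity quadratic form
            self.blocks["u"] = {"slice": take(I - 1), "B": B, "M": M,
                                "L": Lfull, "df": I - 1}
        if spec.include_region and J > 1:
            self.blocks["v"] = {
                "slice": take(J - 1), "B": _sum_zero_basis(J), "M": None,
                "L": None, "df": J - 1,
            }
        if spec.include_time and T > 1:
            B = _sum_zero_basis(T)
            path_pairs = np.column_stack([np.arange(T - 1), np.arange(1, T)])
            Lfull = _graph_laplacian(T, path_pairs)
            M = B.T @ Lfull @ B
            self.blocks["gamma"] = {"slice": take(T - 1), "B": B, "M": M,
                                    "L": Lfull, "df": T - 1}
        if spec.include_interaction and J * T > 1:
            self.blocks["delta"] = {
                "slice": take(J * T - 1), "B": _sum_zero_basis(J * T),
                "M": None, "L": None, "df": J * T - 1,
            }
        self.dim = pos
        self.tau: dict[str, float] = {k: 10.0 for k in self.blocks}

        # region-pattern broadcast map for the u<->v re-splitting update:
        # F a = centered broadcast of the region pattern B_J a to areas
        if "u" in self.blocks and "v" in self.blocks:
            BJ = self.blocks["v"]["B"]
            C = BJ[self.region_index, :]          # (I, J-1) broadcast
            self.F_uv = C - C.mean(axis=0, keepdims=True)
        else:
            self.F_uv = None

    # -- transforms -----------------------------------------------------
    def effects(self, x: np.ndarray) -> dict[str, np.ndarray]:
        out = {}
        for k, b in self.blocks.items():
            out[k] = b["B"] @ x[b["slice"]]
        return out

    def _eta(self, beta: float, eff: dict[str, np.ndarray]) -> np.ndarray:
        eta = np.full((self.I, self.T), beta)
        if "u" in eff:
            eta += eff["u"][:, None]
        if "v" in eff:
            eta += eff["v"][self.region_index][:, None]
        if "gamma" in eff:
            eta += eff["gamma"][None, :]
        if "delta" in eff:
            eta += eff["delta"].reshape(self.J, self.T)[self.region_index, :]
        return eta

    # -- conditional density of the latent surface ----------------------
    def logp_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._logp_grad(x)

    def _logp_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        grad = np.zeros_like(x)
        beta = x[self.s_beta][0]
        eff = self.effects(x)
        eta = self._eta(beta, eff)
        mu = np.where(self.live, self.e * np.exp(eta), 0.0)
        lp = float(np.sum(self.o * eta - mu, where=self.live))
        if not np.isfinite(lp):
            return -np.inf, grad
        R = np.where(self.live, self.o - mu, 0.0)
        grad[self.s_beta] = R.sum()

        pulls = {}
        if "u" in self.blocks:
            pulls["u"] = R.sum(axis=1)
        if "v" in self.blocks:
            pulls["v"] = self.G @ R.sum(axis=1)
        if "gamma" in self.blocks:
            pulls["gamma"] = R.sum(axis=0)
        if "delta" in self.blocks:
            pulls["delta"] = (self.G @ R).reshape(-1)

        for k, b in self.blocks.items():
            y = x[b["slice"]]
            tau = self.tau[k]
            if b["M"] is None:
                prior_grad = -tau * y
                lp += -0.5 * tau * float(y @ y)
            else:
                My = b["M"] @ y
                prior_grad = -tau * My
                lp += -0.5 * tau * float(y @ My)
            grad[b["slice"]] = b["B"].T @ pulls[k] + prior_grad
        return lp, grad

    # -- conjugate precision updates ------------------------------------
    def gibbs_tau(self, x: np.ndarray, rng: np.random.Generator) -> None:
        shape0, rate0 = self.spec.hyper_shape, self.spec.hyper_rate
        for k, b in self.blocks.items():
            y = x[b["slice"]]
            qf = float(y @ y) if b["M"] is None else float(y @ (b["M"] @ y))
            self.tau[k] = rng.gamma(
                shape0 + 0.5 * b["df"], 1.0 / (rate0 + 0.5 * qf)
            )

    def resplit_moves(self, x: np.ndarray, rng: np.random.Generator) -> None:
        """Exact Gibbs updates along likelihood-invariant directions.

        Nested components overlap: a region-level pattern can sit in the
        region effect v, in the within-region means of the area effect u, or
        in the time-means of the interaction delta; a common yearly shift can
        sit in gamma or in the year-means of delta.  The likelihood is flat
        along these trade-offs, so conditional samplers split them only
        through the priors and mix very slowly.  Each move below resamples
        the trade-off coordinates exactly from their Gaussian full
        conditional (the linear predictor is unchanged to machine
        precision), which restores mixing of the variance split.
        """

        def draw_gaussian(A: np.ndarray, b: np.ndarray) -> np.ndarray:
            # a ~ N(A^-1 b, A^-1)
            cf = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, b)
            z = rng.normal(size=b.size)
            return mean + np.linalg.solve(cf.T, z)

        blocks = self.blocks
        # u <-> v: region pattern between area and region effects
        if "u" in blocks and "v" in blocks and self.F_uv is not None:
            bu, bv = blocks["u"], blocks["v"]
            tau_u, tau_v = self.tau["u"], self.tau["v"]
            u = bu["B"] @ x[bu["slice"]]
            y_v = x[bv["slice"]]
            F = self.F_uv
            if bu["L"] is None:
                A = tau_u * (F.T @ F) + tau_v * np.eye(F.shape[1])
                b = tau_u * (F.T @ u) - tau_v * y_v
            else:
                LF = bu["L"] @ F
                A = tau_u * (F.T @ LF) + tau_v * np.eye(F.shape[1])
                b = tau_u * (LF.T @ u) - tau_v * y_v
            a = draw_gaussian(A, b)
            u_new = u - F @ a
            x[bu["slice"]] = bu["B"].T @ u_new
            x[bv["slice"]] = y_v + a
            # the global mean removed by centering the broadcast goes to beta
            x[self.s_beta] -= (bv["B"] @ a)[self.region_index].mean()
        # delta <-> v: time-means of the interaction against region effects
        if "delta" in blocks and "v" in blocks:
            bd, bv = blocks["delta"], blocks["v"]
            tau_d, tau_v = self.tau["delta"], self.tau["v"]
            delta = (bd["B"] @ x[bd["slice"]]).reshape(self.J, self.T)
            y_v = x[bv["slice"]]
            BJ = bv["B"]
            row_means = delta.mean(axis=1)
            A = (self.T * tau_d + tau_v) * np.eye(self.J - 1)
            b = tau_d * self.T * (BJ.T @ row_means) - tau_v * y_v
            a = draw_gaussian(A, b)
            d = BJ @ a
            delta_new = delta - d[:, None]
            x[bd["slice"]] = bd["B"].T @ delta_new.reshape(-1)
            x[bv["slice"]] = y_v + a
        # delta <-> gamma: year-means of the interaction against the trend
        if "delta" in blocks and "gamma" in blocks:
            bd, bg = blocks["delta"], blocks["gamma"]
            tau_d, tau_g = self.tau["delta"], self.tau["gamma"]
            delta = (bd["B"] @ x[bd["slice"]]).reshape(self.J, self.T)
            y_g = x[bg["slice"]]
            BT = bg["B"]
            col_means = delta.mean(axis=0)
            A = self.J * tau_d * np.eye(self.T - 1) + tau_g * bg["M"]
            b = tau_d * self.J * (BT.T @ col_means) - tau_g * (bg["M"] @ y_g)
            a = draw_gaussian(A, b)
            g = BT @ a
            delta_new = delta - g[None, :]
            x[bd["slice"]] = bd["B"].T @ delta_new.reshape(-1)
            x[bg["slice"]] = y_g + a

    def _surface(self, k: str, vec: np.ndarray) -> np.ndarray:
        """Contribution of one component to the (area, year) linear predictor."""
        if k == "u":
            return np.broadcast_to(vec[:, None], (self.I, self.T))
        if k == "v":
            return np.broadcast_to(vec[self.region_index][:, None],
                                   (self.I, self.T))
        if k == "gamma":
            return np.broadcast_to(vec[None, :], (self.I, self.T))
        return vec.reshape(self.J, self.T)[self.region_index, :]

    def scale_moves(
        self, x: np.ndarray, rng: np.random.Generator, step: float = 0.6
    ) -> None:
        """Joint block/precision rescaling (interweaving) Metropolis moves.

        For each component, propose ``tau -> tau e^eps`` with the block
        rescaled by ``e^(-eps/2)`` so its standardized (non-centered)
        coordinates stay fixed.  This moves the sampler along the
        variance-split direction between nested components (e.g. region
        effects versus within-region means of area effects), which plain
        conditional updates traverse very slowly when a variance component
        is near zero.
        """
        shape0, rate0 = self.spec.hyper_shape, self.spec.hyper_rate
        beta = x[self.s_beta][0]
        eff = self.effects(x)
        with np.errstate(over="ignore", invalid="ignore"):
            eta = self._eta(beta, eff)
            mu = np.where(self.live, self.e * np.exp(eta), 0.0)
            ll = float(np.sum(self.o * eta - mu, where=self.live))
            for k, b in self.blocks.items():
                eps = step * rng.normal()
                scale = np.exp(-0.5 * eps)
                comp = self._surface(k, eff[k])
                eta_new = eta + (scale - 1.0) * comp
                mu_new = np.where(self.live, self.e * np.exp(eta_new), 0.0)
                ll_new = float(np.sum(self.o * eta_new - mu_new, where=self.live))
                tau = self.tau[k]
                dlp = (
                    ll_new - ll
                    + shape0 * eps
                    - rate0 * (tau * np.exp(eps) - tau)
                )
                if np.isfinite(dlp) and np.log(rng.uniform()) < dlp:
                    x[b["slice"]] *= scale
                    self.tau[k] = tau * np.exp(eps)
                    eff[k] = eff[k] * scale
                    eta, ll = eta_new, ll_new

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        x = 0.05 * rng.normal(size=self.dim)
        tot_o, tot_e = self.o.sum(), self.e[self.live].sum()
        x[self.s_beta] = np.log(max(tot_o, 0.5) / max(tot_e, 1e-12))
        return x


@dataclasses.dataclass
class PosteriorSummary:
    """Posterior draws, relative-risk summaries and diagnostics of one fit.

    Component draws are stored with an explicit chain axis; every draw
    satisfies the sum-to-zero identifiability constraints exactly.
    Relative-risk summaries carry both posterior means and medians per
    (area, year) cell.
    """

    geo: Geography
    years: tuple[int, ...]
    spec: ModelSpec
    beta: np.ndarray            # (C, S)
    u: np.ndarray | None        # (C, S, I)
    v: np.ndarray | None        # (C, S, J)
    gamma: np.ndarray | None    # (C, S, T)
    delta: np.ndarray | None    # (C, S, J, T)
    tau: dict[str, np.ndarray]  # name -> (C, S)
    rr_mean: np.ndarray         # (I, T)
    rr_median: np.ndarray
    rr_lo: np.ndarray
    rr_hi: np.ndarray
    diagnostics: pd.DataFrame
    converged: bool
    accept_rate: float
    n_divergent: int

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def component_draws(self, name: str) -> np.ndarray | None:
        """Draws of one component flattened over chains."""
        arr = getattr(self, name)
        if arr is None:
            return None
        return arr.reshape((-1,) + arr.shape[2:])

    def linear_predictor_draws(self) -> np.ndarray:
        """log relative risk per draw on the (area, year) grid, (D, I, T)."""
        I, T = len(self.geo.area_ids), len(self.years)
        ri = self.geo.region_index
        D = self.n_draws
        eta = np.broadcast_to(
            self.component_draws("beta")[:, None, None], (D, I, T)
        ).copy()
        if self.u is not None:
            eta += self.component_draws("u")[:, :, None]
        if self.v is not None:
            eta += self.component_draws("v")[:, ri, None]
        if self.gamma is not None:
            eta += self.component_draws("gamma")[:, None, :]
        if self.delta is not None:
            eta += self.component_draws("delta")[:, ri, :]
        return eta

    def rr_table(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_product(
            [self.geo.area_ids, self.years], names=["area_id", "year"]
        )
        return pd.DataFrame(
            {
                "rr_mean": self.rr_mean.reshape(-1),
                "rr_median": self.rr_median.reshape(-1),
                "rr_lo": self.rr_lo.reshape(-1),
                "rr_hi": self.rr_hi.reshape(-1),
            },
            index=idx,
        ).reset_index()


def fit(
    panel: CountsPanel,
    geo: Geography,
    spec: ModelSpec | None = None,
    *,
    chains: int = 2,
    warmup: int = 600,
    draws: int = 500,
    seed: int = 0,
    max_leapfrog: int = 128,
    target_accept: float = 0.9,
) -> PosteriorSummary:
    """Sample the posterior of the spatio-temporal model.

    Runs ``chains`` independent HMC-within-Gibbs chains (deterministic given
    ``seed``), computes split-Rhat and bulk ESS for ``beta`` and the log
    precisions via arviz, and flags (never silently accepts) non-convergence
    at Rhat > 1.05 or ESS < 100.
    """
    spec = spec or ModelSpec()
    if tuple(panel.area_ids) != tuple(geo.area_ids):
        raise ValueError("panel and geography area ids do not match")

    I, T, J = panel.o.shape[0], panel.o.shape[1], geo.n_regions
    C, S = chains, draws
    beta = np.empty((C, S))
    chain_results = []
    tau_records: list[dict[str, list[float]]] = []
    post = None
    for c in range(chains):
        post = _Posterior(panel.o, panel.e, geo, spec)
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), c)))
        taus: dict[str, list[float]] = {k: [] for k in post.blocks}

        def gibbs(x: np.ndarray, rng_: np.random.Generator) -> None:
            # a few sweeps of the precision/split cycle per trajectory: the
            # (tau, variance-split) pair is the slowest subchain and these
            # updates are cheap relative to one HMC trajectory
            for _ in range(3):
                post.gibbs_tau(x, rng_)
                post.resplit_moves(x, rng_)
                post.scale_moves(x, rng_)
            for k in taus:
                taus[k].append(post.tau[k])

        res = sample_hmc(
            post.logp_grad,
            post.initial_point(rng),
            rng,
            warmup,
            draws,
            max_leapfrog=max_leapfrog,
            target_accept=target_accept,
            gibbs=gibbs,
        )
        chain_results.append(res)
        tau_records.append({k: v[-draws:] for k, v in taus.items()})

    u = np.zeros((C, S, I)) if "u" in post.blocks else None
    v = np.zeros((C, S, J)) if "v" in post.blocks else None
    gamma = np.zeros((C, S, T)) if "gamma" in post.blocks else None
    delta = np.zeros((C, S, J, T)) if "delta" in post.blocks else None
    tau = {k: np.empty((C, S)) for k in post.blocks}
    for c, res in enumerate(chain_results):
        for s in range(S):
            x = res.draws[s]
            beta[c, s] = x[post.s_beta][0]
            eff = post.effects(x)
            if u is not None:
                u[c, s] = eff["u"]
            if v is not None:
                v[c, s] = eff["v"]
            if gamma is not None:
                gamma[c, s] = eff["gamma"]
            if delta is not None:
                delta[c, s] = eff["delta"].reshape(J, T)
        for k in tau:
            tau[k][c] = tau_records[c][k]
    tau = {f"tau_{k}": arr for k, arr in tau.items()}

    # diagnostics on beta and the log precisions
    monitored = {"beta": beta}
    monitored.update({f"log_{k}": np.log(arr) for k, arr in tau.items()})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=monitored)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    diag = pd.DataFrame(
        {
            "parameter": list(monitored),
            "rhat": [float(rhat[k].values) for k in monitored],
            "ess": [float(ess[k].values) for k in monitored],
        }
    )
    rhat_ok = bool(np.all(np.nan_to_num(diag["rhat"].values, nan=1.0) <= RHAT_MAX))
    ess_ok = bool(np.all(diag["ess"].values >= min(ESS_MIN, 0.5 * C * S)))
    converged = rhat_ok and ess_ok
    if not converged:
        warnings.warn(
            "sampler did not meet the convergence gates "
            f"(max rhat={np.nanmax(diag['rhat']):.3f}, "
            f"min ess={np.nanmin(diag['ess']):.0f}); results are flagged",
            ConvergenceWarning,
            stacklevel=2,
        )

    summary = PosteriorSummary(
        geo=geo,
        years=panel.years,
        spec=spec,
        beta=beta,
        u=u,
        v=v,
        gamma=gamma,
        delta=delta,
        tau=tau,
        rr_mean=np.empty((I, T)),
        rr_median=np.empty((I, T)),
        rr_lo=np.empty((I, T)),
        rr_hi=np.empty((I, T)),
        diagnostics=diag,
        converged=converged,
        accept_rate=float(np.mean([r.accept_rate for r in chain_results])),
        n_divergent=int(sum(r.n_divergent for r in chain_results)),
    )
    rr = np.exp(summary.linear_predictor_draws())
    summary.rr_mean = rr.mean(axis=0)
    summary.rr_median = np.median(rr, axis=0)
    summary.rr_lo = np.percentile(rr, 2.5, axis=0)
    summary.rr_hi = np.percentile(rr, 97.5, axis=0)
    return summary
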