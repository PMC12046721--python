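"""Besag–York–Mollié (BYM) Poisson spatial model, fit by MCMC.

The model for tract counts ``y_i`` with expected counts ``E_i`` is::

    y_i ~ Poisson(lambda_i)
    log(lambda_i) = log(E_i) + x_i' beta + u_i + v_i

where ``u`` is an intrinsic CAR (ICAR) field over the tract adjacency
(conditional prior mean = neighbor average, conditional precision =
``tau_u * degree_i``, sum-to-zero constrained) and ``v`` is iid Gaussian
with precision ``tau_v``. Only the convolution ``u + v`` is likelihood-
identified; tract relative risks are reported from the sum and the two
components are never interpreted separately.

Sampler: random-walk Metropolis for ``beta`` jointly (proposal scaled by
the inverse Fisher information at the Poisson-GLM mode), chromatic
single-site Metropolis for ``u`` (sites of one graph color updated
simultaneously — their full conditionals are mutually independent),
vectorized single-site Metropolis for ``v``, and conjugate gamma draws
for the precisions. ``u`` is re-centred to sum to zero each sweep with
the mean transferred into the intercept, which leaves the likelihood
invariant. Step sizes adapt during burn-in only.

A negative-binomial likelihood (mean ``lambda_i``, dispersion ``r``; the
Poisson is the ``r -> inf`` limit) is available for overdispersion
comparison, with ``r`` updated by Metropolis on ``log r``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.special import gammaln

from .adjacency import Adjacency
from .design import VALID_TERMS

_ETA_CLIP = 30.0  # keeps exp() finite; |eta| ~ 30 is far outside any real fit


@dataclass
class ModelSpec:
    """Model structure and priors.

    ``prior_beta=None`` is the improper flat prior (default);
    ``prior_beta=(0, 10)`` with ``prior_precision=(0.1, 0.01)`` is the
    weaker sensitivity setting. ``prior_precision`` is the Gamma(shape,
    rate) prior shared by ``tau_u`` and ``tau_v``.
    """

    likelihood: str = "poisson"
    covariates: tuple[str, ...] = VALID_TERMS
    include_structured: bool = True
    include_unstructured: bool = True
    prior_beta: Optional[tuple[float, float]] = None
    prior_precision: tuple[float, float] = (1.0, 5e-4)
    fixed_dispersion: Optional[float] = None  # negative binomial only

    def __post_init__(self) -> None:
        if self.likelihood not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        for term in self.covariates:
            if term not in VALID_TERMS:
                raise ValueError(f"unknown covariate term {term!r}")


@dataclass
class MCMCSettings:
    chains: int = 4
    iterations: int = 25_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1 or self.chains < 1:
            raise ValueError("thin and chains must be >= 1")


@dataclass
class PosteriorDraws:
    """Retained MCMC samples, chains concatenated with labels kept."""

    beta: np.ndarray  # (draws, p)
    u: np.ndarray  # (draws, n); zeros if structured term absent
    v: np.ndarray  # (draws, n); zeros if unstructured term absent
    tau_u: np.ndarray
    tau_v: np.ndarray
    dispersion: Optional[np.ndarray]
    chain: np.ndarray  # (draws,) chain index
    coefficient_names: list[str]
    offset: np.ndarray  # log E, (n,)
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def n_tracts(self) -> int:
        return self.u.shape[1]

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        """Per-draw eta_i = log E_i + x_i'beta + u_i + v_i, shape (draws, n)."""
        return self.offset[None, :] + self.beta @ X.T + self.u + self.v

    def relative_risk(self, X: np.ndarray) -> np.ndarray:
        """Per-draw tract RR (offset-free linear predictor), shape (draws, n)."""
        return np.exp(self.beta @ X.T + self.u + self.v)


@dataclass
class RRSummary:
    """Exponentiated fixed effects and tract-level risk summaries."""

    coefficients: "pd.DataFrame"  # name, rr_mean, rr_2.5%, rr_97.5%
    tracts: "pd.DataFrame"  # median RR + exceedance columns


def poisson_irls(
    y: np.ndarray, offset: np.ndarray, X: np.ndarray, tol: float = 1e-10, max_iter: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Newton/IRLS maximum likelihood for the Poisson log-link GLM.

    Returns the MLE and the inverse Fisher information at it. Used to
    initialize the sampler and scale the beta proposal.
    """
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-8)) - offset.mean()
    for _ in range(max_iter):
        eta = np.clip(offset + X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        XtW = X.T * mu
        H = XtW @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"singular information matrix in IRLS: {err}") from err
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(offset + X @ beta, -_ETA_CLIP, _ETA_CLIP)
    H = (X.T * np.exp(eta)) @ X
    return beta, np.linalg.inv(H)


def _pointwise_loglik(
    y: np.ndarray, eta: np.ndarray, likelihood: str, dispersion: float | None
) -> np.ndarray:
    """Full per-observation log density (constants included)."""
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    if likelihood == "poisson":
        return y * eta - mu - gammaln(y + 1.0)
    r = float(dispersion)
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )


def _site_loglik_delta(
    y: np.ndarray, eta_new: np.ndarray, eta_old: np.ndarray, likelihood: str, r: float | None
) -> np.ndarray:
    """Per-site log-likelihood change (normalizing constants cancel)."""
    eta_new = np.clip(eta_new, -_ETA_CLIP, _ETA_CLIP)
    eta_old = np.clip(eta_old, -_ETA_CLIP, _ETA_CLIP)
    if likelihood == "poisson":
        return y * (eta_new - eta_old) - (np.exp(eta_new) - np.exp(eta_old))
    mu_new, mu_old = np.exp(eta_new), np.exp(eta_old)
    return (y + r) * (np.log(r + mu_old) - np.log(r + mu_new)) + y * (eta_new - eta_old)


class _Adapter:
    """Robbins–Monro step-size adaptation toward a target acceptance rate."""

    def __init__(self, step: float, target: float):
        self.log_step = np.log(step)
        self.target = target
        self.t = 0

    def update(self, accept_rate: float) -> None:
        self.t += 1
        self.log_step += (accept_rate - self.target) / np.sqrt(self.t)

    @property
    def step(self) -> float:
        return float(np.exp(self.log_step))


def fit_bym(
    y: np.ndarray,
    E: np.ndarray,
    X: np.ndarray,
    adj: Adjacency,
    spec: ModelSpec = ModelSpec(),
    mcmc: MCMCSettings = MCMCSettings(),
    coefficient_names: Optional[Sequence[str]] = None,
) -> PosteriorDraws:
    """Run the MCMC sampler and return retained posterior draws.

    Requires ``E_i > 0`` for every modeled tract (drop zero-population
    tracts first) and an adjacency covering all rows of ``X``. Islands
    (neighborless tracts) have their structured effect fixed at zero.
    """
    y = np.asarray(y, dtype=float)
    E = np.asarray(E, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.shape != (n,) or E.shape != (n,):
        raise ValueError("y, E, X have inconsistent shapes")
    if adj.n != n:
        raise ValueError(f"adjacency covers {adj.n} tracts but data has {n}")
    if (E <= 0).any():
        raise ValueError(
            f"non-positive expected counts at tracts {np.flatnonzero(E <= 0).tolist()}; "
            "exclude them before fitting"
        )
    offset = np.log(E)
    names = list(coefficient_names) if coefficient_names is not None else [f"b{j}" for j in range(p)]

    beta0, fisher_inv = poisson_irls(y, offset, X)
    if not np.isfinite(beta0).all():
        raise ValueError("non-finite GLM initialization; check data for degenerate tracts")
    prop_chol = np.linalg.cholesky(fisher_inv + 1e-12 * np.eye(p))

    degree = adj.degree
    # sparse 0/1 adjacency for vectorized neighbor sums and the ICAR quadratic form
    rows = np.array([i for i, nbrs in enumerate(adj.neighbors) for _ in nbrs], dtype=np.int64)
    cols = np.array([j for nbrs in adj.neighbors for j in nbrs], dtype=np.int64)
    W = sparse.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n, n)
    )
    safe_degree = np.maximum(degree, 1)
    islands = np.array(adj.islands(), dtype=np.int64)
    active = np.setdiff1d(np.arange(n), islands)
    colors = adj.greedy_coloring()
    color_groups = [
        np.array([i for i in active if colors[i] == c], dtype=np.int64)
        for c in range(colors.max() + 1 if n else 0)
    ]
    color_groups = [g for g in color_groups if g.size]
    W_by_group = [W[g] for g in color_groups]
    # ICAR quadratic-form rank: active tracts minus connected components among them
    if active.size:
        sub_seen = np.zeros(n, dtype=bool)
        n_comp = 0
        active_set = set(active.tolist())
        for s in active:
            if sub_seen[s]:
                continue
            n_comp += 1
            stack = [s]
            sub_seen[s] = True
            while stack:
                i = stack.pop()
                for j in adj.neighbors[i]:
                    if j in active_set and not sub_seen[j]:
                        sub_seen[j] = True
                        stack.append(j)
        icar_rank = active.size - n_comp
    else:
        icar_rank = 0

    a_tau, b_tau = spec.prior_precision
    nb = spec.likelihood == "negative_binomial"
    keep_every = mcmc.thin
    n_keep_per_chain = (mcmc.iterations - mcmc.burn_in) // keep_every

    all_beta, all_u, all_v = [], [], []
    all_tau_u, all_tau_v, all_disp, all_chain = [], [], [], []
    acc_stats = {"beta": 0.0, "u": 0.0, "v": 0.0}
    acc_norm = 0

    root = np.random.default_rng(mcmc.seed)
    chain_seeds = root.integers(0, 2**31 - 1, size=mcmc.chains)

    for chain_idx in range(mcmc.chains):
        rng = np.random.default_rng(chain_seeds[chain_idx])
        beta = beta0.copy()
        u = np.zeros(n)
        v = np.zeros(n)
        tau_u = max(a_tau / b_tau, 1.0)
        tau_v = max(a_tau / b_tau, 1.0)
        log_r = np.log(spec.fixed_dispersion) if (nb and spec.fixed_dispersion) else np.log(10.0)
        ad_beta = _Adapter(0.8, 0.25)
        ad_u = _Adapter(0.5, 0.40)
        ad_v = _Adapter(0.5, 0.40)
        ad_r = _Adapter(0.5, 0.40)
        acc_win = {"beta": 0, "u": 0, "v": 0, "r": 0, "n": 0, "nu": 0, "nv": 0}

        eta = offset + X @ beta + u + v
        r = float(np.exp(log_r)) if nb else None

        for it in range(mcmc.iterations):
            # --- beta: joint random-walk Metropolis ---
            prop = beta + ad_beta.step * (prop_chol @ rng.standard_normal(p))
            eta_prop = eta + X @ (prop - beta)
            delta = _site_loglik_delta(y, eta_prop, eta, spec.likelihood, r).sum()
            if spec.prior_beta is not None:
                m0, s0 = spec.prior_beta
                delta += (np.sum((beta - m0) ** 2) - np.sum((prop - m0) ** 2)) / (2 * s0**2)
            if np.log(rng.uniform()) < delta:
                beta, eta = prop, eta_prop
                acc_win["beta"] += 1

            # --- u: chromatic single-site Metropolis against ICAR conditional ---
            if spec.include_structured and active.size:
                n_acc_u = 0
                for group, W_g in zip(color_groups, W_by_group):
                    d_g = degree[group]
                    nbr_mean = (W_g @ u) / safe_degree[group]
                    u_old = u[group]
                    u_new = u_old + ad_u.step * rng.standard_normal(group.size)
                    eta_old_g = eta[group]
                    eta_new_g = eta_old_g + (u_new - u_old)
                    dll = _site_loglik_delta(y[group], eta_new_g, eta_old_g, spec.likelihood, r)
                    dlp = -0.5 * tau_u * d_g * ((u_new - nbr_mean) ** 2 - (u_old - nbr_mean) ** 2)
                    accept = np.log(rng.uniform(size=group.size)) < dll + dlp
                    u[group[accept]] = u_new[accept]
                    eta[group[accept]] = eta_new_g[accept]
                    n_acc_u += int(accept.sum())
                acc_win["u"] += n_acc_u
                acc_win["nu"] += active.size
                # re-centre: transfer the mean into the intercept (likelihood-invariant)
                m = u[active].mean()
                u[active] -= m
                beta[0] += m
                # eta unchanged; u'(D-W)u via the sparse structure
                quad = float(u @ (degree * u) - u @ (W @ u))
                tau_u = rng.gamma(a_tau + 0.5 * icar_rank, 1.0 / (b_tau + 0.5 * quad))

            # --- v: vectorized single-site Metropolis ---
            if spec.include_unstructured:
                v_new = v + ad_v.step * rng.standard_normal(n)
                eta_new = eta + (v_new - v)
                dll = _site_loglik_delta(y, eta_new, eta, spec.likelihood, r)
                dlp = -0.5 * tau_v * (v_new**2 - v**2)
                accept = np.log(rng.uniform(size=n)) < dll + dlp
                v[accept] = v_new[accept]
                eta[accept] = eta_new[accept]
                acc_win["v"] += int(accept.sum())
                acc_win["nv"] += n
                tau_v = rng.gamma(a_tau + 0.5 * n, 1.0 / (b_tau + 0.5 * float(v @ v)))

            # --- negative-binomial dispersion ---
            if nb and spec.fixed_dispersion is None:
                lr_new = log_r + ad_r.step * rng.standard_normal()
                r_new = float(np.exp(lr_new))
                ll_new = _pointwise_loglik(y, eta, "negative_binomial", r_new).sum()
                ll_old = _pointwise_loglik(y, eta, "negative_binomial", r).sum()
                # Gamma(2, 0.1) prior on r, with log-scale Jacobian
                dpr = (2.0 * (lr_new - log_r)) - 0.1 * (r_new - r)
                if np.log(rng.uniform()) < ll_new - ll_old + dpr:
                    log_r, r = lr_new, r_new
                    acc_win["r"] += 1

            acc_win["n"] += 1

            # --- adaptation during burn-in ---
            if it < mcmc.burn_in and acc_win["n"] == 50:
                ad_beta.update(acc_win["beta"] / 50.0)
                if spec.include_structured and acc_win["nu"]:
                    ad_u.update(acc_win["u"] / acc_win["nu"])
                if spec.include_unstructured and acc_win["nv"]:
                    ad_v.update(acc_win["v"] / acc_win["nv"])
                if nb and spec.fixed_dispersion is None:
                    ad_r.update(acc_win["r"] / 50.0)
                acc_win = {"beta": 0, "u": 0, "v": 0, "r": 0, "n": 0, "nu": 0, "nv": 0}

            if it >= mcmc.burn_in and (it - mcmc.burn_in) % keep_every == 0:
                all_beta.append(beta.copy())
                all_u.append(u.copy())
                all_v.append(v.copy())
                all_tau_u.append(tau_u)
                all_tau_v.append(tau_v)
                if nb:
                    all_disp.append(float(np.exp(log_r)))
                all_chain.append(chain_idx)

        acc_stats["beta"] += acc_win["beta"]
        acc_stats["u"] += acc_win["u"]
        acc_stats["v"] += acc_win["v"]
        acc_norm += acc_win["n"]

    if not np.all(np.isfinite(all_beta)):
        raise ValueError("non-finite posterior draws; model is numerically degenerate")

    draws = PosteriorDraws(
        beta=np.array(all_beta),
        u=np.array(all_u),
        v=np.array(all_v),
        tau_u=np.array(all_tau_u),
        tau_v=np.array(all_tau_v),
        dispersion=np.array(all_disp) if nb else None,
        chain=np.array(all_chain, dtype=np.int64),
        coefficient_names=names,
        offset=offset,
        acceptance={
            "beta": acc_stats["beta"] / max(acc_norm, 1),
        },
    )
    assert draws.n_draws == n_keep_per_chain * mcmc.chains
    return draws


def summarize_relative_risks(draws: PosteriorDraws, X: np.ndarray) -> RRSummary:
    """Exponentiated-coefficient summaries and per-tract median RR.

    Coefficient summaries are the posterior mean and central 95% interval
    of ``exp(beta)`` (exp applied per draw, then averaged). Tract RR is
    the posterior median of ``exp(x_i'beta + u_i + v_i)``.
    """
    import pandas as pd

    if draws.n_draws < 100:
        raise ValueError(f"need >=100 retained draws for summaries, got {draws.n_draws}")
    rr_beta = np.exp(draws.beta)
    coef = pd.DataFrame(
        {
            "coefficient": draws.coefficient_names,
            "rr_mean": rr_beta.mean(axis=0),
            "rr_lo_2.5": np.quantile(rr_beta, 0.025, axis=0),
            "rr_hi_97.5": np.quantile(rr_beta, 0.975, axis=0),
        }
    )
    rr_tract = draws.relative_risk(X)
    tracts = pd.DataFrame({"rr_median": np.median(rr_tract, axis=0)})
    for c, probs in exceedance_probabilities(draws, X).items():
        tracts[c] = probs
    return RRSummary(coefficients=coef, tracts=tracts)


def exceedance_probabilities(
    draws: PosteriorDraws, X: np.ndarray, thresholds: Sequence[float] = (1.0, 2.0, 3.0, 4.0)
) -> dict[str, np.ndarray]:
    """Pr(RR_i > c) per tract: fraction of draws strictly above each threshold."""
    if draws.n_draws == 0:
        raise ValueError("no posterior draws")
    rr = draws.relative_risk(X)
    return {f"pr_rr_gt_{c:g}": (rr > c).mean(axis=0) for c in thresholds}
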