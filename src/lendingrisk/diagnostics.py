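"""Model comparison and calibration diagnostics.

DIC and WAIC (both on the deviance scale, with their effective-parameter
counts), randomized PIT for count data, posterior-predictive MAE/RMSE,
the raw-count variance-to-mean overdispersion ratio, and
autocorrelation-based effective sample sizes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .bym import PosteriorDraws, _pointwise_loglik


@dataclass
class FitDiagnostics:
    dic: float
    p_d: float
    waic: float
    p_waic: float
    mae: float
    rmse: float
    variance_to_mean: float
    ess: dict[str, float]
    pit: list[float] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _loglik_matrix(draws: PosteriorDraws, y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """(draws, n) pointwise log densities under the fitted likelihood."""
    eta = draws.linear_predictor(X)
    if draws.dispersion is None:
        return _pointwise_loglik(y[None, :], eta, "poisson", None)
    out = np.empty_like(eta)
    for s in range(eta.shape[0]):
        out[s] = _pointwise_loglik(y, eta[s], "negative_binomial", draws.dispersion[s])
    return out


def compute_dic(
    draws: PosteriorDraws, y: np.ndarray, E: np.ndarray, X: np.ndarray
) -> tuple[float, float]:
    """Deviance information criterion and its effective-parameter count.

    ``DIC = Dbar + p_D`` with ``p_D = Dbar - D(thetabar)``, where the
    plug-in is the posterior mean of the per-tract linear predictor (the
    standard choice for hierarchical Poisson models). A negative ``p_D``
    signals a pathological fit and triggers a warning.
    """
    y = np.asarray(y, dtype=float)
    if draws.n_draws < 2:
        raise ValueError("DIC needs at least 2 posterior draws")
    ll = _loglik_matrix(draws, y, X)
    d_bar = float(np.mean(-2.0 * ll.sum(axis=1)))
    eta_bar = draws.linear_predictor(X).mean(axis=0)
    disp_bar = float(draws.dispersion.mean()) if draws.dispersion is not None else None
    lik = "poisson" if draws.dispersion is None else "negative_binomial"
    d_hat = float(-2.0 * _pointwise_loglik(y, eta_bar, lik, disp_bar).sum())
    p_d = d_bar - d_hat
    if p_d < 0:
        warnings.warn(f"negative DIC effective-parameter count p_D={p_d:.3f}", stacklevel=2)
    return d_bar + p_d, p_d


def compute_waic(
    draws: PosteriorDraws, y: np.ndarray, E: np.ndarray, X: np.ndarray
) -> tuple[float, float]:
    """WAIC on the deviance scale: ``-2 (lppd - p_WAIC)``.

    ``lppd = sum_i log mean_s p(y_i | theta_s)`` and
    ``p_WAIC = sum_i var_s log p(y_i | theta_s)`` (population variance
    over draws).
    """
    y = np.asarray(y, dtype=float)
    if draws.n_draws < 2:
        raise ValueError("WAIC needs at least 2 posterior draws")
    ll = _loglik_matrix(draws, y, X)
    lppd = float(np.sum(_colwise_log_mean_exp(ll)))
    p_waic = float(np.sum(ll.var(axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic), p_waic


def _colwise_log_mean_exp(ll: np.ndarray) -> np.ndarray:
    from scipy.special import logsumexp

    return logsumexp(ll, axis=0) - np.log(ll.shape[0])


def _predictive_cdf(
    draws: PosteriorDraws, y_eval: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """Posterior-predictive CDF at integer points ``y_eval`` (per tract)."""
    lam = np.exp(np.clip(draws.linear_predictor(X), -30, 30))
    if draws.dispersion is None:
        return stats.poisson.cdf(y_eval[None, :], lam).mean(axis=0)
    r = draws.dispersion[:, None]
    return stats.nbinom.cdf(y_eval[None, :], r, r / (r + lam)).mean(axis=0)


def pit_values(
    draws: PosteriorDraws,
    y: np.ndarray,
    E: np.ndarray,
    X: np.ndarray,
    randomized: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """Probability integral transform for discrete counts.

    Randomized PIT draws uniformly on ``[F(y_i - 1), F(y_i)]`` where ``F``
    is the posterior-predictive CDF (mixture over draws); the
    non-randomized mode returns the interval midpoint. Uniform PIT values
    indicate a calibrated predictive distribution.
    """
    y = np.asarray(y, dtype=float)
    if draws.n_draws == 0:
        raise ValueError("no posterior draws")
    f_hi = _predictive_cdf(draws, y, X)
    f_lo = np.where(y > 0, _predictive_cdf(draws, y - 1, X), 0.0)
    if randomized:
        rng = np.random.default_rng(seed)
        return f_lo + rng.uniform(size=y.size) * (f_hi - f_lo)
    return 0.5 * (f_lo + f_hi)


def posterior_predictive_stats(
    draws: PosteriorDraws, y: np.ndarray, E: np.ndarray, X: np.ndarray
) -> tuple[float, float]:
    """MAE and RMSE of the posterior-mean prediction ``E[lambda_i | y]``."""
    y = np.asarray(y, dtype=float)
    lam_hat = np.exp(np.clip(draws.linear_predictor(X), -30, 30)).mean(axis=0)
    resid = y - lam_hat
    return float(np.abs(resid).mean()), float(np.sqrt((resid**2).mean()))


def variance_to_mean(y: np.ndarray) -> float:
    """Sample variance (n-1 denominator) over sample mean of raw counts."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 counts")
    m = y.mean()
    if m == 0:
        warnings.warn("zero mean count: variance-to-mean ratio undefined", stacklevel=2)
        return float("nan")
    return float(y.var(ddof=1) / m)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS of a single chain via Geyer's initial-positive-sequence rule.

    Autocovariances are summed in adjacent pairs until a pair sum goes
    non-positive; ``ESS = n / (1 + 2 sum rho_t)``. A constant chain is
    reported as its full length with a degeneracy warning.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("chain too short for ESS")
    x = x - x.mean()
    var0 = float(x @ x) / n
    if var0 == 0:
        warnings.warn("constant chain: ESS reported as draw count", stacklevel=2)
        return float(n)
    # autocovariance via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # Geyer initial positive sequence over pair sums rho[2m] + rho[2m+1]
    s = 0.0
    m = 0
    while 2 * m + 1 < n:
        pair = rho[2 * m] + rho[2 * m + 1]
        if pair <= 0:
            break
        s += pair
        m += 1
    tau = max(2.0 * s - 1.0, 1.0)  # integrated autocorrelation time, >= 1
    return float(n / tau)


def ess_report(draws: PosteriorDraws) -> dict[str, float]:
    """Per-coefficient and per-hyperparameter ESS, summed across chains."""
    out: dict[str, float] = {}

    def _chains(series: np.ndarray) -> float:
        total = 0.0
        for c in np.unique(draws.chain):
            total += effective_sample_size(series[draws.chain == c])
        return total

    for j, name in enumerate(draws.coefficient_names):
        out[name] = _chains(draws.beta[:, j])
    if draws.u.any():
        out["tau_u"] = _chains(draws.tau_u)
    if draws.v.any():
        out["tau_v"] = _chains(draws.tau_v)
    if draws.dispersion is not None:
        out["dispersion"] = _chains(draws.dispersion)
    return out


def diagnose_fit(
    draws: PosteriorDraws,
    y: np.ndarray,
    E: np.ndarray,
    X: np.ndarray,
    pit_seed: int = 0,
    ess_floor: float = 200.0,
) -> FitDiagnostics:
    """Bundle all fit diagnostics; warns (never errors) on low ESS."""
    dic, p_d = compute_dic(draws, y, E, X)
    waic, p_waic = compute_waic(draws, y, E, X)
    mae, rmse = posterior_predictive_stats(draws, y, E, X)
    ess = ess_report(draws)
    low = {k: v for k, v in ess.items() if v < ess_floor}
    if low:
        warnings.warn(f"effective sample size below {ess_floor:g} for: {sorted(low)}", stacklevel=2)
    pit = pit_values(draws, y, E, X, randomized=True, seed=pit_seed)
    return FitDiagnostics(
        dic=dic,
        p_d=p_d,
        waic=waic,
        p_waic=p_waic,
        mae=mae,
        rmse=rmse,
        variance_to_mean=variance_to_mean(y),
        ess=ess,
        pit=[float(p) for p in pit],
    )
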