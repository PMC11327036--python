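"""Autoregressive model fitting and data-adaptive order selection.

Order selection follows the small-sample-corrected Akaike criterion
(AICc).  Contiguous-lag AR(p) models are fit by Levinson-Durbin on the
sample autocovariance (which guarantees a stationary fit); sparse lag
sets — used by the "regularized" high-lag candidates that target slowly
decaying short-TR correlation without paying for a full AR(p_max) — are
fit by conditional least squares with the skipped lags pinned at zero.

A subtlety worth stating: conditional Gaussian likelihoods of AR models of
different orders condition on different numbers of initial observations
and are therefore not directly comparable.  All selection routines here
fix a common conditioning window of ``p_max`` initial observations so
that every candidate's AICc is computed on the same effective sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .synthetic import ar_is_stationary
from .timeseries import TimeSeries

__all__ = [
    "ARModelFit",
    "ARMA11Fit",
    "fit_ar",
    "aicc",
    "stepwise_select",
    "fit_sparse_high_lag",
    "theoretical_acf",
    "fit_arma11",
    "arma11_acf",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ARModelFit:
    """AR model over an explicit lag set.

    ``lag_set`` holds the lags with free coefficients (empty = white
    noise); ``coefficients`` is aligned to it.  ``stationary`` is False for
    sparse conditional-LS fits whose implied AR polynomial has a root on or
    inside the unit circle; such fits are excluded from model selection.
    """

    lag_set: tuple
    coefficients: np.ndarray
    mean: float
    innovation_variance: float
    loglik: float
    aicc: float
    n_effective: int
    stationary: bool = True

    @property
    def p(self) -> int:
        return max(self.lag_set) if self.lag_set else 0

    @property
    def k(self) -> int:
        """Parameter count for AICc: free coefficients + mean + variance."""
        return len(self.lag_set) + 2

    def dense_coefficients(self) -> np.ndarray:
        """Coefficients on lags 1..p with zeros off the lag set."""
        phi = np.zeros(self.p)
        for lag, c in zip(self.lag_set, self.coefficients):
            phi[lag - 1] = c
        return phi

    def to_dict(self) -> dict:
        return {
            "lag_set": list(self.lag_set),
            "coefficients": [float(c) for c in self.coefficients],
            "mean": float(self.mean),
            "innovation_variance": float(self.innovation_variance),
            "loglik": float(self.loglik),
            "aicc": float(self.aicc),
            "n_effective": int(self.n_effective),
            "stationary": bool(self.stationary),
        }


@dataclass(frozen=True)
class ARMA11Fit:
    phi: float
    theta: float
    mean: float
    innovation_variance: float
    loglik: float
    aicc: float
    converged: bool = True


def aicc(loglik: float, n: int, k: int) -> float:
    """Corrected AIC: -2*loglik + 2k + 2k(k+1)/(n-k-1); +inf when the correction blows up."""
    if n - k - 1 <= 0:
        return math.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def _sample_autocov(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased (divide by T) autocovariances of a demeaned vector, lags 0..max_lag."""
    T = x.size
    out = np.empty(max_lag + 1)
    for h in range(max_lag + 1):
        out[h] = x[: T - h] @ x[h:] / T
    return out


def _levinson_durbin(gamma: np.ndarray, p: int) -> np.ndarray:
    """AR(p) coefficients from autocovariances gamma(0..p) via Levinson-Durbin."""
    phi = np.zeros(p)
    sigma2 = gamma[0]
    for m in range(1, p + 1):
        if sigma2 <= 0:
            break
        kappa = (gamma[m] - phi[: m - 1] @ gamma[1:m][::-1]) / sigma2
        phi_new = phi.copy()
        phi_new[m - 1] = kappa
        phi_new[: m - 1] = phi[: m - 1] - kappa * phi[: m - 1][::-1]
        phi = phi_new
        sigma2 = sigma2 * (1.0 - kappa * kappa)
    return phi[:p]


def _conditional_loglik(x: np.ndarray, phi_dense: np.ndarray, cond: int):
    """Gaussian conditional log-likelihood of demeaned x given the first ``cond`` values.

    Returns (loglik, sigma2, n_effective) with sigma2 the mean squared
    one-step residual over t = cond..T-1.
    """
    T = x.size
    p = phi_dense.size
    resid = x[cond:].copy()
    for j in range(1, p + 1):
        if phi_dense[j - 1] != 0.0:
            resid -= phi_dense[j - 1] * x[cond - j : T - j]
    n_eff = T - cond
    sigma2 = float(resid @ resid / n_eff)
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    loglik = -0.5 * n_eff * (_LOG2PI + math.log(sigma2) + 1.0)
    return loglik, sigma2, n_eff


def fit_ar(y: TimeSeries, lag_set, cond: int | None = None) -> ARModelFit:
    """Fit an AR model on an explicit lag set.

    Contiguous sets {1..p} use Levinson-Durbin on the sample ACF (always
    stationary); sparse sets use conditional least squares with the other
    lags fixed at zero, followed by a stationarity check.  ``cond`` fixes
    the number of initial observations conditioned out of the likelihood
    (default: the largest lag), letting callers compare models of
    different orders on a common effective sample.
    """
    lag_set = tuple(sorted(int(l) for l in lag_set))
    if any(l < 1 for l in lag_set) or len(set(lag_set)) != len(lag_set):
        raise ValueError(f"lag_set must be distinct positive integers, got {lag_set}")
    p = max(lag_set) if lag_set else 0
    T = y.n
    if T <= p + 2:
        raise ValueError(f"series of length {T} too short for max lag {p}")
    if y.is_constant():
        raise ValueError("cannot fit an AR model to a constant series")
    if cond is None:
        cond = p
    if cond < p:
        raise ValueError("cond must be >= max(lag_set)")
    mean = float(y.values.mean())
    x = y.values - mean

    if not lag_set:
        coeffs = np.empty(0)
        stationary = True
    elif lag_set == tuple(range(1, p + 1)):
        gamma = _sample_autocov(x, p)
        coeffs = _levinson_durbin(gamma, p)
        stationary = True
    else:
        # conditional least squares on the selected lags only
        X = np.column_stack([x[cond - l : T - l] for l in lag_set])
        coeffs, *_ = np.linalg.lstsq(X, x[cond:], rcond=None)
        stationary = _sparse_is_stationary(lag_set, coeffs)

    phi_dense = np.zeros(p)
    for lag, c in zip(lag_set, coeffs):
        phi_dense[lag - 1] = c
    loglik, sigma2, n_eff = _conditional_loglik(x, phi_dense, cond)
    k = len(lag_set) + 2
    return ARModelFit(lag_set, np.asarray(coeffs, dtype=float), mean, sigma2,
                      loglik, aicc(loglik, n_eff, k), n_eff, stationary)


def _sparse_is_stationary(lag_set, coeffs) -> bool:
    phi = np.zeros(max(lag_set))
    for lag, c in zip(lag_set, coeffs):
        phi[lag - 1] = c
    return ar_is_stationary(phi)


def _round_lag(x: float) -> int:
    return max(1, int(round(x)))


def stepwise_select(y: TimeSeries, p_max: int, cond: int | None = None) -> ARModelFit:
    """Stepwise AICc selection over contiguous AR orders.

    Hill-climbs by +-1 order steps from starts {p_max, p_max/2, p_max/4}
    (rounded, deduplicated), moving to a neighbor only when its AICc is
    strictly lower; the white-noise model AR(0) is always in the candidate
    pool.  Returns the AICc-best fit over all starts.
    """
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    T = y.n
    if T <= p_max + 2:
        p_max = max(1, T - 3)
    if cond is None:
        cond = p_max
    cache: dict[int, ARModelFit] = {}

    def fit_order(p: int) -> ARModelFit:
        if p not in cache:
            cache[p] = fit_ar(y, range(1, p + 1), cond=cond)
        return cache[p]

    best = fit_order(0)
    starts = sorted({p_max, _round_lag(p_max / 2), _round_lag(p_max / 4)}, reverse=True)
    for start in starts:
        current = fit_order(start)
        while True:
            moved = False
            for q in (current.p - 1, current.p + 1):
                if 0 <= q <= p_max:
                    cand = fit_order(q)
                    if cand.aicc < current.aicc:
                        current, moved = cand, True
                        break
            if not moved:
                break
        if current.aicc < best.aicc:
            best = current
    return best


def fit_sparse_high_lag(y: TimeSeries, base: ARModelFit, p_max: int,
                        cond: int | None = None) -> ARModelFit:
    """Regularized high-lag candidate: base lags plus tail lags near p_max.

    Fits the sparse lag set {1..base.p} | {p_max/2, 3*p_max/4, p_max} by
    conditional least squares.  Cheaper than a full AR(p_max) fit while
    still able to capture slowly decaying high-order correlation.
    Non-stationary fits are returned flagged so selection can skip them.
    """
    if p_max <= base.p:
        raise ValueError(f"p_max ({p_max}) must exceed the base order ({base.p})")
    high = {_round_lag(p_max / 2), _round_lag(3 * p_max / 4), p_max}
    lag_set = sorted(set(range(1, base.p + 1)) | {h for h in high if h <= p_max})
    return fit_ar(y, lag_set, cond=cond if cond is not None else p_max)


def theoretical_acf(fit: ARModelFit, max_lag: int) -> np.ndarray:
    """Autocorrelations rho(0..max_lag) implied by a stationary AR fit.

    rho(1..p) solve the Yule-Walker system (with zero coefficients off the
    lag set); higher lags follow the recursion rho(h) = sum_j phi_j rho(h-j).
    """
    if not fit.stationary:
        raise ValueError("theoretical_acf requires a stationary fit")
    phi = fit.dense_coefficients()
    from .synthetic import ar_acf

    return ar_acf(phi, max_lag)


def arma11_acf(phi: float, theta: float, max_lag: int) -> np.ndarray:
    """Autocorrelations rho(0..max_lag) of a stationary, invertible ARMA(1,1)."""
    if abs(phi) >= 1 or abs(theta) >= 1:
        raise ValueError("arma11_acf requires |phi| < 1 and |theta| < 1")
    rho = np.zeros(max_lag + 1)
    rho[0] = 1.0
    if max_lag >= 1:
        rho[1] = (1.0 + phi * theta) * (phi + theta) / (1.0 + 2.0 * phi * theta + theta**2)
        for h in range(2, max_lag + 1):
            rho[h] = phi * rho[h - 1]
    return rho


def fit_arma11(y: TimeSeries) -> ARMA11Fit:
    """ARMA(1,1) fit by conditional sum of squares (Hannan-Rissanen start).

    Mirrors the fixed-order whitening model used by mainstream fMRI
    software.  Falls back to the Hannan-Rissanen estimate (flagged
    non-converged) if the CSS optimizer fails.
    """
    if y.n < 20:
        raise ValueError("fit_arma11 requires at least 20 observations")
    if y.is_constant():
        raise ValueError("cannot fit ARMA(1,1) to a constant series")
    from scipy.optimize import minimize

    mean = float(y.values.mean())
    x = y.values - mean
    T = x.size

    phi0, theta0 = _hannan_rissanen_11(x)

    from scipy.signal import lfilter

    def _resid(phi, theta):
        # innovations of (1 - phi L) x = (1 + theta L) e, conditioning on e_0 = x_0
        return lfilter([1.0, -phi], [1.0, theta], x)

    def css(params):
        phi, theta = np.tanh(params)  # unconstrained -> (-1, 1)
        e = _resid(phi, theta)
        return float(e @ e)

    z0 = np.arctanh(np.clip([phi0, theta0], -0.98, 0.98))
    res = minimize(css, z0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000})
    if res.success:
        phi, theta = (float(v) for v in np.tanh(res.x))
        converged = True
    else:
        phi, theta = float(np.clip(phi0, -0.99, 0.99)), float(np.clip(theta0, -0.99, 0.99))
        converged = False
    # conditional likelihood at the optimum
    e = _resid(phi, theta)
    sigma2 = float(e @ e / T)
    loglik = -0.5 * T * (_LOG2PI + math.log(max(sigma2, np.finfo(float).tiny)) + 1.0)
    return ARMA11Fit(phi, theta, mean, sigma2, loglik, aicc(loglik, T, 4), converged)


def _hannan_rissanen_11(x: np.ndarray) -> tuple[float, float]:
    """Two-stage Hannan-Rissanen initial estimate for ARMA(1,1)."""
    T = x.size
    m = max(4, min(20, int(round(np.log(T) ** 2))))
    gamma = _sample_autocov(x, m)
    phi_long = _levinson_durbin(gamma, m)
    e = x.copy()
    for j in range(1, m + 1):
        e[j:] -= phi_long[j - 1] * x[:-j]
    e[:m] = 0.0
    X = np.column_stack([x[1:-1], e[1:-1]])
    b, *_ = np.linalg.lstsq(X, x[2:], rcond=None)
    return float(b[0]), float(b[1])
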