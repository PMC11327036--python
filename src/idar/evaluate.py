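"""Whitening-adequacy diagnostics.

A whitened series is declared *inadequately whitened* when a family of
Ljung-Box portmanteau tests — one per lag h = 1..floor(20/TR), jointly
Holm-adjusted — yields a smallest adjusted p-value below the significance
level (default 0.05).  A whitening procedure succeeds on a dataset when
fewer than 5% of its series are flagged.  Also provides the sample-ACF
and sliding-window-correlation diagnostics used to eyeball residual
structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .timeseries import TimeSeries

__all__ = [
    "LjungBoxResult",
    "AdequacyReport",
    "sample_acf",
    "acf_significance_band",
    "ljung_box",
    "holm_adjust",
    "adequacy",
    "proportion_inadequate",
    "sliding_window_corr",
]


@dataclass(frozen=True)
class LjungBoxResult:
    lag: int
    Q: float
    p_value: float
    adjusted_p: float = float("nan")


@dataclass(frozen=True)
class AdequacyReport:
    inadequate: bool
    min_adjusted_p: float
    per_lag: tuple
    lag_max: int
    alpha: float

    def to_dict(self) -> dict:
        return {
            "inadequate": bool(self.inadequate),
            "min_adjusted_p": float(self.min_adjusted_p),
            "lag_max": int(self.lag_max),
            "alpha": float(self.alpha),
            "per_lag": [
                {"lag": r.lag, "Q": float(r.Q), "p_value": float(r.p_value),
                 "adjusted_p": float(r.adjusted_p)}
                for r in self.per_lag
            ],
        }


def sample_acf(y: TimeSeries, max_lag: int) -> np.ndarray:
    """Sample autocorrelations rho_hat(0..max_lag), biased (divide-by-T) estimator."""
    T = y.n
    if max_lag >= T:
        raise ValueError(f"max_lag {max_lag} must be < series length {T}")
    if y.is_constant():
        raise ValueError("sample ACF undefined for a constant series")
    x = y.demeaned()
    denom = float(x @ x)
    rho = np.empty(max_lag + 1)
    rho[0] = 1.0
    for h in range(1, max_lag + 1):
        rho[h] = x[: T - h] @ x[h:] / denom
    return rho


def acf_significance_band(T: int, level: float = 0.05) -> float:
    """Half-width of the white-noise significance band for a sample ACF."""
    return float(stats.norm.ppf(1 - level / 2) / np.sqrt(T))


def _ljung_box_q(rho: np.ndarray, T: int, h: int) -> float:
    ks = np.arange(1, h + 1)
    return float(T * (T + 2) * np.sum(rho[1 : h + 1] ** 2 / (T - ks)))


def ljung_box(y: TimeSeries, h: int) -> LjungBoxResult:
    """Ljung-Box portmanteau test of rho(1..h) = 0.

    Q = T(T+2) * sum_{k=1..h} rho_hat(k)^2 / (T-k), referred to a
    chi-square distribution with h degrees of freedom.
    """
    if not 1 <= h < y.n:
        raise ValueError(f"lag h must satisfy 1 <= h < T, got h={h}, T={y.n}")
    rho = sample_acf(y, h)
    Q = _ljung_box_q(rho, y.n, h)
    return LjungBoxResult(h, Q, float(stats.chi2.sf(Q, df=h)))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.minimum(1.0, np.maximum.accumulate(p[order] * (m - np.arange(m))))
    out = np.empty(m)
    out[order] = adj
    return out


def _default_lag_max(T: int, tr: float) -> int:
    return min(max(1, int(np.floor(20.0 / tr))), T // 4)


def adequacy(y: TimeSeries, tr: float | None = None, alpha: float = 0.05,
             lag_max: int | None = None) -> AdequacyReport:
    """Ljung-Box/Holm adequacy decision for one (whitened) series.

    Tests lags 1..lag_max with lag_max = floor(20/tr) capped at T/4;
    the series is inadequately whitened iff the smallest Holm-adjusted
    p-value is below ``alpha``.
    """
    tr = y.tr if tr is None else tr
    if lag_max is None:
        lag_max = _default_lag_max(y.n, tr)
    if y.n <= lag_max + 1:
        raise ValueError(f"series length {y.n} too short for lag_max {lag_max}")
    rho = sample_acf(y, lag_max)
    T = y.n
    raw = []
    for h in range(1, lag_max + 1):
        Q = _ljung_box_q(rho, T, h)
        raw.append(LjungBoxResult(h, Q, float(stats.chi2.sf(Q, df=h))))
    adj = holm_adjust([r.p_value for r in raw])
    per_lag = tuple(LjungBoxResult(r.lag, r.Q, r.p_value, float(a))
                    for r, a in zip(raw, adj))
    min_adj = float(adj.min())
    return AdequacyReport(min_adj < alpha, min_adj, per_lag, lag_max, alpha)


def proportion_inadequate(series_iterable, tr: float | None = None,
                          alpha: float = 0.05) -> float:
    """Fraction of series flagged inadequately whitened.

    Accepts a NodeDataset or any iterable of TimeSeries.  A successful
    whitening procedure keeps this below 0.05.
    """
    if hasattr(series_iterable, "iter_series"):
        series = [s for _, _, s in series_iterable.iter_series()]
        tr = series_iterable.tr if tr is None else tr
    else:
        series = list(series_iterable)
    if not series:
        raise ValueError("no series supplied")
    flags = [adequacy(s, tr=tr, alpha=alpha).inadequate for s in series]
    return float(np.mean(flags))


def sliding_window_corr(y1: TimeSeries, y2: TimeSeries,
                        window_seconds: float = 100.0) -> np.ndarray:
    """Pearson correlation of two series over a sliding window.

    The window spans round(window_seconds / tr) samples and advances one
    sample at a time; degenerate (constant) windows yield NaN.
    """
    if y1.n != y2.n:
        raise ValueError("series must have equal length")
    if y1.tr != y2.tr:
        raise ValueError("series must share the same TR")
    w = int(round(window_seconds / y1.tr))
    if w < 3:
        raise ValueError(f"window of {w} samples is too short (need >= 3)")
    if w > y1.n:
        raise ValueError("window longer than the series")
    a, b = y1.values, y2.values
    out = np.empty(y1.n - w + 1)
    for i in range(out.size):
        xa, xb = a[i : i + w], b[i : i + w]
        sa, sb = xa.std(), xb.std()
        if sa == 0 or sb == 0:
            out[i] = np.nan
        else:
            out[i] = np.corrcoef(xa, xb)[0, 1]
    return out
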