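"""Correlation-matrix construction, regularization, and iterative whitening.

The whitening step for a fitted serial-correlation model with T x T
Toeplitz correlation matrix S is multiplication by the symmetric inverse
square root S^{-1/2}.  High-order fits on short series can make S nearly
rank-deficient, so S is first regularized by banding: the last 10 nonzero
autocorrelation bands are zeroed, repeatedly, until the condition number
drops below 1e8 (with eigenvalue flooring as a terminal fallback for tiny
or stubborn matrices).

IDAR (iterative data-adaptive AR) repeats fit-then-whiten up to
``max_iter`` times, each round modelling whatever serial correlation the
previous round left behind.  The composite transform is the ordered
product of the per-iteration factors, so the final whitened series is a
single linear transform of the (demeaned) input.  Single AR-model
whiteners — AR(1), ARMA(1,1), and the one-iteration variant IDAR-iter1 —
are provided as baselines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz

from . import evaluate
from .armodel import (ARMA11Fit, ARModelFit, arma11_acf, fit_ar, fit_arma11,
                      fit_sparse_high_lag, stepwise_select, theoretical_acf)
from .timeseries import TimeSeries

__all__ = [
    "CorrelationModel",
    "WhiteningTransform",
    "IDARResult",
    "build_corr_matrix",
    "band_regularize",
    "inv_sqrt",
    "whiten_once",
    "idar",
    "baseline_whiten",
    "default_p_max",
    "COND_THRESHOLD",
    "BAND_STEP",
]

COND_THRESHOLD = 1e8
BAND_STEP = 10


@dataclass
class CorrelationModel:
    """Toeplitz correlation matrix built from an autocorrelation sequence."""

    acf: np.ndarray
    matrix: np.ndarray
    bandwidth: int | None = None
    condition_number: float = math.nan
    floored: bool = False
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def T(self) -> int:
        return self.matrix.shape[0]

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (values ascending, vectors)."""
        if self._eig is None:
            vals, vecs = np.linalg.eigh(self.matrix)
            self._eig = (vals, vecs)
        return self._eig


def _condition_number(vals: np.ndarray) -> float:
    """lambda_max / lambda_min; +inf when the matrix is not positive definite."""
    lmin, lmax = vals[0], vals[-1]
    if lmin <= 0 or lmax <= 0:
        return math.inf
    return float(lmax / lmin)


def build_corr_matrix(acf: np.ndarray, T: int) -> CorrelationModel:
    """T x T symmetric Toeplitz matrix M[j, k] = rho(|j - k|)."""
    acf = np.asarray(acf, dtype=float)
    if acf.size < T:
        raise ValueError(f"need {T} autocorrelations, got {acf.size}")
    if not np.isclose(acf[0], 1.0):
        raise ValueError("acf[0] must be 1")
    if np.any(np.abs(acf[:T]) > 1.0 + 1e-10):
        raise ValueError("autocorrelations must lie in [-1, 1]")
    model = CorrelationModel(acf[:T].copy(), toeplitz(acf[:T]))
    model.condition_number = _condition_number(model.eig()[0])
    return model


def band_regularize(model: CorrelationModel, cond_threshold: float = COND_THRESHOLD,
                    step: int = BAND_STEP) -> CorrelationModel:
    """Banding regularization of a correlation matrix.

    Zeroes the trailing ``step`` nonzero bands (entries |j - k| >= T - step,
    then >= T - 2*step, ...) until the condition number falls below
    ``cond_threshold``.  If the bandwidth would collapse (or T <= step),
    eigenvalues below lambda_max / cond_threshold are floored instead.
    """
    T = model.T
    if T < 2:
        return model
    if model.condition_number < cond_threshold:
        return model
    b = T - step
    while b > 1:
        banded = model.matrix.copy()
        idx = np.abs(np.subtract.outer(np.arange(T), np.arange(T))) >= b
        banded[idx] = 0.0
        out = CorrelationModel(model.acf, banded, bandwidth=b)
        out.condition_number = _condition_number(out.eig()[0])
        if out.condition_number < cond_threshold:
            return out
        b -= step
        model = out  # keep banding the already-banded matrix
    # terminal fallback: eigenvalue flooring
    vals, vecs = model.eig()
    lmax = max(float(vals[-1]), np.finfo(float).tiny)
    floor = lmax / cond_threshold
    vals_f = np.maximum(vals, floor)
    floored = (vecs * vals_f) @ vecs.T
    out = CorrelationModel(model.acf, floored, bandwidth=model.bandwidth,
                           floored=True)
    out._eig = (vals_f, vecs)
    out.condition_number = _condition_number(vals_f)
    return out


def inv_sqrt(model: CorrelationModel) -> np.ndarray:
    """Symmetric inverse square root V diag(lambda^{-1/2}) V^T."""
    vals, vecs = model.eig()
    if vals[0] <= 0:
        raise ValueError("matrix is not positive definite; regularize first")
    return (vecs / np.sqrt(vals)) @ vecs.T


def _whiten_with_acf(x: np.ndarray, acf: np.ndarray,
                     cond_threshold: float = COND_THRESHOLD,
                     step: int = BAND_STEP):
    """Whiten a demeaned vector with a model ACF; rescales to the input variance.

    Returns (whitened, factor, model) with the rescale folded into the
    factor so that ``whitened == factor @ x`` exactly.
    """
    T = x.size
    model = build_corr_matrix(acf, T)
    model = band_regularize(model, cond_threshold, step)
    F = inv_sqrt(model)
    w = F @ x
    s_in, s_out = x.std(), w.std()
    if s_out > 0 and s_in > 0:
        c = s_in / s_out
        w, F = w * c, F * c
    return w, F, model


def whiten_once(y: TimeSeries, fit, cond_threshold: float = COND_THRESHOLD,
                step: int = BAND_STEP):
    """One whitening pass of a series under a fitted correlation model.

    ``fit`` is an ARModelFit or ARMA11Fit.  The series is demeaned, then
    multiplied by the regularized inverse-square-root factor; the output is
    rescaled to the input's sample standard deviation (rescale folded into
    the returned factor).  Returns (whitened TimeSeries, factor matrix).
    """
    x = y.demeaned()
    acf = _fit_acf(fit, y.n - 1)
    w, F, _ = _whiten_with_acf(x, acf, cond_threshold, step)
    return y.with_values(w), F


def _fit_acf(fit, max_lag: int) -> np.ndarray:
    if isinstance(fit, ARMA11Fit):
        return arma11_acf(fit.phi, fit.theta, max_lag)
    return theoretical_acf(fit, max_lag)


@dataclass(frozen=True)
class WhiteningTransform:
    """Ordered per-iteration factors and their composite product."""

    factors: tuple
    T: int

    @property
    def composite(self) -> np.ndarray:
        out = np.eye(self.T)
        for F in self.factors:  # factor i applied first
            out = F @ out
        return out

    def apply(self, x: np.ndarray) -> np.ndarray:
        for F in self.factors:
            x = F @ x
        return x


@dataclass(frozen=True)
class IDARResult:
    """Outcome of a whitening run on one series."""

    whitened: TimeSeries
    iterations: int
    fits: tuple
    transform: WhiteningTransform
    adequacy: evaluate.AdequacyReport
    stop_reason: str
    method: str
    correlation_models: tuple = ()

    def summary(self) -> dict:
        return {
            "method": self.method,
            "iterations": self.iterations,
            "stop_reason": self.stop_reason,
            "inadequate": bool(self.adequacy.inadequate),
            "min_adjusted_p": float(self.adequacy.min_adjusted_p),
            "lag_sets": [list(f.lag_set) if isinstance(f, ARModelFit)
                         else ["arma11", f.phi, f.theta] for f in self.fits],
            "condition_numbers": [float(m.condition_number)
                                  for m in self.correlation_models],
            "bandwidths": [m.bandwidth for m in self.correlation_models],
        }


def default_p_max(tr: float, T: int) -> int:
    """Maximum AR lag order: floor(10 s / TR), capped at T/5, at least 1.

    10 s reflects the time span over which hemodynamic-response-driven
    correlation plausibly persists; the T/5 cap protects short series from
    rank-deficient high-order fits.
    """
    return max(1, min(int(math.floor(10.0 / tr)), T // 5))


def _select_model(current: TimeSeries, p_max: int) -> ARModelFit:
    """AICc-best candidate: stepwise winner vs sparse high-lag model (AR(0) included)."""
    best = stepwise_select(current, p_max)
    if best.p < p_max:
        sparse = fit_sparse_high_lag(current, best, p_max)
        if sparse.stationary and sparse.aicc < best.aicc:
            best = sparse
    return best


def idar(y: TimeSeries, tr: float | None = None, max_iter: int = 5,
         alpha: float = 0.05, p_max: int | None = None,
         cond_threshold: float = COND_THRESHOLD, band_step: int = BAND_STEP,
         method_name: str = "idar") -> IDARResult:
    """Iterative data-adaptive AR whitening.

    Each iteration selects an AR model for the current series by AICc
    (stepwise contiguous search plus a sparse high-lag candidate), whitens
    with the model's regularized Toeplitz correlation matrix, and re-checks
    adequacy.  Stops when the selected model is white noise (``white_fit``),
    when the Ljung-Box/Holm adequacy test passes (``adequacy_pass``), or at
    ``max_iter`` iterations.
    """
    tr = y.tr if tr is None else tr
    T = y.n
    if p_max is None:
        p_max = default_p_max(tr, T)
    if T <= p_max + 2:
        raise ValueError(f"series of length {T} too short for p_max {p_max}")
    x = y.demeaned()
    current = TimeSeries(x, tr)
    factors: list[np.ndarray] = []
    fits: list[ARModelFit] = []
    models: list[CorrelationModel] = []
    stop_reason = None
    K = 0
    while True:
        best = _select_model(current, p_max)
        if best.p == 0:
            stop_reason = "white_fit"
            break
        w, F, model = _whiten_with_acf(current.values, theoretical_acf(best, T - 1),
                                       cond_threshold, band_step)
        factors.append(F)
        fits.append(best)
        models.append(model)
        current = TimeSeries(w, tr)
        K += 1
        report = evaluate.adequacy(current, tr=tr, alpha=alpha)
        if not report.inadequate:
            stop_reason = "adequacy_pass"
            break
        if K >= max_iter:
            stop_reason = "max_iter"
            break
    if stop_reason in ("white_fit",) or K == 0:
        report = evaluate.adequacy(current, tr=tr, alpha=alpha)
    transform = WhiteningTransform(tuple(factors), T)
    return IDARResult(current, K, tuple(fits), transform, report, stop_reason,
                      method_name, tuple(models))


def baseline_whiten(y: TimeSeries, tr: float | None = None, method: str = "ar1",
                    alpha: float = 0.05, cond_threshold: float = COND_THRESHOLD,
                    band_step: int = BAND_STEP, max_iter: int = 5) -> IDARResult:
    """Whiten with one of the reference procedures.

    ``ar1``: single pass with a forced AR(1) fit (the long-TR default of
    mainstream GLM packages).  ``arma11``: single pass with a fitted
    ARMA(1,1).  ``idar_iter1``: IDAR capped at one iteration, i.e. one-shot
    data-adaptive high-order AR whitening.  ``idar``: the full iterative
    procedure.  ``none``: identity transform.
    """
    tr = y.tr if tr is None else tr
    method = method.replace("-", "_")
    if method == "idar":
        return idar(y, tr=tr, alpha=alpha, max_iter=max_iter,
                    cond_threshold=cond_threshold, band_step=band_step)
    if method == "idar_iter1":
        return idar(y, tr=tr, alpha=alpha, max_iter=1,
                    cond_threshold=cond_threshold, band_step=band_step,
                    method_name="idar_iter1")
    x = y.demeaned()
    current = TimeSeries(x, tr)
    if method == "none":
        report = evaluate.adequacy(current, tr=tr, alpha=alpha)
        return IDARResult(current, 0, (), WhiteningTransform((), y.n), report,
                          "identity", "none", ())
    if method == "ar1":
        fit = fit_ar(current, (1,))
    elif method == "arma11":
        fit = fit_arma11(current)
    else:
        raise ValueError(f"unknown whitening method {method!r}")
    w, F, model = _whiten_with_acf(x, _fit_acf(fit, y.n - 1),
                                   cond_threshold, band_step)
    whitened = TimeSeries(w, tr)
    report = evaluate.adequacy(whitened, tr=tr, alpha=alpha)
    return IDARResult(whitened, 1, (fit,), WhiteningTransform((F,), y.n),
                      report, "single_pass", method, (model,))
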