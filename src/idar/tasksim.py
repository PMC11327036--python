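"""Simulated block-design task fMRI and the whitened GLM association test.

Serial correlation in BOLD noise shrinks the effective sample size of a
GLM time-series regression, so a naive Wald test of the task effect
rejects far too often.  This module builds the standard simulation used
to quantify that: a 30-s block boxcar (15-s task epoch, 15-s rest; each
task epoch randomly A or B, with A twice B's intensity) is convolved
with a canonical double-gamma HRF, scaled so that the regressor's mean
equals ``snr`` times the standard deviation of a resting-state series
(SNR 0.1 by default), and added to that series to create a task run with
known signal.  Power, type-I error, and accuracy of the whitened Wald
test are then tallied across series for any set of whitening methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import whiten as whiten_mod
from .synthetic import NodeDataset
from .timeseries import TimeSeries

__all__ = [
    "TaskDesign",
    "GLMResult",
    "ExperimentSummary",
    "boxcar_design",
    "canonical_hrf",
    "convolve_design",
    "scale_regressor",
    "make_task_series",
    "make_task_design",
    "glm_wald",
    "run_experiment",
]

BLOCK_SECONDS = 30.0
EPOCH_SECONDS = 15.0
HRF_SUPPORT_SECONDS = 32.0


@dataclass(frozen=True)
class TaskDesign:
    """One realized boxcar task paradigm with its HRF-convolved regressor."""

    block_assignments: tuple  # 'A' / 'B' per block
    boxcar: np.ndarray
    regressor_unscaled: np.ndarray
    scale_factor: float
    regressor: np.ndarray  # X, scaled
    snr: float
    cnr: float
    seed: int


@dataclass(frozen=True)
class GLMResult:
    beta0: float
    beta1: float
    se_beta1: float
    wald: float
    df: int
    p_value: float
    rejected: bool


@dataclass(frozen=True)
class ExperimentSummary:
    """Per-method power / type-I error / accuracy plus adequacy fractions."""

    methods: tuple
    power: dict
    type1: dict
    accuracy: dict
    prop_inadequate_rest: dict
    prop_inadequate_task: dict
    n_series: int
    n_failed: dict

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "method": list(self.methods),
                "power": [self.power[m] for m in self.methods],
                "type1": [self.type1[m] for m in self.methods],
                "accuracy": [self.accuracy[m] for m in self.methods],
                "prop_inadequate_rest": [self.prop_inadequate_rest[m] for m in self.methods],
                "prop_inadequate_task": [self.prop_inadequate_task[m] for m in self.methods],
            }
        )


def boxcar_design(T: int, tr: float, u: float = 1.0, seed: int = 0):
    """Boxcar paradigm over 30-s blocks: 15-s task epoch then 15-s rest.

    Each task epoch is A (level ``2u``) or B (level ``u``) with equal
    probability.  Returns (assignments, boxcar); a trailing partial block
    is truncated to length T.
    """
    if u < 0:
        raise ValueError("u must be nonnegative")
    epoch = int(round(EPOCH_SECONDS / tr))
    if epoch < 1 or T < epoch:
        raise ValueError(f"series of length {T} holds no complete {EPOCH_SECONDS}-s epoch")
    block = 2 * epoch
    n_blocks = int(math.ceil(T / block))
    rng = np.random.default_rng(seed)
    assignments = tuple(rng.choice(["A", "B"], size=n_blocks))
    box = np.zeros(n_blocks * block)
    for i, a in enumerate(assignments):
        level = 2.0 * u if a == "A" else u
        box[i * block : i * block + epoch] = level
    return assignments, box[:T]


def canonical_hrf(tr: float, peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                  peak_disp: float = 1.0, undershoot_disp: float = 1.0,
                  undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the TR.

    h(t) = g(t; peak) - ratio * g(t; undershoot) on t = 0, tr, ..., 32 s,
    with gamma-density components peaking at 6 s and 16 s and an
    undershoot ratio of 1/6; normalized to peak 1.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    for v in (peak_delay, undershoot_delay, peak_disp, undershoot_disp):
        if v <= 0:
            raise ValueError("HRF shape parameters must be positive")
    t = np.arange(int(math.floor(HRF_SUPPORT_SECONDS / tr)) + 1) * tr
    # gamma density with mode at `delay`: shape = delay/disp + 1, scale = disp
    h = stats.gamma.pdf(t, peak_delay / peak_disp + 1.0, scale=peak_disp)
    h = h - undershoot_ratio * stats.gamma.pdf(
        t, undershoot_delay / undershoot_disp + 1.0, scale=undershoot_disp)
    peak = np.max(np.abs(h))
    if peak == 0:
        raise ValueError("degenerate HRF")
    return h / peak


def convolve_design(boxcar: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal discrete convolution of the boxcar with the HRF, truncated to T."""
    boxcar = np.asarray(boxcar, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if boxcar.size == 0 or kernel.size == 0:
        raise ValueError("convolve_design requires nonempty inputs")
    return np.convolve(boxcar, kernel)[: boxcar.size]


def scale_regressor(x_unscaled: np.ndarray, y_rest: TimeSeries, snr: float = 0.1):
    """Scale the regressor so mean(X) = snr * sd(resting series).

    Returns (X, scale_factor, cnr) with the contrast-to-noise ratio
    defined as the regressor's range over the resting noise sd.
    """
    x_unscaled = np.asarray(x_unscaled, dtype=float)
    m = float(x_unscaled.mean())
    if m <= 0:
        raise ValueError("unscaled regressor must have positive mean")
    sd = float(y_rest.values.std())
    if sd == 0:
        raise ValueError("resting series is constant")
    scale = snr * sd / m
    X = scale * x_unscaled
    cnr = float((X.max() - X.min()) / sd)
    return X, scale, cnr


def make_task_series(y_rest: TimeSeries, X: np.ndarray) -> TimeSeries:
    """Task run = resting series + scaled task regressor, TR preserved."""
    X = np.asarray(X, dtype=float)
    if X.size != y_rest.n:
        raise ValueError(f"regressor length {X.size} != series length {y_rest.n}")
    return y_rest.with_values(y_rest.values + X)


def make_task_design(y_rest: TimeSeries, snr: float = 0.1, u: float = 1.0,
                     seed: int = 0) -> TaskDesign:
    """Full pipeline: boxcar -> HRF convolution -> SNR scaling for one series."""
    assignments, box = boxcar_design(y_rest.n, y_rest.tr, u=u, seed=seed)
    kernel = canonical_hrf(y_rest.tr)
    x_un = convolve_design(box, kernel)
    X, scale, cnr = scale_regressor(x_un, y_rest, snr=snr)
    return TaskDesign(assignments, box, x_un, scale, X, snr, cnr, seed)


def glm_wald(y: TimeSeries, X: np.ndarray, transform: np.ndarray | None = None,
             alpha: float = 0.05) -> GLMResult:
    """Wald test of the task slope in the whitened GLM Y = b0 + b1 X + e.

    The outcome, the regressor, and the intercept column are all
    premultiplied by the whitening transform; ordinary least squares on the
    transformed model then yields the Wald statistic b1_hat / SE(b1_hat),
    referred to a t distribution with T - 2 degrees of freedom.
    """
    X = np.asarray(X, dtype=float)
    T = y.n
    if X.size != T:
        raise ValueError("regressor and outcome lengths differ")
    ones = np.ones(T)
    yv = y.values
    if transform is not None:
        yv = transform @ yv
        X = transform @ X
        ones = transform @ ones
    D = np.column_stack([ones, X])
    # collinearity check on the transformed design
    if np.linalg.matrix_rank(D) < 2:
        raise ValueError("regressor collinear with the intercept after transformation")
    beta, _, _, _ = np.linalg.lstsq(D, yv, rcond=None)
    resid = yv - D @ beta
    df = T - 2
    sse = float(resid @ resid)
    if df <= 0:
        raise ValueError("not enough observations for inference")
    sigma2 = sse / df
    if sigma2 <= np.finfo(float).eps * max(1.0, float(yv @ yv)):
        raise ValueError("degenerate inference: residual variance is zero")
    XtX_inv = np.linalg.inv(D.T @ D)
    se1 = math.sqrt(sigma2 * XtX_inv[1, 1])
    wald = float(beta[1] / se1)
    p = float(2.0 * stats.t.sf(abs(wald), df))
    return GLMResult(float(beta[0]), float(beta[1]), se1, wald, df, p, p < alpha)


_METHOD_ALIASES = {"idar-iter1": "idar_iter1"}


def _whiten_transform(series: TimeSeries, method: str, alpha: float,
                      max_iter: int):
    res = whiten_mod.baseline_whiten(series, method=method, alpha=alpha,
                                     max_iter=max_iter)
    C = res.transform.composite if res.transform.factors else None
    return C, res.adequacy.inadequate


def run_experiment(dataset: NodeDataset, methods, alpha: float = 0.05,
                   snr: float = 0.1, seed: int = 0, max_iter: int = 5) -> ExperimentSummary:
    """Power / type-I / accuracy of the whitened Wald test across a dataset.

    For every (subject, node) series the subject's boxcar design is scaled
    to the series and added to form the task outcome.  For each whitening
    method the transform is estimated from the outcome series under test
    (task outcome for power, resting outcome for type-I), the design is
    transformed accordingly, and the slope is Wald-tested at ``alpha``.
    Accuracy = (rejections on task + non-rejections on rest) / (2 N).
    """
    methods = [_METHOD_ALIASES.get(m, m) for m in methods]
    counts = {m: {"power": 0, "type1": 0, "n": 0, "inad_rest": 0, "inad_task": 0,
                  "failed": 0} for m in methods}
    subject_seeds = {s: int(np.random.SeedSequence([int(seed), s]).generate_state(1)[0] % (2**31 - 1))
                     for s in range(dataset.n_subjects)}
    for s, j, y_rs in dataset.iter_series():
        design = make_task_design(y_rs, snr=snr, seed=subject_seeds[s])
        y_ts = make_task_series(y_rs, design.regressor)
        for m in methods:
            try:
                C_ts, inad_ts = _whiten_transform(y_ts, m, alpha, max_iter)
                C_rs, inad_rs = _whiten_transform(y_rs, m, alpha, max_iter)
                r_power = glm_wald(y_ts, design.regressor, C_ts, alpha=alpha)
                r_null = glm_wald(y_rs, design.regressor, C_rs, alpha=alpha)
            except ValueError:
                counts[m]["failed"] += 1
                continue
            c = counts[m]
            c["n"] += 1
            c["power"] += r_power.rejected
            c["type1"] += r_null.rejected
            c["inad_task"] += inad_ts
            c["inad_rest"] += inad_rs
    power, type1, accuracy, inad_r, inad_t, failed = {}, {}, {}, {}, {}, {}
    for m in methods:
        c = counts[m]
        n = max(c["n"], 1)
        power[m] = c["power"] / n
        type1[m] = c["type1"] / n
        accuracy[m] = (c["power"] + (c["n"] - c["type1"])) / (2 * n)
        inad_r[m] = c["inad_rest"] / n
        inad_t[m] = c["inad_task"] / n
        failed[m] = c["failed"]
    return ExperimentSummary(tuple(methods), power, type1, accuracy, inad_r,
                             inad_t, dataset.n_subjects * dataset.n_nodes, failed)
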