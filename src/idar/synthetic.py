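"""Seeded generators for resting-state-like synthetic time series.

The generators cover the serial-correlation regimes a node-averaged BOLD
signal can present: white noise, stationary AR(p), ARMA(1,1), and a
"stacked" process built by applying the symmetric square roots of several
AR Toeplitz correlation matrices to white noise.  The stacked process is
the interesting one: its correlation structure is a product of AR
structures and is, in general, not expressible as any single AR model —
exactly the situation in which one-shot AR pre-whitening leaves residual
serial correlation and an iterative whitener earns its keep.

All generators are deterministic under a seed; multi-series datasets
derive one child seed per (subject, node) from the master seed so that any
slice can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.linalg import toeplitz
from scipy.signal import lfilter

from .timeseries import TimeSeries

__all__ = [
    "GeneratorSpec",
    "NodeDataset",
    "gen_white",
    "gen_ar",
    "gen_arma11",
    "gen_stacked",
    "gen_dataset",
    "ar_is_stationary",
]


def ar_is_stationary(phi: np.ndarray) -> bool:
    """True when all roots of 1 - phi_1 z - ... - phi_p z^p lie outside the unit circle."""
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    if phi.size == 0 or np.all(phi == 0):
        return True
    # roots of z^p - phi_1 z^{p-1} - ... - phi_p (the reciprocal polynomial,
    # monic, so no tiny-leading-coefficient issues) must lie inside the circle
    roots = np.roots(np.r_[1.0, -phi])
    return bool(np.all(np.abs(roots) < 1.0 - 1e-10))


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic series.

    kind
        One of ``white``, ``ar``, ``arma11``, ``stacked``.
    coefficients
        AR coefficients ``phi`` (and for ``arma11`` the pair ``(phi, theta)``).
    innovation_sd
        Standard deviation of the Gaussian innovations.
    """

    kind: str
    coefficients: tuple = ()
    innovation_sd: float = 1.0
    length: int = 500
    tr: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"white", "ar", "arma11", "stacked"}:
            raise ValueError(f"unknown generator kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not self.innovation_sd >= 0:
            raise ValueError("innovation_sd must be nonnegative")
        if not self.tr > 0:
            raise ValueError("tr must be positive")
        object.__setattr__(self, "coefficients", tuple(float(c) for c in np.atleast_1d(self.coefficients)) if self.kind != "white" else tuple())
        if self.kind == "ar" and not ar_is_stationary(np.asarray(self.coefficients)):
            raise ValueError(f"AR coefficients {self.coefficients} are not stationary")
        if self.kind == "arma11":
            if len(self.coefficients) != 2:
                raise ValueError("arma11 requires coefficients (phi, theta)")
            phi, theta = self.coefficients
            if abs(phi) >= 1 or abs(theta) >= 1:
                raise ValueError("arma11 requires |phi| < 1 and |theta| < 1")


@dataclass(frozen=True)
class NodeDataset:
    """subjects x nodes x time array of independent synthetic series."""

    data: np.ndarray
    tr: float
    labels: tuple
    seeds: np.ndarray  # (subjects, nodes) child seeds

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be subjects x nodes x time")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_time(self) -> int:
        return self.data.shape[2]

    def series(self, subject: int, node: int) -> TimeSeries:
        return TimeSeries(self.data[subject, node], self.tr)

    def iter_series(self):
        for s in range(self.n_subjects):
            for j in range(self.n_nodes):
                yield s, j, self.series(s, j)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def gen_white(T: int, sd: float = 1.0, seed: int = 0, tr: float = 1.0) -> TimeSeries:
    """I.i.d. Gaussian series of length ``T`` with standard deviation ``sd``."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    return TimeSeries(_rng(seed).normal(0.0, sd, size=T) if sd > 0 else np.zeros(T), tr)


def _burn_in(p: int) -> int:
    # long enough that initialization transients are negligible
    return 10 * max(p, 1) + 100


def gen_ar(spec: GeneratorSpec) -> TimeSeries:
    """Simulate a stationary AR(p) process y_t = sum_j phi_j y_{t-j} + eps_t."""
    phi = np.asarray(spec.coefficients, dtype=float)
    if not ar_is_stationary(phi):
        raise ValueError(f"AR coefficients {tuple(phi)} are not stationary")
    p = phi.size
    if p == 0 or np.all(phi == 0):
        return gen_white(spec.length, spec.innovation_sd, spec.seed, spec.tr)
    burn = _burn_in(p)
    n = spec.length + burn
    eps = _rng(spec.seed).normal(0.0, spec.innovation_sd, size=n)
    y = lfilter([1.0], np.r_[1.0, -phi], eps)
    return TimeSeries(y[burn:], spec.tr)


def gen_arma11(spec: GeneratorSpec) -> TimeSeries:
    """Simulate y_t = phi*y_{t-1} + eps_t + theta*eps_{t-1} after burn-in."""
    phi, theta = spec.coefficients
    burn = _burn_in(1)
    n = spec.length + burn
    eps = _rng(spec.seed).normal(0.0, spec.innovation_sd, size=n)
    y = lfilter([1.0, theta], [1.0, -phi], eps)
    return TimeSeries(y[burn:], spec.tr)


def ar_acf(phi: Sequence[float], max_lag: int) -> np.ndarray:
    """Theoretical autocorrelation of a stationary AR process (lags 0..max_lag).

    Solves the Yule-Walker system for lags 1..p, then extends by the AR
    recursion.  Used here to build exact Toeplitz correlation matrices for
    the stacked generator; the model-fitting side has its own copy tied to
    fitted lag sets.
    """
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    if not ar_is_stationary(phi):
        raise ValueError("AR coefficients are not stationary")
    p = phi.size
    rho = np.zeros(max_lag + 1)
    rho[0] = 1.0
    if p == 0 or np.all(phi == 0):
        return rho
    A = np.eye(p)
    b = np.zeros(p)
    for h in range(1, p + 1):
        for j in range(1, p + 1):
            d = abs(h - j)
            if d == 0:
                b[h - 1] += phi[j - 1]
            else:
                A[h - 1, d - 1] -= phi[j - 1]
    rho_head = np.linalg.solve(A, b)
    upto = min(p, max_lag)
    rho[1 : upto + 1] = rho_head[:upto]
    for h in range(p + 1, max_lag + 1):
        rho[h] = phi @ rho[h - p : h][::-1]
    return rho


@lru_cache(maxsize=16)
def _stacked_transform(coef_sets: tuple, T: int) -> np.ndarray:
    """W = Sigma_1^{1/2} Sigma_2^{1/2} ... for AR Toeplitz correlation matrices."""
    W = np.eye(T)
    for phi in coef_sets:
        rho = ar_acf(np.asarray(phi), T - 1)
        M = toeplitz(rho)
        vals, vecs = np.linalg.eigh(M)
        vals = np.clip(vals, 0.0, None)
        W = W @ (vecs * np.sqrt(vals)) @ vecs.T
    return W


def gen_stacked(specs: Sequence[GeneratorSpec], T: int, seed: int, tr: float = 1.0,
                sd: float = 1.0) -> TimeSeries:
    """Series with stacked (product-of-AR) correlation structure.

    Returns ``W @ eps`` with ``W`` the ordered product of the symmetric
    square roots of each spec's Toeplitz correlation matrix.  The resulting
    correlation ``W W^T`` is not a single-AR structure in general.
    """
    if len(specs) < 2:
        raise ValueError("gen_stacked requires at least 2 AR specs")
    coef_sets = []
    for s in specs:
        if s.kind != "ar":
            raise ValueError("gen_stacked accepts AR specs only")
        if not ar_is_stationary(np.asarray(s.coefficients)):
            raise ValueError("all stacked specs must be stationary")
        coef_sets.append(tuple(s.coefficients))
    W = _stacked_transform(tuple(coef_sets), T)
    eps = _rng(seed).normal(0.0, sd, size=T)
    return TimeSeries(W @ eps, tr)


def stacked_correlation(specs: Sequence[GeneratorSpec], T: int) -> np.ndarray:
    """True correlation matrix W W^T of the stacked process, unit-diagonal rescaled."""
    coef_sets = tuple(tuple(s.coefficients) for s in specs)
    W = _stacked_transform(coef_sets, T)
    C = W @ W.T
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


def child_seed(master_seed: int, subject: int, node: int) -> int:
    """Deterministic per-series seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(subject), int(node)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _generate_one(spec: GeneratorSpec, T: int, tr: float, seed: int) -> np.ndarray:
    spec = GeneratorSpec(spec.kind, spec.coefficients, spec.innovation_sd, T, tr, seed)
    if spec.kind == "white":
        return gen_white(T, spec.innovation_sd, seed, tr).values
    if spec.kind == "ar":
        return gen_ar(spec).values
    if spec.kind == "arma11":
        return gen_arma11(spec).values
    raise ValueError(f"cannot generate kind {spec.kind!r} per-node here")


def gen_dataset(n_subjects: int, n_nodes: int, specs, T: int, tr: float,
                seed: int, labels=None) -> NodeDataset:
    """Independent series per (subject, node), child seeds from the master seed.

    ``specs`` is either one GeneratorSpec applied to every node or a list of
    one spec per node.
    """
    if n_subjects < 1 or n_nodes < 1:
        raise ValueError("n_subjects and n_nodes must be >= 1")
    if isinstance(specs, GeneratorSpec):
        specs = [specs] * n_nodes
    if len(specs) != n_nodes:
        raise ValueError(f"got {len(specs)} specs for {n_nodes} nodes")
    data = np.empty((n_subjects, n_nodes, T))
    seeds = np.empty((n_subjects, n_nodes), dtype=np.int64)
    for s in range(n_subjects):
        for j in range(n_nodes):
            cs = child_seed(seed, s, j)
            seeds[s, j] = cs
            data[s, j] = _generate_one(specs[j], T, tr, cs)
    if labels is None:
        labels = tuple(f"node{j + 1}" for j in range(n_nodes))
    return NodeDataset(data, tr, tuple(labels), seeds)
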