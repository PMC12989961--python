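"""NMF solvers (HALS, MU), NNDSVD-family initialization and quality metrics.

Both engines minimize the squared Euclidean distance ½‖X − WH‖²_F over
nonnegative W (m×r, components as columns) and H (r×n, components as rows).
Convergence is declared when the relative change of every component — each
column of W and each row of H — falls below a tolerance ϵ:

    ‖w_j⁽ᵏ⁺¹⁾ − w_j⁽ᵏ⁾‖² ≤ ϵ ‖w_j⁽ᵏ⁺¹⁾ + w_j⁽ᵏ⁾‖²   for all j,

and the analogous condition on the rows of H.  A component that is exactly
zero in both iterates counts as converged (it is unchanging).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .exceptions import (DimensionError, NumericError, UndefinedMetricError,
                         ValidationError)
from .linalg import truncated_svd

__all__ = ["Factorization", "ConvergenceConfig", "sed_objective",
           "relative_fitting_error", "has_converged", "nndsvd_init",
           "run_hals", "run_mu", "random_init"]

logger = logging.getLogger(__name__)

#: denominator floor for multiplicative updates
_MU_FLOOR = 1e-9


@dataclass
class Factorization:
    """A nonnegative factorization X ≈ WH with provenance.

    ``objective_trace`` holds (iteration, ½‖X − WH‖²_F) pairs when tracing
    was requested; it is empty otherwise because evaluating the objective
    costs more than an update sweep.
    """

    W: np.ndarray
    H: np.ndarray
    converged: bool = False
    iterations: int = 0
    objective_trace: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def rank(self) -> int:
        return self.W.shape[1]

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if self.W.ndim != 2 or self.H.ndim != 2 or self.W.shape[1] != self.H.shape[0]:
            raise DimensionError(
                f"W {self.W.shape} and H {self.H.shape} are not conformable")
        if self.W.min(initial=0.0) < 0 or self.H.min(initial=0.0) < 0:
            raise ValidationError("W and H must be nonnegative")

    def copy(self) -> "Factorization":
        return Factorization(self.W.copy(), self.H.copy(), self.converged,
                             self.iterations, list(self.objective_trace),
                             dict(self.meta))


@dataclass
class ConvergenceConfig:
    """Tolerances for the staged pipeline.

    ``eps`` is the generic tolerance; ``eps0`` governs the under-complete
    stage and ``eps1`` the final refinement (both default to ``eps``).
    """

    eps: float = 1e-4
    eps0: float | None = None
    eps1: float | None = None
    max_iter: int = 10_000

    def __post_init__(self):
        if self.eps0 is None:
            self.eps0 = self.eps
        if self.eps1 is None:
            self.eps1 = self.eps
        if min(self.eps, self.eps0, self.eps1) <= 0:
            raise ValidationError("tolerances must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")


def _check_shapes(X, W, H):
    X = np.asarray(X, dtype=float)
    if X.shape != (W.shape[0], H.shape[1]):
        raise DimensionError(
            f"X {X.shape} incompatible with W {W.shape}, H {H.shape}")
    return X


def sed_objective(X: np.ndarray, fact: Factorization) -> float:
    """Squared Euclidean distance objective ½‖X − WH‖²_F."""
    X = _check_shapes(X, fact.W, fact.H)
    R = X - fact.W @ fact.H
    return 0.5 * float(np.sum(R * R))


def relative_fitting_error(X: np.ndarray, fact: Factorization) -> float:
    """Relative fitting error 100·‖X − WH‖²_F / ‖X‖²_F, in percent."""
    X = _check_shapes(X, fact.W, fact.H)
    denom = float(np.sum(X * X))
    if denom == 0.0:
        raise UndefinedMetricError("relative fitting error undefined for X = 0")
    R = X - fact.W @ fact.H
    return 100.0 * float(np.sum(R * R)) / denom


def _converged_arrays(Wp, Hp, W, H, eps) -> bool:
    for prev, curr, axis in ((Wp, W, 0), (Hp, H, 1)):
        d = np.sum((curr - prev) ** 2, axis=axis)
        s = np.sum((curr + prev) ** 2, axis=axis)
        # dead component (both zero): unchanging, counts as converged
        live = s > 0
        if np.any(d[live] > eps * s[live]):
            return False
        if np.any(d[~live] > 0):
            return False
    return True


def has_converged(prev: Factorization, curr: Factorization, eps: float) -> bool:
    """Component-wise relative-change stopping rule (see module docstring)."""
    if prev.rank != curr.rank or prev.W.shape != curr.W.shape \
            or prev.H.shape != curr.H.shape:
        raise DimensionError("factorizations differ in rank or shape")
    return _converged_arrays(prev.W, prev.H, curr.W, curr.H, eps)


def nndsvd_init(X: np.ndarray, r: int, variant: str = "plain",
                seed: int | None = None) -> Factorization:
    """NNDSVD initialization: nonnegative double SVD.

    Each of the leading ``r`` singular triples (σ, u, v) is truncated to its
    dominant nonnegative section (positive or negative parts of u and v,
    whichever has the larger norm product) and rescaled so the outer product
    keeps the section's magnitude.  Variants: ``plain`` leaves truncation
    zeros in place, ``a`` fills them with mean(X), ``ar`` with small uniform
    random values drawn from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    if not 1 <= r <= min(m, n):
        raise DimensionError(f"r={r} must be in [1, min(m,n)={min(m, n)}]")
    if variant not in ("plain", "a", "ar"):
        raise ValidationError(f"unknown NNDSVD variant {variant!r}")
    svd = truncated_svd(X, r)
    W = np.zeros((m, r))
    H = np.zeros((r, n))
    # leading component of a nonnegative matrix is nonnegative (Perron-Frobenius)
    W[:, 0] = np.sqrt(svd.sigma[0]) * np.abs(svd.U[:, 0])
    H[0, :] = np.sqrt(svd.sigma[0]) * np.abs(svd.V[:, 0])
    for j in range(1, r):
        u, v = svd.U[:, j], svd.V[:, j]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        nup, nun = np.linalg.norm(up), np.linalg.norm(un)
        nvp, nvn = np.linalg.norm(vp), np.linalg.norm(vn)
        termp, termn = nup * nvp, nun * nvn
        if termp >= termn:
            if termp > 0:
                scale = np.sqrt(svd.sigma[j] * termp)
                W[:, j] = scale * up / nup
                H[j, :] = scale * vp / nvp
        elif termn > 0:
            scale = np.sqrt(svd.sigma[j] * termn)
            W[:, j] = scale * un / nun
            H[j, :] = scale * vn / nvn
    if variant == "a":
        mean = X.mean()
        W[W == 0] = mean
        H[H == 0] = mean
    elif variant == "ar":
        rng = np.random.default_rng(seed)
        mean = X.mean()
        wz, hz = W == 0, H == 0
        W[wz] = rng.uniform(0, mean / 100.0, wz.sum())
        H[hz] = rng.uniform(0, mean / 100.0, hz.sum())
    return Factorization(W, H, meta={"init": f"nndsvd{'' if variant == 'plain' else variant}",
                                     "seed": seed})


def random_init(X: np.ndarray, r: int, seed: int | None = None) -> Factorization:
    """Uniform random initialization scaled so that E[WH] ≈ mean(X)."""
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(X.mean(), 0.0) / max(r, 1))
    W = rng.uniform(0, 2 * scale, (m, r))
    H = rng.uniform(0, 2 * scale, (r, n))
    return Factorization(W, H, meta={"init": "random", "seed": seed})


def _finish(X, W, H, converged, it, trace, init) -> Factorization:
    fact = Factorization(W, H, converged=converged, iterations=it,
                         objective_trace=trace,
                         meta=dict(init.meta))
    return fact


def run_hals(X: np.ndarray, init: Factorization, config: ConvergenceConfig,
             eps: float | None = None, trace_objective: bool = False) -> Factorization:
    """Hierarchical alternating least squares: exact per-component updates.

    Each sweep updates the columns of W, then the rows of H, by the
    closed-form nonnegative rank-1 least-squares solution; the objective is
    non-increasing sweep to sweep.
    """
    X = _check_shapes(X, init.W, init.H)
    eps = config.eps if eps is None else eps
    W, H = init.W.copy(), init.H.copy()
    r = W.shape[1]
    floor = 1e-16 * X.max(initial=0.0)
    trace: list = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        Wp, Hp = W.copy(), H.copy()
        HHt = H @ H.T
        XHt = X @ H.T
        for p in range(r):
            denom = HHt[p, p]
            if denom <= 0:
                continue
            w = W[:, p] + (XHt[:, p] - W @ HHt[:, p]) / denom
            np.maximum(w, 0, out=w)
            if not w.any():
                # keep the component alive at a tiny uniform level
                logger.debug("HALS: W column %d hit zero; flooring", p)
                w[:] = floor
            W[:, p] = w
        WtW = W.T @ W
        WtX = W.T @ X
        for p in range(r):
            denom = WtW[p, p]
            if denom <= 0:
                continue
            h = H[p, :] + (WtX[p, :] - WtW[p, :] @ H) / denom
            np.maximum(h, 0, out=h)
            if not h.any():
                logger.debug("HALS: H row %d hit zero; flooring", p)
                h[:] = floor
            H[p, :] = h
        if not (np.all(np.isfinite(W)) and np.all(np.isfinite(H))):
            raise NumericError(f"non-finite factor entries at iteration {it}")
        if trace_objective:
            R = X - W @ H
            trace.append((it, 0.5 * float(np.sum(R * R))))
        if _converged_arrays(Wp, Hp, W, H, eps):
            converged = True
            break
    return _finish(X, W, H, converged, it, trace, init)


def run_mu(X: np.ndarray, init: Factorization, config: ConvergenceConfig,
           eps: float | None = None, trace_objective: bool = False) -> Factorization:
    """Multiplicative updates (Lee–Seung) for the squared Euclidean objective.

    Entries that start at exactly zero stay zero (multiplicative locking);
    callers refining a truncated initialization should perturb it first.
    """
    X = _check_shapes(X, init.W, init.H)
    eps = config.eps if eps is None else eps
    W, H = init.W.copy(), init.H.copy()
    trace: list = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        Wp, Hp = W.copy(), H.copy()
        W *= (X @ H.T) / (W @ (H @ H.T) + _MU_FLOOR)
        H *= (W.T @ X) / ((W.T @ W) @ H + _MU_FLOOR)
        if not (np.all(np.isfinite(W)) and np.all(np.isfinite(H))):
            raise NumericError(f"non-finite factor entries at iteration {it}")
        if trace_objective:
            R = X - W @ H
            trace.append((it, 0.5 * float(np.sum(R * R))))
        if _converged_arrays(Wp, Hp, W, H, eps):
            converged = True
            break
    return _finish(X, W, H, converged, it, trace, init)


ENGINES = {"hals": run_hals, "mu": run_mu}
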