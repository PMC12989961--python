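"""End-to-end staged pipeline: under-complete NMF → recovery → refinement.

The full procedure factorizes X at a deliberately small rank r0 (stage 1,
tolerance ϵ0), proposes k additional components by GSVD feature recovery
against the rank-r0 truncated SVD (stage 2), and refines the augmented
rank-(r0+k) factorization with the same NMF engine (stage 3, tolerance ϵ1).
Because recovery cannot increase the fitting error and refinement is
initialized from its output, the final error never exceeds the
under-complete error (HALS engine).

Also provided: incremental one-at-a-time expansion from a small starting
rank, and a paired benchmarking protocol comparing direct rank-r NMF
against rank expansion from a shared initialization.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import UnsupportedRankError, ValidationError
from .linalg import truncated_svd
from .nmf import (ENGINES, ConvergenceConfig, Factorization, nndsvd_init,
                  random_init, relative_fitting_error)
from .recovery import MU_PERTURBATION, gsvd_feature_recovery

__all__ = ["PipelineConfig", "BenchmarkRecord", "resolve_k", "gsvd_nmf",
           "incremental_expand", "benchmark_compare"]


def resolve_k(policy, r0: int) -> int:
    """Resolve a component-count policy to an integer.

    Accepts an explicit positive integer, ``"one"``, or ``"fraction:f"``
    which yields ``max(1, round(f * r0))`` with half-away-from-zero
    rounding.
    """
    if isinstance(policy, (int, np.integer)):
        if policy < 1:
            raise ValidationError("k must be >= 1")
        return int(policy)
    if policy == "one":
        return 1
    if isinstance(policy, str) and policy.startswith("fraction:"):
        frac = float(policy.split(":", 1)[1])
        if frac <= 0:
            raise ValidationError("fraction must be positive")
        return max(1, int(np.floor(frac * r0 + 0.5)))
    raise ValidationError(f"unrecognized k policy {policy!r}")


@dataclass
class PipelineConfig:
    """Configuration of the staged pipeline."""

    r0: int = 2
    k: object = 1                   # int, "one", or "fraction:0.2"
    engine: str = "hals"
    init: str = "nndsvd"            # random | nndsvd | nndsvda | nndsvdar
    tolerances: ConvergenceConfig = field(default_factory=ConvergenceConfig)
    seed: int | None = None
    trace_objective: bool = False
    solver: str = "decoupled"

    def __post_init__(self):
        if self.engine not in ENGINES:
            raise ValidationError(f"unknown engine {self.engine!r}")
        if self.init not in ("random", "nndsvd", "nndsvda", "nndsvdar"):
            raise ValidationError(f"unknown init {self.init!r}")


@dataclass
class BenchmarkRecord:
    """One arm of one seeded comparison run."""

    dataset: str
    seed: int
    arm: str                        # "standard" | "gsvd"
    error_pct: float
    iterations: int
    timings: dict = field(default_factory=dict)


def _initialize(X, r, config: PipelineConfig) -> Factorization:
    if config.init == "random":
        return random_init(X, r, seed=config.seed)
    variant = {"nndsvd": "plain", "nndsvda": "a", "nndsvdar": "ar"}[config.init]
    return nndsvd_init(X, r, variant=variant, seed=config.seed)


def gsvd_nmf(X: np.ndarray, config: PipelineConfig,
             W00: np.ndarray | None = None,
             H00: np.ndarray | None = None) -> Factorization:
    """Full pipeline; returns the rank-(r0+k) factorization with provenance.

    ``W00``/``H00`` override the stage-1 initialization (e.g. the first r0
    components of a shared random start in the benchmarking protocol).
    """
    X = np.asarray(X, dtype=float)
    r0 = config.r0
    if r0 < 2:
        raise UnsupportedRankError("the pipeline requires r0 >= 2")
    k = resolve_k(config.k, r0)
    engine = ENGINES[config.engine]
    tol = config.tolerances
    prov: dict = {"r0": r0, "k": k, "engine": config.engine}

    t0 = time.perf_counter()
    if W00 is None or H00 is None:
        init0 = _initialize(X, r0, config)
    else:
        init0 = Factorization(W00, H00)
    under = engine(X, init0, tol, eps=tol.eps0,
                   trace_objective=config.trace_objective)
    prov["stage1"] = {"iterations": under.iterations,
                      "error_pct": relative_fitting_error(X, under),
                      "seconds": time.perf_counter() - t0}

    t1 = time.perf_counter()
    svd = truncated_svd(X, r0)
    prop = gsvd_feature_recovery(X, under.W, under.H, svd=svd, k=k,
                                 solver=config.solver)
    Wg, Hg = prop.Wg, prop.Hg
    if config.engine == "mu":
        Wg = Wg + MU_PERTURBATION
        Hg = Hg + MU_PERTURBATION
    prov["stage2"] = {
        "error_pct": relative_fitting_error(X, Factorization(prop.Wg, prop.Hg)),
        "lambda_spectrum": prop.lambda_spectrum.tolist(),
        "nothing_to_recover": prop.nothing_to_recover,
        "seconds": time.perf_counter() - t1}

    t2 = time.perf_counter()
    final = engine(X, Factorization(Wg, Hg), tol, eps=tol.eps1,
                   trace_objective=config.trace_objective)
    prov["stage3"] = {"iterations": final.iterations,
                      "error_pct": relative_fitting_error(X, final),
                      "seconds": time.perf_counter() - t2}
    final.meta.update(prov)
    return final


def incremental_expand(X: np.ndarray, r_start: int, r_target: int,
                       config: PipelineConfig):
    """Grow the rank one component at a time from r_start to r_target.

    Returns ``(factorization, trajectory)`` where trajectory is the list of
    (rank, relative fitting error %) after each refinement.
    """
    X = np.asarray(X, dtype=float)
    if not 2 <= r_start <= r_target:
        raise ValidationError("need 2 <= r_start <= r_target")
    engine = ENGINES[config.engine]
    tol = config.tolerances
    fact = engine(X, _initialize(X, r_start, config), tol, eps=tol.eps1,
                  trace_objective=config.trace_objective)
    trajectory = [(r_start, relative_fitting_error(X, fact))]
    r = r_start
    while r < r_target:
        prop = gsvd_feature_recovery(X, fact.W, fact.H, k=1,
                                     solver=config.solver)
        Wg, Hg = prop.Wg, prop.Hg
        if config.engine == "mu":
            Wg = Wg + MU_PERTURBATION
            Hg = Hg + MU_PERTURBATION
        fact = engine(X, Factorization(Wg, Hg), tol, eps=tol.eps1,
                      trace_objective=config.trace_objective)
        r += 1
        trajectory.append((r, relative_fitting_error(X, fact)))
    fact.meta["trajectory"] = trajectory
    return fact, trajectory


def benchmark_compare(X: np.ndarray, r: int, k, n_seeds: int,
                      config: PipelineConfig, dataset: str = "X",
                      base_seed: int = 0):
    """Paired protocol: rank-r NMF from scratch vs rank expansion.

    For each seed a random rank-r initialization is drawn; the "standard"
    arm runs the engine at rank r from it, while the "gsvd" arm runs the
    under-complete stage from its first r0 = r − k components (tolerance
    ϵ0) and then expands and refines.  Both arms therefore share as much of
    the initialization as their ranks allow.
    """
    X = np.asarray(X, dtype=float)
    if n_seeds < 1:
        raise ValidationError("n_seeds must be >= 1")
    k = resolve_k(k, r - 1)
    r0 = r - k
    if r0 < 2:
        raise UnsupportedRankError(f"r - k = {r0} must be >= 2")
    engine = ENGINES[config.engine]
    tol = config.tolerances
    records: list[BenchmarkRecord] = []
    for s in range(n_seeds):
        seed = base_seed + s
        init = random_init(X, r, seed=seed)
        try:
            t0 = time.perf_counter()
            std = engine(X, init, tol, eps=tol.eps1)
            records.append(BenchmarkRecord(
                dataset, seed, "standard", relative_fitting_error(X, std),
                std.iterations, {"seconds": time.perf_counter() - t0}))
            t0 = time.perf_counter()
            cfg = replace(config, r0=r0, k=k, seed=seed)
            exp = gsvd_nmf(X, cfg, W00=init.W[:, :r0], H00=init.H[:r0, :])
            records.append(BenchmarkRecord(
                dataset, seed, "gsvd", relative_fitting_error(X, exp),
                exp.iterations, {"seconds": time.perf_counter() - t0}))
        except Exception as exc:  # record and continue the sweep
            records.append(BenchmarkRecord(dataset, seed, "failed",
                                           float("nan"), 0,
                                           {"error": repr(exc)}))
    return records
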