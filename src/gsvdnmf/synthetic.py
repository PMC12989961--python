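"""Seeded synthetic data: smooth nonnegative components plus Gaussian noise.

The generator emulates a source-separation scenario: each of r_true ground
truth components is a smooth unimodal bump, in both the loading axis (a
column of W) and the coefficient axis (a row of H), with randomized center
and width.  The data matrix is X = W H + σ·E with E i.i.d. standard normal
scaled by the signal RMS, clipped at zero by default so the result remains
valid NMF input.  Pairwise cosine similarity between distinct true
components is kept below 0.95 so every component is identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .exceptions import DimensionError, GsvdNmfError, ValidationError

__all__ = ["SyntheticSpec", "make_ground_truth", "make_matrix", "fixture_2x2",
           "match_components"]

#: maximum pairwise cosine similarity between ground-truth components
_MAX_COSINE = 0.95


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic scenario.

    Defaults: a 200×300 matrix with 10 bump components and Gaussian noise
    at 10% of the signal RMS, clipped at zero.  Bump widths are uniform in
    ``width_range`` (as a fraction of the axis length) and centers uniform
    within a margin of one half-width from the edges.
    """

    m: int = 200
    n: int = 300
    r_true: int = 10
    width_range: tuple = (0.03, 0.10)
    noise_sigma: float = 0.1
    seed: int = 0
    clip_negative: bool = True


def _bumps(length: int, r: int, width_range, rng) -> np.ndarray:
    # stratified centers: one bump per equal-width stratum, jittered, in
    # shuffled order so component index carries no positional information
    x = np.arange(length)
    edges = np.linspace(0, length, r + 1)
    strata = rng.permutation(r)
    cols = np.empty((length, r))
    for j in range(r):
        width = rng.uniform(*width_range) * length
        lo, hi = edges[strata[j]], edges[strata[j] + 1]
        center = rng.uniform(lo + 0.25 * (hi - lo), hi - 0.25 * (hi - lo))
        cols[:, j] = np.exp(-0.5 * ((x - center) / width) ** 2)
    return cols


def _max_pairwise_cosine(A: np.ndarray) -> float:
    norms = np.linalg.norm(A, axis=0)
    C = (A / norms).T @ (A / norms)
    np.fill_diagonal(C, 0.0)
    return float(np.abs(C).max()) if A.shape[1] > 1 else 0.0


def make_ground_truth(spec: SyntheticSpec):
    """Draw (Wtrue, Htrue): nonnegative smooth bump components.

    Regenerates (up to 100 attempts) until all pairwise cosine
    similarities, in W columns and H rows alike, are below 0.95.
    """
    if spec.r_true > min(spec.m, spec.n):
        raise DimensionError("r_true exceeds matrix dimensions")
    if spec.r_true < 1:
        raise ValidationError("r_true must be >= 1")
    rng = np.random.default_rng(spec.seed)
    for _ in range(100):
        W = _bumps(spec.m, spec.r_true, spec.width_range, rng)
        H = _bumps(spec.n, spec.r_true, spec.width_range, rng).T
        if max(_max_pairwise_cosine(W), _max_pairwise_cosine(H.T)) < _MAX_COSINE:
            return W, H
    raise GsvdNmfError(
        "could not draw sufficiently distinct components in 100 attempts; "
        "reduce r_true or widen the matrix")


def make_matrix(Wtrue: np.ndarray, Htrue: np.ndarray, noise_sigma: float,
                seed: int, clip_negative: bool = True) -> np.ndarray:
    """X = Wtrue·Htrue + σ·RMS(signal)·E, optionally clipped at zero."""
    if Wtrue.shape[1] != Htrue.shape[0]:
        raise DimensionError("Wtrue and Htrue are not conformable")
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    signal = Wtrue @ Htrue
    if noise_sigma == 0:
        return signal.copy()
    rng = np.random.default_rng(seed)
    rms = np.sqrt(np.mean(signal ** 2))
    X = signal + noise_sigma * rms * rng.standard_normal(signal.shape)
    if clip_negative:
        np.maximum(X, 0, out=X)
    return X


def make_dataset(spec: SyntheticSpec):
    """Convenience: ground truth plus the noisy matrix, all from one spec."""
    W, H = make_ground_truth(spec)
    X = make_matrix(W, H, spec.noise_sigma, seed=spec.seed + 1,
                    clip_negative=spec.clip_negative)
    return X, W, H


def fixture_2x2():
    """The printed 2×2 worked example: X and a deliberately poor (W0, H0)."""
    X = np.array([[3.0, 0.385], [0.84, 0.8087]])
    W0 = np.array([[1.5012, 0.0000], [0.2252, 1.2493]])
    H0 = np.array([[1.4655, 0.6395], [0.0000, 0.9605]])
    return X, W0, H0


def match_components(Wtrue: np.ndarray, West: np.ndarray):
    """Optimal one-to-one component matching by Pearson correlation.

    Solves the assignment problem maximizing the summed correlation of
    matched columns.  Returns ``(matching, correlations)`` where
    ``matching[i]`` is the column of ``West`` paired with column i of
    ``Wtrue`` (−1 if unmatched) and ``correlations`` the per-pair Pearson
    correlations (0 for zero-variance columns).
    """
    Wtrue = np.asarray(Wtrue, dtype=float)
    West = np.asarray(West, dtype=float)
    rt, re = Wtrue.shape[1], West.shape[1]
    C = np.zeros((rt, re))
    for i in range(rt):
        a = Wtrue[:, i] - Wtrue[:, i].mean()
        na = np.linalg.norm(a)
        if na <= 1e-12 * np.linalg.norm(Wtrue[:, i]):
            continue
        for j in range(re):
            b = West[:, j] - West[:, j].mean()
            nb = np.linalg.norm(b)
            # variance at rounding level counts as a constant column
            if nb <= 1e-12 * np.linalg.norm(West[:, j]):
                continue
            C[i, j] = float(a @ b) / (na * nb)
    row, col = scipy.optimize.linear_sum_assignment(-C)
    matching = np.full(rt, -1, dtype=int)
    matching[row] = col
    corr = np.zeros(rt)
    corr[row] = C[row, col]
    return matching, corr
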