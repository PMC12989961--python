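"""GSVD-based feature recovery: augment an under-complete NMF with new components.

Given a nonnegative factorization W0 H0 of rank r0 and the rank-r0
truncated SVD U Σ Vᵀ of the data X, the recovery step

1. compares the two factorizations through the GSVD of the pair
   (Σ, Uᵀ(W0 H0)V) and proposes the k coefficient directions
   y_i = V Q⁻ᵀ z_i with the largest generalized singular values — the
   directions along which the SVD carries energy that the NMF does not;
2. truncates each proposed row to its nonnegative part best aligned (in
   1-norm through the nonnegative residual ΔX = max(X − W0H0, 0)) with the
   unexplained signal;
3. solves a least-squares problem for the new loading columns S and
   nonnegative amplitude rescalers α of the old components, either by a
   decoupled closed form (default, O(mnr)) or by one large NNLS on the
   Kronecker-structured design (reference solver);
4. truncates each new rank-1 pair (s_p, y_p) to its dominant nonnegative
   section (the NNDSVD truncation);
5. rebalances all r0+k component amplitudes by NNLS.

The result can only lower the fitting error relative to W0 H0, and lowers
it strictly whenever the residual is nonzero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .exceptions import (DegenerateDirectionsError, DimensionError,
                         UnsupportedRankError, ValidationError)
from .linalg import TruncatedSVD, gsvd_pair, truncated_svd

__all__ = ["RecoveryProposal", "propose_directions", "truncate_direction_rows",
           "solve_direct_nnls", "solve_decoupled", "nndsvd_truncate_pairs",
           "rebalance_amplitudes", "gsvd_feature_recovery"]

logger = logging.getLogger(__name__)

#: MU engines are sensitive to exact zeros; this perturbation is added to all
#: entries of the recovered factors before an MU refinement stage
MU_PERTURBATION = 1e-5

#: default element budget for materializing the direct NNLS design matrix
_DIRECT_BUDGET = 50_000_000

#: relative residual below which there is nothing to recover
_NOTHING_TO_RECOVER_RTOL = 1e-12


@dataclass
class RecoveryProposal:
    """All intermediates and outputs of the recovery step."""

    Y: np.ndarray               # k×n selected directions (pre-truncation)
    Ynn: np.ndarray             # k×n nonnegative truncated directions
    S: np.ndarray               # m×k proposed loadings (may be signed)
    alpha: np.ndarray           # r0 amplitude rescalers of old components
    Wnew: np.ndarray            # m×k nonnegative truncated loadings
    Hnew: np.ndarray            # k×n nonnegative truncated coefficients
    beta: np.ndarray            # r0+k final amplitudes
    Wg: np.ndarray              # m×(r0+k) output loadings
    Hg: np.ndarray              # (r0+k)×n output coefficients
    lambda_selected: np.ndarray  # k generalized singular values used
    lambda_spectrum: np.ndarray  # full λ spectrum (diagnostics)
    nothing_to_recover: bool = False
    notes: list = field(default_factory=list)


def _as_2d(A, name):
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise DimensionError(f"{name} must be 2-D, got ndim={A.ndim}")
    return A


def propose_directions(svd: TruncatedSVD, W0: np.ndarray, H0: np.ndarray,
                       k: int):
    """Top-k coefficient directions where the SVD and the NMF disagree.

    Returns ``(Y, lambda_selected)``: Y is k×n with unit-norm rows ordered
    by descending generalized singular value (infinite first).
    """
    W0, H0 = _as_2d(W0, "W0"), _as_2d(H0, "H0")
    r0 = svd.rank
    if r0 < 2:
        raise UnsupportedRankError(
            "direction proposal requires an under-complete rank of at least 2")
    if not 1 <= k <= r0:
        raise ValidationError(f"k={k} must be in [1, r0={r0}]")
    A1 = np.diag(svd.sigma)
    A2 = (svd.U.T @ W0) @ (H0 @ svd.V)
    g = gsvd_pair(A1, A2)
    Z = scipy.linalg.solve(g.Q.T, np.eye(r0))  # columns Q⁻ᵀ z_i
    Y = (svd.V @ Z).T                          # rows y_iᵀ, λ-descending order
    norms = np.linalg.norm(Y, axis=1)
    norms[norms == 0] = 1.0
    Y = Y / norms[:, None]
    return Y[:k], g.lam[:k].copy()


def truncate_direction_rows(Y: np.ndarray, X: np.ndarray, W0: np.ndarray,
                            H0: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
    """Keep, per row, the sign section best aligned with the residual.

    With ΔX = max(X − W0H0, 0), row y is replaced by max(y, 0) if
    ‖ΔX·max(y,0)‖₁ ≥ ‖ΔX·max(−y,0)‖₁ and by max(−y, 0) otherwise.
    """
    Y = _as_2d(Y, "Y")
    X = _as_2d(X, "X")
    if B is None:
        B = W0 @ H0
    return _truncate_rows_with_delta(Y, np.maximum(X - B, 0))


def _truncate_rows_with_delta(Y, DeltaX):
    Ypos = np.maximum(Y, 0)
    Yneg = np.maximum(-Y, 0)
    # ΔX and the sections are nonnegative, so the 1-norms are plain sums
    score_pos = (DeltaX @ Ypos.T).sum(axis=0)
    score_neg = (DeltaX @ Yneg.T).sum(axis=0)
    keep_pos = score_pos >= score_neg
    Ynn = np.where(keep_pos[:, None], Ypos, Yneg)
    for p in np.flatnonzero(~Ynn.any(axis=1)):
        logger.warning("direction row %d truncated to zero", p)
    return Ynn


def _nnls_quadratic(G: np.ndarray, c: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Minimize ½xᵀGx − cᵀx subject to x ≥ 0, G symmetric PSD.

    Small systems go through an eigen square root and the Lawson–Hanson
    active-set solver; larger ones fall back to projected gradient with a
    KKT-residual stopping rule.
    """
    G = np.asarray(G, dtype=float)
    c = np.asarray(c, dtype=float)
    d = G.shape[0]
    if d == 0:
        return np.zeros(0)
    if d <= 200:
        w, E = scipy.linalg.eigh(G)
        w = np.clip(w, 0.0, None)
        A = (E * np.sqrt(w)).T
        b, *_ = np.linalg.lstsq(A.T, c, rcond=None)
        x, _ = scipy.optimize.nnls(A, b)
        return x
    # projected gradient with Nesterov momentum
    L = max(float(scipy.linalg.eigh(G, eigvals_only=True,
                                    subset_by_index=[d - 1, d - 1])[0]), 1e-30)
    x = np.zeros(d)
    z = x.copy()
    t = 1.0
    scale = max(np.abs(c).max(), 1e-30)
    for _ in range(10_000):
        grad = G @ z - c
        x_new = np.maximum(z - grad / L, 0.0)
        t_new = 0.5 * (1 + np.sqrt(1 + 4 * t * t))
        z = x_new + ((t - 1) / t_new) * (x_new - x)
        x, t = x_new, t_new
        kkt = np.where(x > 0, np.abs(grad), np.minimum(grad, 0.0))
        if np.abs(kkt).max() <= tol * scale:
            break
    return x


def solve_direct_nnls(X: np.ndarray, W0: np.ndarray, H0: np.ndarray,
                      Ynn: np.ndarray, max_elements: int = _DIRECT_BUDGET):
    """Joint NNLS for (S, α) on the materialized Kronecker design (reference).

    Minimizes ‖vec(X) − [Yᵀ⊗I_m, vec(w_p h_pᵀ)…]·θ‖² over θ ≥ 0 where θ
    stacks the column-flattened S and α.  Cost O(m²nk) — use
    :func:`solve_decoupled` in production.
    """
    X = _as_2d(X, "X")
    W0, H0, Ynn = _as_2d(W0, "W0"), _as_2d(H0, "H0"), _as_2d(Ynn, "Ynn")
    m, n = X.shape
    r0 = W0.shape[1]
    k = Ynn.shape[0]
    n_elem = m * n * (m * k + r0)
    if n_elem > max_elements:
        raise MemoryError(
            f"direct design matrix needs {n_elem:.2e} elements "
            f"(budget {max_elements:.2e}); use solve_decoupled instead")
    if not np.all(np.linalg.norm(Ynn, axis=1) > 0):
        raise ValidationError("Ynn has a zero row")
    F = np.kron(Ynn.T, np.eye(m))                # mn × mk, column-major S blocks
    A_alpha = np.empty((m * n, r0))
    for p in range(r0):
        A_alpha[:, p] = np.outer(W0[:, p], H0[p]).ravel(order="F")
    design = np.hstack([F, A_alpha])
    theta, _ = scipy.optimize.nnls(design, X.ravel(order="F"),
                                   maxiter=10 * design.shape[1])
    S = theta[:m * k].reshape((m, k), order="F")
    alpha = theta[m * k:]
    return S, alpha


def _reduced_system(X, W0, H0, Ynn):
    """Coefficients (Hess, c) of the reduced amplitude problem in α.

    Eliminating S from the joint quadratic gives
    ½αᵀ·Hess·α − cᵀα + const with
    Hess = (W0ᵀW0) ⊙ (H0H0ᵀ − HY·G⁻¹·HYᵀ), G = YYᵀ, HY = H0Yᵀ.
    The mk×mk operator (YYᵀ ⊗ I) is only ever applied through k×k solves.
    """
    G = Ynn @ Ynn.T
    k = Ynn.shape[0]
    norms = np.linalg.norm(Ynn, axis=1)
    if np.any(norms == 0):
        bad = np.flatnonzero(norms == 0).tolist()
        raise DegenerateDirectionsError(f"zero direction rows: {bad}")
    cond = np.linalg.cond(G)
    if not np.isfinite(cond) or cond > 1e10:
        raise DegenerateDirectionsError(
            f"direction rows nearly dependent (cond(YYᵀ)={cond:.3e})")
    cho = scipy.linalg.cho_factor(G)
    HY = H0 @ Ynn.T                                    # r0×k
    XY = X @ Ynn.T                                     # m×k
    WtW = W0.T @ W0
    Hess = WtW * (H0 @ H0.T - HY @ scipy.linalg.cho_solve(cho, HY.T))
    XHt = X @ H0.T
    xi = np.einsum("ip,ip->p", W0, XHt)
    proj = XY @ scipy.linalg.cho_solve(cho, HY.T)      # m×r0
    c = xi - np.einsum("ip,ip->p", W0, proj)
    return Hess, c, cho, XY, HY, XHt


def _solve_decoupled_full(X, W0, H0, Ynn):
    Hess, c, cho, XY, HY, XHt = _reduced_system(X, W0, H0, Ynn)
    alpha = _nnls_quadratic(Hess, c)
    S = scipy.linalg.cho_solve(cho, (XY - (W0 * alpha) @ HY).T).T
    return S, alpha, XHt


def solve_decoupled(X: np.ndarray, W0: np.ndarray, H0: np.ndarray,
                    Ynn: np.ndarray):
    """Decoupled solve for (S, α): closed-form S given α, NNLS in α only.

    α ≥ 0 minimizes the convex reduced quadratic; S is then recovered from
    the stationarity condition S = (X − W0·diag(α)·H0) Yᵀ (YYᵀ)⁻¹ and may
    contain negative entries (handled by the later truncation).
    """
    X = _as_2d(X, "X")
    W0, H0, Ynn = _as_2d(W0, "W0"), _as_2d(H0, "H0"), _as_2d(Ynn, "Ynn")
    S, alpha, _ = _solve_decoupled_full(X, W0, H0, Ynn)
    return S, alpha


def nndsvd_truncate_pairs(S: np.ndarray, Y: np.ndarray):
    """Truncate each rank-1 pair (s_p, y_p) to its dominant nonnegative section.

    The section (positive or negative parts of both vectors) with the
    larger product of Euclidean norms is kept and rebalanced so the two
    factors share the magnitude evenly; its outer product equals the kept
    section's outer product.
    """
    S, Y = _as_2d(S, "S"), _as_2d(Y, "Y")
    if S.shape[1] != Y.shape[0]:
        raise DimensionError(f"S {S.shape} and Y {Y.shape} not conformable")
    m, k = S.shape
    n = Y.shape[1]
    Wnew = np.zeros((m, k))
    Hnew = np.zeros((k, n))
    for p in range(k):
        s, y = S[:, p], Y[p]
        sp, sn = np.maximum(s, 0), np.maximum(-s, 0)
        yp, yn = np.maximum(y, 0), np.maximum(-y, 0)
        nsp, nsn = np.linalg.norm(sp), np.linalg.norm(sn)
        nyp, nyn = np.linalg.norm(yp), np.linalg.norm(yn)
        termp, termn = nsp * nyp, nsn * nyn
        if termp >= termn:
            skept, ykept, term, ns, ny = sp, yp, termp, nsp, nyp
        else:
            skept, ykept, term, ns, ny = sn, yn, termn, nsn, nyn
        if term <= 0:
            logger.warning("rank-1 pair %d truncated to zero; the amplitude "
                           "rebalancing will drop it", p)
            continue
        scale = np.sqrt(term)
        Wnew[:, p] = scale * skept / ns
        Hnew[p] = scale * ykept / ny
    return Wnew, Hnew


def _rebalance_with_error(X, W, H, phi, XHt=None):
    """β NNLS plus the achieved squared error, from the Gram system only."""
    G = (W.T @ W) * (H @ H.T)
    if XHt is None:
        XHt = X @ H.T
    c = np.einsum("ip,ip->p", W, XHt)
    beta = _nnls_quadratic(G, c)
    dead = (np.linalg.norm(W, axis=0) == 0) | (np.linalg.norm(H, axis=1) == 0)
    beta[dead] = 0.0
    err = float(phi - 2 * c @ beta + beta @ G @ beta)
    return beta, max(err, 0.0)


def rebalance_amplitudes(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> np.ndarray:
    """NNLS over per-component amplitudes β minimizing ‖X − Σ β_p w_p h_pᵀ‖²."""
    X = _as_2d(X, "X")
    W, H = _as_2d(W, "W"), _as_2d(H, "H")
    if W.shape[1] != H.shape[0] or X.shape != (W.shape[0], H.shape[1]):
        raise DimensionError("X, W, H shapes are not conformable")
    beta, _ = _rebalance_with_error(X, W, H, float(np.sum(X * X)))
    return beta


def _ansatz_direction(X, W0, H0):
    """Constructive fallback: the unit coefficient row e_jᵀ at the largest
    positive residual entry (guaranteed to admit an error-reducing rank-1)."""
    R = X - W0 @ H0
    i, j = np.unravel_index(np.argmax(R), R.shape)
    y = np.zeros(X.shape[1])
    y[j] = 1.0
    return y


def gsvd_feature_recovery(X: np.ndarray, W0: np.ndarray, H0: np.ndarray,
                          svd: TruncatedSVD | None = None, k: int = 1,
                          solver: str = "decoupled",
                          truncate_before_solve: bool = True) -> RecoveryProposal:
    """One-shot rank expansion of (W0, H0) by k components (see module docstring).

    ``solver`` selects the decoupled closed form (default) or the direct
    Kronecker NNLS (``"direct"``, reference).  With
    ``truncate_before_solve=False`` the proposed rows enter the solve with
    their signs and both S and Y are truncated jointly afterwards.
    """
    X = _as_2d(X, "X")
    W0, H0 = _as_2d(W0, "W0"), _as_2d(H0, "H0")
    m, n = X.shape
    r0 = W0.shape[1]
    if r0 < 2:
        raise UnsupportedRankError(
            "feature recovery requires an under-complete rank of at least 2")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if svd is None:
        svd = truncated_svd(X, r0)
    if svd.rank != r0:
        raise DimensionError(f"svd rank {svd.rank} != factorization rank {r0}")

    phi = float(np.dot(X.ravel(), X.ravel()))
    xnorm = np.sqrt(phi)
    B = W0 @ H0
    R = X - B
    base_err = float(np.dot(R.ravel(), R.ravel()))
    notes: list = []

    if np.sqrt(base_err) <= _NOTHING_TO_RECOVER_RTOL * xnorm:
        Wg = np.hstack([W0, np.zeros((m, k))])
        Hg = np.vstack([H0, np.zeros((k, n))])
        return RecoveryProposal(
            Y=np.zeros((k, n)), Ynn=np.zeros((k, n)), S=np.zeros((m, k)),
            alpha=np.ones(r0), Wnew=np.zeros((m, k)), Hnew=np.zeros((k, n)),
            beta=np.concatenate([np.ones(r0), np.zeros(k)]), Wg=Wg, Hg=Hg,
            lambda_selected=np.full(k, np.nan), lambda_spectrum=np.full(r0, np.nan),
            nothing_to_recover=True, notes=["nothing to recover"])

    Yall, lam_all = propose_directions(svd, W0, H0, k=r0)

    # pick k usable directions in λ order, skipping rows that truncate to
    # zero; truncation is done lazily in chunks of k since the top-k rows
    # almost always suffice
    DeltaX = np.maximum(R, 0)
    rows, lam_sel, rows_raw = [], [], []
    done = 0
    while len(rows) < k and done < r0:
        chunk = slice(done, min(done + k, r0))
        Ynn_chunk = _truncate_rows_with_delta(Yall[chunk], DeltaX)
        for off, ynn in enumerate(Ynn_chunk):
            idx = done + off
            if len(rows) == k:
                break
            if ynn.any():
                rows.append(ynn)
                rows_raw.append(Yall[idx])
                lam_sel.append(lam_all[idx])
            else:
                notes.append(f"direction {idx} truncated to zero; skipped")
        done = chunk.stop
    while len(rows) < k:
        y = _ansatz_direction(X, W0, H0)
        rows.append(y)
        rows_raw.append(y)
        lam_sel.append(np.nan)
        notes.append("substituted largest-residual ansatz direction")

    Ysel = np.vstack(rows_raw)
    Ynn = np.vstack(rows)
    lam_sel = np.asarray(lam_sel)

    Ysolve = Ynn if truncate_before_solve else Ysel
    XHt0 = None
    if solver == "decoupled":
        S, alpha, XHt0 = _solve_decoupled_full(X, W0, H0, Ysolve)
    elif solver == "direct":
        S, alpha = solve_direct_nnls(X, W0, H0, Ysolve)
    else:
        raise ValidationError(f"unknown solver {solver!r}")

    Wnew, Hnew = nndsvd_truncate_pairs(S, Ysolve)

    W = np.hstack([W0 * alpha, Wnew])
    H = np.vstack([H0, Hnew])
    XHt_full = None
    if XHt0 is not None:
        XHt_full = np.hstack([XHt0, X @ Hnew.T])
    beta, err = _rebalance_with_error(X, W, H, phi, XHt=XHt_full)
    Wg = W * beta
    Hg = H

    if err > base_err:
        # an α entry at zero can make the original factorization infeasible
        # for the β rescaling; absorb α into β over the unscaled W0 instead
        W = np.hstack([W0, Wnew])
        beta, err = _rebalance_with_error(X, W, H, phi, XHt=XHt_full)
        Wg = W * beta
        notes.append("rebalanced over unscaled W0 to restore non-increase")

    if err >= base_err and np.sqrt(base_err) > 1e-12 * xnorm:
        # nonzero residual guarantees an error-reducing nonnegative rank-1:
        # substitute the constructive ansatz for the first new component
        i, j = np.unravel_index(np.argmax(R), R.shape)
        if R[i, j] > 0:
            Wnew = Wnew.copy()
            Hnew = Hnew.copy()
            Wnew[:, 0] = 0.0
            Wnew[i, 0] = 1.0
            Hnew[0, :] = 0.0
            Hnew[0, j] = R[i, j]
            W = np.hstack([W0, Wnew])
            H = np.vstack([H0, Hnew])
            beta, err = _rebalance_with_error(X, W, H, phi)
            Wg = W * beta
            Hg = H
            notes.append("substituted residual ansatz to guarantee strict decrease")

    return RecoveryProposal(
        Y=Ysel, Ynn=Ynn, S=S, alpha=alpha, Wnew=Wnew, Hnew=Hnew, beta=beta,
        Wg=Wg, Hg=Hg, lambda_selected=lam_sel, lambda_spectrum=lam_all,
        nothing_to_recover=False, notes=notes)
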