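"""Truncated SVD and generalized SVD of small matrix pairs.

The generalized SVD (GSVD) of a pair (A1, A2) with a common column space
writes A1 = M1 D1 Qᵀ and A2 = M2 D2 Qᵀ with M1, M2 orthogonal, Q invertible
and D1, D2 diagonal.  The squared ratios of the paired diagonal entries are
the generalized singular values λ_i = d1_i² / d2_i², which also solve the
generalized eigenproblem A1ᵀA1 ŷ = λ A2ᵀA2 ŷ with eigenvectors given by the
columns of Q⁻ᵀ.  When A2 is rank deficient (rank l < r0), r0 − l of the λ
are infinite.

The GSVD is computed by the QR + cosine-sine route: stack [A1; A2], take a
full QR, and CS-decompose the orthogonal factor.  This avoids forming the
cross-products A1ᵀA1 and A2ᵀA2, which would square the condition number.
The cross-product route survives only as :func:`generalized_eigen_oracle`,
a brute-force reference used in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .exceptions import DegeneratePairError, DimensionError, ValidationError

__all__ = ["TruncatedSVD", "GSVDResult", "truncated_svd", "gsvd_pair",
           "generalized_eigen_oracle"]

#: relative threshold below which a D2 diagonal entry counts as exactly zero
#: (the corresponding generalized singular value is classified as infinite)
_D2_ZERO_RTOL = 1e-12

#: condition-number ceiling for Q before the pair is declared degenerate
_Q_COND_MAX = 1e12


@dataclass(frozen=True)
class TruncatedSVD:
    """Rank-``rank`` SVD triple of a dense matrix.

    ``U`` (m×r0) and ``V`` (n×r0) have orthonormal columns; ``sigma`` holds
    the singular values in descending order.
    """

    U: np.ndarray
    sigma: np.ndarray
    V: np.ndarray
    rank: int

    def reconstruct(self) -> np.ndarray:
        return (self.U * self.sigma) @ self.V.T


@dataclass(frozen=True)
class GSVDResult:
    """GSVD factors of a pair (A1, A2), sorted by descending λ.

    ``lam`` may contain ``np.inf`` entries (exactly ``rank - l`` of them,
    where ``l`` is the rank of A2); infinite values sort first and keep the
    decomposition's native order among themselves.
    """

    M1: np.ndarray
    M2: np.ndarray
    Q: np.ndarray
    D1: np.ndarray
    D2: np.ndarray
    lam: np.ndarray
    l: int
    rank: int = field(default=0)

    def reconstruct_first(self) -> np.ndarray:
        return self.M1 @ self.D1 @ self.Q.T

    def reconstruct_second(self) -> np.ndarray:
        return self.M2 @ self.D2 @ self.Q.T


def _check_finite(X: np.ndarray, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValidationError(f"{name} contains non-finite entries")
    return X


def truncated_svd(X: np.ndarray, r0: int) -> TruncatedSVD:
    """Best rank-``r0`` SVD of a dense matrix, with a fixed sign convention.

    Each column of U is flipped so that its entry of largest magnitude is
    nonnegative (V flipped to match), making the output deterministic.
    """
    X = _check_finite(X)
    m, n = X.shape
    if not 1 <= r0 <= min(m, n):
        raise DimensionError(f"r0={r0} must be in [1, min(m, n)={min(m, n)}]")
    U, s, Vt = scipy.linalg.svd(X, full_matrices=False)
    U, s, V = U[:, :r0], s[:r0], Vt[:r0].T
    # sign convention: dominant entry of each left singular vector >= 0
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(r0)])
    signs[signs == 0] = 1.0
    return TruncatedSVD(U=U * signs, sigma=s, V=V * signs, rank=r0)


def gsvd_pair(A1: np.ndarray, A2: np.ndarray) -> GSVDResult:
    """GSVD of a square pair (A1 diagonal nonnegative, A2 arbitrary).

    Returns factors satisfying ``A1 = M1 D1 Qᵀ`` and ``A2 = M2 D2 Qᵀ`` with
    D1, D2 diagonal and generalized singular values
    ``lam_i = D1[i,i]² / D2[i,i]²`` sorted descending (infinite first).
    """
    A1 = _check_finite(A1, "A1")
    A2 = _check_finite(A2, "A2")
    if A1.shape != A2.shape or A1.ndim != 2 or A1.shape[0] != A1.shape[1]:
        raise DimensionError(
            f"expected square pair of equal shape, got {A1.shape} and {A2.shape}")
    off = A1 - np.diag(np.diag(A1))
    if np.abs(off).max(initial=0.0) > 1e-12 * max(np.abs(A1).max(), 1e-300):
        raise ValidationError("A1 must be diagonal")
    if np.diag(A1).min() < 0:
        raise ValidationError("A1 diagonal must be nonnegative")
    r0 = A1.shape[0]

    Z = np.vstack([A1, A2])
    Qfull, R = scipy.linalg.qr(Z, mode="full")
    R1 = R[:r0, :]
    (U1, U2), theta, (V1h, _) = scipy.linalg.cossin(
        Qfull, p=r0, q=r0, separate=True)
    # cossin(separate=True) returns the principal angles; build the diagonals
    c, s = np.cos(theta), np.sin(theta)
    # angles occupy the trailing block; leading entries are exact cos=1/sin=0
    d1 = np.ones(r0)
    d2 = np.zeros(r0)
    d1[r0 - len(theta):] = c
    d2[r0 - len(theta):] = s
    Q = R1.T @ V1h.T

    cond = np.linalg.cond(Q)
    if not np.isfinite(cond) or cond > _Q_COND_MAX:
        raise DegeneratePairError(
            f"Q is numerically singular (cond={cond:.3e} > {_Q_COND_MAX:.0e}); "
            "the pair has a common null direction")

    d2max = d2.max(initial=0.0)
    infinite = d2 <= _D2_ZERO_RTOL * d2max if d2max > 0 else np.ones(r0, bool)
    lam = np.empty(r0)
    lam[infinite] = np.inf
    lam[~infinite] = (d1[~infinite] / d2[~infinite]) ** 2
    l = int(np.count_nonzero(~infinite))

    order = np.argsort(-lam, kind="stable")
    return GSVDResult(
        M1=U1[:, order], M2=U2[:, order], Q=Q[:, order],
        D1=np.diag(d1[order]), D2=np.diag(d2[order]),
        lam=lam[order], l=l, rank=r0)


def generalized_eigen_oracle(G1: np.ndarray, G2: np.ndarray):
    """Dense generalized eigensolve of a symmetric PSD pair (test oracle).

    Solves G1 v = λ G2 v by the QZ route and returns (eigenvalues,
    eigenvectors) sorted by descending eigenvalue with infinite values
    first.  This is a brute-force cross-check for :func:`gsvd_pair`; it is
    never used in the recovery path.
    """
    G1 = _check_finite(G1, "G1")
    G2 = _check_finite(G2, "G2")
    if G1.shape != G2.shape or G1.shape[0] != G1.shape[1]:
        raise DimensionError("G1, G2 must be square and of equal shape")
    for name, G in (("G1", G1), ("G2", G2)):
        if np.abs(G - G.T).max(initial=0.0) > 1e-10 * max(np.abs(G).max(), 1e-300):
            raise ValidationError(f"{name} is not symmetric")
    # QZ with homogeneous eigenvalues (alpha, beta): lam = alpha/beta,
    # beta ~ 0 marking an infinite eigenvalue
    (alpha, beta), vr = scipy.linalg.eig(G1, G2, homogeneous_eigvals=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(np.abs(beta) > 1e-14 * np.abs(alpha).max(initial=1.0),
                       (alpha / beta).real, np.inf)
    order = np.argsort(-lam, kind="stable")
    return lam[order], vr[:, order]
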