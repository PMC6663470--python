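"""Laplacian eigendecomposition, graph Fourier transform, and the matrix
square root of the normalized Laplacian (exact and Taylor-approximated).

The Taylor route rewrites ``L^{1/2} = (I - A)^{1/2}`` as the series
``I - sum_k c_k A^k`` with

    c_k = (2k)! / (2^{2k} (k!)^2 (2k - 1)),

i.e. c_1 = 1/2, c_2 = 1/8, c_3 = 1/16, c_4 = 5/128, ...  The series
converges because the spectrum of A lies in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import scipy.linalg

from .graph_core import NormalizedOperators

__all__ = [
    "SpectralBasis",
    "TaylorApprox",
    "eigendecompose",
    "gft",
    "igft",
    "sqrt_laplacian_exact",
    "taylor_coefficient",
    "taylor_coefficient_exact",
    "taylor_coefficients",
    "sqrt_laplacian_taylor",
    "lagrange_remainder_bound",
    "fix_signs",
]


@dataclass
class SpectralBasis:
    """Orthonormal eigenbasis of the normalized Laplacian.

    ``U`` holds eigenvectors as columns, ``lambdas`` the eigenvalues in
    ascending order (graph frequencies, in [0, 2]).  For connected graphs
    lambda_1 = 0 and u_1 is proportional to D^{1/2} 1.
    """

    U: np.ndarray
    lambdas: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.U.shape[0]


@dataclass
class TaylorApprox:
    """Order-K truncation of the square-root series of the Laplacian."""

    K: int
    coeffs: np.ndarray          # c_1 .. c_K
    sqrtL_approx: np.ndarray    # I - sum_{k<=K} c_k A^k
    d_K: float                  # Frobenius distance to the exact L^{1/2}


def fix_signs(V: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: flip each column so its
    largest-magnitude entry is positive (ties: lowest row index wins).
    """
    V = V.copy()
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def eigendecompose(ops: NormalizedOperators) -> SpectralBasis:
    """Full dense eigendecomposition of L, eigenvalues ascending."""
    if not np.all(np.isfinite(ops.L)):
        raise ValueError("Laplacian contains non-finite entries")
    lambdas, U = scipy.linalg.eigh(ops.L)
    return SpectralBasis(U=fix_signs(U), lambdas=lambdas)


def gft(basis: SpectralBasis, x: np.ndarray) -> np.ndarray:
    """Graph Fourier transform: x_hat = U^T x."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != basis.n_nodes:
        raise ValueError(f"signal length {x.shape[0]} != {basis.n_nodes} nodes")
    return basis.U.T @ x


def igft(basis: SpectralBasis, x_hat: np.ndarray) -> np.ndarray:
    """Inverse graph Fourier transform: x = U x_hat."""
    x_hat = np.asarray(x_hat, dtype=float)
    if x_hat.shape[0] != basis.n_nodes:
        raise ValueError(f"spectrum length {x_hat.shape[0]} != {basis.n_nodes}")
    return basis.U @ x_hat


def sqrt_laplacian_exact(basis: SpectralBasis) -> np.ndarray:
    """Exact L^{1/2} = U diag(sqrt(lambda)) U^T.

    Small negative eigenvalues (>= -1e-10, floating-point noise) are
    clamped to zero; anything below -1e-6 marks an invalid basis.
    """
    lam = basis.lambdas
    if np.any(lam < -1e-6):
        raise ValueError(f"negative eigenvalue {lam.min():.3e}: invalid basis")
    lam = np.clip(lam, 0.0, None)
    S = (basis.U * np.sqrt(lam)) @ basis.U.T
    return (S + S.T) / 2.0


def taylor_coefficient(k: int) -> float:
    """c_k of the square-root series, by multiplicative recurrence.

    c_1 = 1/2 and c_{k+1} = c_k (2k - 1) / (2k + 2); avoids factorial
    overflow for any practical k.
    """
    if k <= 0:
        raise ValueError("k must be >= 1")
    c = 0.5
    for i in range(1, k):
        c *= (2 * i - 1) / (2 * i + 2)
    return c


def taylor_coefficient_exact(k: int) -> Fraction:
    """Exact rational c_k = (2k)! / (2^{2k} (k!)^2 (2k-1)).

    Integer arithmetic; reference path used only for validation (k <= ~50).
    """
    if k <= 0:
        raise ValueError("k must be >= 1")
    import math

    return Fraction(math.factorial(2 * k),
                    2 ** (2 * k) * math.factorial(k) ** 2 * (2 * k - 1))


def taylor_coefficients(K: int) -> np.ndarray:
    """Vector (c_1, ..., c_K) via the recurrence."""
    if K <= 0:
        raise ValueError("K must be >= 1")
    c = np.empty(K)
    c[0] = 0.5
    for i in range(1, K):
        c[i] = c[i - 1] * (2 * i - 1) / (2 * i + 2)
    return c


def sqrt_laplacian_taylor(ops: NormalizedOperators, K: int) -> TaylorApprox:
    """Order-K Taylor approximation of L^{1/2} and its Frobenius error.

    Returns the matrix ``I - sum_{k=1}^K c_k A^k``, the coefficients, and
    d_K = ||L^{1/2}_exact - approx||_F.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > 10_000:
        raise ValueError("K > 10000: refusing (series gains nothing there)")
    coeffs = taylor_coefficients(K)
    n = ops.n_nodes
    approx = np.eye(n)
    Ak = np.eye(n)
    for k in range(K):
        Ak = Ak @ ops.A
        approx -= coeffs[k] * Ak
    exact = sqrt_laplacian_exact(eigendecompose(ops))
    d_K = float(np.linalg.norm(exact - approx, "fro"))
    return TaylorApprox(K=K, coeffs=coeffs, sqrtL_approx=approx, d_K=d_K)


def _sqrt_deriv_abs(order: int, x: float) -> float:
    """|f^{(order)}(x)| for f = sqrt, x > 0."""
    # f^(m)(x) = (1/2)(1/2-1)...(1/2-m+1) x^{1/2-m}
    coef = 1.0
    for j in range(order):
        coef *= 0.5 - j
    return abs(coef) * x ** (0.5 - order)


def lagrange_remainder_bound(lam: float, K: int) -> float:
    """Conservative Lagrange remainder bound |R_K(lambda)| for sqrt at 1.

    R_K(x) = f^{(K+1)}(y) (x-1)^{K+1} / (K+1)! for some y between x and 1;
    we bound by the supremum of |f^{(K+1)}| over [min(x,1), max(x,1)].
    The derivative magnitude is decreasing in its argument, so the sup sits
    at the left endpoint; it diverges as lambda -> 0, giving an infinite
    (but still valid) bound at the zero eigenvalue of a connected graph.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    lo = min(lam, 1.0)
    if lo <= 0.0:
        return np.inf
    import math

    sup = _sqrt_deriv_abs(K + 1, lo)
    return sup / math.factorial(K + 1) * abs(lam - 1.0) ** (K + 1)
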