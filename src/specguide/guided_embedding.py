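"""Guided spectral embedding via the criterion zeta = mu - xi.

The guiding idea: maximize energy concentration (mu) on an importance-
weighted node set while minimizing the modified embedded distance (xi,
a localized graph frequency), jointly and at full bandwidth.  The two
goals oppose each other, so the joint criterion

    zeta(g) = (g^T M g - g^T L^{1/2} M L^{1/2} g) / g^T g

is a stable eigenvalue problem of the symmetric criterion matrix
``M - L^{1/2} M L^{1/2}``.  M is a diagonal cooperation matrix with
nonnegative node weights (1 = unmodified importance, 0 = maximally
de-emphasized; binary M recovers classical subset selection).  For
M = I the criterion matrix collapses to the normalized adjacency A, so
the unguided embedding is the adjacency eigenvector embedding.

Taylor-expanding L^{1/2} in powers of A gives interpretable
approximations: the linear criterion (MA + AM)/2 reweights each edge by
the mean cooperation weight of its endpoints; the quadratic one adds
length-2-path terms (MA^2 + A^2M)/8 - AMA/4, rewarding paths between
important endpoints and penalizing passage through unimportant nodes.

Eigenvalues are sorted descending; the paper-of-record bound
m_max >= zeta_1 >= ... >= zeta_N >= -2 m_max follows from the Laplacian
spectrum living in [0, 2].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .graph_core import Graph, NormalizedOperators, normalize, validate_connectivity
from .spectral_ops import (
    eigendecompose,
    fix_signs,
    sqrt_laplacian_exact,
    sqrt_laplacian_taylor,
)

__all__ = [
    "CooperationProfile",
    "GuidedSpectrum",
    "Trajectory",
    "criterion_matrix_exact",
    "criterion_matrix_linear",
    "criterion_matrix_quadratic",
    "criterion_matrix_orderK",
    "guided_spectrum",
    "embed",
    "procrustes_align",
    "focus_sweep",
    "cluster_endpoint",
]

_BOUND_TOL = 1e-6


@dataclass
class CooperationProfile:
    """Diagonal cooperation matrix M of nonnegative node weights."""

    m: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if np.any(self.m < 0):
            raise ValueError("cooperation weights must be nonnegative")

    @property
    def m_max(self) -> float:
        return float(self.m.max())

    @property
    def is_binary(self) -> bool:
        return bool(np.all(np.isin(self.m, (0.0, 1.0))))

    @classmethod
    def identity(cls, n: int) -> "CooperationProfile":
        return cls(np.ones(n))

    @classmethod
    def focus(cls, n: int, focus_idx: np.ndarray, t: float) -> "CooperationProfile":
        """Weight 1 on the focus set, t everywhere else."""
        m = np.full(n, float(t))
        m[np.asarray(focus_idx)] = 1.0
        return cls(m)


@dataclass
class GuidedSpectrum:
    """Eigenpairs of a (possibly approximated) guided criterion matrix.

    ``mu_equiv`` and ``xi_equiv`` are the concentration and embedded-
    distance Rayleigh quotients of each eigenvector, always measured
    against the exact M and exact L^{1/2} M L^{1/2} so that approximation
    orders are compared in one fixed frame.
    """

    zetas: np.ndarray
    vectors: np.ndarray
    mu_equiv: np.ndarray
    xi_equiv: np.ndarray
    approx_order: str  # "exact", "linear", "quadratic", or "K=<int>"

    @property
    def n_nodes(self) -> int:
        return self.vectors.shape[0]


@dataclass
class Trajectory:
    """Per-node 2-D coordinates across a focus sweep, Procrustes-aligned."""

    steps: np.ndarray                  # focus strengths t, from 1 to 0
    coords: np.ndarray                 # (n_steps, N, 2) aligned positions
    focus_idx: np.ndarray              # indices of nodes held at weight 1
    node_ids: list[str]
    node_class: list[str] | None = None
    transforms: list[np.ndarray] = field(default_factory=list)

    @property
    def endpoint(self) -> np.ndarray:
        return self.coords[-1]

    def to_frame(self):
        """Long-format table (step, t, node_id, class, x, y)."""
        import pandas as pd

        n_steps, n, _ = self.coords.shape
        recs = []
        for si in range(n_steps):
            for ni in range(n):
                recs.append(
                    {
                        "step": si,
                        "t": self.steps[si],
                        "node_id": self.node_ids[ni],
                        "class": self.node_class[ni] if self.node_class else "",
                        "x": self.coords[si, ni, 0],
                        "y": self.coords[si, ni, 1],
                    }
                )
        return pd.DataFrame.from_records(recs)


def _check_coop(coop: CooperationProfile, n: int) -> np.ndarray:
    if coop.m.size != n:
        raise ValueError(f"cooperation length {coop.m.size} != {n} nodes")
    return coop.m


def criterion_matrix_exact(
    ops: NormalizedOperators, sqrtL: np.ndarray, coop: CooperationProfile
) -> np.ndarray:
    """Exact criterion matrix M - L^{1/2} M L^{1/2}."""
    m = _check_coop(coop, ops.n_nodes)
    C = np.diag(m) - (sqrtL * m) @ sqrtL
    return (C + C.T) / 2.0


def criterion_matrix_linear(
    ops: NormalizedOperators, coop: CooperationProfile
) -> np.ndarray:
    """Linear approximation (MA + AM)/2: edge (i,j) reweighted by (m_i+m_j)/2."""
    m = _check_coop(coop, ops.n_nodes)
    return ops.A * (m[:, None] + m[None, :]) / 2.0


def criterion_matrix_quadratic(
    ops: NormalizedOperators, coop: CooperationProfile
) -> np.ndarray:
    """Quadratic approximation: linear term + (MA^2 + A^2M)/8 - AMA/4.

    Length-2 paths i-l-j gain weight (m_i + m_j)/8 and lose m_l/4,
    penalizing passage through de-emphasized nodes.
    """
    m = _check_coop(coop, ops.n_nodes)
    A = ops.A
    A2 = A @ A
    quad = A2 * (m[:, None] + m[None, :]) / 8.0 - (A * m) @ A / 4.0
    return criterion_matrix_linear(ops, coop) + (quad + quad.T) / 2.0


def criterion_matrix_orderK(
    ops: NormalizedOperators, coop: CooperationProfile, K: int
) -> np.ndarray:
    """Order-K criterion M - Q_K M Q_K with Q_K the order-K Taylor L^{1/2}.

    Square-root-first truncation: consistent with the series expansion of
    the criterion up to total order K, differing from a direct double-sum
    truncation only in cross terms of higher total order.
    """
    m = _check_coop(coop, ops.n_nodes)
    Q = sqrt_laplacian_taylor(ops, K).sqrtL_approx
    C = np.diag(m) - (Q * m) @ Q
    return (C + C.T) / 2.0


def guided_spectrum(
    criterion: np.ndarray,
    ops: NormalizedOperators,
    sqrtL: np.ndarray,
    coop: CooperationProfile,
    approx_order: str = "exact",
) -> GuidedSpectrum:
    """Eigendecompose a criterion matrix; eigenvalues descending.

    Each eigenvector's equivalent mu and xi are computed against the exact
    M and L^{1/2} M L^{1/2}.  The spectral bound m_max >= zeta_1 and
    zeta_N >= -2 m_max is asserted (violation beyond 1e-6 means the input
    was not a valid criterion matrix).
    """
    m = _check_coop(coop, ops.n_nodes)
    if np.max(np.abs(criterion - criterion.T)) > 1e-10:
        raise ValueError("criterion matrix is not symmetric")
    zetas, G = scipy.linalg.eigh(criterion)
    order = np.argsort(zetas)[::-1]
    zetas, G = zetas[order], fix_signs(G[:, order])
    if zetas.size and (
        zetas[0] > coop.m_max + _BOUND_TOL or zetas[-1] < -2 * coop.m_max - _BOUND_TOL
    ):
        raise ValueError(
            f"eigenvalue bound violated: zeta_1={zetas[0]:.6g}, "
            f"zeta_N={zetas[-1]:.6g}, m_max={coop.m_max:.6g}"
        )
    mu_equiv = np.einsum("ik,i,ik->k", G, m, G)
    H = sqrtL @ G
    xi_equiv = np.einsum("ik,i,ik->k", H, m, H)
    return GuidedSpectrum(
        zetas=zetas, vectors=G, mu_equiv=mu_equiv, xi_equiv=xi_equiv,
        approx_order=approx_order,
    )


def embed(
    spec: GuidedSpectrum, component_indices: tuple[int, int] = (2, 3)
) -> np.ndarray:
    """Project nodes on two chosen eigenvectors (1-based, descending zeta).

    The default (2, 3) mirrors the Laplacian-embedding convention of using
    the second and third eigenvectors; for the guided spectrum these are
    the second and third *largest*.  A degenerate requested pair (equal
    eigenvalues) is flagged with a warning since the plane is then only
    defined up to rotation within the eigenspace.
    """
    i, j = component_indices
    n = spec.zetas.size
    if not (1 <= i <= n and 1 <= j <= n) or i == j:
        raise ValueError(f"invalid component indices {component_indices}")
    if abs(spec.zetas[i - 1] - spec.zetas[j - 1]) < 1e-10:
        warnings.warn(
            f"requested eigenvalues {i},{j} are degenerate; embedding plane "
            "is arbitrary within the eigenspace",
            stacklevel=2,
        )
    return spec.vectors[:, [i - 1, j - 1]].copy()


def procrustes_align(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal Procrustes: rotate/reflect X onto reference Y.

    Returns (X @ R, R) with R = argmin ||X R - Y||_F over orthogonal R,
    obtained from the SVD of X^T Y.  No centering or scaling: the origin
    of an eigenvector embedding is meaningful and norms carry energy
    information.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch {X.shape} vs {Y.shape}")
    M = X.T @ Y
    if np.allclose(M, 0):
        warnings.warn("rank-0 cross-covariance; returning identity transform",
                      stacklevel=2)
        return X.copy(), np.eye(X.shape[1])
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    return X @ R, R


def _criterion_for(
    ops: NormalizedOperators,
    sqrtL: np.ndarray,
    coop: CooperationProfile,
    approx: str | int,
) -> tuple[np.ndarray, str]:
    if approx == "exact":
        return criterion_matrix_exact(ops, sqrtL, coop), "exact"
    if approx == "linear":
        return criterion_matrix_linear(ops, coop), "linear"
    if approx == "quadratic":
        return criterion_matrix_quadratic(ops, coop), "quadratic"
    K = int(approx)
    return criterion_matrix_orderK(ops, coop, K), f"K={K}"


def focus_sweep(
    g: Graph,
    focus_set: np.ndarray,
    n_steps: int = 51,
    approx: str | int = "exact",
    component_indices: tuple[int, int] = (2, 3),
) -> Trajectory:
    """Sweep the off-focus cooperation weight t from 1 down to 0.

    At each of `n_steps` evenly spaced t values, the focus nodes keep
    weight 1 while all others get weight t; the guided spectrum is
    computed, nodes are embedded on `component_indices`, and each step is
    Procrustes-aligned to the previous aligned step (chained alignment;
    step 0, t = 1, is the unguided M = I reference frame).
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    focus_set = np.unique(np.asarray(focus_set, dtype=int))
    n = g.n_nodes
    if focus_set.size == 0:
        raise ValueError("focus set is empty")
    if np.any(focus_set < 0) or np.any(focus_set >= n):
        raise ValueError("focus index out of range")
    if not validate_connectivity(g)[0]:
        raise ValueError("graph must be connected for a focus sweep")

    ops = normalize(g)
    basis = eigendecompose(ops)
    sqrtL = sqrt_laplacian_exact(basis)
    ts = np.linspace(1.0, 0.0, n_steps)

    coords = np.empty((n_steps, n, 2))
    transforms: list[np.ndarray] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate-pair warnings per step
        for si, t in enumerate(ts):
            coop = CooperationProfile.focus(n, focus_set, t)
            C, label = _criterion_for(ops, sqrtL, coop, approx)
            spec = guided_spectrum(C, ops, sqrtL, coop, approx_order=label)
            X = embed(spec, component_indices)
            if si == 0:
                coords[si] = X
                transforms.append(np.eye(2))
            else:
                aligned, R = procrustes_align(X, coords[si - 1])
                coords[si] = aligned
                transforms.append(R)
    return Trajectory(
        steps=ts,
        coords=coords,
        focus_idx=focus_set,
        node_ids=list(g.node_ids),
        node_class=list(g.node_class) if g.node_class else None,
        transforms=transforms,
    )


def cluster_endpoint(
    traj: Trajectory,
    k_range: range | list[int] = range(2, 11),
    seed: int = 0,
) -> tuple[np.ndarray, int, float]:
    """K-means on the focus nodes' endpoint coordinates.

    k is chosen by maximal mean silhouette over `k_range` (50 restarts per
    k, fixed seed).  Returns (labels for focus nodes, chosen k, silhouette).
    """
    ks = [k for k in k_range]
    if any(k < 2 for k in ks):
        raise ValueError("k must be >= 2 (silhouette undefined for k=1)")
    X = traj.endpoint[traj.focus_idx]
    if X.shape[0] <= max(ks):
        raise ValueError(
            f"{X.shape[0]} focus nodes cannot support k up to {max(ks)}"
        )
    best = None
    for k in ks:
        km = KMeans(n_clusters=k, n_init=50, random_state=seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(X, labels)
        if best is None or score > best[2]:
            best = (labels, k, score)
    if best is None:
        raise ValueError("no valid clustering found over k_range")
    return best
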