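"""Graph ingestion, validation, symmetric normalization, and synthetic fixtures.

The package operates on undirected, weighted graphs without self-loops.
All downstream spectral machinery consumes the symmetrically normalized
operators ``A = D^{-1/2} Ã D^{-1/2}`` and ``L = I - A``, whose eigenvalues
lie in [0, 2].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Graph",
    "NormalizedOperators",
    "load_graph",
    "save_mtx",
    "validate_connectivity",
    "normalize",
    "synth_fixture",
]

_SYMMETRY_TOL = 1e-12


@dataclass
class Graph:
    """A validated undirected weighted graph.

    Attributes
    ----------
    node_ids : list of str
        Unique node identifiers in first-appearance order; all vectors and
        matrix rows downstream follow this ordering.
    A_raw : ndarray of shape (N, N)
        Symmetric nonnegative weight matrix with zero diagonal.
    node_class : list of str or None
        Optional class label per node (e.g. sensory / inter / motor).
    """

    node_ids: list[str]
    A_raw: np.ndarray
    node_class: list[str] | None = None

    def __post_init__(self) -> None:
        self.A_raw = np.asarray(self.A_raw, dtype=float)
        _validate_adjacency(self.A_raw, self.node_ids)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def degrees(self) -> np.ndarray:
        """Weighted degree of each node, d_i = sum_j ã_ij."""
        return self.A_raw.sum(axis=1)

    @property
    def D(self) -> np.ndarray:
        """Diagonal degree matrix."""
        return np.diag(self.degrees)

    def binarized(self) -> "Graph":
        """Return a copy with every positive weight set to 1."""
        return Graph(
            node_ids=list(self.node_ids),
            A_raw=(self.A_raw > 0).astype(float),
            node_class=list(self.node_class) if self.node_class else None,
        )

    def drop_isolated(self) -> "Graph":
        """Return a copy with zero-degree nodes removed."""
        keep = np.flatnonzero(self.degrees > 0)
        return Graph(
            node_ids=[self.node_ids[i] for i in keep],
            A_raw=self.A_raw[np.ix_(keep, keep)],
            node_class=[self.node_class[i] for i in keep] if self.node_class else None,
        )

    def class_indices(self, label: str) -> np.ndarray:
        if self.node_class is None:
            raise ValueError("graph carries no node-class metadata")
        return np.flatnonzero(np.asarray(self.node_class) == label)


@dataclass
class NormalizedOperators:
    """Symmetrically normalized adjacency and Laplacian of a graph."""

    A: np.ndarray
    L: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]


def _validate_adjacency(A: np.ndarray, node_ids: Sequence[str]) -> None:
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if len(node_ids) != A.shape[0]:
        raise ValueError(
            f"{len(node_ids)} node ids for a {A.shape[0]}-node matrix"
        )
    if len(set(node_ids)) != len(node_ids):
        raise ValueError("duplicate node ids")
    if not np.all(np.isfinite(A)):
        raise ValueError("adjacency contains non-finite entries")
    if np.max(np.abs(A - A.T)) > _SYMMETRY_TOL:
        raise ValueError("adjacency is asymmetric beyond tolerance 1e-12")
    if np.any(np.diag(A) != 0):
        bad = np.flatnonzero(np.diag(A))[0]
        raise ValueError(f"self-loop on node {node_ids[bad]!r}")
    if np.any(A < 0):
        raise ValueError("negative edge weight")


def _read_edge_list(path: Path) -> tuple[list[str], np.ndarray]:
    rows: list[tuple[str, str, float]] = []
    first_data_line = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) == 2:
                src, dst, w = parts[0], parts[1], 1.0
            elif len(parts) >= 3:
                src, dst = parts[0], parts[1]
                try:
                    w = float(parts[2])
                except ValueError:
                    if first_data_line:  # optional header line
                        continue
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric weight {parts[2]!r}"
                    ) from None
            else:
                raise ValueError(f"{path}:{lineno}: cannot parse edge line {line!r}")
            first_data_line = False
            rows.append((src, dst, w))
    if not rows:
        raise ValueError(f"{path}: no edges found")

    node_ids: list[str] = []
    index: dict[str, int] = {}
    for src, dst, _ in rows:
        for nid in (src, dst):
            if nid not in index:
                index[nid] = len(node_ids)
                node_ids.append(nid)
    n = len(node_ids)
    A = np.zeros((n, n))
    seen: set[tuple[int, int]] = set()
    for src, dst, w in rows:
        i, j = index[src], index[dst]
        if i == j:
            raise ValueError(f"self-loop on node {src!r}")
        key = (min(i, j), max(i, j))
        if key in seen:
            raise ValueError(f"duplicate edge {src!r}-{dst!r}")
        seen.add(key)
        A[i, j] = A[j, i] = w
    return node_ids, A


def _read_dense_csv(path: Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, header=None)
    first_cell = str(df.iloc[0, 0])
    has_labels = False
    try:
        float(first_cell)
    except ValueError:
        has_labels = True
    if has_labels:
        df = pd.read_csv(path, index_col=0)
        node_ids = [str(c) for c in df.columns]
        A = df.to_numpy(dtype=float)
    else:
        A = df.to_numpy(dtype=float)
        node_ids = [str(i + 1) for i in range(A.shape[0])]
    return node_ids, A


def _read_mtx(path: Path) -> tuple[list[str], np.ndarray]:
    M = scipy.io.mmread(str(path))
    A = np.asarray(M.todense() if sp.issparse(M) else M, dtype=float)
    node_ids = [str(i + 1) for i in range(A.shape[0])]
    return node_ids, A


def load_graph(
    path: str | Path,
    format: str = "edge_list",
    metadata_path: str | Path | None = None,
    binarize: bool = False,
    drop_isolated: bool = False,
) -> Graph:
    """Load an undirected weighted graph from disk.

    Parameters
    ----------
    path : path to the graph file.
    format : one of ``edge_list``, ``dense_csv``, ``mtx``.
    metadata_path : optional TSV with columns ``node_id  class  label``.
    binarize : replace every positive weight by 1 (combined structural
        matrices, e.g. chemical synapses OR gap junctions).
    drop_isolated : remove zero-degree nodes instead of rejecting them.

    Returns
    -------
    Graph with nodes in first-appearance order of the input file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    readers = {
        "edge_list": _read_edge_list,
        "edgelist": _read_edge_list,
        "dense_csv": _read_dense_csv,
        "csv": _read_dense_csv,
        "mtx": _read_mtx,
    }
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(readers)}")
    node_ids, A = readers[format](path)

    node_class = None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
        if "node_id" not in meta.columns or "class" not in meta.columns:
            raise ValueError("metadata must have columns 'node_id' and 'class'")
        mapping = dict(zip(meta["node_id"], meta["class"]))
        missing = [nid for nid in node_ids if nid not in mapping]
        if missing:
            raise ValueError(f"metadata missing ids: {missing[:5]}")
        extra = set(mapping) - set(node_ids)
        if extra:
            raise ValueError(f"metadata ids not in graph: {sorted(extra)[:5]}")
        node_class = [mapping[nid] for nid in node_ids]

    if binarize:
        A = (A > 0).astype(float)
    g = Graph(node_ids=node_ids, A_raw=A, node_class=node_class)
    if drop_isolated:
        g = g.drop_isolated()
    else:
        zero = np.flatnonzero(g.degrees == 0)
        if zero.size:
            raise ValueError(
                f"zero-degree node(s): {[g.node_ids[i] for i in zero[:5]]}; "
                "use drop_isolated=True to remove them"
            )
    return g


def save_mtx(g: Graph, path: str | Path) -> None:
    """Write the raw adjacency in Matrix Market coordinate format."""
    scipy.io.mmwrite(str(path), sp.coo_matrix(g.A_raw), symmetry="symmetric")


def validate_connectivity(g: Graph) -> tuple[bool, np.ndarray]:
    """Check connectedness; returns (is_connected, component labels)."""
    n_comp, labels = connected_components(
        sp.csr_matrix(g.A_raw), directed=False
    )
    return n_comp == 1, labels


def normalize(g: Graph) -> NormalizedOperators:
    """Symmetric normalization A = D^{-1/2} Ã D^{-1/2}, L = I - A.

    Raises
    ------
    ValueError if any node has zero degree (normalization undefined).
    """
    d = g.degrees
    zero = np.flatnonzero(d == 0)
    if zero.size:
        raise ValueError(f"zero-degree node {g.node_ids[zero[0]]!r}")
    inv_sqrt_d = 1.0 / np.sqrt(d)
    A = g.A_raw * np.outer(inv_sqrt_d, inv_sqrt_d)
    A = (A + A.T) / 2.0  # kill rounding asymmetry
    L = np.eye(g.n_nodes) - A
    return NormalizedOperators(A=A, L=L)


def synth_fixture(
    n_per_class: tuple[int, int, int] = (50, 50, 50),
    p_within: float = 0.3,
    p_between: float = 0.05,
    seed: int = 0,
    max_retries: int = 100,
) -> Graph:
    """Three-class planted-partition graph, a stand-in for a small connectome.

    Nodes fall into classes ``A``, ``B``, ``C``; edges are Bernoulli with
    probability `p_within` inside a class and `p_between` across classes.
    Regenerates (up to `max_retries`) until the graph is connected.
    Deterministic for fixed seed and parameters.
    """
    if len(n_per_class) != 3 or any(n < 1 for n in n_per_class):
        raise ValueError("n_per_class must be three integers >= 1")
    for p in (p_within, p_between):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = sum(n_per_class)
    classes = np.repeat(["A", "B", "C"], n_per_class)
    same = classes[:, None] == classes[None, :]
    p_mat = np.where(same, p_within, p_between)
    for _ in range(max_retries):
        upper = np.triu(rng.random((n, n)) < p_mat, k=1)
        A = (upper | upper.T).astype(float)
        g = Graph(
            node_ids=[f"n{i}" for i in range(n)],
            A_raw=A,
            node_class=list(classes),
        )
        if np.all(g.degrees > 0) and validate_connectivity(g)[0]:
            return g
    raise RuntimeError(
        f"could not generate a connected graph in {max_retries} tries; "
        "increase p_within/p_between"
    )


def ring_with_chords(n: int, n_chords: int, seed: int = 0) -> Graph:
    """Connected ring lattice with `n_chords` random chord edges.

    Handy as a deterministic connected test graph of arbitrary size.
    """
    rng = np.random.default_rng(seed)
    A = np.zeros((n, n))
    idx = np.arange(n)
    A[idx, (idx + 1) % n] = 1.0
    A[(idx + 1) % n, idx] = 1.0
    added = 0
    guard = 0
    while added < n_chords and guard < 100 * n_chords + 1000:
        guard += 1
        i, j = rng.integers(0, n, size=2)
        if i == j or A[i, j]:
            continue
        A[i, j] = A[j, i] = 1.0
        added += 1
    if added < n_chords:
        warnings.warn(f"placed only {added}/{n_chords} chords")
    return Graph(node_ids=[str(i + 1) for i in range(n)], A_raw=A)
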