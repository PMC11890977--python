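"""Binary graph-topology battery with degree-preserving nulls.

Global measures: global efficiency (Eglob), local efficiency (Eloc),
clustering coefficient (Cp), characteristic path length (Lp) and
small-worldness Sigma = (Cp/<Cp_null>)/(Lp/<Lp_null>) against a
Maslov-Sneppen degree-preserving null ensemble.  Nodal measures: degree,
normalized betweenness, nodal efficiency (NEglob), nodal local efficiency
(NEloc), nodal clustering (NCp) and nodal shortest path length (NLp).

Definitions follow the standard binary-undirected conventions
(Rubinov & Sporns, NeuroImage 2010).  On disconnected graphs Lp and NLp
average over finite pairs only and an explicit flag is set rather than
returning infinity: this keeps the low-sparsity end of a functional sweep
computable while surfacing the disconnection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .datatypes import AnalysisConfig, ConnectivityMatrix
from .networks import SparsityGrid, sparsity_threshold

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "NullEnsembleParams",
    "all_shortest_path_lengths",
    "global_metrics",
    "nodal_metrics",
    "maslov_sneppen_rewire",
    "metrics_over_sparsity",
    "auc_curve",
    "GLOBAL_METRIC_NAMES",
    "NODAL_METRIC_NAMES",
]

GLOBAL_METRIC_NAMES = ("Eglob", "Eloc", "Cp", "Lp", "Sigma")
NODAL_METRIC_NAMES = ("degree", "betweenness", "NEglob", "NEloc", "NCp", "NLp")


@dataclass(frozen=True)
class GlobalMetrics:
    Eglob: float
    Eloc: float
    Cp: float
    Lp: float
    Sigma: float
    disconnected: bool

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in GLOBAL_METRIC_NAMES}


@dataclass(frozen=True)
class NodalMetrics:
    degree: np.ndarray
    betweenness: np.ndarray
    betweenness_raw: np.ndarray
    NEglob: np.ndarray
    NEloc: np.ndarray
    NCp: np.ndarray
    NLp: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in NODAL_METRIC_NAMES}


@dataclass(frozen=True)
class NullEnsembleParams:
    """Degree-preserving null ensemble for small-worldness."""

    n_nulls: int = 100
    swaps_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nulls < 1 or self.swaps_per_edge < 1:
            raise ValueError("n_nulls and swaps_per_edge must both be >= 1")


def _as_adjacency(graph: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    a = graph.values if isinstance(graph, ConnectivityMatrix) else np.asarray(graph, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.isin(a, (0.0, 1.0)).all():
        raise ValueError("adjacency must be binary")
    if np.max(np.abs(a - a.T)) > 0:
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diagonal(a) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    return a


def all_shortest_path_lengths(graph: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Exact BFS shortest-path distances; inf for unreachable pairs."""
    a = _as_adjacency(graph)
    if a.shape[0] == 0:
        return np.zeros((0, 0))
    return _csgraph_shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)


def _efficiency_from_distances(d: np.ndarray) -> float:
    """Mean inverse distance over ordered pairs (1/inf = 0)."""
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _clustering_vector(a: np.ndarray) -> np.ndarray:
    """Per-node clustering C_i = (edges among neighbors) / (k_i choose 2)."""
    k = a.sum(axis=1)
    triangles = np.diagonal(a @ a @ a) / 2.0  # edges among neighbors of i
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c


def _nodal_local_efficiency(a: np.ndarray) -> np.ndarray:
    """Global efficiency of each node's neighbor-induced subgraph (0 if k<2)."""
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        out[i] = _efficiency_from_distances(
            _csgraph_shortest_path(csr_matrix(sub), method="D", unweighted=True, directed=False)
        )
    return out


def global_metrics(
    graph: ConnectivityMatrix | np.ndarray,
    nulls: NullEnsembleParams | None = None,
    null_graphs: list[np.ndarray] | None = None,
    cp_zero_mode: str = "include",
) -> GlobalMetrics:
    """Compute the global metric battery on a binary undirected graph.

    Sigma requires a null ensemble: pass ``nulls`` to generate one here, or
    ``null_graphs`` to reuse a precomputed ensemble.  With neither, Sigma is
    NaN.  Graphs with fewer than 3 nodes are rejected as degenerate.
    """
    a = _as_adjacency(graph)
    n = a.shape[0]
    if n < 3:
        raise ValueError(f"global metrics are degenerate below 3 nodes (got {n})")
    d = all_shortest_path_lengths(a)
    eglob = _efficiency_from_distances(d)
    c = _clustering_vector(a)
    if cp_zero_mode == "exclude":
        k = a.sum(axis=1)
        cp = float(c[k >= 2].mean()) if np.any(k >= 2) else 0.0
    else:
        cp = float(c.mean())
    eloc = float(_nodal_local_efficiency(a).mean())
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d[off])
    disconnected = not finite.all()
    lp = float(d[off][finite].mean()) if finite.any() else np.nan
    sigma = np.nan
    if null_graphs is None and nulls is not None:
        null_graphs = maslov_sneppen_rewire(a, nulls)
    if null_graphs:
        cp_nulls, lp_nulls = [], []
        for na in null_graphs:
            cp_nulls.append(float(_clustering_vector(na).mean()))
            nd = all_shortest_path_lengths(na)
            nfin = np.isfinite(nd[off])
            lp_nulls.append(float(nd[off][nfin].mean()) if nfin.any() else np.nan)
        cp_null = float(np.mean(cp_nulls))
        lp_null = float(np.nanmean(lp_nulls))
        if cp_null > 0 and np.isfinite(lp) and np.isfinite(lp_null) and lp_null > 0 and lp > 0:
            sigma = (cp / cp_null) / (lp / lp_null)
    return GlobalMetrics(Eglob=eglob, Eloc=eloc, Cp=cp, Lp=lp, Sigma=sigma, disconnected=disconnected)


def nodal_metrics(graph: ConnectivityMatrix | np.ndarray) -> NodalMetrics:
    """Compute the nodal metric battery on a binary undirected graph."""
    a = _as_adjacency(graph)
    n = a.shape[0]
    d = all_shortest_path_lengths(a)
    degree = a.sum(axis=1).astype(int)
    g = nx.from_numpy_array(a)
    bc_norm = np.array([v for _, v in sorted(nx.betweenness_centrality(g, normalized=True).items())])
    bc_raw = np.array([v for _, v in sorted(nx.betweenness_centrality(g, normalized=False).items())])
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    neglob = inv.sum(axis=1) / max(n - 1, 1)
    neloc = _nodal_local_efficiency(a)
    ncp = _clustering_vector(a)
    nlp = np.full(n, np.nan)
    for i in range(n):
        row = np.delete(d[i], i)
        finite = np.isfinite(row)
        if finite.any():
            nlp[i] = row[finite].mean()
    return NodalMetrics(
        degree=degree, betweenness=bc_norm, betweenness_raw=bc_raw,
        NEglob=neglob, NEloc=neloc, NCp=ncp, NLp=nlp,
    )


def maslov_sneppen_rewire(
    graph: ConnectivityMatrix | np.ndarray, params: NullEnsembleParams
) -> list[np.ndarray]:
    """Degree-preserving random rewiring (double-edge swaps).

    Each null attempts ``swaps_per_edge * E`` double-edge swaps, rejecting
    any swap that would create a self-loop or a multi-edge.  The degree
    sequence of every null is asserted equal to the input's.  If no swap
    succeeds for any null (e.g. a complete graph has no legal swap), copies
    are returned with a warning.
    """
    a = _as_adjacency(graph)
    iu, ju = np.triu_indices(a.shape[0], k=1)
    edges0 = [(int(i), int(j)) for i, j in zip(iu, ju) if a[i, j] > 0]
    n_edges = len(edges0)
    if n_edges < 2:
        raise ValueError("rewiring needs a graph with at least 2 edges")
    rng = np.random.default_rng(params.seed)
    degree0 = a.sum(axis=1)
    nulls: list[np.ndarray] = []
    any_swapped = False
    attempts = params.swaps_per_edge * n_edges
    for _ in range(params.n_nulls):
        adj = a.copy()
        edges = list(edges0)
        pair_idx = rng.integers(0, n_edges, size=(attempts, 2))
        flips = rng.integers(0, 2, size=attempts)
        for (e1, e2), flip in zip(pair_idx, flips):
            if e1 == e2:
                continue
            u, v = edges[e1]
            x, y = edges[e2]
            if flip:
                x, y = y, x
            # Proposed swap: (u,v),(x,y) -> (u,x),(v,y)
            if u == x or u == y or v == x or v == y:
                continue
            if adj[u, x] or adj[v, y]:
                continue
            adj[u, v] = adj[v, u] = 0
            adj[x, y] = adj[y, x] = 0
            adj[u, x] = adj[x, u] = 1
            adj[v, y] = adj[y, v] = 1
            edges[e1] = (u, x)
            edges[e2] = (v, y)
            any_swapped = True
        if not np.array_equal(adj.sum(axis=1), degree0):
            raise AssertionError("null graph degree sequence differs from input")
        nulls.append(adj)
    if not any_swapped:
        warnings.warn("no legal double-edge swap found; null ensemble equals the input graph", stacklevel=2)
    return nulls


@dataclass
class SparsityLevelMetrics:
    """Metric battery at one sparsity level of a functional sweep."""

    sparsity: float
    global_metrics: GlobalMetrics
    nodal_metrics: NodalMetrics
    shortfall: bool


def metrics_over_sparsity(
    z_matrix: ConnectivityMatrix,
    grid: SparsityGrid,
    nulls: NullEnsembleParams | None = None,
) -> list[SparsityLevelMetrics]:
    """Threshold a weighted matrix over the sparsity grid and compute the
    full battery at each level.

    Disconnected levels carry flags (``disconnected``, NaN Lp contributions
    handled by finite-pair averaging), never silent omissions.  Null seeds
    are derived per level so the sweep is reproducible level-by-level.
    """
    out: list[SparsityLevelMetrics] = []
    for idx, s in enumerate(grid):
        binary, shortfall = sparsity_threshold(z_matrix, s)
        level_nulls = None
        if nulls is not None:
            level_nulls = NullEnsembleParams(
                n_nulls=nulls.n_nulls,
                swaps_per_edge=nulls.swaps_per_edge,
                seed=int((nulls.seed * 1000003 + idx) % (2**31 - 1)),
            )
        gm = global_metrics(binary, nulls=level_nulls)
        nm = nodal_metrics(binary)
        out.append(SparsityLevelMetrics(sparsity=s, global_metrics=gm, nodal_metrics=nm, shortfall=shortfall))
    return out


def auc_curve(values: np.ndarray, grid: SparsityGrid) -> float:
    """Trapezoidal area under a metric curve over the sparsity grid domain."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(grid):
        raise ValueError(f"{values.shape[0]} values for a grid of {len(grid)} levels")
    if len(grid) < 2:
        raise ValueError("AUC over a single-level grid has zero-width domain")
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        levels = [grid.values[i] for i in bad]
        raise ValueError(f"undefined metric values at sparsity level(s) {levels}")
    return float(np.trapezoid(values, grid.as_array))
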