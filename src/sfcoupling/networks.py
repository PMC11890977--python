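"""Network construction: structural binarization, consistency masking,
functional correlation matrices and sparsity thresholding.

Structural networks are built once at a single streamline-count threshold
followed by a group-consistency mask; functional networks are Pearson
correlation matrices, Fisher z-transformed, then binarized over a sparsity
grid.  Negative and zero weights never become functional edges: the
small-world battery presumes meaningful binary edges, and discarding
negative correlations is the dominant convention for sparsity-thresholded
binary FC networks (config-exposed upstream).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datatypes import ConnectivityMatrix, Modality

__all__ = [
    "SparsityGrid",
    "GroupMask",
    "binarize_sc",
    "group_consistency_mask",
    "apply_mask",
    "pearson_fc",
    "fisher_z",
    "sparsity_threshold",
]


@dataclass(frozen=True)
class SparsityGrid:
    """A uniform grid of sparsity levels in (0, 1).

    The default grid is 0.01 to 0.40 in steps of 0.01 (40 levels).
    """

    values: tuple[float, ...]
    step: float

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.size == 0:
            raise ValueError("sparsity grid is empty")
        if np.any(vals <= 0) or np.any(vals >= 1):
            raise ValueError("sparsity levels must lie in (0, 1)")
        diffs = np.diff(vals)
        if vals.size > 1:
            if np.any(diffs <= 0):
                raise ValueError("sparsity levels must be strictly increasing")
            if np.max(np.abs(diffs - self.step)) > 1e-12:
                raise ValueError("sparsity levels must be uniformly spaced by `step`")

    @classmethod
    def from_range(cls, lo: float = 0.01, hi: float = 0.40, step: float = 0.01) -> "SparsityGrid":
        n = int(round((hi - lo) / step)) + 1
        values = tuple(round(lo + i * step, 12) for i in range(n))
        return cls(values=values, step=step)

    @classmethod
    def default(cls) -> "SparsityGrid":
        return cls.from_range()

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    @property
    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class GroupMask:
    """Binary edge-retention mask with per-edge consistency proportions."""

    mask: np.ndarray
    consistency: np.ndarray
    proportion: float

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=float)
        if np.max(np.abs(mask - mask.T)) > 0:
            raise ValueError("group mask must be symmetric")
        if np.any(np.diagonal(mask) != 0):
            raise ValueError("group mask must have a zero diagonal")
        object.__setattr__(self, "mask", mask)

    @property
    def n_edges(self) -> int:
        return int(self.mask.sum() // 2)


def binarize_sc(counts: ConnectivityMatrix, fiber_threshold: int = 3) -> ConnectivityMatrix:
    """Binarize a streamline-count matrix: edge present iff count >= threshold."""
    if counts.modality != Modality.STRUCTURAL_COUNT:
        raise ValueError(f"expected structural_count matrix, got {counts.modality}")
    if np.any(counts.values < 0):
        raise ValueError("negative streamline counts")
    binary = (counts.values >= fiber_threshold).astype(float)
    np.fill_diagonal(binary, 0.0)
    return ConnectivityMatrix(binary, counts.node_labels, Modality.STRUCTURAL_BINARY)


def group_consistency_mask(
    binaries: Sequence[ConnectivityMatrix], proportion: float = 0.8
) -> GroupMask:
    """Retain edges present in strictly more than ``proportion`` of subjects.

    The strict inequality reads "over 80%" literally: an edge present in
    exactly 80% of subjects is dropped at proportion 0.8.
    """
    if len(binaries) == 0:
        raise ValueError("group_consistency_mask needs at least one subject")
    labels = binaries[0].node_labels
    for b in binaries:
        if b.modality != Modality.STRUCTURAL_BINARY:
            raise ValueError(f"expected structural_binary matrices, got {b.modality}")
        if b.node_labels != labels:
            raise ValueError("all subjects must share node order")
    stack = np.stack([b.values for b in binaries])
    consistency = stack.mean(axis=0)
    mask = (consistency > proportion).astype(float)
    np.fill_diagonal(mask, 0.0)
    return GroupMask(mask=mask, consistency=consistency, proportion=proportion)


def apply_mask(matrix: ConnectivityMatrix, mask: GroupMask) -> ConnectivityMatrix:
    """Zero all edges not retained by the group mask."""
    return matrix.with_values(matrix.values * mask.mask)


def pearson_fc(series: np.ndarray, node_labels: Sequence[str] | None = None) -> ConnectivityMatrix:
    """Pearson correlation between regional BOLD time series.

    ``series`` is node-by-time.  Requires >= 3 timepoints and no constant
    rows (a constant row has undefined correlations).  Diagonal is zeroed.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be a node-by-time matrix")
    n_nodes, n_time = series.shape
    if n_time < 3:
        raise ValueError(f"need >= 3 timepoints, got {n_time}")
    sd = series.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(f"constant BOLD series at node(s) {constant.tolist()}: correlation undefined")
    r = np.corrcoef(series)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    labels = tuple(node_labels) if node_labels is not None else tuple(f"node_{i}" for i in range(n_nodes))
    return ConnectivityMatrix(r, labels, Modality.FUNCTIONAL_WEIGHTED)


# |r| at or beyond this bound is clipped before arctanh to keep z finite.
_FISHER_CLIP = 1.0 - 1e-7


def fisher_z(r_matrix: ConnectivityMatrix) -> tuple[ConnectivityMatrix, int]:
    """Entrywise Fisher z-transform (arctanh) of a correlation matrix.

    Returns the transformed matrix and the number of off-diagonal entries
    clipped to +/-(1 - 1e-7) before the transform.
    """
    r = r_matrix.values
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    # Diagonal is zero by invariant, so it never counts as clipped.
    n_clipped = int(np.count_nonzero(np.abs(r) >= _FISHER_CLIP) // 2)
    z = np.arctanh(np.clip(r, -_FISHER_CLIP, _FISHER_CLIP))
    np.fill_diagonal(z, 0.0)
    return r_matrix.with_values(z), n_clipped


def sparsity_threshold(
    weighted: ConnectivityMatrix, sparsity: float
) -> tuple[ConnectivityMatrix, bool]:
    """Binarize a weighted matrix at a sparsity level.

    Keeps the ``E = floor(sparsity * N(N-1)/2)`` largest strictly positive
    off-diagonal weights as edges.  Ties at the cutoff are broken by
    ascending (i, j) lexicographic order so the result is deterministic and
    edge sets nest across sparsity levels.  If fewer than E positive weights
    exist, all positive weights are kept and the shortfall flag is set.

    Returns ``(binary_matrix, shortfall)``.
    """
    if not (0 < sparsity < 1):
        raise ValueError(f"sparsity must lie in (0, 1), got {sparsity}")
    w = weighted.values
    n = w.shape[0]
    n_target = int(np.floor(sparsity * n * (n - 1) / 2))
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    positive = vals > 0
    # Sort by (-weight, i, j): descending weight, lexicographic tie-break.
    order = np.lexsort((ju, iu, -vals))
    order = order[positive[order]]
    shortfall = order.size < n_target
    keep = order[:n_target]
    binary = np.zeros_like(w)
    binary[iu[keep], ju[keep]] = 1.0
    binary += binary.T
    return ConnectivityMatrix(binary, weighted.node_labels, Modality.FUNCTIONAL_BINARY), shortfall
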