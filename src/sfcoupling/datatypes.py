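"""Core in-memory containers for cohort connectivity analysis.

The package works on three kinds of object: per-subject connectivity
matrices (:class:`ConnectivityMatrix`), subject metadata
(:class:`SubjectRecord`), and a :class:`Cohort` bundling both modalities for
every subject.  :class:`AnalysisConfig` carries every tunable analysis
constant so nothing is hard-coded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Modality",
    "ConnectivityMatrix",
    "SubjectRecord",
    "Cohort",
    "AnalysisConfig",
    "COGNITIVE_SCORES",
    "GROUPS",
    "SYMMETRY_TOL",
]

#: Cognitive scores tracked in a subject manifest.
COGNITIVE_SCORES = ("MMSE", "AVLT", "AVLT_N5", "SDMT", "STT_B", "BNT")

#: The two study groups: healthy controls and vascular cognitive impairment.
GROUPS = ("HC", "VCI")

#: Maximum tolerated asymmetry in any input connectivity matrix.
SYMMETRY_TOL = 1e-10


class Modality:
    """String constants naming the connectivity modalities."""

    STRUCTURAL_COUNT = "structural_count"
    STRUCTURAL_BINARY = "structural_binary"
    FUNCTIONAL_WEIGHTED = "functional_weighted"
    FUNCTIONAL_BINARY = "functional_binary"

    ALL = (STRUCTURAL_COUNT, STRUCTURAL_BINARY, FUNCTIONAL_WEIGHTED, FUNCTIONAL_BINARY)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """A square, symmetric, zero-diagonal node-by-node connectivity matrix.

    Parameters
    ----------
    values
        Square real matrix.  Symmetric within :data:`SYMMETRY_TOL`, zero
        diagonal.  ``structural_count`` entries must be non-negative
        integers; binary modalities must contain only 0 and 1.
    node_labels
        Ordered node labels; length must equal the matrix order.
    modality
        One of the :class:`Modality` constants.
    """

    values: np.ndarray
    node_labels: tuple[str, ...]
    modality: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got shape {values.shape}")
        n = values.shape[0]
        labels = tuple(self.node_labels)
        if len(labels) != n:
            raise ValueError(f"{len(labels)} node labels for a matrix of order {n}")
        asym = np.max(np.abs(values - values.T)) if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"matrix asymmetry {asym:.3e} exceeds tolerance {SYMMETRY_TOL:g}")
        values = (values + values.T) / 2.0
        if np.any(np.diagonal(values) != 0):
            raise ValueError("connectivity matrix must have a zero diagonal")
        if self.modality not in Modality.ALL:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == Modality.STRUCTURAL_COUNT:
            if np.any(values < 0) or np.any(values != np.round(values)):
                raise ValueError("structural_count entries must be non-negative integers")
        if self.modality in (Modality.STRUCTURAL_BINARY, Modality.FUNCTIONAL_BINARY):
            if not np.isin(values, (0.0, 1.0)).all():
                raise ValueError("binary matrix entries must be 0 or 1")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def with_values(self, values: np.ndarray, modality: str | None = None) -> "ConnectivityMatrix":
        return ConnectivityMatrix(values, self.node_labels, modality or self.modality)


@dataclass
class SubjectRecord:
    """One row of a cohort manifest.

    Missing cognitive scores are stored as NaN and never imputed; downstream
    analyses exclude them pairwise and report the exclusion.
    """

    subject_id: str
    group: str
    age: float
    sex: str
    education: float
    cognitive_scores: dict[str, float] = field(default_factory=dict)
    sc_source: str | None = None
    bold_source: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"subject {self.subject_id}: unknown group {self.group!r} (expected one of {GROUPS})")
        if self.sex not in ("male", "female"):
            raise ValueError(f"subject {self.subject_id}: sex must be 'male' or 'female', got {self.sex!r}")
        scores = {name: float(self.cognitive_scores.get(name, np.nan)) for name in COGNITIVE_SCORES}
        self.cognitive_scores = scores

    def score(self, name: str) -> float:
        return self.cognitive_scores[name]


@dataclass
class Cohort:
    """All subjects of a study plus their connectivity inputs.

    Invariants (checked by :func:`sfcoupling.io.validate_cohort`): every
    subject has both a structural count matrix and a BOLD series, all
    matrices share the atlas node order, and any group analysis needs at
    least two subjects per group.
    """

    subjects: list[SubjectRecord]
    sc_matrices: dict[str, ConnectivityMatrix]
    bold_series: dict[str, np.ndarray]
    atlas_labels: tuple[str, ...]

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def n_nodes(self) -> int:
        return len(self.atlas_labels)

    def by_group(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]


@dataclass
class AnalysisConfig:
    """Every analysis constant, with the study defaults.

    Attributes
    ----------
    fiber_threshold
        Minimum streamline count for a structural edge (edge present iff
        count >= threshold).  Default 3.
    group_consistency
        Structural edges are kept only when present in strictly more than
        this proportion of subjects.  Default 0.8.
    consistency_scope
        ``"all"`` pools every subject when computing the consistency mask;
        ``"per_group"`` builds one mask per group and intersects them.
    sparsity_grid
        (min, max, step) of the functional sparsity sweep.  Default
        (0.01, 0.40, 0.01), i.e. 40 levels.
    null_count, swaps_per_edge
        Degree-preserving null ensemble size and attempted swaps per edge
        for small-worldness.
    permutations
        Label permutations for max-statistic FWE correction.
    alpha
        Two-tailed significance level.
    fwe_method
        ``"permutation_maxT"`` or ``"bonferroni"``.
    coupling_sc_weighting
        SC profile used for coupling: ``"count"`` (default) or ``"binary"``.
    coupling_selection
        Profile entries entering the Spearman correlation: ``"sc_nonzero"``
        (default) or ``"both_nonzero"``.
    min_coupling_pairs
        Minimum profile pairs for a defined nodal coupling value.
    cp_zero_mode
        ``"include"`` averages C_i = 0 for degree-<2 nodes into Cp
        (default); ``"exclude"`` drops them from the mean.
    """

    fiber_threshold: int = 3
    group_consistency: float = 0.8
    consistency_scope: str = "all"
    sparsity_grid: tuple[float, float, float] = (0.01, 0.40, 0.01)
    null_count: int = 100
    swaps_per_edge: int = 10
    permutations: int = 1000
    alpha: float = 0.05
    fwe_method: str = "permutation_maxT"
    seed: int = 0
    coupling_sc_weighting: str = "count"
    coupling_selection: str = "sc_nonzero"
    min_coupling_pairs: int = 10
    cp_zero_mode: str = "include"

    def __post_init__(self) -> None:
        lo, hi, step = self.sparsity_grid
        if not (0 < lo <= hi < 1):
            raise ValueError(f"sparsity grid must satisfy 0 < min <= max < 1, got {self.sparsity_grid}")
        if step <= 0:
            raise ValueError("sparsity step must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.fiber_threshold < 1:
            raise ValueError("fiber_threshold must be >= 1")
        if not (0 <= self.group_consistency < 1):
            raise ValueError("group_consistency must lie in [0, 1)")
        if self.fwe_method not in ("permutation_maxT", "bonferroni"):
            raise ValueError(f"unknown fwe_method {self.fwe_method!r}")
        if self.consistency_scope not in ("all", "per_group"):
            raise ValueError(f"unknown consistency_scope {self.consistency_scope!r}")
        if self.coupling_sc_weighting not in ("count", "binary"):
            raise ValueError(f"unknown coupling_sc_weighting {self.coupling_sc_weighting!r}")
        if self.coupling_selection not in ("sc_nonzero", "both_nonzero"):
            raise ValueError(f"unknown coupling_selection {self.coupling_selection!r}")
        if self.cp_zero_mode not in ("include", "exclude"):
            raise ValueError(f"unknown cp_zero_mode {self.cp_zero_mode!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "AnalysisConfig":
        kwargs = dict(mapping)
        if "sparsity_grid" in kwargs:
            kwargs["sparsity_grid"] = tuple(float(v) for v in kwargs["sparsity_grid"])
        return cls(**kwargs)

    def to_mapping(self) -> dict:
        out = dict(self.__dict__)
        out["sparsity_grid"] = list(self.sparsity_grid)
        return out

    def replace(self, **changes) -> "AnalysisConfig":
        return replace(self, **changes)
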