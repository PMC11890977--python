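"""Nodal structure-function coupling.

A node's coupling is the Spearman rank correlation between its structural
connectivity profile (one column of the SC matrix, self-entry removed) and
its functional profile (same column of the weighted Fisher-z FC matrix),
restricted to entries where the structural profile is non-zero.  Per-node
values are averaged across the cohort.

The SC profile defaults to streamline counts: Spearman against an all-ones
binary profile is degenerate, so the binary mode is retained only for
sensitivity analysis.  The FC profile is taken from the weighted
(pre-threshold) z-matrix, since the coupling statistic references the
connectivity matrix, not the binarized graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnalysisConfig, Cohort, ConnectivityMatrix, Modality

__all__ = ["CouplingProfile", "node_coupling", "subject_coupling", "cohort_coupling"]


@dataclass
class CouplingProfile:
    """Per-node Spearman rho for one subject; NaN where undefined."""

    subject_id: str
    rho: np.ndarray
    n_pairs: np.ndarray

    def defined(self) -> np.ndarray:
        return np.isfinite(self.rho)


def node_coupling(
    sc_profile: np.ndarray,
    fc_profile: np.ndarray,
    min_pairs: int = 10,
    selection: str = "sc_nonzero",
) -> tuple[float, int]:
    """Spearman rho between one node's SC and FC profiles.

    Selects indices where the SC entry is non-zero (``selection="sc_nonzero"``,
    the default) or where both entries are non-zero (``"both_nonzero"``);
    average ranks resolve ties.  Returns ``(rho, n_pairs)`` with rho = NaN
    when fewer than ``min_pairs`` entries are selected or either selected
    vector is constant.
    """
    sc = np.asarray(sc_profile, dtype=float)
    fc = np.asarray(fc_profile, dtype=float)
    if sc.shape != fc.shape:
        raise ValueError(f"profile length mismatch: {sc.shape} vs {fc.shape}")
    if selection == "both_nonzero":
        idx = np.flatnonzero((sc != 0) & (fc != 0))
    else:
        idx = np.flatnonzero(sc != 0)
    n_pairs = int(idx.size)
    if n_pairs < max(min_pairs, 2):
        return np.nan, n_pairs
    x, y = sc[idx], fc[idx]
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, n_pairs
    rho = stats.spearmanr(x, y).statistic
    return float(rho), n_pairs


def subject_coupling(
    sc: ConnectivityMatrix,
    fc: ConnectivityMatrix,
    config: AnalysisConfig | None = None,
) -> CouplingProfile:
    """Per-node coupling profile for one subject.

    ``sc`` may be a count or binary structural matrix per
    ``config.coupling_sc_weighting``; ``fc`` is the weighted z-matrix.
    The diagonal (self-connection) is excluded from every profile.
    """
    config = config or AnalysisConfig()
    if sc.node_labels != fc.node_labels:
        raise ValueError("SC and FC node order differ")
    if fc.modality not in (Modality.FUNCTIONAL_WEIGHTED,):
        raise ValueError(f"FC matrix must be functional_weighted, got {fc.modality}")
    expected_sc = (
        Modality.STRUCTURAL_COUNT if config.coupling_sc_weighting == "count" else Modality.STRUCTURAL_BINARY
    )
    if sc.modality != expected_sc:
        raise ValueError(
            f"SC matrix modality {sc.modality} does not match coupling_sc_weighting="
            f"{config.coupling_sc_weighting!r} (expected {expected_sc})"
        )
    n = sc.n_nodes
    rho = np.full(n, np.nan)
    n_pairs = np.zeros(n, dtype=int)
    mask = ~np.eye(n, dtype=bool)
    for i in range(n):
        sc_prof = sc.values[i][mask[i]]
        fc_prof = fc.values[i][mask[i]]
        rho[i], n_pairs[i] = node_coupling(
            sc_prof, fc_prof, min_pairs=config.min_coupling_pairs, selection=config.coupling_selection
        )
    subject_id = getattr(sc, "subject_id", "")
    return CouplingProfile(subject_id=subject_id, rho=rho, n_pairs=n_pairs)


def cohort_coupling(
    profiles: list[CouplingProfile], node_labels: tuple[str, ...], groups: dict[str, str] | None = None
) -> pd.DataFrame:
    """Cohort summary of nodal coupling.

    Returns a per-node table with the mean rho over defined values, the
    count of contributing subjects, and (when ``groups`` maps subject_id to
    group label) per-group means and counts.  Nodes with zero defined
    subjects are flagged with ``defined=False``.
    """
    if not profiles:
        raise ValueError("no coupling profiles")
    rho = np.vstack([p.rho for p in profiles])
    n_nodes = rho.shape[1]
    if len(node_labels) != n_nodes:
        raise ValueError("node_labels length does not match profiles")
    finite = np.isfinite(rho)
    counts = finite.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_rho = np.where(finite, rho, 0.0).sum(axis=0) / np.where(counts > 0, counts, 1)
    out = pd.DataFrame(
        {
            "node": range(n_nodes),
            "label": node_labels,
            "mean_rho": np.where(counts > 0, mean_rho, np.nan),
            "n_subjects": counts,
            "defined": counts > 0,
        }
    )
    if groups is not None:
        for grp in sorted(set(groups.values())):
            sel = [i for i, p in enumerate(profiles) if groups.get(p.subject_id) == grp]
            sub = rho[sel]
            sub_finite = np.isfinite(sub)
            cnt = sub_finite.sum(axis=0)
            grp_mean = np.where(sub_finite, sub, 0.0).sum(axis=0) / np.where(cnt > 0, cnt, 1)
            out[f"mean_rho_{grp}"] = np.where(cnt > 0, grp_mean, np.nan)
            out[f"n_{grp}"] = cnt
    return out
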