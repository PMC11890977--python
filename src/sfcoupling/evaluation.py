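"""Recovery scoring and calibration simulations for the synthetic design.

These helpers run the package end-to-end on generated cohorts and score the
outcome against the stored ground truth: planted-node detection, empirical
family-wise error under the global null, and power as a function of the
planted coupling boost.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coupling import subject_coupling
from .datatypes import AnalysisConfig, Cohort
from .inference import ComparisonResult, compare_groups, fwe_correct, route_test
from .networks import fisher_z, pearson_fc
from .simulate import GroundTruth, SimulationParams, generate_cohort

__all__ = [
    "coupling_feature_table",
    "manifest_frame",
    "coupling_contrast",
    "score_recovery",
    "null_fwer",
    "boost_detection_rate",
]


def manifest_frame(cohort: Cohort) -> pd.DataFrame:
    """Subject covariate/group table indexed by subject_id."""
    return pd.DataFrame(
        [
            {"subject_id": s.subject_id, "group": s.group, "age": s.age, "sex": s.sex,
             "education": s.education, **s.cognitive_scores}
            for s in cohort.subjects
        ]
    ).set_index("subject_id")


def coupling_feature_table(cohort: Cohort, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-subject nodal coupling (rows: subjects, columns: node indices)."""
    config = config or AnalysisConfig(min_coupling_pairs=5)
    rows = {}
    for sid in cohort.subject_ids:
        sc = cohort.sc_matrices[sid]
        z, _ = fisher_z(pearson_fc(cohort.bold_series[sid], node_labels=sc.node_labels))
        rows[sid] = subject_coupling(sc, z, config).rho
    return pd.DataFrame(rows).T


def coupling_contrast(
    cohort: Cohort, config: AnalysisConfig | None = None, permutations: int = 500, seed: int = 0
) -> list[ComparisonResult]:
    """Covariate-adjusted VCI-vs-HC contrast of nodal coupling."""
    features = coupling_feature_table(cohort, config)
    features = features.loc[:, features.notna().all()]
    features.columns = [str(c) for c in features.columns]
    cfg = (config or AnalysisConfig()).replace(permutations=permutations, seed=seed)
    return compare_groups(features, manifest_frame(cohort), cfg, family="coupling")


def score_recovery(
    results: list[ComparisonResult], truth: GroundTruth, alpha: float = 0.05
) -> tuple[int, int]:
    """(boost nodes detected with positive direction, false-positive nodes)."""
    boost = set(truth.boost_nodes)
    sig_pos = {int(r.feature) for r in results if r.p_fwe is not None and r.p_fwe <= alpha and r.direction > 0}
    sig = {int(r.feature) for r in results if r.p_fwe is not None and r.p_fwe <= alpha}
    return len(sig_pos & boost), len(sig - boost)


def null_fwer(
    n_sims: int = 200,
    permutations: int = 500,
    n_features: int = 90,
    n_per_group: int = 30,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical FWER of maxT correction under a Gaussian global null.

    Each simulation draws independent standard-normal features for both
    groups, routes each feature through the normality-gated two-group test
    and applies permutation maxT; a family counts as a false positive when
    any feature reaches p_fwe <= alpha.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    is_a = np.zeros(n, dtype=bool)
    is_a[:n_per_group] = True
    false_positives = 0
    for s in range(n_sims):
        x = rng.standard_normal((n, n_features))
        results = [
            route_test(x[is_a, j], x[~is_a, j], feature=str(j)) for j in range(n_features)
        ]
        out = fwe_correct(
            results, method="permutation_maxT", residuals=x, is_group_a=is_a,
            permutations=permutations, seed=int(rng.integers(2**31 - 1)),
        )
        if min(r.p_fwe for r in out) <= alpha:
            false_positives += 1
    return false_positives / n_sims


def boost_detection_rate(
    boost: float,
    n_reps: int = 10,
    n_per_group: int = 30,
    n_timepoints: int = 500,
    permutations: int = 300,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of planted boost nodes detected (positive direction, FWE)
    across replicate cohorts at a given coupling boost."""
    hits = 0
    total = 0
    for rep in range(n_reps):
        params = SimulationParams(
            n_hc=n_per_group, n_vci=n_per_group, n_timepoints=n_timepoints,
            coupling_boost=boost, seed=seed + 1000 * rep + int(boost * 1000),
        )
        cohort, truth = generate_cohort(params)
        results = coupling_contrast(
            cohort, AnalysisConfig(min_coupling_pairs=5), permutations=permutations, seed=seed + rep
        )
        h, _ = score_recovery(results, truth, alpha)
        hits += h
        total += len(truth.boost_nodes)
    return hits / total
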