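"""Synthetic coupled SC/FC cohort generator.

Generates seeded cohorts emulating a two-group (HC vs VCI) connectome
study: per-subject streamline-count matrices sampled around a small-world
group template, BOLD time series drawn from a covariance that blends a
normalized SC component with a decoupled random component per node, and
cognitive scores tied (negatively) to the planted coupling at designated
regions.

Planted effects:

* ``vci_structural_deficit`` multiplicatively weakens template edges
  incident to ``deficit_nodes`` in the VCI group, lowering streamline
  counts and hence binary-network topology there.
* ``coupling_boost`` raises the SC->FC covariance mixing weight at
  ``boost_nodes`` for VCI subjects from ``coupling_base`` to
  ``coupling_base + coupling_boost``, producing elevated nodal
  structure-function coupling recoverable by the Spearman estimator.
* ``cognition_effect`` (negative) makes AVLT and SDMT decrease in the
  subject's mean true coupling over the boost nodes; the remaining scores
  have null coupling slopes.

The generator is fully deterministic under a fixed seed: all randomness
flows through ``numpy.random.SeedSequence(seed)`` substreams, so
regenerating a cohort byte-identically reproduces every matrix, series and
score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .atlas import AAL90_LABELS, label_index
from .datatypes import Cohort, ConnectivityMatrix, Modality, SubjectRecord

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "make_structural_template",
    "sample_subject_sc",
    "sample_subject_bold",
    "sample_cognition",
    "generate_cohort",
    "DEFAULT_BOOST_LABELS",
    "DEFAULT_DEFICIT_LABELS",
]

# Regions with elevated VCI coupling (visual/temporal cortex) and with
# structural deficits (default-mode and sensorimotor nodes), fixed in the
# AAL-90 order.
DEFAULT_BOOST_LABELS = (
    "Calcarine_L", "Calcarine_R", "Lingual_L", "Lingual_R", "Fusiform_L",
    "Fusiform_R", "Temporal_Sup_L", "Temporal_Sup_R", "Temporal_Mid_L", "Temporal_Mid_R",
)
DEFAULT_DEFICIT_LABELS = (
    "Cingulum_Post_L", "Cingulum_Post_R", "Precuneus_L", "Precuneus_R",
    "Putamen_L", "Putamen_R", "Cuneus_R", "Occipital_Mid_R", "Parietal_Sup_R", "Postcentral_R",
)


def _default_boost_nodes(n_nodes: int = 90) -> tuple[int, ...]:
    if n_nodes == 90:
        return tuple(label_index(lb) for lb in DEFAULT_BOOST_LABELS)
    k = max(1, n_nodes // 9)
    return tuple(range(n_nodes - k, n_nodes))


def _default_deficit_nodes(n_nodes: int = 90) -> tuple[int, ...]:
    if n_nodes == 90:
        return tuple(label_index(lb) for lb in DEFAULT_DEFICIT_LABELS)
    k = max(1, n_nodes // 9)
    return tuple(range(k))


@dataclass
class SimulationParams:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the emulated design: 90 nodes, 53 HC + 68 VCI
    subjects, 200-timepoint BOLD.  Effect sizes are chosen for estimator
    testability (see docs/methods.md), not to match any unpublished
    magnitude.
    """

    n_nodes: int = 90
    n_hc: int = 53
    n_vci: int = 68
    n_timepoints: int = 200
    backbone_k: int = 16
    backbone_p: float = 0.1
    count_scale: float = 12.0
    count_sigma: float = 1.0       # log-sd of the heavy-tailed edge weights
    count_dispersion: float = 3.0  # negative-binomial size r (var = mu + mu^2/r)
    vci_structural_deficit: float = 0.3
    coupling_base: float = 0.35
    coupling_boost: float = 0.3
    deficit_nodes: tuple[int, ...] | None = None
    boost_nodes: tuple[int, ...] | None = None
    cognition_effect: float = -30.0
    noise_sd: float = 7.0
    age_mean: float = 68.0
    age_sd: float = 6.0
    age_range: tuple[float, float] = (50.0, 75.0)
    education_mean: float = 10.5
    education_sd: float = 2.5
    sex_male_prob: float = 0.44
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone_k >= self.n_nodes:
            raise ValueError(f"backbone_k ({self.backbone_k}) must be < n_nodes ({self.n_nodes})")
        if not (0 <= self.coupling_base and 0 <= self.coupling_boost
                and self.coupling_base + self.coupling_boost <= 1):
            raise ValueError("need coupling_base, coupling_boost >= 0 and base + boost <= 1")
        if self.deficit_nodes is None:
            self.deficit_nodes = _default_deficit_nodes(self.n_nodes)
        if self.boost_nodes is None:
            self.boost_nodes = _default_boost_nodes(self.n_nodes)
        for name, nodes in (("deficit_nodes", self.deficit_nodes), ("boost_nodes", self.boost_nodes)):
            nodes = tuple(int(i) for i in nodes)
            if any(i < 0 or i >= self.n_nodes for i in nodes):
                raise ValueError(f"{name} must lie in [0, {self.n_nodes})")
            setattr(self, name, nodes)
        if self.noise_sd <= 0 or self.count_sigma <= 0 or self.age_sd <= 0 or self.education_sd <= 0:
            raise ValueError("all standard deviations must be positive")
        if not (0 <= self.vci_structural_deficit <= 1):
            raise ValueError("vci_structural_deficit must lie in [0, 1]")
        if self.count_dispersion <= 0:
            raise ValueError("count_dispersion must be positive")

    def node_labels(self) -> tuple[str, ...]:
        if self.n_nodes == 90:
            return AAL90_LABELS
        return tuple(f"node_{i:03d}" for i in range(self.n_nodes))

    def to_mapping(self) -> dict:
        out = asdict(self)
        for key in ("deficit_nodes", "boost_nodes"):
            out[key] = list(out[key])
        out["age_range"] = list(out["age_range"])
        return out

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimulationParams":
        kwargs = dict(mapping)
        for key in ("deficit_nodes", "boost_nodes"):
            if key in kwargs:
                kwargs[key] = tuple(int(v) for v in kwargs[key])
        if "age_range" in kwargs:
            kwargs["age_range"] = tuple(float(v) for v in kwargs["age_range"])
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Planted effects of a generated cohort, sufficient to score recovery."""

    mixing: dict[str, np.ndarray]           # subject_id -> per-node true mixing weight
    deficit_nodes: tuple[int, ...]
    boost_nodes: tuple[int, ...]
    cognition_effect: float
    affected_scores: tuple[str, ...]
    template_hc: np.ndarray
    template_vci: np.ndarray

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mixing": {sid: m.tolist() for sid, m in self.mixing.items()},
            "deficit_nodes": list(self.deficit_nodes),
            "boost_nodes": list(self.boost_nodes),
            "cognition_effect": self.cognition_effect,
            "affected_scores": list(self.affected_scores),
            "template_hc": self.template_hc.tolist(),
            "template_vci": self.template_vci.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            mixing={sid: np.asarray(m) for sid, m in payload["mixing"].items()},
            deficit_nodes=tuple(payload["deficit_nodes"]),
            boost_nodes=tuple(payload["boost_nodes"]),
            cognition_effect=payload["cognition_effect"],
            affected_scores=tuple(payload["affected_scores"]),
            template_hc=np.asarray(payload["template_hc"]),
            template_vci=np.asarray(payload["template_vci"]),
        )


def _base_template(params: SimulationParams) -> np.ndarray:
    """Shared (pre-deficit) weighted template: small-world backbone with
    heavy-tailed edge weights."""
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x5C]))
    g = nx.watts_strogatz_graph(
        params.n_nodes, params.backbone_k, params.backbone_p,
        seed=int(rng.integers(2**31 - 1)),
    )
    template = np.zeros((params.n_nodes, params.n_nodes))
    for u, v in sorted(g.edges()):
        # lognormal with median count_scale: heavy-tailed positive weights
        w = params.count_scale * rng.lognormal(mean=0.0, sigma=params.count_sigma)
        template[u, v] = template[v, u] = w
    return template


def make_structural_template(params: SimulationParams, group: str) -> np.ndarray:
    """Group-level weighted SC template.

    HC and VCI share the same seeded backbone and base weights; for VCI,
    weights on edges incident to ``deficit_nodes`` are multiplied by
    ``1 - vci_structural_deficit``.
    """
    if group not in ("HC", "VCI"):
        raise ValueError(f"unknown group {group!r}")
    template = _base_template(params)
    if group == "VCI" and params.vci_structural_deficit > 0:
        factor = 1.0 - params.vci_structural_deficit
        idx = np.array(params.deficit_nodes, dtype=int)
        template[idx, :] *= factor
        template[:, idx] *= factor
        # Edges between two deficit nodes were scaled twice; undo one factor.
        sub = np.ix_(idx, idx)
        if factor > 0:
            template[sub] /= factor
    return template


def sample_subject_sc(
    template: np.ndarray, params: SimulationParams, rng: np.random.Generator,
    node_labels: tuple[str, ...] | None = None,
) -> ConnectivityMatrix:
    """Draw integer streamline counts around a template.

    Counts are negative-binomial with mean equal to the template weight and
    dispersion ``count_dispersion`` (variance mu + mu^2/r): overdispersed
    non-negative integers, zero wherever the template is zero.
    """
    n = template.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mu = template[iu, ju]
    counts = np.zeros_like(mu)
    pos = mu > 0
    r = params.count_dispersion
    p = r / (r + mu[pos])
    counts[pos] = rng.negative_binomial(r, p)
    mat = np.zeros((n, n))
    mat[iu, ju] = counts
    mat += mat.T
    labels = node_labels or (params.node_labels() if n == params.n_nodes
                             else tuple(f"node_{i:03d}" for i in range(n)))
    return ConnectivityMatrix(mat, labels, Modality.STRUCTURAL_COUNT)


class CovarianceError(RuntimeError):
    """Target BOLD covariance could not be made positive definite."""


def _target_covariance(
    sc_values: np.ndarray, mixing: np.ndarray, rng: np.random.Generator,
    min_eig: float = 1e-6, max_ridge: float = 10.0, sc_power: float = 0.5,
) -> np.ndarray:
    """Blend normalized SC with a decoupled random component per node.

    Sigma = M * SCn + (1 - M) * R with M_ij = max(m_i, m_j), unit diagonal,
    then a geometrically escalated diagonal ridge until the smallest
    eigenvalue exceeds ``min_eig``.  The max-blend gives a node's entire
    connectivity profile its own mixing weight, so a planted per-node
    coupling level is expressed on every incident edge rather than being
    diluted through edge-wise averaging.

    SCn is the count matrix scaled to unit max and raised to ``sc_power``
    (default square root): a strictly monotone compression that preserves
    the rank structure the coupling estimator assumes while keeping the
    covariance gaps between weak connections above the finite-sample noise
    of the empirical correlations.
    """
    n = sc_values.shape[0]
    sc_max = sc_values.max()
    scn = np.power(sc_values / sc_max, sc_power) if sc_max > 0 else np.zeros_like(sc_values)
    w = rng.standard_normal((n, n)) / np.sqrt(n)
    r0 = w @ w.T
    d = np.sqrt(np.diagonal(r0))
    r_decoupled = r0 / np.outer(d, d)
    np.fill_diagonal(r_decoupled, 0.0)
    m = np.maximum(mixing[:, None], mixing[None, :])
    cov = m * scn + (1.0 - m) * r_decoupled
    np.fill_diagonal(cov, 1.0)
    eps = 0.0
    step = 1e-4
    while True:
        ridged = cov + eps * np.eye(n)
        if np.linalg.eigvalsh(ridged)[0] > min_eig:
            return ridged
        eps = step if eps == 0 else eps * 2
        if eps > max_ridge:
            smallest = float(np.linalg.eigvalsh(cov + max_ridge * np.eye(n))[0])
            raise CovarianceError(
                f"covariance not positive definite at max ridge {max_ridge} "
                f"(smallest eigenvalue {smallest:.3e})"
            )


def sample_subject_bold(
    sc: ConnectivityMatrix, mixing: np.ndarray, n_timepoints: int, rng: np.random.Generator,
) -> np.ndarray:
    """Draw a node-by-time BOLD series whose covariance mixes SC with a
    decoupled random component according to per-node mixing weights."""
    if sc.modality != Modality.STRUCTURAL_COUNT:
        raise ValueError(f"expected structural_count SC, got {sc.modality}")
    mixing = np.asarray(mixing, dtype=float)
    if mixing.shape != (sc.n_nodes,):
        raise ValueError("mixing must have one weight per node")
    if np.any(mixing < 0) or np.any(mixing > 1):
        raise ValueError("mixing weights must lie in [0, 1]")
    cov = _target_covariance(sc.values, mixing, rng)
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal((sc.n_nodes, n_timepoints))


# Cognitive score generating model: intercept, age slope (per year),
# education slope (per year), residual sd scale (relative to noise_sd).
_SCORE_MODEL = {
    "MMSE":    {"intercept": 29.0, "age": -0.02, "edu": 0.05, "sd_scale": 0.25, "affected": False},
    "AVLT":    {"intercept": 44.0, "age": -0.15, "edu": 0.60, "sd_scale": 1.0, "affected": True},
    "AVLT_N5": {"intercept": 7.0,  "age": -0.03, "edu": 0.10, "sd_scale": 0.25, "affected": False},
    "SDMT":    {"intercept": 52.0, "age": -0.25, "edu": 0.80, "sd_scale": 1.2, "affected": True},
    "STT_B":   {"intercept": 150.0, "age": 1.0,  "edu": -2.0, "sd_scale": 5.0, "affected": False},
    "BNT":     {"intercept": 24.0, "age": -0.02, "edu": 0.15, "sd_scale": 0.4, "affected": False},
}

AFFECTED_SCORES = tuple(k for k, v in _SCORE_MODEL.items() if v["affected"])


def sample_cognition(
    age: float, education: float, mean_boost_coupling: float,
    params: SimulationParams, rng: np.random.Generator,
) -> dict[str, float]:
    """Draw the six cognitive scores for one subject.

    AVLT and SDMT carry the planted coupling slope
    (``cognition_effect * mean_boost_coupling``); the others have null
    coupling slopes.  All scores get mild age/education terms and Gaussian
    noise scaled from ``noise_sd``.
    """
    scores: dict[str, float] = {}
    for name, spec in _SCORE_MODEL.items():
        mu = (
            spec["intercept"]
            + spec["age"] * (age - params.age_mean)
            + spec["edu"] * (education - params.education_mean)
        )
        if spec["affected"]:
            mu += params.cognition_effect * mean_boost_coupling
        scores[name] = float(mu + params.noise_sd * spec["sd_scale"] * rng.standard_normal())
    return scores


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def generate_cohort(params: SimulationParams | None = None) -> tuple[Cohort, GroundTruth]:
    """Generate a full synthetic cohort with its ground truth.

    HC subjects receive mixing ``coupling_base`` everywhere; VCI subjects
    receive ``coupling_base + coupling_boost`` at ``boost_nodes`` and
    ``coupling_base`` elsewhere.  Every subject gets covariates, cognition,
    an SC count matrix around the group template and a BOLD series.
    """
    params = params or SimulationParams()
    labels = params.node_labels()
    templates = {grp: make_structural_template(params, grp) for grp in ("HC", "VCI")}
    root_ss = np.random.SeedSequence([params.seed, 0xC0])
    subject_seeds = root_ss.spawn(params.n_hc + params.n_vci)
    subjects: list[SubjectRecord] = []
    sc_matrices: dict[str, ConnectivityMatrix] = {}
    bold_series: dict[str, np.ndarray] = {}
    mixing_truth: dict[str, np.ndarray] = {}
    groups = ["HC"] * params.n_hc + ["VCI"] * params.n_vci
    counters = {"HC": 0, "VCI": 0}
    for group, sseq in zip(groups, subject_seeds):
        counters[group] += 1
        sid = f"{group}{counters[group]:03d}"
        rng = np.random.default_rng(sseq)
        mixing = np.full(params.n_nodes, params.coupling_base)
        if group == "VCI" and params.coupling_boost > 0:
            mixing[list(params.boost_nodes)] += params.coupling_boost
        sc = sample_subject_sc(templates[group], params, rng, node_labels=labels)
        bold = sample_subject_bold(sc, mixing, params.n_timepoints, rng)
        age = _truncated_normal(rng, params.age_mean, params.age_sd, *params.age_range)
        education = float(max(0.0, np.round(rng.normal(params.education_mean, params.education_sd))))
        sex = "male" if rng.random() < params.sex_male_prob else "female"
        mean_boost = float(mixing[list(params.boost_nodes)].mean()) if params.boost_nodes else 0.0
        scores = sample_cognition(age, education, mean_boost, params, rng)
        subjects.append(
            SubjectRecord(
                subject_id=sid, group=group, age=age, sex=sex, education=education,
                cognitive_scores=scores,
            )
        )
        sc_matrices[sid] = sc
        bold_series[sid] = bold
        mixing_truth[sid] = mixing
    cohort = Cohort(
        subjects=subjects, sc_matrices=sc_matrices, bold_series=bold_series, atlas_labels=labels
    )
    truth = GroundTruth(
        mixing=mixing_truth,
        deficit_nodes=params.deficit_nodes,
        boost_nodes=params.boost_nodes,
        cognition_effect=params.cognition_effect,
        affected_scores=AFFECTED_SCORES,
        template_hc=templates["HC"],
        template_vci=templates["VCI"],
    )
    return cohort, truth
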