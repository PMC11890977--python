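"""Reading and writing manifests, matrices, time series and configs.

File formats are deliberately plain: a CSV manifest with a fixed header, one
whitespace-delimited text file per subject per modality, an atlas label file
with one label per line, and YAML configs.  Imaging formats (NIfTI/DICOM)
and BIDS layouts are out of scope.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .atlas import AAL90_LABELS
from .datatypes import (
    COGNITIVE_SCORES,
    GROUPS,
    SYMMETRY_TOL,
    AnalysisConfig,
    Cohort,
    ConnectivityMatrix,
    Modality,
    SubjectRecord,
)

__all__ = [
    "MANIFEST_COLUMNS",
    "read_manifest",
    "write_manifest",
    "read_matrix",
    "write_matrix",
    "read_series",
    "write_series",
    "read_labels",
    "write_labels",
    "read_config",
    "write_config",
    "validate_cohort",
    "load_cohort",
    "save_cohort",
]

MANIFEST_COLUMNS = (
    "subject_id",
    "group",
    "age",
    "sex",
    "education",
    *COGNITIVE_SCORES,
    "sc_source",
    "bold_source",
)

_REQUIRED_COLUMNS = ("subject_id", "group", "age", "sex", "education")


class SchemaError(ValueError):
    """A manifest or matrix file does not match the expected schema."""


def read_manifest(path: str | Path) -> list[SubjectRecord]:
    """Read a cohort manifest CSV into subject records.

    Missing cognitive-score cells become NaN (recorded, never imputed).
    Raises :class:`SchemaError` for a missing required column, a duplicated
    subject id, or an unknown group label.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"manifest {path}: missing required column {col!r}")
    dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dupes:
        raise SchemaError(f"manifest {path}: duplicate subject_id(s) {sorted(set(dupes))}")
    bad_groups = sorted(set(df["group"]) - set(GROUPS))
    if bad_groups:
        raise SchemaError(f"manifest {path}: unknown group label(s) {bad_groups} (expected {list(GROUPS)})")
    records = []
    for _, row in df.iterrows():
        scores = {name: float(row[name]) if name in df.columns and pd.notna(row[name]) else np.nan
                  for name in COGNITIVE_SCORES}
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                education=float(row["education"]),
                cognitive_scores=scores,
                sc_source=str(row["sc_source"]) if "sc_source" in df.columns and pd.notna(row.get("sc_source")) else None,
                bold_source=str(row["bold_source"]) if "bold_source" in df.columns and pd.notna(row.get("bold_source")) else None,
            )
        )
    return records


def write_manifest(records: Sequence[SubjectRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row: dict = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "age": rec.age,
            "sex": rec.sex,
            "education": rec.education,
        }
        row.update({name: rec.cognitive_scores.get(name, np.nan) for name in COGNITIVE_SCORES})
        row["sc_source"] = rec.sc_source or ""
        row["bold_source"] = rec.bold_source or ""
        rows.append(row)
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(path, index=False, float_format="%.12g")


def _load_delimited(path: str | Path) -> np.ndarray:
    """Load a whitespace- or comma-delimited numeric text file."""
    try:
        return np.loadtxt(path, ndmin=2)
    except ValueError:
        try:
            return np.loadtxt(path, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise SchemaError(f"{path}: could not parse numeric matrix: {exc}") from exc


def read_matrix(
    path: str | Path,
    expected_order: int | None = None,
    modality: str = Modality.STRUCTURAL_COUNT,
    node_labels: Sequence[str] | None = None,
) -> ConnectivityMatrix:
    """Read a square connectivity matrix from delimited text.

    Symmetry is enforced within ``1e-10`` (symmetrized by averaging);
    larger asymmetry is an error since count matrices are symmetric by
    construction and asymmetry signals corrupt input.  A nonzero diagonal is
    zeroed with a warning.
    """
    values = _load_delimited(path)
    if values.shape[0] != values.shape[1]:
        raise SchemaError(f"{path}: matrix is not square (shape {values.shape})")
    if expected_order is not None and values.shape[0] != expected_order:
        raise SchemaError(f"{path}: matrix order {values.shape[0]} != expected {expected_order}")
    asym = np.max(np.abs(values - values.T)) if values.size else 0.0
    if asym > SYMMETRY_TOL:
        raise SchemaError(f"{path}: asymmetry {asym:.3e} exceeds tolerance {SYMMETRY_TOL:g}")
    values = (values + values.T) / 2.0
    if np.any(np.diagonal(values) != 0):
        warnings.warn(f"{path}: nonzero diagonal zeroed", stacklevel=2)
        np.fill_diagonal(values, 0.0)
    labels = tuple(node_labels) if node_labels is not None else tuple(
        f"node_{i}" for i in range(values.shape[0])
    )
    return ConnectivityMatrix(values, labels, modality)


def write_matrix(matrix: ConnectivityMatrix | np.ndarray, path: str | Path) -> None:
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    np.savetxt(path, values, fmt="%.17g")


def read_series(path: str | Path, expected_nodes: int | None = None) -> np.ndarray:
    """Read a node-by-time BOLD series from delimited text."""
    values = _load_delimited(path)
    if expected_nodes is not None and values.shape[0] != expected_nodes:
        raise SchemaError(f"{path}: series has {values.shape[0]} rows, expected {expected_nodes} nodes")
    return values


def write_series(series: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(series), fmt="%.17g")


def read_labels(path: str | Path) -> tuple[str, ...]:
    with open(path) as fh:
        return tuple(line.strip() for line in fh if line.strip())


def write_labels(labels: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(labels) + "\n")


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg


def write_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def analysis_config_from_file(path: str | Path) -> AnalysisConfig:
    cfg = read_config(path)
    return AnalysisConfig.from_mapping(cfg.get("analysis", cfg))


def validate_cohort(cohort: Cohort) -> list[str]:
    """Check every cohort invariant; return a list of violations.

    An empty list means the cohort is analyzable.
    """
    violations: list[str] = []
    ids = cohort.subject_ids
    seen: set[str] = set()
    for sid in ids:
        if sid in seen:
            violations.append(f"duplicate subject_id {sid!r}")
        seen.add(sid)
    n_nodes = cohort.n_nodes
    for sid in ids:
        sc = cohort.sc_matrices.get(sid)
        if sc is None:
            violations.append(f"subject {sid}: missing structural matrix")
        else:
            if sc.n_nodes != n_nodes:
                violations.append(f"subject {sid}: structural matrix order {sc.n_nodes} != atlas order {n_nodes}")
            elif sc.node_labels != cohort.atlas_labels:
                violations.append(f"subject {sid}: structural node labels differ from atlas labels")
        bold = cohort.bold_series.get(sid)
        if bold is None:
            violations.append(f"subject {sid}: missing BOLD series")
        elif bold.shape[0] != n_nodes:
            violations.append(f"subject {sid}: BOLD series has {bold.shape[0]} rows, atlas order is {n_nodes}")
    for extra in sorted(set(cohort.sc_matrices) - set(ids)):
        violations.append(f"structural matrix for unknown subject {extra!r}")
    for extra in sorted(set(cohort.bold_series) - set(ids)):
        violations.append(f"BOLD series for unknown subject {extra!r}")
    for group in GROUPS:
        n = len(cohort.by_group(group))
        if 0 < n < 2:
            violations.append(f"group {group} has only {n} subject(s); group analyses need >= 2")
    return violations


def save_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, str]:
    """Write a cohort to ``out_dir`` (manifest, labels, sc/, bold/).

    Returns a mapping of logical name to written file path.
    """
    out = Path(out_dir)
    (out / "sc").mkdir(parents=True, exist_ok=True)
    (out / "bold").mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    records = []
    for rec in cohort.subjects:
        sc_path = out / "sc" / f"{rec.subject_id}.txt"
        bold_path = out / "bold" / f"{rec.subject_id}.txt"
        write_matrix(cohort.sc_matrices[rec.subject_id], sc_path)
        write_series(cohort.bold_series[rec.subject_id], bold_path)
        rec = SubjectRecord(
            subject_id=rec.subject_id, group=rec.group, age=rec.age, sex=rec.sex,
            education=rec.education, cognitive_scores=dict(rec.cognitive_scores),
            sc_source=str(sc_path.relative_to(out)), bold_source=str(bold_path.relative_to(out)),
        )
        records.append(rec)
        written[f"sc/{rec.subject_id}"] = str(sc_path)
        written[f"bold/{rec.subject_id}"] = str(bold_path)
    write_manifest(records, out / "manifest.csv")
    write_labels(cohort.atlas_labels, out / "atlas_labels.txt")
    written["manifest"] = str(out / "manifest.csv")
    written["atlas_labels"] = str(out / "atlas_labels.txt")
    return written


def load_cohort(cohort_dir: str | Path) -> Cohort:
    """Load a cohort previously written by :func:`save_cohort`."""
    root = Path(cohort_dir)
    records = read_manifest(root / "manifest.csv")
    labels_path = root / "atlas_labels.txt"
    labels = read_labels(labels_path) if labels_path.exists() else AAL90_LABELS
    sc: dict[str, ConnectivityMatrix] = {}
    bold: dict[str, np.ndarray] = {}
    for rec in records:
        if rec.sc_source:
            sc[rec.subject_id] = read_matrix(
                root / rec.sc_source, expected_order=len(labels),
                modality=Modality.STRUCTURAL_COUNT, node_labels=labels,
            )
        if rec.bold_source:
            bold[rec.subject_id] = read_series(root / rec.bold_source, expected_nodes=len(labels))
    return Cohort(subjects=records, sc_matrices=sc, bold_series=bold, atlas_labels=tuple(labels))
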