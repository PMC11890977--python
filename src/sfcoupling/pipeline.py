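"""File-based pipeline stages and the end-to-end runner.

Each stage consumes and produces only files, so stages can be re-run
individually with identical results: ``simulate`` writes a cohort
directory, ``build`` the per-subject networks, ``topology``/``coupling``
tidy metric CSVs, ``stats``/``correlate`` the inference tables, and
``report`` a machine-readable JSON plus a human-readable summary.  A
:class:`RunRecord` lists every output with a content hash; rerunning with
the same config and master seed reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import coupling as _coupling
from . import inference as _inference
from . import networks as _networks
from . import topology as _topology
from .datatypes import AnalysisConfig, Cohort, Modality
from .io import (
    load_cohort,
    read_config,
    read_manifest,
    read_matrix,
    read_labels,
    save_cohort,
    write_config,
    write_matrix,
)
from .simulate import SimulationParams, generate_cohort

__all__ = ["RunRecord", "run_all", "make_report", "STAGES"]

log = logging.getLogger("sfcoupling")

STAGES = ("simulate", "build", "topology", "coupling", "stats", "correlate", "report")

_CSV_FLOAT = "%.12g"

COGNITION_SCORES_FOR_CORRELATION = ("BNT", "STT_B", "SDMT", "AVLT")


@dataclass
class RunRecord:
    """Provenance of one pipeline run."""

    config: dict
    seed: int
    version: str = __version__
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # relative path -> sha256

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _hash_outputs(out_dir: Path, record: RunRecord) -> None:
    for p in sorted(out_dir.rglob("*")):
        # logs carry timestamps; the record itself cannot contain its own hash
        if p.is_file() and p.name != "run_record.json" and p.suffix != ".log":
            record.outputs[str(p.relative_to(out_dir))] = _sha256(p)


def _analysis_config(config: dict, seed: int | None = None) -> AnalysisConfig:
    cfg = AnalysisConfig.from_mapping(config.get("analysis", {}))
    if seed is not None:
        cfg = cfg.replace(seed=seed)
    return cfg


def _sim_params(config: dict, seed: int | None = None) -> SimulationParams:
    params = SimulationParams.from_mapping(config.get("simulate", {}))
    if seed is not None:
        params = SimulationParams.from_mapping({**params.to_mapping(), "seed": seed})
    return params


# --------------------------------------------------------------------- stages

def stage_simulate(config: dict, out_dir: Path, seed: int | None = None) -> Path:
    """Generate a synthetic cohort and write it under ``out_dir/cohort``."""
    params = _sim_params(config, seed)
    cohort, truth = generate_cohort(params)
    cohort_dir = out_dir / "cohort"
    save_cohort(cohort, cohort_dir)
    truth.to_json(cohort_dir / "ground_truth.json")
    write_config({"simulate": params.to_mapping()}, cohort_dir / "simulation_params.yaml")
    log.info("simulate: %d subjects, %d nodes -> %s", len(cohort.subjects), cohort.n_nodes, cohort_dir)
    return cohort_dir


def stage_build(
    cohort_dir: Path, config: dict, out_dir: Path, seed: int | None = None,
    write_sparsity: bool = False,
) -> Path:
    """Build per-subject networks: masked binary SC, weighted and z FC."""
    cfg = _analysis_config(config, seed)
    cohort = load_cohort(cohort_dir)
    build_dir = out_dir / "networks"
    for sub in ("sc_binary", "fc_z"):
        (build_dir / sub).mkdir(parents=True, exist_ok=True)
    binaries = {
        sid: _networks.binarize_sc(cohort.sc_matrices[sid], cfg.fiber_threshold)
        for sid in cohort.subject_ids
    }
    mask = _networks.group_consistency_mask(list(binaries.values()), cfg.group_consistency)
    for sid, binary in binaries.items():
        write_matrix(_networks.apply_mask(binary, mask), build_dir / "sc_binary" / f"{sid}.txt")
    write_matrix(mask.mask, build_dir / "mask.txt")
    write_matrix(mask.consistency, build_dir / "consistency.txt")
    grid = _networks.SparsityGrid.from_range(*cfg.sparsity_grid)
    for sid in cohort.subject_ids:
        r = _networks.pearson_fc(cohort.bold_series[sid], node_labels=cohort.atlas_labels)
        z, _ = _networks.fisher_z(r)
        write_matrix(z, build_dir / "fc_z" / f"{sid}.txt")
        if write_sparsity:
            sdir = build_dir / "fc_binary" / sid
            sdir.mkdir(parents=True, exist_ok=True)
            for s in grid:
                binary, _ = _networks.sparsity_threshold(z, s)
                write_matrix(binary, sdir / f"s{s:.2f}.txt")
    log.info("build: mask retains %d edges -> %s", mask.n_edges, build_dir)
    return build_dir


def stage_topology(
    cohort_dir: Path, build_dir: Path, config: dict, out_dir: Path, seed: int | None = None,
    functional_sigma: bool = False,
) -> Path:
    """Topology battery: structural metrics and functional sparsity AUCs."""
    cfg = _analysis_config(config, seed)
    labels = read_labels(cohort_dir / "atlas_labels.txt")
    manifest = read_manifest(cohort_dir / "manifest.csv")
    ids = [r.subject_id for r in manifest]
    topo_dir = out_dir / "topology"
    topo_dir.mkdir(parents=True, exist_ok=True)
    grid = _networks.SparsityGrid.from_range(*cfg.sparsity_grid)

    sg_rows, sn_rows, fg_rows, fn_rows = [], [], [], []
    for k, sid in enumerate(ids):
        sc_bin = read_matrix(
            build_dir / "sc_binary" / f"{sid}.txt", expected_order=len(labels),
            modality=Modality.STRUCTURAL_BINARY, node_labels=labels,
        )
        nulls = _topology.NullEnsembleParams(
            n_nulls=cfg.null_count, swaps_per_edge=cfg.swaps_per_edge,
            seed=int((cfg.seed * 9973 + k) % (2**31 - 1)),
        )
        gm = _topology.global_metrics(sc_bin, nulls=nulls, cp_zero_mode=cfg.cp_zero_mode)
        nm = _topology.nodal_metrics(sc_bin)
        sg_rows.append({"subject_id": sid, **gm.as_dict(), "disconnected": gm.disconnected})
        for i, lab in enumerate(labels):
            sn_rows.append({"subject_id": sid, "node": i, "label": lab,
                            **{n_: float(v[i]) for n_, v in nm.as_dict().items()}})
        z = read_matrix(
            build_dir / "fc_z" / f"{sid}.txt", expected_order=len(labels),
            modality=Modality.FUNCTIONAL_WEIGHTED, node_labels=labels,
        )
        level_nulls = None
        if functional_sigma:
            level_nulls = _topology.NullEnsembleParams(
                n_nulls=cfg.null_count, swaps_per_edge=cfg.swaps_per_edge,
                seed=int((cfg.seed * 7919 + k) % (2**31 - 1)),
            )
        sweep = _topology.metrics_over_sparsity(z, grid, nulls=level_nulls)
        frow: dict = {"subject_id": sid}
        for name in ("Eglob", "Eloc", "Cp", "Lp", "Sigma"):
            vals = np.array([getattr(lv.global_metrics, name) for lv in sweep])
            frow[f"a{name}"] = _topology.auc_curve(vals, grid) if np.all(np.isfinite(vals)) else np.nan
        fg_rows.append(frow)
        for i, lab in enumerate(labels):
            nrow = {"subject_id": sid, "node": i, "label": lab}
            for name in _topology.NODAL_METRIC_NAMES:
                col = np.array([lv.nodal_metrics.as_dict()[name][i] for lv in sweep], dtype=float)
                nrow[f"a{name}"] = _topology.auc_curve(col, grid) if np.all(np.isfinite(col)) else np.nan
            fn_rows.append(nrow)
    pd.DataFrame(sg_rows).to_csv(topo_dir / "structural_global.csv", index=False, float_format=_CSV_FLOAT)
    pd.DataFrame(sn_rows).to_csv(topo_dir / "structural_nodal.csv", index=False, float_format=_CSV_FLOAT)
    pd.DataFrame(fg_rows).to_csv(topo_dir / "functional_global_auc.csv", index=False, float_format=_CSV_FLOAT)
    pd.DataFrame(fn_rows).to_csv(topo_dir / "functional_nodal_auc.csv", index=False, float_format=_CSV_FLOAT)
    log.info("topology: %d subjects -> %s", len(ids), topo_dir)
    return topo_dir


def stage_coupling(
    cohort_dir: Path, build_dir: Path, config: dict, out_dir: Path, seed: int | None = None
) -> Path:
    """Per-subject nodal coupling profiles as a tidy CSV."""
    cfg = _analysis_config(config, seed)
    cohort = load_cohort(cohort_dir)
    coup_dir = out_dir / "coupling"
    coup_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid in cohort.subject_ids:
        z = read_matrix(
            build_dir / "fc_z" / f"{sid}.txt", expected_order=cohort.n_nodes,
            modality=Modality.FUNCTIONAL_WEIGHTED, node_labels=cohort.atlas_labels,
        )
        if cfg.coupling_sc_weighting == "count":
            sc = cohort.sc_matrices[sid]
        else:
            sc = read_matrix(
                build_dir / "sc_binary" / f"{sid}.txt", expected_order=cohort.n_nodes,
                modality=Modality.STRUCTURAL_BINARY, node_labels=cohort.atlas_labels,
            )
        prof = _coupling.subject_coupling(sc, z, cfg)
        for i, lab in enumerate(cohort.atlas_labels):
            rows.append({"subject_id": sid, "node": i, "label": lab,
                         "rho": prof.rho[i], "n_pairs": int(prof.n_pairs[i])})
    pd.DataFrame(rows).to_csv(coup_dir / "coupling.csv", index=False, float_format=_CSV_FLOAT)
    log.info("coupling: -> %s", coup_dir / "coupling.csv")
    return coup_dir


def _manifest_frame(cohort_dir: Path) -> pd.DataFrame:
    records = read_manifest(cohort_dir / "manifest.csv")
    return pd.DataFrame(
        [{"subject_id": r.subject_id, "group": r.group, "age": r.age, "sex": r.sex,
          "education": r.education, **r.cognitive_scores} for r in records]
    ).set_index("subject_id")


def stage_stats(
    cohort_dir: Path, topo_dir: Path, coup_dir: Path, config: dict, out_dir: Path,
    seed: int | None = None,
) -> Path:
    """Covariate-adjusted group contrasts with FWE, one CSV per family."""
    cfg = _analysis_config(config, seed)
    man = _manifest_frame(cohort_dir)
    stats_dir = out_dir / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    tables = []

    def contrast(features: pd.DataFrame, family: str) -> None:
        features = features.loc[:, features.nunique() > 1].dropna(axis=1)
        if features.shape[1] == 0:
            tables.append(_inference.comparison_table([], family=family))
            return
        results = _inference.compare_groups(features, man, cfg, family=family)
        tables.append(_inference.comparison_table(results, family=family))

    sg = pd.read_csv(topo_dir / "structural_global.csv").set_index("subject_id")
    contrast(sg[[c for c in ("Eglob", "Eloc", "Cp", "Lp", "Sigma") if c in sg]], "structural_global")
    sn = pd.read_csv(topo_dir / "structural_nodal.csv")
    for metric in _topology.NODAL_METRIC_NAMES:
        wide = sn.pivot(index="subject_id", columns="label", values=metric)
        contrast(wide, f"structural_nodal_{metric}")
    fg = pd.read_csv(topo_dir / "functional_global_auc.csv").set_index("subject_id")
    contrast(fg, "functional_global_auc")
    fn = pd.read_csv(topo_dir / "functional_nodal_auc.csv")
    for metric in _topology.NODAL_METRIC_NAMES:
        wide = fn.pivot(index="subject_id", columns="label", values=f"a{metric}")
        contrast(wide, f"functional_nodal_a{metric}")
    coup = pd.read_csv(coup_dir / "coupling.csv")
    wide = coup.pivot(index="subject_id", columns="label", values="rho")
    contrast(wide, "coupling")

    all_tables = pd.concat(tables, ignore_index=True)
    all_tables.to_csv(stats_dir / "contrasts.csv", index=False, float_format=_CSV_FLOAT)
    log.info("stats: %d families -> %s", all_tables["family"].nunique(), stats_dir)
    return stats_dir


def stage_correlate(
    cohort_dir: Path, coup_dir: Path, config: dict, out_dir: Path, seed: int | None = None
) -> Path:
    """Coupling x cognition partial correlations (long-format CSV)."""
    cfg = _analysis_config(config, seed)
    man = _manifest_frame(cohort_dir)
    corr_dir = out_dir / "correlations"
    corr_dir.mkdir(parents=True, exist_ok=True)
    coup = pd.read_csv(coup_dir / "coupling.csv")
    wide = coup.pivot(index="subject_id", columns="label", values="rho").dropna(axis=1)
    rows = []
    for score in COGNITION_SCORES_FOR_CORRELATION:
        family = []
        for region in wide.columns:
            df = pd.concat([wide[region], man[[score, "age", "sex", "education"]]], axis=1).dropna()
            if len(df) <= 5 or df[region].nunique() <= 1 or df[score].nunique() <= 1:
                continue
            family.append(
                _inference.partial_correlation(
                    df[region].to_numpy(float), df[score].to_numpy(float),
                    df[["age", "sex", "education"]], method="auto", region=str(region), score=score,
                )
            )
        m = len(family)
        for res in family:
            rows.append({"region": res.region, "score": res.score, "rho_partial": res.rho_partial,
                         "p_raw": res.p_raw, "p_fwe": min(1.0, m * res.p_raw), "method": res.method,
                         "n": res.n})
    pd.DataFrame(rows, columns=["region", "score", "rho_partial", "p_raw", "p_fwe", "method", "n"]).to_csv(
        corr_dir / "coupling_cognition.csv", index=False, float_format=_CSV_FLOAT
    )
    log.info("correlate: -> %s", corr_dir / "coupling_cognition.csv")
    return corr_dir


def make_report(out_dir: Path, config: dict, alpha: float = 0.05) -> dict:
    """Assemble the run report from stage outputs.

    Missing stage outputs mark their section unavailable instead of
    failing.  Significant-feature lists are sorted by (p_fwe, label).
    """
    report: dict = {"alpha": alpha, "sections": {}}

    def significant(table: pd.DataFrame) -> list[dict]:
        sig = table[table["p_fwe"].notna() & (table["p_fwe"] <= alpha)]
        sig = sig.sort_values(["p_fwe", "feature"])
        return [
            {"feature": r["feature"], "statistic": float(r["statistic"]), "test": r["test"],
             "p_raw": float(r["p_raw"]), "p_fwe": float(r["p_fwe"]), "direction": int(r["direction"])}
            for _, r in sig.iterrows()
        ]

    contrasts_path = out_dir / "stats" / "contrasts.csv"
    if contrasts_path.exists():
        contrasts = pd.read_csv(contrasts_path)
        for key, prefix in (
            ("structural_global", "structural_global"),
            ("structural_nodal", "structural_nodal_"),
            ("functional_auc", "functional_"),
            ("coupling", "coupling"),
        ):
            if prefix.endswith("_"):
                sel = contrasts[contrasts["family"].str.startswith(prefix)]
            else:
                sel = contrasts[contrasts["family"] == prefix]
            if len(sel):
                report["sections"][key] = {
                    "n_features": int(len(sel)),
                    "significant": significant(sel),
                }
            else:
                report["sections"][key] = {"available": False}
    else:
        for key in ("structural_global", "structural_nodal", "functional_auc", "coupling"):
            report["sections"][key] = {"available": False}

    corr_path = out_dir / "correlations" / "coupling_cognition.csv"
    if corr_path.exists():
        corr = pd.read_csv(corr_path)
        sig = corr[corr["p_fwe"].notna() & (corr["p_fwe"] <= alpha)].sort_values(["p_fwe", "region"])
        report["sections"]["coupling_cognition"] = {
            "n_pairs": int(len(corr)),
            "significant": [
                {"region": r["region"], "score": r["score"], "rho_partial": float(r["rho_partial"]),
                 "p_raw": float(r["p_raw"]), "p_fwe": float(r["p_fwe"]), "method": r["method"]}
                for _, r in sig.iterrows()
            ],
        }
    else:
        report["sections"]["coupling_cognition"] = {"available": False}
    return report


def _report_markdown(report: dict) -> str:
    lines = ["# Structure-function coupling pipeline report", ""]
    for name, section in report["sections"].items():
        lines.append(f"## {name}")
        if section.get("available") is False:
            lines.append("section unavailable (stage output missing)")
            lines.append("")
            continue
        sig = section.get("significant", [])
        if not sig:
            lines.append("no significant features")
        for entry in sig:
            if "feature" in entry:
                dir_sym = {1: "VCI>HC", -1: "VCI<HC", 0: "="}[entry["direction"]]
                lines.append(f"- {entry['feature']}: p_fwe={entry['p_fwe']:.4g} ({entry['test']}, {dir_sym})")
            else:
                lines.append(
                    f"- {entry['region']} x {entry['score']}: rho={entry['rho_partial']:+.3f}, "
                    f"p_fwe={entry['p_fwe']:.4g} ({entry['method']})"
                )
        lines.append("")
    return "\n".join(lines)


def run_all(
    config: dict | str | Path, out_dir: str | Path, seed: int | None = None,
    functional_sigma: bool = False,
) -> RunRecord:
    """Run every stage in order and write a hashed run record.

    A stage failure aborts with the stage name and cause; outputs of
    completed stages are retained.
    """
    if not isinstance(config, dict):
        config = read_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(config.get("seed", 0))
    record = RunRecord(config=json.loads(json.dumps(config, default=str)), seed=seed)
    alpha = float(config.get("analysis", {}).get("alpha", 0.05))

    stage_args: dict = {}

    def run_stage(name, fn, *args, **kwargs):
        t0 = time.monotonic()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        record.stage_seconds[name] = round(time.monotonic() - t0, 3)
        log.info("stage %s finished in %.1fs", name, record.stage_seconds[name])
        return result

    cohort_dir = config.get("cohort_dir")
    if cohort_dir:
        cohort_dir = Path(cohort_dir)
    else:
        cohort_dir = run_stage("simulate", stage_simulate, config, out, seed)
    build_dir = run_stage("build", stage_build, cohort_dir, config, out, seed)
    topo_dir = run_stage("topology", stage_topology, cohort_dir, build_dir, config, out, seed,
                         functional_sigma=functional_sigma)
    coup_dir = run_stage("coupling", stage_coupling, cohort_dir, build_dir, config, out, seed)
    run_stage("stats", stage_stats, cohort_dir, topo_dir, coup_dir, config, out, seed)
    run_stage("correlate", stage_correlate, cohort_dir, coup_dir, config, out, seed)
    report = run_stage("report", make_report, out, config, alpha)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "report.md").write_text(_report_markdown(report))
    _hash_outputs(out, record)
    record.to_json(out / "run_record.json")
    return record
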