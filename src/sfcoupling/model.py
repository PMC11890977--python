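"""Model/Results front end for a full structure-function coupling study.

:class:`CouplingStudy` is built from a :class:`~sfcoupling.datatypes.Cohort`
plus an :class:`~sfcoupling.datatypes.AnalysisConfig`; :meth:`CouplingStudy.fit`
runs the complete analysis and returns a :class:`CouplingStudyResults`
carrying the metric tables, group contrasts, coupling maps and
coupling-cognition partial correlations, with a :meth:`summary` table in the
style of a fitted statistical model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling as _coupling
from . import inference as _inference
from . import networks as _networks
from . import topology as _topology
from .datatypes import AnalysisConfig, Cohort, ConnectivityMatrix, Modality
from .io import load_cohort, validate_cohort
from .simulate import GroundTruth, SimulationParams, generate_cohort

__all__ = ["CouplingStudy", "CouplingStudyResults"]

COGNITION_SCORES_FOR_CORRELATION = ("BNT", "STT_B", "SDMT", "AVLT")


class CouplingStudy:
    """A structure-function coupling study on a two-group cohort.

    Parameters
    ----------
    cohort
        Validated cohort with SC count matrices and BOLD series.
    config
        Analysis constants; defaults reproduce the emulated design
        (fiber threshold 3, >80% consistency, sparsity 0.01-0.40/0.01).
    ground_truth
        Optional planted-effect record (kept for scoring recovery on
        synthetic cohorts; ignored by the analysis itself).
    """

    def __init__(
        self,
        cohort: Cohort,
        config: AnalysisConfig | None = None,
        ground_truth: GroundTruth | None = None,
    ):
        violations = validate_cohort(cohort)
        if violations:
            raise ValueError("invalid cohort:\n  " + "\n  ".join(violations))
        self.cohort = cohort
        self.config = config or AnalysisConfig()
        self.ground_truth = ground_truth

    @classmethod
    def from_simulation(
        cls, params: SimulationParams | None = None, config: AnalysisConfig | None = None
    ) -> "CouplingStudy":
        cohort, truth = generate_cohort(params)
        return cls(cohort, config=config, ground_truth=truth)

    @classmethod
    def from_directory(cls, cohort_dir: str | Path, config: AnalysisConfig | None = None) -> "CouplingStudy":
        return cls(load_cohort(cohort_dir), config=config)

    # ------------------------------------------------------------------ fit

    def fit(
        self,
        functional_sigma: bool = False,
        compute_functional: bool = True,
        progress: bool = False,
    ) -> "CouplingStudyResults":
        """Run the full analysis.

        Stages: structural binarization + group-consistency mask ->
        structural topology (with null ensembles for Sigma) -> functional
        Pearson/Fisher-z matrices -> sparsity sweep + AUC -> nodal coupling
        -> covariate-adjusted group contrasts with FWE -> coupling-cognition
        partial correlations.

        ``functional_sigma=False`` (default) skips the per-level null
        ensembles of the functional sweep, whose Sigma curves are by far
        the most expensive quantity; global/nodal AUCs are unaffected.
        """
        cfg = self.config
        cohort = self.cohort
        labels = cohort.atlas_labels
        ids = cohort.subject_ids
        manifest = self._manifest_frame()

        # --- structural networks -------------------------------------------------
        binaries = {sid: _networks.binarize_sc(cohort.sc_matrices[sid], cfg.fiber_threshold) for sid in ids}
        if cfg.consistency_scope == "per_group":
            masks = [
                _networks.group_consistency_mask(
                    [binaries[s.subject_id] for s in cohort.by_group(grp)], cfg.group_consistency
                )
                for grp in ("HC", "VCI")
            ]
            combined = masks[0].mask * masks[1].mask
            mask = _networks.GroupMask(
                mask=combined, consistency=np.minimum(masks[0].consistency, masks[1].consistency),
                proportion=cfg.group_consistency,
            )
        else:
            mask = _networks.group_consistency_mask(list(binaries.values()), cfg.group_consistency)
        masked = {sid: _networks.apply_mask(b, mask) for sid, b in binaries.items()}

        struct_global_rows = []
        struct_nodal_rows = []
        for k, sid in enumerate(ids):
            nulls = _topology.NullEnsembleParams(
                n_nulls=cfg.null_count, swaps_per_edge=cfg.swaps_per_edge,
                seed=int((cfg.seed * 9973 + k) % (2**31 - 1)),
            )
            gm = _topology.global_metrics(masked[sid], nulls=nulls, cp_zero_mode=cfg.cp_zero_mode)
            nm = _topology.nodal_metrics(masked[sid])
            row = {"subject_id": sid, **gm.as_dict(), "disconnected": gm.disconnected}
            struct_global_rows.append(row)
            for i, lab in enumerate(labels):
                struct_nodal_rows.append(
                    {"subject_id": sid, "node": i, "label": lab,
                     **{name: float(vec[i]) for name, vec in nm.as_dict().items()}}
                )
        structural_global = pd.DataFrame(struct_global_rows).set_index("subject_id")
        structural_nodal = pd.DataFrame(struct_nodal_rows)

        # --- functional networks -------------------------------------------------
        grid = _networks.SparsityGrid.from_range(*cfg.sparsity_grid)
        fc_weighted: dict[str, ConnectivityMatrix] = {}
        fc_z: dict[str, ConnectivityMatrix] = {}
        functional_auc = None
        functional_nodal_auc = None
        if compute_functional:
            func_global_rows = []
            func_nodal_auc_rows = []
            for k, sid in enumerate(ids):
                r = _networks.pearson_fc(cohort.bold_series[sid], node_labels=labels)
                z, _ = _networks.fisher_z(r)
                fc_weighted[sid] = r
                fc_z[sid] = z
                level_nulls = None
                if functional_sigma:
                    level_nulls = _topology.NullEnsembleParams(
                        n_nulls=cfg.null_count, swaps_per_edge=cfg.swaps_per_edge,
                        seed=int((cfg.seed * 7919 + k) % (2**31 - 1)),
                    )
                sweep = _topology.metrics_over_sparsity(z, grid, nulls=level_nulls)
                row: dict = {"subject_id": sid}
                for name in ("Eglob", "Eloc", "Cp", "Lp", "Sigma"):
                    values = np.array([getattr(lv.global_metrics, name) for lv in sweep])
                    if np.all(np.isfinite(values)):
                        row[f"a{name}"] = _topology.auc_curve(values, grid)
                    else:
                        row[f"a{name}"] = np.nan
                func_global_rows.append(row)
                nodal_stack = {
                    name: np.vstack([lv.nodal_metrics.as_dict()[name] for lv in sweep])
                    for name in _topology.NODAL_METRIC_NAMES
                }
                for i, lab in enumerate(labels):
                    nrow = {"subject_id": sid, "node": i, "label": lab}
                    for name, stack in nodal_stack.items():
                        col = stack[:, i].astype(float)
                        nrow[f"a{name}"] = (
                            _topology.auc_curve(col, grid) if np.all(np.isfinite(col)) else np.nan
                        )
                    func_nodal_auc_rows.append(nrow)
            functional_auc = pd.DataFrame(func_global_rows).set_index("subject_id")
            functional_nodal_auc = pd.DataFrame(func_nodal_auc_rows)
        else:
            for sid in ids:
                r = _networks.pearson_fc(cohort.bold_series[sid], node_labels=labels)
                z, _ = _networks.fisher_z(r)
                fc_weighted[sid] = r
                fc_z[sid] = z

        # --- coupling ------------------------------------------------------------
        profiles = []
        for sid in ids:
            sc_for_coupling = (
                cohort.sc_matrices[sid] if cfg.coupling_sc_weighting == "count" else masked[sid]
            )
            prof = _coupling.subject_coupling(sc_for_coupling, fc_z[sid], cfg)
            prof.subject_id = sid
            profiles.append(prof)
        coupling_table = _coupling.cohort_coupling(
            profiles, labels, groups={s.subject_id: s.group for s in cohort.subjects}
        )
        coupling_by_subject = pd.DataFrame(
            {sid: p.rho for sid, p in zip(ids, profiles)}, index=range(len(labels))
        ).T

        # --- group contrasts -----------------------------------------------------
        contrasts: dict[str, pd.DataFrame] = {}
        contrasts["structural_global"] = self._contrast(
            structural_global[[c for c in ("Eglob", "Eloc", "Cp", "Lp", "Sigma")
                               if structural_global[c].notna().all()]],
            manifest, "structural_global",
        )
        for metric in _topology.NODAL_METRIC_NAMES:
            wide = structural_nodal.pivot(index="subject_id", columns="label", values=metric)
            wide = wide.loc[:, wide.nunique() > 1]
            if wide.shape[1]:
                contrasts[f"structural_nodal_{metric}"] = self._contrast(
                    wide, manifest, f"structural_nodal_{metric}"
                )
        if functional_auc is not None:
            func_cols = [c for c in functional_auc.columns if functional_auc[c].notna().all()]
            if func_cols:
                contrasts["functional_global_auc"] = self._contrast(
                    functional_auc[func_cols], manifest, "functional_global_auc"
                )
        coupling_defined = coupling_by_subject.loc[:, coupling_by_subject.notna().all()]
        coupling_defined.columns = [labels[i] for i in coupling_defined.columns]
        contrasts["coupling"] = self._contrast(coupling_defined, manifest, "coupling")

        # --- coupling-cognition partial correlations -----------------------------
        partials = self._partial_correlations(coupling_defined, manifest)

        return CouplingStudyResults(
            model=self,
            config=cfg,
            mask=mask,
            structural_global=structural_global,
            structural_nodal=structural_nodal,
            functional_auc=functional_auc,
            functional_nodal_auc=functional_nodal_auc,
            coupling_profiles=profiles,
            coupling_table=coupling_table,
            coupling_by_subject=coupling_by_subject,
            contrasts=contrasts,
            partial_correlations=partials,
        )

    # ------------------------------------------------------------ internals

    def _manifest_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.cohort.subjects:
            rows.append(
                {"subject_id": s.subject_id, "group": s.group, "age": s.age, "sex": s.sex,
                 "education": s.education, **s.cognitive_scores}
            )
        return pd.DataFrame(rows).set_index("subject_id")

    def _contrast(self, features: pd.DataFrame, manifest: pd.DataFrame, family: str) -> pd.DataFrame:
        # Constant features carry no group information and would make the
        # routed tests degenerate; drop them from the family.
        features = features.loc[:, features.nunique() > 1]
        if features.shape[1] == 0:
            return _inference.comparison_table([], family=family)
        results = _inference.compare_groups(features, manifest, self.config, family=family)
        return _inference.comparison_table(results, family=family)

    def _partial_correlations(
        self, coupling_wide: pd.DataFrame, manifest: pd.DataFrame
    ) -> pd.DataFrame:
        """Partial correlations (age/sex/education-adjusted) between nodal
        coupling and cognitive scores, FWE-corrected per score family."""
        cfg = self.config
        rows = []
        for score in COGNITION_SCORES_FOR_CORRELATION:
            if score not in manifest.columns:
                continue
            family_results = []
            for region in coupling_wide.columns:
                df = pd.concat(
                    [coupling_wide[region], manifest[[score, "age", "sex", "education", "group"]]], axis=1
                ).dropna()
                if len(df) <= 5:
                    continue
                res = _inference.partial_correlation(
                    df[region].to_numpy(float), df[score].to_numpy(float),
                    df[["age", "sex", "education"]], method="auto",
                    region=str(region), score=score,
                )
                family_results.append(res)
            m = len(family_results)
            for res in family_results:
                p_fwe = min(1.0, m * res.p_raw) if np.isfinite(res.p_raw) else np.nan
                rows.append(
                    {"region": res.region, "score": res.score, "rho_partial": res.rho_partial,
                     "p_raw": res.p_raw, "p_fwe": p_fwe, "method": res.method, "n": res.n}
                )
        return pd.DataFrame(rows, columns=["region", "score", "rho_partial", "p_raw", "p_fwe", "method", "n"])


@dataclass
class CouplingStudyResults:
    """Fitted results of a :class:`CouplingStudy`.

    Attributes hold tidy tables: per-subject global/nodal structural
    metrics, functional AUCs over the sparsity grid, per-subject nodal
    coupling, covariate-adjusted group contrasts per feature family (raw
    and FWE p-values, direction of the VCI-HC difference) and
    coupling-cognition partial correlations.
    """

    model: CouplingStudy
    config: AnalysisConfig
    mask: "_networks.GroupMask"
    structural_global: pd.DataFrame
    structural_nodal: pd.DataFrame
    functional_auc: pd.DataFrame | None
    functional_nodal_auc: pd.DataFrame | None
    coupling_profiles: list
    coupling_table: pd.DataFrame
    coupling_by_subject: pd.DataFrame
    contrasts: dict[str, pd.DataFrame]
    partial_correlations: pd.DataFrame

    def significant(self, family: str, alpha: float | None = None) -> pd.DataFrame:
        """Features of a contrast family significant after FWE correction."""
        alpha = alpha if alpha is not None else self.config.alpha
        table = self.contrasts[family]
        out = table[table["p_fwe"] <= alpha].copy()
        return out.sort_values(["p_fwe", "feature"]).reset_index(drop=True)

    def summary(self, alpha: float | None = None) -> str:
        """Human-readable study summary."""
        alpha = alpha if alpha is not None else self.config.alpha
        cohort = self.model.cohort
        n_hc = len(cohort.by_group("HC"))
        n_vci = len(cohort.by_group("VCI"))
        lines = []
        lines.append("Structure-Function Coupling Study Results")
        lines.append("=" * 57)
        lines.append(f"Subjects:            {n_hc + n_vci} ({n_vci} VCI, {n_hc} HC)")
        lines.append(f"Nodes:               {cohort.n_nodes}")
        lines.append(f"Mask edges retained: {self.mask.n_edges}")
        lines.append(f"FWE method:          {self.config.fwe_method} (alpha={alpha:g})")
        lines.append("")
        lines.append("Global structural metrics (group means and contrast)")
        lines.append("-" * 57)
        man = self.model._manifest_frame()
        sg = self.structural_global.join(man["group"])
        means = sg.groupby("group")[["Eglob", "Eloc", "Cp", "Lp", "Sigma"]].mean()
        header = f"{'metric':<8}{'HC':>10}{'VCI':>10}{'test':>14}{'p_fwe':>10}  dir"
        lines.append(header)
        glob = self.contrasts.get("structural_global")
        for metric in ("Eglob", "Eloc", "Cp", "Lp", "Sigma"):
            hc = means.loc["HC", metric] if "HC" in means.index else np.nan
            vci = means.loc["VCI", metric] if "VCI" in means.index else np.nan
            row = glob[glob["feature"] == metric] if glob is not None else None
            if row is not None and len(row):
                r = row.iloc[0]
                dir_sym = {1: "VCI>HC", -1: "VCI<HC", 0: "="}[int(r["direction"])]
                lines.append(
                    f"{metric:<8}{hc:>10.4f}{vci:>10.4f}{r['test']:>14}{r['p_fwe']:>10.4f}  {dir_sym}"
                )
            else:
                lines.append(f"{metric:<8}{hc:>10.4f}{vci:>10.4f}{'-':>14}{'-':>10}")
        lines.append("")
        for family in sorted(self.contrasts):
            if family == "structural_global":
                continue
            sig = self.significant(family, alpha)
            lines.append(f"{family}: {len(sig)} of {len(self.contrasts[family])} features significant at FWE {alpha:g}")
            for _, r in sig.head(12).iterrows():
                dir_sym = {1: "VCI>HC", -1: "VCI<HC", 0: "="}[int(r["direction"])]
                lines.append(f"    {r['feature']:<24} p_fwe={r['p_fwe']:.4g}  {dir_sym}")
            if len(sig) > 12:
                lines.append(f"    ... and {len(sig) - 12} more")
        lines.append("")
        pc = self.partial_correlations
        if len(pc):
            sig_pc = pc[pc["p_fwe"] <= alpha].sort_values(["p_fwe", "region"])
            lines.append(
                f"Coupling-cognition partial correlations: {len(sig_pc)} of {len(pc)} significant at FWE {alpha:g}"
            )
            for _, r in sig_pc.head(12).iterrows():
                lines.append(
                    f"    {r['region']:<20} x {r['score']:<7} rho={r['rho_partial']:+.3f}  p_fwe={r['p_fwe']:.4g}"
                )
        return "\n".join(lines)

    # ------------------------------------------------------------ plotting

    def plot_coupling_profile(self, ax=None):
        """Bar plot of cohort-mean nodal coupling by group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(12, 3))
        t = self.coupling_table
        ax.plot(t["node"], t.get("mean_rho_HC", t["mean_rho"]), label="HC", lw=1)
        if "mean_rho_VCI" in t:
            ax.plot(t["node"], t["mean_rho_VCI"], label="VCI", lw=1)
        ax.set_xlabel("node")
        ax.set_ylabel("mean Spearman rho")
        ax.legend()
        return ax

    def plot_structural_metrics(self, ax=None):
        """Group box plots of the global structural metrics."""
        import matplotlib.pyplot as plt

        man = self.model._manifest_frame()
        sg = self.structural_global.join(man["group"])
        metrics = ["Eglob", "Eloc", "Cp"]
        if ax is None:
            _, ax = plt.subplots(1, len(metrics), figsize=(3 * len(metrics), 3))
        axes = np.atleast_1d(ax)
        for a, metric in zip(axes, metrics):
            data = [sg.loc[sg["group"] == g, metric].dropna() for g in ("HC", "VCI")]
            a.boxplot(data, tick_labels=["HC", "VCI"])
            a.set_title(metric)
        return axes
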