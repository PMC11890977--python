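# sfcoupling

Structure–function coupling analysis of brain connectomes for two-group
case–control studies — here, vascular cognitive impairment (VCI) versus
healthy controls (HC).

Cerebrovascular disease damages white-matter pathways; whether and how the
brain's functional organization tracks that structural damage is captured
by *structure–function coupling*: for each of 90 AAL parcels, the Spearman
rank correlation between the node's structural connectivity profile
(streamline counts to every other node) and its functional connectivity
profile (Fisher-z Pearson correlations of regional BOLD time series),
evaluated at the entries where structural connections exist, then averaged
over the cohort.  The package implements the full analysis around that
statistic:

- **Network construction** — structural: binarize streamline counts at a
  fiber threshold (default ≥ 3) and keep edges present in strictly more
  than 80% of subjects; functional: Pearson → Fisher z → binary graphs
  over a sparsity grid (0.01–0.40, step 0.01).
- **Graph topology battery** — global efficiency `Eglob`, local
  efficiency `Eloc`, clustering `Cp`, characteristic path length `Lp`,
  small-worldness `Sigma = (Cp/⟨Cp_null⟩)/(Lp/⟨Lp_null⟩)` against
  Maslov–Sneppen degree-preserving nulls; nodal degree, betweenness,
  `NEglob`, `NEloc`, `NCp`, `NLp`; sparsity-curve areas (AUC) for the
  functional sweep.
- **Nodal SC–FC coupling** — per-node Spearman ρ as above, with cohort and
  per-group summaries.
- **Group inference** — every feature residualized on age, sex and
  education; Shapiro–Wilk-routed two-sample tests (t vs Mann–Whitney U,
  χ² for categoricals), two-tailed; family-wise error control by
  max-statistic label permutation (Westfall–Young) or Bonferroni; partial
  correlations between nodal coupling and cognitive scores (AVLT, SDMT,
  STT_B, BNT).
- **Synthetic cohort generator** — seeded cohorts (default 68 VCI + 53 HC,
  90 nodes, 200 BOLD volumes) with planted structural deficits, elevated
  coupling at designated regions, and cognition tied negatively to that
  coupling, so the whole pipeline is testable without any imaging data.

## Worked example

```python
import sfcoupling as sf

params = sf.SimulationParams(n_hc=30, n_vci=30, n_timepoints=500, seed=101)
config = sf.AnalysisConfig(null_count=20, permutations=500, min_coupling_pairs=5)
study = sf.CouplingStudy.from_simulation(params, config)
results = study.fit()
print(results.summary())
```

prints (abridged):

```
Structure-Function Coupling Study Results
=========================================================
Subjects:            60 (30 VCI, 30 HC)
Nodes:               90
Mask edges retained: 508
FWE method:          permutation_maxT (alpha=0.05)

Global structural metrics (group means and contrast)
---------------------------------------------------------
metric          HC       VCI          test     p_fwe  dir
Eglob       0.4726    0.4718             t    0.1737  VCI<HC
Eloc        0.5575    0.5566             t    0.9421  VCI<HC
Cp          0.3504    0.3487  mann_whitney    0.6168  VCI<HC
Lp          2.4328    2.4370             t    0.4551  VCI>HC
Sigma       2.7748    2.7965             t    0.4331  VCI>HC

coupling: 10 of 90 features significant at FWE 0.05
    Calcarine_L              p_fwe=0.001996  VCI>HC
    Calcarine_R              p_fwe=0.001996  VCI>HC
    Fusiform_L               p_fwe=0.001996  VCI>HC
    ...
structural_nodal_degree: 1 of 90 features significant at FWE 0.05
    Cingulum_Post_R          p_fwe=0.007984  VCI<HC

Coupling-cognition partial correlations: 3 of 360 significant at FWE 0.05
    Temporal_Mid_R       x AVLT    rho=-0.559  p_fwe=0.0005635
    Calcarine_L          x AVLT    rho=-0.459  p_fwe=0.03008
    Fusiform_L           x SDMT    rho=-0.444  p_fwe=0.04873
```

The coupling contrast recovers all ten planted boost regions (bilateral
calcarine, lingual, fusiform, superior and middle temporal cortex) with
the VCI > HC direction; the planted structural deficit surfaces in the
nodal degree and efficiency contrasts (right posterior cingulate,
VCI < HC), and coupling at boost regions correlates negatively with
memory (AVLT) and processing speed (SDMT) after adjusting for age, sex
and education.  `results.contrasts` holds one tidy table per feature family
(statistic, raw and FWE p-values, direction), `results.coupling_table`
the per-node cohort means, and `results.partial_correlations` the
coupling × cognition table.

The same analysis runs from the shell on directories of plain-text
matrices:

```bash
sfcoupling run-all --config config.yaml --out-dir out/ --seed 1
```

with stages (`simulate`, `build`, `topology`, `coupling`, `stats`,
`correlate`, `report`) also invocable individually on each other's file
outputs.  `out/report.json` / `report.md` summarize significant features
per family, and `out/run_record.json` hashes every output: reruns with
the same config and seed are byte-identical.

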