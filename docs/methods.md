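# Methods

## The analysis

The package studies how closely a brain region's functional connectivity
follows its structural wiring, and whether that coupling differs between
vascular cognitive impairment (VCI) patients and healthy controls (HC).

**Structural networks.** Each subject contributes a 90×90 streamline-count
matrix on the AAL cerebral parcellation. An edge exists when the count
reaches the fiber threshold (default 3); spurious connections are further
suppressed by a group-consistency mask that keeps an edge only when it is
present in *strictly more than* a given proportion of subjects (default
0.8 — the strict inequality reads "over 80%" literally; both the
proportion and whether the mask pools all subjects or is built per group
and intersected are configurable). Structural topology is computed once on
the masked binary network; an optional sparsity sweep of the structural
matrices is available but not the default, since a single thresholded
network is the conventional treatment of deterministic tractography
counts.

**Functional networks.** Regional BOLD series (default 200 volumes) give
Pearson correlation matrices, Fisher z-transformed (arctanh; |r| ≥ 1−1e−7
is clipped and the clip count reported). Binary graphs are formed at each
level of a sparsity grid (default 0.01–0.40, step 0.01, 40 levels) by
keeping the `floor(s·N(N−1)/2)` largest strictly positive weights.
Negative and zero correlations never become edges — the binary small-world
battery presumes meaningful edges, and discarding negative weights is the
dominant convention for sparsity-thresholded FC graphs. Ties at the cutoff
break by ascending (i, j) order, which makes the graphs bit-reproducible
and the edge sets nested across sparsity levels; since arctanh is strictly
monotone, binarization before or after the z-transform is provably
identical (tested).

**Topology battery.** Standard binary-undirected definitions (Rubinov &
Sporns 2010): Eglob is the mean inverse shortest-path length over ordered
pairs (1/∞ = 0); nodal NEglob the per-node analogue; C_i =
(edges among neighbors)/(k_i choose 2) with C_i = 0 for degree < 2 (an
exclude-mode for Cp is config-exposed); Eloc/NEloc the global efficiency
of each node's neighbor-induced subgraph; Lp the mean over *finite* pairs
with an explicit disconnection flag (rather than ∞ or a harmonic
substitute — this keeps the low-sparsity end of the sweep computable
while surfacing disconnection); betweenness is exact (Brandes), reported
both raw and normalized by (N−1)(N−2)/2. Sigma =
(Cp/⟨Cp_null⟩)/(Lp/⟨Lp_null⟩) over a Maslov–Sneppen ensemble: each null
attempts `swaps_per_edge·E` double-edge swaps (default 10·E), rejecting
self-loops and multi-edges, with the degree sequence asserted exactly;
defaults are 100 nulls per network, seeded per subject (and per sparsity
level in the functional sweep). On a complete graph no legal swap exists,
the ensemble equals the input, and Sigma = 1 — a useful fixed point.
Sparsity curves are summarized by the trapezoidal AUC over the grid
domain; undefined levels are an error listing the offending levels, never
a silent omission.

**Coupling.** For node i, take column i of the subject's SC matrix and of
the weighted (pre-threshold) Fisher-z FC matrix, drop the self-entry,
select the indices where the SC entry is non-zero, and compute Spearman ρ
with average ranks. ρ is flagged undefined (never imputed as 0) when
fewer than `min_coupling_pairs` (default 10) entries survive or a
selected vector is constant. Design choices, each config-exposed:

- SC profile defaults to streamline *counts*: Spearman against an
  all-ones binary profile is degenerate, so binary weighting is retained
  only for sensitivity analysis.
- Selection defaults to SC-nonzero entries; requiring both profiles
  non-zero is selectable but generically identical, since FC entries are
  almost surely non-zero.
- FC comes from the weighted z-matrix, not the binarized graphs: the
  statistic concerns graded connectivity profiles.

Cohort summaries average defined values per node and report the number of
contributing subjects.

**Inference.** Features (global structural metrics, nodal structural
metrics, functional AUCs, nodal coupling) are residualized on
[intercept, age, sex, education] by OLS; the residuals are routed by
Shapiro–Wilk (both groups p > 0.05 → pooled-variance t-test, otherwise
Mann–Whitney U; categoricals → Pearson χ²), two-tailed. Family-wise error
is controlled per feature family, either by Bonferroni or (default) by a
max-statistic label permutation: group labels are permuted within the
residualized matrix, the maximum |t| over the family is recorded per
permutation, and each feature's p_fwe is the add-one exceedance
probability, floored at its raw p so p_fwe ≥ p_raw always. The
permutation statistic is the pooled-variance |t| on covariate residuals
for every feature — a max-statistic family needs a common scale, so the
routed per-feature test determines p_raw while the t statistic drives the
correction; a rank-based variant (|t| on rank-transformed residuals,
invariant to monotone feature rescaling) is exposed. Partial correlations
between nodal coupling and cognition correlate the covariate residuals of
both variables (rank-transformed first for the Spearman variant, which is
routed by normality like the group tests; both variants are always
computed and stored), with p from the t approximation on n−5 degrees of
freedom and Bonferroni FWE within each score family. Missing cognitive
scores are excluded pairwise and reflected in the reported n.

## The synthetic cohort generator

No imaging data ship with the package; a seeded generator emulates the
study design so every stage is testable end-to-end.

**Structure.** A Watts–Strogatz backbone (default k = 16, rewiring
p = 0.1; density ≈ 0.18, matching typical thresholded 90-node structural
connectomes) carries lognormal edge weights (median `count_scale` = 12,
log-sd 1.0 — streamline counts are heavy-tailed). Subjects draw
negative-binomial counts per edge (mean = template weight, dispersion
r = 3, variance μ + μ²/r: overdispersed non-negative integers). The VCI
template multiplies weights on edges incident to the designated deficit
nodes by (1 − `vci_structural_deficit`), default 0.3, lowering counts,
binary degree and efficiency there. Default deficit regions are posterior
cingulate, precuneus and putamen bilaterally plus right cuneus,
middle-occipital, superior-parietal and postcentral nodes — default-mode
and sensorimotor territory.

**Function.** BOLD is multivariate normal with covariance
Σ = M∘SCⁿ + (1−M)∘R, unit diagonal, where SCⁿ is the count matrix scaled
to unit maximum and raised to the power ½, R is a per-subject random
correlation matrix (Wishart-style, the "decoupled" component), and
M_ij = max(m_i, m_j) maps per-node mixing weights m to edges. A diagonal
ridge is escalated geometrically (1e−4, doubling) until the smallest
eigenvalue exceeds 1e−6; if a cap of 10 is reached the generator fails
loudly with the offending eigenvalue. Two deliberate choices:

- the square-root compression of SCⁿ is strictly monotone — it preserves
  exactly the rank structure the Spearman estimator assumes — while
  keeping the covariance gaps between weak connections above the
  ~1/√T sampling noise of empirical correlations, so planted coupling is
  recoverable at realistic series lengths;
- the max-blend gives a node's entire profile its own mixing weight, so a
  planted per-node coupling level is expressed on every incident edge
  instead of being halved on edges to unboosted partners. The cost is
  mild spillover onto neighbors of boosted nodes, visible as occasional
  extra significant nodes in recovery experiments.

HC subjects receive m = `coupling_base` (0.35) everywhere; VCI subjects
additionally get `coupling_boost` (0.3) at the designated boost nodes
(bilateral calcarine, lingual, fusiform, superior and middle temporal
cortex — visual/temporal territory).

**Cognition and covariates.** AVLT and SDMT decline linearly in the
subject's mean true mixing over the boost nodes (slope
`cognition_effect` = −30, residual sd scaled from `noise_sd` = 7); MMSE,
AVLT_N5, STT_B and BNT have null coupling slopes. All scores carry mild
age/education terms, and intercepts place the group means near a
realistic elderly VCI/HC cohort (e.g. AVLT ≈ 31 vs 22, SDMT ≈ 40 vs 27).
Age ~ N(68, 6) truncated to [50, 75], education ~ rounded N(10.5, 2.5),
sex ~ Bernoulli(0.44 male). Effect sizes are chosen for estimator
testability, not to reproduce any particular published magnitude.

**Determinism.** All randomness flows through
`numpy.random.SeedSequence(seed)` substreams (one per subject);
regenerating a cohort is byte-identical, and the pipeline run record
hashes every output file to make this checkable end-to-end.

**What the generator does not emulate.** Hemodynamics and autocorrelated
BOLD noise, spatial geometry and distance-dependent connectivity,
head-motion artifacts, scanner drift, and tractography biases. Passing
tests therefore demonstrate that the *estimators and inference machinery*
behave correctly under a faithful statistical abstraction of the design —
not that the pipeline is robust to every artifact of real imaging data.

## Numerical and degenerate-input choices

- Input matrices must be symmetric within 1e−10 (count matrices are
  symmetric by construction, so worse asymmetry signals corrupt input);
  they are symmetrized by averaging, and nonzero diagonals are zeroed
  with a warning.
- Graphs with fewer than 3 nodes are rejected for global metrics;
  isolated nodes get NLp = NaN with a flag; all-identical feature values
  in both groups are a degenerate-input error naming the feature.
- Shapiro–Wilk on constant or n < 3 samples counts as non-normal
  (routing falls through to Mann–Whitney).
- maxT p-values use the add-one estimator (1 + exceedances)/(perms + 1),
  so they are never zero and never below 1/(perms + 1).

## Problem sizes used in tests and the acceptance script

Oracle equivalence uses 200 Erdős–Rényi graphs with n ∈ [5, 12] against
Floyd–Warshall / exhaustive-enumeration oracles. Small-world calibration
uses 20 ER graphs (n = 90, density 0.15) and 20 Watts–Strogatz graphs
(k = 10, p = 0.05) with 50 nulls each. Coupling separation compares fully
coupled vs decoupled subjects at T = 2000. Error control uses 200 global-
null simulations × 500 permutations × 90 features at n = 30/30; planted
recovery one cohort (boost 0.3, T = 500, n = 30/30) scored against ground
truth, and power monotonicity 10 cohorts per boost level in
{0.1, 0.2, 0.3} (5 in the acceptance script) with 300 permutations each.
The reproducibility check runs the full pipeline twice on a 25-node,
8-subject cohort. These sizes are the package's own trade-off between
statistical resolution and a test suite that runs in a few minutes on one
core.

## Known limitations

- The mask-then-analyze structural pipeline assumes a shared node order
  and a single site; no harmonization is provided.
- Sigma on very sparse or disconnected graphs is flagged rather than
  extrapolated; AUC refuses families containing undefined levels, so
  functional Sigma AUCs require nulls at every level (off by default for
  runtime).
- Partial-correlation p-values use the t approximation, adequate at the
  cohort sizes simulated here but approximate for very small n.
- The generator's group difference in functional *topology* is incidental
  (it inherits only weak structure differences), mirroring a design in
  which functional topology shows no group effect; it is not a planted
  null in the strict sense.
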