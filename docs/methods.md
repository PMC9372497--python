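# Methods

## The procedure

`netfuse` treats a cognitive network (say, the fronto-parietal network)
as a *concept* with several concrete *instances*, one per brain atlas.
The method asks: which instance, and then which enlargement of it, best
separates two or more cognitive states when summarised by a graph
property of its functional-connectivity graph?

**Combined network.** Instances are first clipped to a common anatomical
boundary — by default the frontal and parietal lobes, the conventional
extent of the FPN — and concatenated. No deduplication is performed:
an MNI coordinate shared by two atlases denotes two ROIs, because each
carries its own atlas's definitional context. ROI identity is
`(source_atlas, roi_id)` throughout. Clipping that would empty an
instance is an error rather than a silent drop.

**Connectivity.** For each condition × subject cell, the ROI time series
(assumed preprocessed; no motion correction, filtering or nuisance
regression is attempted here) yield a Pearson correlation matrix and
two-sided p-values from the exact t-distribution null with t − 2 degrees
of freedom. Edges are then screened per matrix by Benjamini–Hochberg FDR
over the n(n−1)/2 upper-triangle p-values at q = 0.05 (configurable).
Correlations are not Fisher-z transformed and FDR is per-matrix, not
pooled across subjects; both choices are deliberate and recorded in the
run configuration. By default only positive significant correlations
become edges (the common convention for binary connectomes); an
`absolute` mode keeps both signs. A zero-variance ROI time series is
tolerated: its edges get r = 0, p = 1, and a logged warning, so one flat
channel cannot abort a group run.

**Graph property.** The default metric is degree centrality. For a
multi-ROI candidate the score of a slice is the mean of deg(v)/(k − 1)
over the subgraph *induced* by the candidate's k ROIs — so a candidate's
value does not depend on ROIs outside it. For a single ROI (used when
ranking supplementary ROIs) the nodal degree centrality is computed in
the *full* combined-network graph, normalised by |CCN| − 1 — the only
meaningful scope for a lone node. Which scope a multi-node evaluation
should use is genuinely ambiguous in this family of methods; the
induced-subgraph reading was chosen for its independence property, and
both code paths are explicit (`subset_property` vs `nodal_property`).
Clustering coefficient and global efficiency (mean inverse shortest-path
length) are available behind the same interface; degree is the default
because it is the standard choice for state discrimination.

**Discriminability.** A candidate's per-subject property values form a
|conditions| × |subjects| matrix. With two conditions the rows are
compared by a two-sided t-test — *paired* by default, since designs of
this kind measure every subject under every condition; an unpaired flag
exists. With more than two conditions a one-way ANOVA is used
(repeated-measures ANOVA is out of scope). Degenerate inputs are given
limits rather than NaNs: all values identical → p = 1 (with a warning);
paired differences constant but nonzero → p = 0. Candidate p-values are
used raw for ranking — deliberately no multiple-testing correction
across candidates, since the p-value serves as an ordering score, not an
inference.

**Selection and fusion.** The instance with the minimum p-value becomes
the main network (ties broken by input order, making the step
deterministic). All other instances' ROIs are sorted ascending by nodal
p-value with a stable sort; constant-property ROIs sort to the end at
p = 1. Fusion evaluates main ∪ prefix(supp, i) for i = 0 … |supp| and
takes the first-occurrence argmin. Including i = 0 guarantees
fused_p ≤ main_p. The greedy search is over prefixes only — no general
subset optimisation — and an externally produced ranking (e.g. a tree
ensemble's feature importances) can be passed in place of the nodal
ordering via `fuse(..., supp_order=...)`.

## Synthetic data

No suitable public dataset ships with the package, so validation runs on
a planted-subnetwork Gaussian model. ROI time series are zero-mean
multivariate normal with correlation

- `base_corr + effect` between planted ROIs under condition 1,
- `base_corr` between planted ROIs under other conditions,
- `0.5 * base_corr` between all other pairs,

plus symmetric per-subject jitter (sd `subject_sd`) on every off-diagonal
entry, shared across a subject's conditions so that paired tests see
within-subject correlation, as real repeated measures would. Jittered
matrices are projected to the nearest positive-semidefinite correlation
matrix (eigenvalue clipping at 1e-6, diagonal renormalisation) before
Cholesky sampling; a base target that is not PSD is an error reporting
the offending eigenvalue. Everything is reproducible from one seed.

Defaults mirror a two-condition, 21-subject study over a 72-ROI combined
network built from four instances of 10/21/24/17 ROIs (frontal/parietal
6+4, 13+8, 17+7, 11+6), with t = 180 time points. The correlation levels
— base 0.25, effect +0.30, background 0.125, jitter sd 0.05 — were chosen
once as representative of task-fMRI functional connectivity: within-network
edges in the 0.2–0.6 range, a strong task modulation, weaker diffuse
background coupling. With these values, planted edges are almost always
FDR-significant under the boosted condition and only intermittently under
the baseline condition, so the planted instance's degree centrality
separates the conditions sharply — the regime the method is designed for.

The generator emulates the *structure* the pipeline consumes, not the
physiology: there is no hemodynamic response, no temporal
autocorrelation, no motion or physiological artifacts, and the planted
effect is exactly block-shaped. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated model,
not robustness to realistic fMRI noise.

## Problem sizes used in tests

The test and acceptance studies run a proportionally reduced design —
4 instances of 4/7/8/5 ROIs (24 total), 8 subjects, t = 60 — which
preserves every qualitative feature of the full-scale layout while
keeping simulation studies (1000 null replicates, 100 recovery
replicates, 50 oracle-equivalence stacks) fast. Full-scale runs
(2 × 21 × 72, t = 180) are exercised once in the fused-size arithmetic
check.

Observed behaviour at the reduced scale: the planted instance is selected
essentially always under the default effect; the type-I error of the
candidate score under a null (effect = 0) design sits at the nominal 5%;
and when planted ROIs extend into the supplementary list the priority
ranking recovers them at the top (top-k recall ≈ 1.0) even though the
greedy argmin — faithfully — sometimes stops before absorbing all of
them, because the main network alone already achieves a very small
p-value.

## Numerical choices

- Pearson p-values use the regularised incomplete beta identity
  2·T₍df₎.sf(|t|) = I₁₋ᵣ²(df/2, 1/2), matching `scipy.stats.pearsonr`
  to machine precision while vectorising over all edges.
- BH-FDR delegates to `statsmodels.stats.multitest.multipletests`
  (`fdr_bh`); tests verify it against the step-up definition directly.
- Ties in any argmin resolve to the first occurrence; sorts are stable.
  Given identical inputs and configuration the entire pipeline is
  deterministic — the only randomness in the package is the generator's.
- Correlation matrices are symmetrised after computation to remove
  floating-point asymmetry; container types validate symmetry, unit
  diagonal and value ranges on construction.
- NIfTI spherical extraction includes voxels at world-space distance
  ≤ radius (default 5 mm) from the ROI centre; an empty sphere is an
  error naming the ROI.

## Limitations

- Repeated-measures ANOVA, non-parametric tests and the χ² alternative
  for two conditions are not implemented; property values here are
  continuous and the t/F families cover the supported designs.
- Weighted-graph metrics, community structure and small-world statistics
  are out of scope.
- Instances are point/sphere ROI sets; label-volume parcellations and
  automatic lobe inference from coordinates are not supported.
- The per-matrix FDR scope and the absence of Fisher-z transformation
  are fixed conventions, flagged in output metadata rather than
  configurable.
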