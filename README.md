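# netfuse

Multi-atlas cognitive-network fusion by graph-metric discriminability.

Cognitive networks such as the fronto-parietal network (FPN) are defined
differently by every brain atlas: AAL gives it 10 regions, Dosenbach-160
gives 21 ROIs, Power-264 gives 25, Willard-499's executive control network
has 24. Analyses built on any single definition see only one slice of the
network. `netfuse` implements a principled fusion of these competing
definitions, driven by how well each candidate ROI set discriminates
cognitive states in task fMRI:

1. **Combine.** Clip each atlas instance to a common lobe boundary
   (frontal + parietal by default) and concatenate them into one combined
   network *CCN* = CN₁ ∪ CN₂ ∪ … ∪ CNₖ. ROIs from different atlases stay
   distinct even at identical MNI coordinates; identity is
   (atlas, roi_id), never the coordinates.
2. **Connect.** For every condition *c* and subject *s*, compute the
   Pearson functional-connectivity matrix over the CCN's ROI time series,
   with two-sided edge p-values, and threshold the edges with
   Benjamini–Hochberg FDR (q = 0.05, positive edges by default) into a
   binary graph G<sub>c,s</sub>.
3. **Select.** Score every instance by the p-value of a two-sided paired
   t-test (ANOVA for > 2 conditions) comparing its per-subject graph
   property — mean degree centrality deg(v)/(k−1) on the induced subgraph —
   across conditions. The minimum-p instance becomes the **main** network;
   all other ROIs are ranked ascending by the same test applied to their
   nodal degree centrality in the full CCN graph, forming the
   supplementary priority list.
4. **Fuse.** Grow candidate networks main ∪ prefix(supp, i) for
   i = 0 … |supp|, score each, and keep the minimum-p prefix: the **fused**
   network. Because i = 0 is in the search set, the fused network is never
   worse than the main network alone.

The statistical machinery (Pearson r and p, BH-FDR, t-test/ANOVA, graph
metrics) rides on numpy/scipy/statsmodels/networkx; the selection and
fusion algorithms, the 4-D connectivity container, and a planted-subnetwork
simulator for validation are implemented here.

## Worked example

Real fMRI inputs are ROI tables (TSV: `roi_id name x y z lobe network
atlas`) plus per-cell time-series tables (`{condition}__{subject}.tsv`) or
4-D NIfTI volumes for spherical extraction. The built-in simulator
generates the same formats with a known planted subnetwork, so the full
pipeline can be demonstrated without data:

```python
from netfuse import (PlantedDesign, REDUCED_LAYOUT, generate_stack,
                     select_main, fuse, evaluate_recovery)

design = PlantedDesign(layout=REDUCED_LAYOUT, n_subjects=8, t=60,
                       extra_planted=3, seed=7)
instances, ccn, stack = generate_stack(design)
selection = select_main(stack, instances)
result = fuse(stack, selection)
print(selection.instance_pvalues)
print(result.fused_index, len(result.fused_rois), result.fused_pvalue)
print(evaluate_recovery(selection, result, design))
```

prints

```
{'atlas1': 0.000212, 'atlas2': 2.92e-06, 'atlas3': 0.222, 'atlas4': 0.598}
1 8 2.13e-07
{'n_planted': 10, 'fused_precision': 1.0, 'fused_recall': 0.8,
 'supp_topk_recall': 1.0, 'main_is_planted_instance': True}
```

`atlas2` — the instance carrying the planted condition effect — wins the
selection with p ≈ 2.9 × 10⁻⁶; the greedy search absorbs one top-priority
supplementary ROI (fused index 1, 8 ROIs total) and improves the
discriminability to p ≈ 2.1 × 10⁻⁷, an order of magnitude better than the
main network alone. Recovery metrics confirm that everything in the fused
network is planted (precision 1.0) and the priority ranking put all
eligible planted ROIs at the top (top-k recall 1.0).

The same pipeline is scriptable from the shell:

```sh
netfuse simulate --reduced --seed 7 --out sim/
netfuse combine --atlas-table sim/atlas_table.tsv --out combined.tsv
netfuse fuse --atlas-table sim/atlas_table.tsv \
             --timeseries-dir sim/timeseries --out report.json
netfuse report --report-json report.json --out-dir tables/
```

## Layout

- `netfuse.atlas_model` — ROI/instance/combined-network types, atlas-table
  IO, lobe clipping, combination
- `netfuse.connectivity` — Pearson FC with p-values, BH-FDR edge masks,
  the 4-D condition stack, NIfTI spherical extraction, TSV/HDF5 IO
- `netfuse.graph_metrics` — binary graphs, degree centrality, clustering,
  global efficiency (induced-subgraph and nodal scopes)
- `netfuse.stats_tests` — the t-test/ANOVA discriminability dispatcher and
  candidate scoring
- `netfuse.fusion` — main-network selection, supplementary prioritisation,
  greedy prefix fusion, reporting
- `netfuse.synthetic_data` — the planted-subnetwork generator and recovery
  metrics
- `netfuse.cli` — the `netfuse` command

See `docs/methods.md` for the model, its assumptions, parameter defaults
and limitations.
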