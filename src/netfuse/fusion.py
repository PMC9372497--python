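"""Main-network selection, ROI prioritisation and greedy network fusion.

Stage one scores every atlas instance of the network by the
discriminability of its induced-subgraph property across conditions and
selects the minimum-p instance as the *main* network; the remaining
instances' ROIs are ranked into a priority list by their nodal
discriminability.  Stage two grows candidate networks by prefixes of that
priority list — main alone, main + 1 ROI, main + 2 ROIs, ... — scores each
prefix, and keeps the minimum-p prefix as the *fused* network.

The prefix of length zero (main network alone) is part of the search, so
the fused network is never worse than the main network it started from.
Ties in p-values are broken by first occurrence, making both stages fully
deterministic.  An externally produced ROI ranking (e.g. a tree-ensemble
feature importance) can be substituted for the nodal-p ordering.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .atlas_model import NetworkInstance
from .config import FusionConfig
from .connectivity import ConditionStack
from .stats_tests import discriminability, index_matrix, score_candidate

__all__ = ["SelectionResult", "FusionResult", "select_main", "fuse",
           "report"]


@dataclass
class SelectionResult:
    """Outcome of main-network selection and supplementary-ROI ranking."""

    main_instance: str
    main_rois: list[str]  # qualified ids, instance order (non-priority)
    supp_rois: list[str]  # qualified ids, ascending nodal p (priority)
    instance_pvalues: dict[str, float]
    roi_pvalues: dict[str, float]
    config: FusionConfig = field(default_factory=FusionConfig)

    def __post_init__(self) -> None:
        if set(self.main_rois) & set(self.supp_rois):
            raise ValueError("main and supplementary ROI sets overlap")

    def to_dict(self) -> dict:
        return {
            "main_instance": self.main_instance,
            "main_rois": list(self.main_rois),
            "supp_rois": list(self.supp_rois),
            "instance_pvalues": dict(self.instance_pvalues),
            "roi_pvalues": dict(self.roi_pvalues),
            "config": self.config.to_dict(),
        }


@dataclass
class FusionResult:
    """Outcome of the greedy prefix search.

    ``pvalue_trace[i]`` is the p-value of main + the first ``i``
    supplementary ROIs; ``fused_index`` is the first-occurrence argmin.
    """

    fused_rois: list[str]
    fused_index: int
    pvalue_trace: list[float]
    fused_pvalue: float

    def __post_init__(self) -> None:
        if self.fused_index < 0 or self.fused_index >= len(self.pvalue_trace):
            raise ValueError("fused_index outside trace")
        if not math.isclose(
            self.fused_pvalue, min(self.pvalue_trace), rel_tol=0, abs_tol=0
        ):
            raise ValueError("fused_pvalue must equal min(pvalue_trace)")

    def to_dict(self) -> dict:
        return {
            "fused_rois": list(self.fused_rois),
            "fused_index": self.fused_index,
            "pvalue_trace": list(self.pvalue_trace),
            "fused_pvalue": self.fused_pvalue,
        }


def select_main(
    stack: ConditionStack,
    instances: Sequence[NetworkInstance],
    cfg: FusionConfig | None = None,
) -> SelectionResult:
    """Choose the main instance and priority-rank the remaining ROIs.

    Every instance's ROIs must be present in the stack.  The instance with
    the minimum discriminability p-value wins (first wins on ties).  The
    other instances' ROIs are sorted ascending by their nodal p-value with
    a stable sort, so equal-p ROIs keep combined order; ROIs whose nodal
    property is degenerate across subjects sort to the end with p = 1.
    """
    if not instances:
        raise ValueError("need at least one instance")
    cfg = cfg or FusionConfig()
    present = set(stack.qualified_ids)
    seen: set[str] = set()
    for inst in instances:
        missing = [q for q in inst.qualified_ids if q not in present]
        if missing:
            raise ValueError(
                f"instance {inst.instance_name!r} has ROIs absent from the "
                f"stack: {missing}"
            )
        overlap = seen & set(inst.qualified_ids)
        if overlap:
            raise ValueError(
                f"instances share ROI identities: {sorted(overlap)[:3]}..."
            )
        seen |= set(inst.qualified_ids)

    instance_pvalues: dict[str, float] = {}
    for inst in instances:
        instance_pvalues[inst.instance_name] = score_candidate(
            stack, inst.qualified_ids, cfg
        )
    best = min(
        range(len(instances)),
        key=lambda i: instance_pvalues[instances[i].instance_name],
    )  # min() keeps the first index on ties
    main = instances[best]

    supp_unsorted: list[str] = []
    for i, inst in enumerate(instances):
        if i != best:
            supp_unsorted.extend(inst.qualified_ids)

    roi_pvalues: dict[str, float] = {}
    for qid in supp_unsorted:
        # degenerate (constant-everywhere) nodal properties come back as
        # p = 1 from discriminability and hence sort to the end
        m = index_matrix(stack, [qid], cfg)
        roi_pvalues[qid] = discriminability(m, cfg.paired)
    supp_sorted = sorted(supp_unsorted, key=lambda q: roi_pvalues[q])

    return SelectionResult(
        main_instance=main.instance_name,
        main_rois=main.qualified_ids,
        supp_rois=supp_sorted,
        instance_pvalues=instance_pvalues,
        roi_pvalues=roi_pvalues,
        config=cfg,
    )


def fuse(
    stack: ConditionStack,
    selection: SelectionResult,
    cfg: FusionConfig | None = None,
    supp_order: Sequence[str] | None = None,
    fixed_index: int | None = None,
) -> FusionResult:
    """Greedy prefix search over the supplementary priority list.

    Evaluates main + first ``i`` supplementary ROIs for
    ``i = 0..|supp_rois|`` and keeps the minimum-p prefix (first wins on
    ties).  ``supp_order`` substitutes an externally ranked ROI list (a
    permutation of the selection's supplementary ROIs); ``fixed_index``
    skips the argmin and fuses exactly that prefix length (the trace is
    still evaluated in full).
    """
    cfg = cfg or (selection.config if selection.config else FusionConfig())
    supp = list(supp_order) if supp_order is not None else list(
        selection.supp_rois
    )
    if supp_order is not None and sorted(supp) != sorted(selection.supp_rois):
        raise ValueError(
            "supp_order must be a permutation of selection.supp_rois"
        )

    trace: list[float] = []
    for i in range(len(supp) + 1):
        candidate = list(selection.main_rois) + supp[:i]
        trace.append(score_candidate(stack, candidate, cfg))

    if fixed_index is None:
        fused_index = int(np.argmin(trace))  # first occurrence
    else:
        if not 0 <= fixed_index <= len(supp):
            raise ValueError(
                f"fixed_index must be in [0, {len(supp)}], got {fixed_index}"
            )
        fused_index = int(fixed_index)
    fused_rois = list(selection.main_rois) + supp[:fused_index]
    return FusionResult(
        fused_rois=fused_rois,
        fused_index=fused_index,
        pvalue_trace=trace,
        fused_pvalue=min(trace),
    )


def report(
    selection: SelectionResult,
    fusion: FusionResult,
    stack: ConditionStack,
) -> dict:
    """Machine-readable run report (JSON-serialisable).

    Includes per-instance p-values, the supplementary priority table with
    atlas/lobe provenance, the fusion p-value trace, per-condition mean
    property of the fused network, and the fused composition broken down by
    source atlas and by lobe.
    """
    roi_by_qid = {r.qualified_id: r for r in stack.rois}
    priority_table = [
        {
            "rank": rank,
            "roi": qid,
            "atlas": roi_by_qid[qid].source_atlas,
            "lobe": roi_by_qid[qid].lobe,
            "name": roi_by_qid[qid].name,
            "pvalue": selection.roi_pvalues[qid],
        }
        for rank, qid in enumerate(selection.supp_rois)
    ]
    by_atlas: dict[str, int] = {}
    by_lobe: dict[str, int] = {}
    for qid in fusion.fused_rois:
        roi = roi_by_qid[qid]
        by_atlas[roi.source_atlas] = by_atlas.get(roi.source_atlas, 0) + 1
        by_lobe[roi.lobe] = by_lobe.get(roi.lobe, 0) + 1
    fused_means = index_matrix(
        stack, fusion.fused_rois, selection.config
    ).condition_means()
    return {
        "config": selection.config.to_dict(),
        "main_instance": selection.main_instance,
        "instance_pvalues": dict(selection.instance_pvalues),
        "priority_table": priority_table,
        "fused": {
            "rois": list(fusion.fused_rois),
            "n_rois": len(fusion.fused_rois),
            "index": fusion.fused_index,
            "pvalue": fusion.fused_pvalue,
            "pvalue_trace": list(fusion.pvalue_trace),
            "condition_means": fused_means,
            "composition_by_atlas": by_atlas,
            "composition_by_lobe": by_lobe,
        },
    }


def report_roundtrip(rep: dict) -> dict:
    """Serialise a report to JSON text and back (identity check helper)."""
    return json.loads(json.dumps(rep))
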