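"""Condition-discriminability testing of graph properties.

A candidate network (or a single ROI) is scored by filling a
``|conditions| x |subjects|`` matrix of per-subject property values and
testing whether its rows differ: a two-sided t-test for two conditions
(paired by default — within-subject designs measure every subject under
every condition) or a one-way ANOVA for more than two.  The returned
p-value is the candidate's performance: smaller means the property
discriminates the cognitive states better.

p-values are used raw for ranking candidates; no multiple-testing
correction is applied across candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .config import FusionConfig
from .connectivity import ConditionStack
from .graph_metrics import BinaryGraph, nodal_property, subset_property

__all__ = ["IndexMatrix", "discriminability", "index_matrix",
           "score_candidate"]

logger = logging.getLogger(__name__)


@dataclass
class IndexMatrix:
    """Per-(condition, subject) property values; rows are conditions."""

    conditions: list[str]
    subjects: list[str]
    values: np.ndarray  # (C, S)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.conditions), len(self.subjects))
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match design "
                f"{expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("property values must be finite")

    def condition_means(self) -> dict[str, float]:
        return {
            c: float(self.values[i].mean())
            for i, c in enumerate(self.conditions)
        }


def discriminability(m: IndexMatrix, paired: bool = True) -> float:
    """p-value for a difference in the property across conditions.

    Two conditions: two-sided t-test, paired by default.  More than two:
    one-way ANOVA across independent condition groups.  Degenerate inputs
    (no variance anywhere) return p = 1 with a warning; a paired design
    whose differences are constant but nonzero returns the limiting p = 0.
    """
    rows = m.values
    n_cond, n_subj = rows.shape
    if n_cond < 2:
        raise ValueError("need at least 2 conditions")
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")

    if n_cond == 2:
        if paired:
            diff = rows[0] - rows[1]
            if np.ptp(diff) == 0:
                if diff[0] == 0:
                    logger.warning(
                        "degenerate paired design: all differences zero; p=1"
                    )
                    return 1.0
                return 0.0  # constant nonzero difference: limiting p
            return float(stats.ttest_rel(rows[0], rows[1]).pvalue)
        if np.ptp(rows[0]) == 0 and np.ptp(rows[1]) == 0:
            if rows[0, 0] == rows[1, 0]:
                logger.warning("zero variance in both groups; p=1")
                return 1.0
            return 0.0
        p = float(stats.ttest_ind(rows[0], rows[1]).pvalue)
        return 1.0 if np.isnan(p) else p

    if all(np.ptp(row) == 0 for row in rows):
        if len({row[0] for row in rows}) == 1:
            logger.warning("zero variance in all groups; p=1")
            return 1.0
        return 0.0
    result = stats.f_oneway(*rows)
    p = float(result.pvalue)
    return 1.0 if np.isnan(p) else p


def index_matrix(
    stack: ConditionStack,
    subset: Sequence[str],
    cfg: FusionConfig | None = None,
) -> IndexMatrix:
    """Fill the property matrix for a candidate ROI subset.

    Multi-ROI subsets use the induced-subgraph property; a single ROI uses
    its nodal property within the full combined-network graph.
    """
    cfg = cfg or FusionConfig()
    adj = stack.graphs(q=cfg.fdr_q, mode=cfg.edge_sign)
    C, S, N, _ = adj.shape
    idx = stack.indices_of(list(subset))
    values = np.empty((C, S))

    if cfg.metric == "degree":
        # vectorised across all slices
        if idx.size == 1:
            values = adj[:, :, idx[0], :].sum(axis=-1) / (N - 1)
        else:
            k = idx.size
            sub = adj[:, :, idx[:, None], idx[None, :]]
            values = sub.sum(axis=(-2, -1)) / (k * (k - 1))
    else:
        names = stack.qualified_ids
        for c in range(C):
            for s in range(S):
                g = BinaryGraph(nodes=names, adjacency=adj[c, s].copy())
                if idx.size == 1:
                    values[c, s] = nodal_property(g, subset[0], cfg.metric)
                else:
                    values[c, s] = subset_property(g, list(subset), cfg.metric)
    return IndexMatrix(
        conditions=list(stack.conditions),
        subjects=list(stack.subjects),
        values=values,
    )


def score_candidate(
    stack: ConditionStack,
    subset: Sequence[str],
    cfg: FusionConfig | None = None,
) -> float:
    """Discriminability p-value of a candidate ROI subset."""
    cfg = cfg or FusionConfig()
    return discriminability(index_matrix(stack, subset, cfg), cfg.paired)
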