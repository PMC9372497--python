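"""Planted-subnetwork simulator for end-to-end pipeline testing.

Real task-fMRI data for this kind of analysis (two task conditions, ~20
subjects, a combined multi-atlas ROI set) are rarely shareable, so the
package ships a generative stand-in: zero-mean Gaussian ROI time series
whose correlation structure contains a *planted* ROI subset.  Planted edges
have correlation ``base_corr + effect`` under the first condition and
``base_corr`` under the others; all remaining edges sit at a weaker
background of ``0.5 * base_corr``.  Between-subject variability is modelled
as symmetric jitter (sd ``subject_sd``) added to every off-diagonal
correlation, shared across conditions within a subject so that paired
designs see correlated errors, as they would in vivo.

Jittered target matrices are projected to the nearest positive-semidefinite
correlation matrix (eigenvalue clipping + diagonal renormalisation) before
Cholesky sampling.  Everything is reproducible from the design seed.

The default design mirrors a two-condition, 21-subject study over a
72-ROI combined network built from four atlas instances of sizes
10/21/24/17 (frontal/parietal split 6+4, 13+8, 17+7, 11+6); a
proportionally reduced layout is provided for fast tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .atlas_model import ROI, CombinedNetwork, NetworkInstance, combine
from .connectivity import ConditionStack, TimeSeriesSet, build_stack
from .fusion import FusionResult, SelectionResult

__all__ = [
    "DEFAULT_LAYOUT",
    "REDUCED_LAYOUT",
    "PlantedDesign",
    "generate",
    "generate_stack",
    "evaluate_recovery",
]

#: (frontal, parietal) ROI counts per instance, full-scale default.
DEFAULT_LAYOUT: tuple[tuple[int, int], ...] = (
    (6, 4), (13, 8), (17, 7), (11, 6)
)

#: Proportionally reduced layout (24 ROIs) used by the fast test suite.
REDUCED_LAYOUT: tuple[tuple[int, int], ...] = ((3, 1), (4, 3), (5, 3), (3, 2))


@dataclass
class PlantedDesign:
    """Study design for the planted-subnetwork generator.

    ``planted_rois`` (qualified ids) overrides the default planted set,
    which is all ROIs of instance ``planted_instance`` plus the first
    ``extra_planted`` ROIs drawn in order from the other instances.
    ``effect = 0`` yields a null design with no condition difference.
    """

    n_conditions: int = 2
    n_subjects: int = 21
    t: int = 180
    layout: tuple[tuple[int, int], ...] = DEFAULT_LAYOUT
    planted_instance: int = 1
    extra_planted: int = 0
    planted_rois: frozenset[str] | None = None
    base_corr: float = 0.25
    effect: float = 0.30
    subject_sd: float = 0.05
    seed: int = 0
    network_concept: str = "FPN"

    def __post_init__(self) -> None:
        if self.n_conditions < 2:
            raise ValueError("need at least 2 conditions")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.t < 3:
            raise ValueError("need at least 3 time points")
        if not 0 <= self.planted_instance < len(self.layout):
            raise ValueError("planted_instance out of range")
        if abs(self.base_corr + self.effect) >= 1:
            raise ValueError("base_corr + effect must lie in (-1, 1)")

    @property
    def n_rois(self) -> int:
        return sum(f + p for f, p in self.layout)

    @property
    def instance_sizes(self) -> tuple[int, ...]:
        return tuple(f + p for f, p in self.layout)

    def make_instances(self) -> list[NetworkInstance]:
        """Deterministic mock instances with the configured lobe layout."""
        instances = []
        for i, (n_front, n_par) in enumerate(self.layout):
            atlas = f"atlas{i + 1}"
            rois = []
            for k in range(n_front + n_par):
                lobe = "frontal" if k < n_front else "parietal"
                rois.append(
                    ROI(
                        roi_id=f"r{k + 1:03d}",
                        name=f"{atlas} region {k + 1}",
                        # synthetic MNI-like coordinates, unique by layout
                        mni=(
                            -60.0 + 4.0 * k,
                            45.0 if lobe == "frontal" else -55.0,
                            8.0 + 6.0 * i,
                        ),
                        lobe=lobe,
                        source_atlas=atlas,
                        source_network=self.network_concept,
                    )
                )
            instances.append(
                NetworkInstance(
                    network_concept=self.network_concept,
                    instance_name=atlas,
                    rois=rois,
                )
            )
        return instances

    def resolve_planted(self) -> list[str]:
        """Qualified ids of the planted ROI set, in combined order."""
        instances = self.make_instances()
        all_ids = [q for inst in instances for q in inst.qualified_ids]
        if self.planted_rois is not None:
            unknown = set(self.planted_rois) - set(all_ids)
            if unknown:
                raise ValueError(
                    f"planted_rois not in generated ROI set: "
                    f"{sorted(unknown)}"
                )
            return [q for q in all_ids if q in self.planted_rois]
        planted = list(instances[self.planted_instance].qualified_ids)
        pool = [
            q
            for i, inst in enumerate(instances)
            if i != self.planted_instance
            for q in inst.qualified_ids
        ]
        if self.extra_planted > len(pool):
            raise ValueError("extra_planted exceeds available ROIs")
        extra = pool[: self.extra_planted]
        return [q for q in all_ids if q in set(planted) | set(extra)]


def _target_correlation(
    design: PlantedDesign, planted_idx: np.ndarray, condition: int
) -> np.ndarray:
    n = design.n_rois
    r = np.full((n, n), 0.5 * design.base_corr)
    block = design.base_corr + (design.effect if condition == 0 else 0.0)
    r[np.ix_(planted_idx, planted_idx)] = block
    np.fill_diagonal(r, 1.0)
    return r


def _nearest_psd_correlation(sigma: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and renormalise to unit diagonal."""
    w, v = np.linalg.eigh(sigma)
    if w.min() >= 1e-10:
        return sigma
    w = np.clip(w, 1e-6, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def generate(
    design: PlantedDesign,
) -> tuple[list[NetworkInstance], list[TimeSeriesSet]]:
    """Draw the full factorial set of per-(condition, subject) time series.

    Raises if a base target correlation matrix is not positive
    semidefinite, reporting the offending eigenvalue.
    """
    instances = design.make_instances()
    all_ids = [q for inst in instances for q in inst.qualified_ids]
    planted = design.resolve_planted()
    planted_idx = np.array([all_ids.index(q) for q in planted], dtype=int)

    targets = []
    for c in range(design.n_conditions):
        r = _target_correlation(design, planted_idx, c)
        w = np.linalg.eigvalsh(r)
        if w.min() < -1e-8:
            raise ValueError(
                f"target correlation for condition {c} is not positive "
                f"semidefinite (min eigenvalue {w.min():.3g}); reduce "
                f"|base_corr| or |effect|"
            )
        targets.append(r)

    rng = np.random.default_rng(design.seed)
    n = design.n_rois
    iu = np.triu_indices(n, k=1)

    # subject-level correlation jitter, shared across conditions
    jitters = []
    for _ in range(design.n_subjects):
        j = np.zeros((n, n))
        j[iu] = rng.normal(0.0, design.subject_sd, size=iu[0].size)
        jitters.append(j + j.T)

    series: list[TimeSeriesSet] = []
    for c in range(design.n_conditions):
        for s in range(design.n_subjects):
            sigma = targets[c] + jitters[s]
            off = ~np.eye(n, dtype=bool)
            sigma[off] = np.clip(sigma[off], -0.99, 0.99)
            sigma = _nearest_psd_correlation(sigma)
            chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(n))
            z = rng.standard_normal((design.t, n))
            series.append(
                TimeSeriesSet(
                    condition=f"cond{c + 1}",
                    subject=f"sub{s + 1:02d}",
                    data=z @ chol.T,
                )
            )
    return instances, series


def generate_stack(
    design: PlantedDesign,
) -> tuple[list[NetworkInstance], CombinedNetwork, ConditionStack]:
    """Generate, combine and ingest in one call."""
    instances, series = generate(design)
    ccn = combine(instances)
    stack = build_stack(series, ccn)
    return instances, ccn, stack


def evaluate_recovery(
    selection: SelectionResult,
    fusion: FusionResult,
    design: PlantedDesign,
    fused_rois: Sequence[str] | None = None,
) -> dict:
    """Precision/recall of the planted ROIs in the pipeline's output.

    Reports recovery of the planted set (a) within the fused network and
    (b) within the top-k of the supplementary priority list, where k is the
    number of planted ROIs that were eligible for ranking (i.e. not already
    in the main network).
    """
    planted = set(design.resolve_planted())
    fused = set(fused_rois if fused_rois is not None else fusion.fused_rois)
    tp = len(planted & fused)
    precision = tp / len(fused) if fused else 0.0
    recall = tp / len(planted) if planted else 0.0

    supp_planted = planted & set(selection.supp_rois)
    k = len(supp_planted)
    topk = set(selection.supp_rois[:k])
    topk_recall = len(supp_planted & topk) / k if k else 1.0
    return {
        "n_planted": len(planted),
        "fused_precision": precision,
        "fused_recall": recall,
        "supp_topk_recall": topk_recall,
        "main_is_planted_instance": set(selection.main_rois) <= planted,
    }
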