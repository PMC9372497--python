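"""Cognitive-network instances across brain atlases and their combination.

A *cognitive network* (e.g. the fronto-parietal network, FPN) is a concept;
each brain atlas that defines it yields one concrete *instance* — an ordered
set of point ROIs with MNI-millimetre centres and anatomical lobe labels.
Because atlases disagree on boundaries, the same conceptual network has
different ROI sets in AAL, Dosenbach-160, Power-264, Willard-499 and so on.

This module represents instances, clips them to a lobe boundary (the FPN is
conventionally confined to frontal + parietal cortex), and forms the
*combined* network: the concatenated union of all instances, in which ROIs
from different atlases are kept distinct even when their MNI coordinates
coincide.  ROI identity is always ``(source_atlas, roi_id)``, never the
coordinates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "LOBES",
    "DEFAULT_KEEP_LOBES",
    "ROI",
    "NetworkInstance",
    "CombinedNetwork",
    "AtlasTableError",
    "load_instances",
    "save_instances",
    "clip_to_lobes",
    "combine",
]

#: Closed anatomical-lobe vocabulary.  Labels are case-normalised at load
#: time; anything outside this set is rejected rather than guessed at,
#: because lobe clipping semantics depend on it.
LOBES = frozenset(
    {"frontal", "parietal", "occipital", "temporal", "limbic", "insula",
     "cerebellum", "other"}
)

#: Default clip boundary: the conventional fronto-parietal extent.
DEFAULT_KEEP_LOBES = frozenset({"frontal", "parietal"})

ATLAS_COLUMNS = ["roi_id", "name", "x", "y", "z", "lobe", "network", "atlas"]


class AtlasTableError(ValueError):
    """Raised when an atlas table violates the format or its invariants."""


@dataclass(frozen=True)
class ROI:
    """A point region of interest tagged with its atlas provenance.

    Parameters
    ----------
    roi_id:
        Token unique within the source atlas.
    name:
        Free-text anatomical name.
    mni:
        MNI centre in millimetres, exactly three finite components.
    lobe:
        One of :data:`LOBES`.
    source_atlas, source_network:
        Provenance tokens; ``(source_atlas, roi_id)`` is the ROI's identity.
    """

    roi_id: str
    name: str
    mni: tuple[float, float, float]
    lobe: str
    source_atlas: str
    source_network: str

    def __post_init__(self) -> None:
        if len(self.mni) != 3 or not all(math.isfinite(v) for v in self.mni):
            raise ValueError(
                f"ROI {self.roi_id!r}: mni must have 3 finite components, "
                f"got {self.mni!r}"
            )
        object.__setattr__(self, "mni", tuple(float(v) for v in self.mni))
        lobe = self.lobe.strip().lower()
        if lobe not in LOBES:
            raise ValueError(
                f"ROI {self.roi_id!r}: unknown lobe {self.lobe!r} "
                f"(expected one of {sorted(LOBES)})"
            )
        object.__setattr__(self, "lobe", lobe)

    @property
    def key(self) -> tuple[str, str]:
        """Identity: ``(source_atlas, roi_id)``."""
        return (self.source_atlas, self.roi_id)

    @property
    def qualified_id(self) -> str:
        """Globally unique token ``atlas:roi_id`` used as a graph node id."""
        return f"{self.source_atlas}:{self.roi_id}"


@dataclass
class NetworkInstance:
    """One atlas's version of a cognitive network.

    Invariants: at least one ROI; roi_ids unique; no two ROIs within the
    same instance share identical MNI coordinates (within-atlas regions are
    spatially distinct — only *cross*-atlas coordinate clashes are allowed).
    """

    network_concept: str
    instance_name: str
    rois: list[ROI] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rois:
            raise ValueError(
                f"instance {self.instance_name!r}: needs at least one ROI"
            )
        seen_ids: set[str] = set()
        seen_mni: dict[tuple[float, float, float], str] = {}
        for roi in self.rois:
            if roi.roi_id in seen_ids:
                raise ValueError(
                    f"instance {self.instance_name!r}: duplicate roi_id "
                    f"{roi.roi_id!r}"
                )
            seen_ids.add(roi.roi_id)
            if roi.mni in seen_mni:
                raise ValueError(
                    f"instance {self.instance_name!r}: ROIs "
                    f"{seen_mni[roi.mni]!r} and {roi.roi_id!r} share MNI "
                    f"coordinates {roi.mni}"
                )
            seen_mni[roi.mni] = roi.roi_id

    def __len__(self) -> int:
        return len(self.rois)

    @property
    def roi_ids(self) -> list[str]:
        return [r.roi_id for r in self.rois]

    @property
    def qualified_ids(self) -> list[str]:
        return [r.qualified_id for r in self.rois]


@dataclass
class CombinedNetwork:
    """Concatenation of several instances of one network concept.

    The size is additive — cross-atlas duplicates by coordinate are retained
    as distinct ROIs, each keeping its ``source_atlas`` tag.
    """

    network_concept: str
    sources: list[str]
    rois: list[ROI]

    def __len__(self) -> int:
        return len(self.rois)

    @property
    def qualified_ids(self) -> list[str]:
        return [r.qualified_id for r in self.rois]

    def index_of(self, qualified_id: str) -> int:
        try:
            return self.qualified_ids.index(qualified_id)
        except ValueError:
            raise KeyError(f"ROI {qualified_id!r} not in combined network")

    def lobe_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for roi in self.rois:
            counts[roi.lobe] = counts.get(roi.lobe, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# table IO


def _rois_from_frame(df: pd.DataFrame, path: str) -> list[ROI]:
    rois = []
    for idx, row in df.iterrows():
        for c in ("x", "y", "z"):
            try:
                float(row[c])
            except (TypeError, ValueError):
                raise AtlasTableError(
                    f"{path}: row {idx} ({row['roi_id']!r}): non-numeric "
                    f"coordinate {c}={row[c]!r}"
                )
        try:
            rois.append(
                ROI(
                    roi_id=str(row["roi_id"]),
                    name=str(row["name"]),
                    mni=(float(row["x"]), float(row["y"]), float(row["z"])),
                    lobe=str(row["lobe"]),
                    source_atlas=str(row["atlas"]),
                    source_network=str(row["network"]),
                )
            )
        except ValueError as exc:
            raise AtlasTableError(f"{path}: row {idx}: {exc}") from exc
    return rois


def load_instances(path: str | Path) -> list[NetworkInstance]:
    """Read an atlas table (TSV or JSON) into network instances.

    The tab-separated format has the header
    ``roi_id  name  x  y  z  lobe  network  atlas`` with one ROI per row;
    instances are the ``(network, atlas)`` groups in first-appearance order,
    with row order preserved within each group.  A ``.json`` file holding the
    equivalent ``{"rois": [...]}`` document is accepted too.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        df = pd.DataFrame(doc["rois"], columns=ATLAS_COLUMNS)
    else:
        try:
            df = pd.read_csv(path, sep="\t", dtype=str)
        except pd.errors.EmptyDataError:
            raise AtlasTableError(f"{path}: no instances (empty file)")
    missing = [c for c in ATLAS_COLUMNS if c not in df.columns]
    if missing:
        raise AtlasTableError(f"{path}: missing columns {missing}")
    dupes = df.columns[df.columns.duplicated()].tolist()
    if dupes:
        raise AtlasTableError(f"{path}: duplicate columns {dupes}")
    if df.empty:
        raise AtlasTableError(f"{path}: no instances")

    instances: list[NetworkInstance] = []
    order: list[tuple[str, str]] = []
    groups: dict[tuple[str, str], pd.DataFrame] = {}
    for key, sub in df.groupby(["network", "atlas"], sort=False):
        order.append(key)
        groups[key] = sub
    for network, atlas in order:
        rois = _rois_from_frame(groups[(network, atlas)], str(path))
        try:
            instances.append(
                NetworkInstance(
                    network_concept=network, instance_name=atlas, rois=rois
                )
            )
        except ValueError as exc:
            raise AtlasTableError(f"{path}: {exc}") from exc
    return instances


def _roi_record(roi: ROI) -> dict:
    return {
        "roi_id": roi.roi_id,
        "name": roi.name,
        "x": roi.mni[0],
        "y": roi.mni[1],
        "z": roi.mni[2],
        "lobe": roi.lobe,
        "network": roi.source_network,
        "atlas": roi.source_atlas,
    }


def save_instances(
    instances: Iterable[NetworkInstance], path: str | Path
) -> None:
    """Write instances as an atlas table; ``.json`` suffix selects JSON."""
    path = Path(path)
    records = [
        _roi_record(roi) for inst in instances for roi in inst.rois
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps({"rois": records}, indent=1))
    else:
        pd.DataFrame(records, columns=ATLAS_COLUMNS).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# clipping and combination


def clip_to_lobes(
    instance: NetworkInstance,
    keep: Iterable[str] = DEFAULT_KEEP_LOBES,
) -> NetworkInstance:
    """Retain only the ROIs whose lobe is in ``keep`` (order preserved).

    Idempotent; the input instance is not modified.  Raises if the clip
    would leave the instance empty or if ``keep`` is empty/unknown.
    """
    keep_set = {str(k).strip().lower() for k in keep}
    if not keep_set:
        raise ValueError("keep must be a non-empty set of lobe labels")
    unknown = keep_set - LOBES
    if unknown:
        raise ValueError(f"unknown lobe labels in keep: {sorted(unknown)}")
    kept = [r for r in instance.rois if r.lobe in keep_set]
    if not kept:
        raise ValueError(
            f"clipping removed all ROIs of instance "
            f"{instance.instance_name!r} (keep={sorted(keep_set)})"
        )
    return NetworkInstance(
        network_concept=instance.network_concept,
        instance_name=instance.instance_name,
        rois=list(kept),
    )


def combine(instances: Sequence[NetworkInstance]) -> CombinedNetwork:
    """Concatenate all instances of one network concept.

    Size-additive by construction: ``len(combined) == sum(len(i))``.  ROIs
    with identical MNI coordinates from *different* atlases stay distinct.
    """
    if not instances:
        raise ValueError("combine needs at least one instance")
    concepts = {inst.network_concept for inst in instances}
    if len(concepts) != 1:
        raise ValueError(
            f"cannot combine instances of different network concepts: "
            f"{sorted(concepts)}"
        )
    rois: list[ROI] = []
    seen: set[tuple[str, str]] = set()
    for inst in instances:
        for roi in inst.rois:
            if roi.key in seen:
                raise ValueError(
                    f"duplicate ROI identity {roi.key} across instances"
                )
            seen.add(roi.key)
            rois.append(roi)
    return CombinedNetwork(
        network_concept=concepts.pop(),
        sources=[inst.instance_name for inst in instances],
        rois=rois,
    )
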