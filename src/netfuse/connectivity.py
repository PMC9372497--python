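"""Functional connectivity: per-condition, per-subject correlation matrices.

Given per-subject ROI time series (rows = time points, columns = the ROIs of
a combined network, in combined order), this module computes Pearson
functional-connectivity matrices with two-sided edge p-values, applies
Benjamini–Hochberg FDR thresholding to the edges, and stacks everything into
the 4-D ``condition x subject x ROI x ROI`` structure the fusion algorithms
consume.  Spherical mean-signal extraction from 4-D NIfTI volumes is
provided for users starting from preprocessed images rather than tables.

Correlations are plain Pearson r (no Fisher-z transform) and FDR is applied
per matrix over the upper triangle; both choices are surfaced in the stack
metadata.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.stats.multitest import multipletests

from .atlas_model import ROI, CombinedNetwork

__all__ = [
    "TimeSeriesSet",
    "ConditionStack",
    "pearson_fc",
    "fdr_edges",
    "build_stack",
    "extract_roi_timeseries",
    "save_timeseries",
    "load_timeseries_dir",
    "save_stack",
    "load_stack",
]

logger = logging.getLogger(__name__)

_TS_FILE_RE = re.compile(r"^(?P<condition>.+)__(?P<subject>.+)\.tsv$")


@dataclass
class TimeSeriesSet:
    """BOLD-like signals for one (condition, subject) cell of the design."""

    condition: str
    subject: str
    data: np.ndarray  # (t, n_rois), column order = combined ROI order

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (t, n_rois)")
        if self.data.shape[0] < 3:
            raise ValueError(
                f"({self.condition}, {self.subject}): need at least 3 time "
                f"points, got {self.data.shape[0]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError(
                f"({self.condition}, {self.subject}): non-finite values in "
                "time series"
            )

    @property
    def t(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class ConditionStack:
    """4-D connectivity container: ``[condition][subject][roi][roi]``.

    Each 2-D slice is a symmetric unit-diagonal Pearson correlation matrix
    with a matching two-sided p-value matrix.  Thresholded binary graphs are
    derived lazily and cached per ``(q, sign-mode)``.
    """

    conditions: list[str]
    subjects: list[str]
    rois: list[ROI]
    matrices: np.ndarray  # (C, S, N, N) correlations
    pvals: np.ndarray  # (C, S, N, N) two-sided p-values
    _graph_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        C, S, N = len(self.conditions), len(self.subjects), len(self.rois)
        expected = (C, S, N, N)
        if self.matrices.shape != expected or self.pvals.shape != expected:
            raise ValueError(
                f"stack arrays must have shape {expected}, got "
                f"{self.matrices.shape} / {self.pvals.shape}"
            )
        flat = self.matrices.reshape(C * S, N, N)
        if not np.allclose(flat, flat.transpose(0, 2, 1), atol=1e-10):
            raise ValueError("connectivity slices must be symmetric")
        if not np.allclose(flat[:, np.arange(N), np.arange(N)], 1.0):
            raise ValueError("connectivity slices must have unit diagonal")
        off = flat[:, ~np.eye(N, dtype=bool)]
        if off.size and (off.min() < -1 - 1e-9 or off.max() > 1 + 1e-9):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    @property
    def qualified_ids(self) -> list[str]:
        return [r.qualified_id for r in self.rois]

    def indices_of(self, qualified_ids: Sequence[str]) -> np.ndarray:
        lookup = {qid: i for i, qid in enumerate(self.qualified_ids)}
        try:
            return np.array([lookup[q] for q in qualified_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"ROI {exc.args[0]!r} not present in stack")

    def graphs(self, q: float = 0.05, mode: str = "positive") -> np.ndarray:
        """Boolean adjacency array (C, S, N, N) of FDR-surviving edges.

        ``mode='positive'`` keeps only positive-r significant edges (the
        common connectome convention); ``'absolute'`` keeps both signs.
        Results are cached on the stack.
        """
        key = (float(q), mode)
        if key not in self._graph_cache:
            C, S, N = len(self.conditions), len(self.subjects), self.n_rois
            adj = np.zeros((C, S, N, N), dtype=bool)
            for c in range(C):
                for s in range(S):
                    mask = fdr_edges(self.pvals[c, s], q)
                    if mode == "positive":
                        mask &= self.matrices[c, s] > 0
                    elif mode != "absolute":
                        raise ValueError(
                            f"mode must be 'positive' or 'absolute', "
                            f"got {mode!r}"
                        )
                    adj[c, s] = mask
            self._graph_cache[key] = adj
        return self._graph_cache[key]


# ---------------------------------------------------------------------------
# correlation and FDR


def pearson_fc(
    ts: TimeSeriesSet | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation matrix with two-sided p-values.

    p-values come from the exact null distribution of r for bivariate
    Gaussian data (a beta distribution in (1+r)/2, equivalent to the
    t-distribution with t-2 df), matching ``scipy.stats.pearsonr``.

    Zero-variance columns do not abort the run: their edges are reported as
    r = 0 with p = 1 and a warning is logged, so one flat ROI cannot kill a
    group analysis.
    """
    data = ts.data if isinstance(ts, TimeSeriesSet) else np.asarray(ts, float)
    t, n = data.shape
    if t < 3:
        raise ValueError("need at least 3 time points for correlation")
    sd = data.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        logger.warning(
            "zero-variance time series in %d column(s) %s: their edges get "
            "r=0, p=1",
            flat.size,
            flat.tolist(),
        )
    centred = data - data.mean(axis=0)
    denom = np.sqrt((centred**2).sum(axis=0))
    denom[denom == 0] = 1.0  # flat columns: numerator is 0 anyway
    r = (centred.T @ centred) / np.outer(denom, denom)
    np.clip(r, -1.0, 1.0, out=r)
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    np.fill_diagonal(r, 1.0)

    # two-sided p = I_{1-r^2}(df/2, 1/2), the t-distribution tail with
    # df = t - 2 expressed through the regularised incomplete beta
    df = t - 2
    p = special.betainc(df / 2.0, 0.5, np.clip(1.0 - r**2, 0.0, 1.0))
    p[flat, :] = 1.0
    p[:, flat] = 1.0
    np.fill_diagonal(p, 0.0)
    # enforce exact symmetry against fp noise
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    p = (p + p.T) / 2.0
    return r, p


def fdr_edges(pmat: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up over the upper-triangle edge p-values.

    The family size is m = n(n-1)/2 (each undirected edge counted once).
    Returns a symmetric boolean mask with a False diagonal.
    """
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    pmat = np.asarray(pmat, dtype=float)
    n = pmat.shape[0]
    iu = np.triu_indices(n, k=1)
    pvec = pmat[iu]
    mask = np.zeros_like(pmat, dtype=bool)
    if pvec.size:
        reject, *_ = multipletests(pvec, alpha=q, method="fdr_bh")
        mask[iu] = reject
        mask |= mask.T
    return mask


# ---------------------------------------------------------------------------
# stack construction


def build_stack(
    series: Sequence[TimeSeriesSet], ccn: CombinedNetwork
) -> ConditionStack:
    """Assemble the 4-D stack from a complete factorial set of time series.

    Conditions and subjects are ordered by first appearance.  Every
    (condition, subject) cell must be present exactly once and every series
    must have one column per combined-network ROI.
    """
    if not series:
        raise ValueError("no time series supplied")
    n = len(ccn)
    conditions: list[str] = []
    subjects: list[str] = []
    cells: dict[tuple[str, str], TimeSeriesSet] = {}
    for ts in series:
        if ts.n_rois != n:
            raise ValueError(
                f"({ts.condition}, {ts.subject}): {ts.n_rois} columns but "
                f"combined network has {n} ROIs"
            )
        key = (ts.condition, ts.subject)
        if key in cells:
            raise ValueError(f"duplicate (condition, subject) pair {key}")
        cells[key] = ts
        if ts.condition not in conditions:
            conditions.append(ts.condition)
        if ts.subject not in subjects:
            subjects.append(ts.subject)
    missing = [
        (c, s) for c in conditions for s in subjects if (c, s) not in cells
    ]
    if missing:
        raise ValueError(f"incomplete design; missing cells: {missing}")

    C, S = len(conditions), len(subjects)
    matrices = np.empty((C, S, n, n))
    pvals = np.empty((C, S, n, n))
    for ci, c in enumerate(conditions):
        for si, s in enumerate(subjects):
            matrices[ci, si], pvals[ci, si] = pearson_fc(cells[(c, s)])
    return ConditionStack(
        conditions=conditions,
        subjects=subjects,
        rois=list(ccn.rois),
        matrices=matrices,
        pvals=pvals,
    )


# ---------------------------------------------------------------------------
# NIfTI spherical extraction


def extract_roi_timeseries(
    volume,
    rois: Sequence[ROI],
    radius: float = 5.0,
    condition: str = "cond",
    subject: str = "subj",
) -> TimeSeriesSet:
    """Mean signal within a sphere of ``radius`` mm around each ROI centre.

    ``volume`` is a 4-D NIfTI image (or path); its affine maps voxel indices
    to MNI mm.  A sphere that covers zero voxels raises, naming the ROI.
    """
    import nibabel as nib

    if isinstance(volume, (str, Path)):
        volume = nib.load(str(volume))
    if radius <= 0:
        raise ValueError("radius must be > 0")
    data = np.asanyarray(volume.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got shape {data.shape}")
    affine = volume.affine
    inv = np.linalg.inv(affine)
    nx, ny, nz, t = data.shape

    cols = np.empty((t, len(rois)))
    for j, roi in enumerate(rois):
        centre_vox = inv @ np.array([*roi.mni, 1.0])
        # voxel bounding box wide enough to contain the sphere
        zooms = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
        half = np.ceil(radius / zooms).astype(int) + 1
        lo = np.maximum(np.floor(centre_vox[:3]).astype(int) - half, 0)
        hi = np.minimum(
            np.ceil(centre_vox[:3]).astype(int) + half + 1, [nx, ny, nz]
        )
        if np.any(lo >= hi):
            raise ValueError(
                f"sphere for ROI {roi.qualified_id!r} contains no voxels"
            )
        gi, gj, gk = np.meshgrid(
            np.arange(lo[0], hi[0]),
            np.arange(lo[1], hi[1]),
            np.arange(lo[2], hi[2]),
            indexing="ij",
        )
        vox = np.stack([gi, gj, gk, np.ones_like(gi)], axis=-1).reshape(-1, 4)
        world = vox @ affine.T
        dist = np.linalg.norm(world[:, :3] - np.array(roi.mni), axis=1)
        inside = vox[dist <= radius, :3].astype(int)
        if inside.shape[0] == 0:
            raise ValueError(
                f"sphere for ROI {roi.qualified_id!r} contains no voxels"
            )
        cols[:, j] = data[inside[:, 0], inside[:, 1], inside[:, 2], :].mean(
            axis=0
        )
    return TimeSeriesSet(condition=condition, subject=subject, data=cols)


# ---------------------------------------------------------------------------
# serialisation


def save_timeseries(series: Sequence[TimeSeriesSet], directory: str | Path,
                    roi_ids: Sequence[str]) -> None:
    """Write one ``{condition}__{subject}.tsv`` per cell, header = roi ids."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ts in series:
        df = pd.DataFrame(ts.data, columns=list(roi_ids))
        df.to_csv(directory / f"{ts.condition}__{ts.subject}.tsv",
                  sep="\t", index=False)


def load_timeseries_dir(
    directory: str | Path, ccn: CombinedNetwork | None = None
) -> list[TimeSeriesSet]:
    """Read every ``{condition}__{subject}.tsv`` in a directory.

    If ``ccn`` is given, columns are checked (and reordered if needed) to
    the combined ROI order.
    """
    directory = Path(directory)
    series: list[TimeSeriesSet] = []
    for path in sorted(directory.glob("*.tsv")):
        m = _TS_FILE_RE.match(path.name)
        if m is None:
            continue
        df = pd.read_csv(path, sep="\t")
        if ccn is not None:
            expected = ccn.qualified_ids
            if set(df.columns) != set(expected):
                raise ValueError(
                    f"{path.name}: columns do not match combined network"
                )
            df = df[expected]
        series.append(
            TimeSeriesSet(
                condition=m.group("condition"),
                subject=m.group("subject"),
                data=df.to_numpy(dtype=float),
            )
        )
    if not series:
        raise ValueError(f"no time-series tables found in {directory}")
    return series


def save_stack(stack: ConditionStack, path: str | Path) -> None:
    """Serialise a stack to one HDF5 file (arrays + ROI metadata)."""
    import h5py

    from .atlas_model import _roi_record

    with h5py.File(path, "w") as f:
        f.create_dataset("matrices", data=stack.matrices)
        f.create_dataset("pvals", data=stack.pvals)
        f.attrs["conditions"] = json.dumps(stack.conditions)
        f.attrs["subjects"] = json.dumps(stack.subjects)
        f.attrs["rois"] = json.dumps([_roi_record(r) for r in stack.rois])


def load_stack(path: str | Path) -> ConditionStack:
    import h5py

    with h5py.File(path, "r") as f:
        matrices = f["matrices"][()]
        pvals = f["pvals"][()]
        conditions = json.loads(f.attrs["conditions"])
        subjects = json.loads(f.attrs["subjects"])
        roi_records = json.loads(f.attrs["rois"])
    rois = [
        ROI(
            roi_id=rec["roi_id"],
            name=rec["name"],
            mni=(rec["x"], rec["y"], rec["z"]),
            lobe=rec["lobe"],
            source_atlas=rec["atlas"],
            source_network=rec["network"],
        )
        for rec in roi_records
    ]
    return ConditionStack(
        conditions=conditions,
        subjects=subjects,
        rois=rois,
        matrices=matrices,
        pvals=pvals,
    )
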