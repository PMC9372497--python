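"""Pearson connectivity, BH edge thresholding, stack assembly, extraction."""

from __future__ import annotations

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import _oracles as oracles
from conftest import make_instance
from netfuse import (
    ROI,
    TimeSeriesSet,
    build_stack,
    combine,
    extract_roi_timeseries,
    fdr_edges,
    load_stack,
    load_timeseries_dir,
    pearson_fc,
    save_stack,
    save_timeseries,
)


class TestPearsonFC:
    def test_identical_columns_give_r_one(self):
        x = np.arange(10.0)
        r, p = pearson_fc(np.column_stack([x, x]))
        assert r[0, 1] == pytest.approx(1.0)

    def test_negated_column_gives_r_minus_one(self):
        x = np.arange(10.0)
        r, _ = pearson_fc(np.column_stack([x, -x]))
        assert r[0, 1] == pytest.approx(-1.0)

    def test_hand_evaluated_sum_formula(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 6]
        r, _ = pearson_fc(np.column_stack([x, y]).astype(float))
        assert r[0, 1] == pytest.approx(oracles.pearson_sum_formula(x, y),
                                        abs=1e-12)

    def test_matches_scipy_pearsonr(self, rng):
        data = rng.standard_normal((20, 5))
        r, p = pearson_fc(data)
        for i in range(5):
            for j in range(i + 1, 5):
                ref = stats.pearsonr(data[:, i], data[:, j])
                assert r[i, j] == pytest.approx(ref.statistic, abs=1e-12)
                assert p[i, j] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_symmetric_unit_diagonal(self, rng):
        r, p = pearson_fc(rng.standard_normal((15, 6)))
        assert np.array_equal(r, r.T)
        assert np.allclose(np.diag(r), 1.0)
        assert np.array_equal(p, p.T)

    def test_zero_variance_column_degrades_gracefully(self, rng, caplog):
        data = rng.standard_normal((12, 3))
        data[:, 1] = 7.0
        with caplog.at_level(logging.WARNING, logger="netfuse.connectivity"):
            r, p = pearson_fc(data)
        assert "zero-variance" in caplog.text
        assert r[0, 1] == 0.0 and p[0, 1] == 1.0
        assert r[1, 1] == 1.0  # diagonal convention survives


class TestFdrEdges:
    def test_all_edges_pass_at_stepup_boundary(self):
        # evenly spread p-values ending exactly at q: the largest k with
        # p(k) <= k*q/m is k = m, so the step-up accepts every edge even
        # though the small ones fail their individual thresholds
        pvec = [0.01, 0.02, 0.03, 0.04, 0.045, 0.05]
        assert oracles.bh_stepup(pvec, 0.05) == [True] * 6
        p = np.zeros((4, 4))
        iu = np.triu_indices(4, k=1)
        p[iu] = pvec
        p = p + p.T
        mask = fdr_edges(p, 0.05)
        assert mask[iu].all()

    def test_all_ones_gives_empty_mask(self):
        p = np.ones((5, 5))
        np.fill_diagonal(p, 0.0)
        assert not fdr_edges(p, 0.05).any()

    def test_single_edge_family(self):
        p = np.array([[0.0, 0.04], [0.04, 0.0]])
        assert fdr_edges(p, 0.05)[0, 1]

    def test_diagonal_always_false_and_symmetric(self, rng):
        p = rng.uniform(size=(8, 8))
        p = (p + p.T) / 2
        mask = fdr_edges(p, 0.2)
        assert not np.diag(mask).any()
        assert np.array_equal(mask, mask.T)

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError, match="q must be"):
            fdr_edges(np.eye(3), 1.5)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        n=st.integers(min_value=2, max_value=14),
        seed=st.integers(min_value=0, max_value=10_000),
        q=st.sampled_from([0.01, 0.05, 0.1, 0.3]),
    )
    def test_matches_stepup_definition(self, n, seed, q):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=(n, n)) ** 2  # skew small to trigger rejections
        p = (p + p.T) / 2
        np.fill_diagonal(p, 0.0)
        mask = fdr_edges(p, q)
        iu = np.triu_indices(n, k=1)
        expected = oracles.bh_stepup(list(p[iu]), q)
        assert list(mask[iu]) == expected


def _series(condition, subject, data):
    return TimeSeriesSet(condition=condition, subject=subject, data=data)


class TestBuildStack:
    def test_shape_follows_design(self, reduced_pipeline):
        design, _, ccn, stack = reduced_pipeline
        assert stack.matrices.shape == (2, 8, 24, 24)
        assert stack.pvals.shape == (2, 8, 24, 24)

    def test_minimal_design(self, rng):
        ccn = combine([make_instance("a", {"frontal": 3})])
        series = [_series("c1", "s1", rng.standard_normal((10, 3))),
                  _series("c2", "s1", rng.standard_normal((10, 3)))]
        stack = build_stack(series, ccn)
        assert stack.matrices.shape == (2, 1, 3, 3)

    def test_duplicate_cell_rejected(self, rng):
        ccn = combine([make_instance("a", {"frontal": 3})])
        series = [_series("c1", "s1", rng.standard_normal((10, 3))),
                  _series("c1", "s1", rng.standard_normal((10, 3)))]
        with pytest.raises(ValueError, match="duplicate"):
            build_stack(series, ccn)

    def test_missing_cell_listed(self, rng):
        ccn = combine([make_instance("a", {"frontal": 3})])
        series = [_series("c1", "s1", rng.standard_normal((10, 3))),
                  _series("c2", "s2", rng.standard_normal((10, 3)))]
        with pytest.raises(ValueError, match=r"\('c1', 's2'\)"):
            build_stack(series, ccn)

    def test_column_count_mismatch_rejected(self, rng):
        ccn = combine([make_instance("a", {"frontal": 3})])
        series = [_series("c1", "s1", rng.standard_normal((10, 4)))]
        with pytest.raises(ValueError, match="columns"):
            build_stack(series, ccn)

    def test_slices_satisfy_invariants(self, reduced_pipeline):
        *_, stack = reduced_pipeline
        n = stack.n_rois
        for c in range(2):
            for s in range(8):
                m = stack.matrices[c, s]
                assert np.allclose(m, m.T)
                assert np.allclose(np.diag(m), 1.0)
                off = m[~np.eye(n, dtype=bool)]
                assert off.min() >= -1 and off.max() <= 1


class TestTimeSeriesIO:
    def test_round_trip(self, tmp_path, rng):
        ccn = combine([make_instance("a", {"frontal": 3})])
        series = [_series("c1", "s1", rng.standard_normal((10, 3))),
                  _series("c2", "s1", rng.standard_normal((10, 3)))]
        save_timeseries(series, tmp_path, ccn.qualified_ids)
        loaded = load_timeseries_dir(tmp_path, ccn)
        by_key = {(ts.condition, ts.subject): ts for ts in loaded}
        for ts in series:
            np.testing.assert_allclose(
                by_key[(ts.condition, ts.subject)].data, ts.data
            )

    def test_stack_hdf5_round_trip(self, tmp_path, reduced_pipeline):
        *_, stack = reduced_pipeline
        path = tmp_path / "stack.h5"
        save_stack(stack, path)
        loaded = load_stack(path)
        np.testing.assert_array_equal(loaded.matrices, stack.matrices)
        np.testing.assert_array_equal(loaded.pvals, stack.pvals)
        assert loaded.conditions == stack.conditions
        assert loaded.rois == stack.rois


# ---------------------------------------------------------------------------
# NIfTI spherical extraction


def _image(data, affine=None):
    import nibabel as nib

    if affine is None:
        affine = np.eye(4)
    return nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)


def _roi(roi_id, mni):
    return ROI(roi_id, roi_id, mni, "frontal", "a", "FPN")


class TestExtraction:
    def test_constant_image_gives_constant_columns(self):
        img = _image(np.full((10, 10, 10, 4), 5.0))
        ts = extract_roi_timeseries(img, [_roi("r1", (5.0, 5.0, 5.0))],
                                    radius=2.0)
        np.testing.assert_allclose(ts.data, 5.0)

    def test_ramp_within_sphere_recovered(self):
        data = np.zeros((10, 10, 10, 10))
        centre = (4, 4, 4)
        for t in range(10):
            data[2:7, 2:7, 2:7, t] = t
        img = _image(data)
        ts = extract_roi_timeseries(img, [_roi("r1", tuple(map(float,
                                                               centre)))],
                                    radius=2.0)
        np.testing.assert_allclose(ts.data[:, 0], np.arange(10.0))

    def test_mean_equals_bruteforce_voxel_mask(self, rng):
        data = rng.standard_normal((12, 12, 12, 6))
        affine = np.diag([2.0, 2.0, 2.0, 1.0])  # 2 mm voxels
        img = _image(data, affine)
        centre = (10.0, 12.0, 8.0)
        radius = 5.0
        ts = extract_roi_timeseries(img, [_roi("r1", centre)], radius=radius)
        # oracle: test every voxel in the volume
        expected = []
        voxels = []
        for i in range(12):
            for j in range(12):
                for k in range(12):
                    world = affine @ np.array([i, j, k, 1.0])
                    if np.linalg.norm(world[:3] - np.array(centre)) <= radius:
                        voxels.append((i, j, k))
        stack = np.array([data[i, j, k, :] for i, j, k in voxels])
        np.testing.assert_allclose(ts.data[:, 0], stack.mean(axis=0),
                                   atol=1e-10)

    def test_overlapping_spheres_correlate(self, rng):
        data = rng.standard_normal((16, 16, 16, 30))
        img = _image(data)
        rois = [_roi("r1", (8.0, 8.0, 8.0)), _roi("r2", (9.0, 8.0, 8.0))]
        ts = extract_roi_timeseries(img, rois, radius=6.0)
        r = np.corrcoef(ts.data.T)[0, 1]
        assert r > 0

    def test_empty_sphere_names_roi(self):
        img = _image(np.zeros((5, 5, 5, 4)))
        with pytest.raises(ValueError, match="far"):
            extract_roi_timeseries(img, [_roi("far", (500.0, 0.0, 0.0))],
                                   radius=1.0)
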