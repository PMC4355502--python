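"""Fuzzy c-means refinement: update rules, cluster combination, finalize."""

import warnings

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.morphology import disk

from lungseg.fcm_refine import (
    fcm,
    finalize,
    gate_inner,
    gate_outer,
    harden_and_sort,
    keep_largest,
    process_c5,
    refine,
)
from lungseg.metrics import evaluate


class TestFcm:
    def test_two_value_image_recovers_both_levels(self):
        data = np.concatenate([np.full(300, 0.2), np.full(200, 0.8)])
        model = fcm(data, n=2, seed=0)
        assert np.allclose(model.centroids, [0.2, 0.8], atol=1e-3)

    def test_memberships_sum_to_one(self, rng):
        model = fcm(rng.uniform(size=500), n=4, seed=1)
        assert np.allclose(model.memberships.sum(axis=1), 1.0)

    def test_objective_trace_non_increasing(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            model = fcm(r.uniform(size=400), n=3, seed=seed)
            trace = model.objective_trace
            assert (np.diff(trace) <= 1e-9 * max(trace[0], 1.0)).all()

    def test_centroids_sorted_ascending(self, rng):
        model = fcm(rng.uniform(size=300), n=5, seed=3)
        assert (np.diff(model.centroids) > 0).all()

    def test_too_few_distinct_values_raises(self):
        with pytest.raises(ValueError):
            fcm(np.array([0.1, 0.9, 0.1, 0.9]), n=3)

    def test_deterministic_for_fixed_seed(self, rng):
        data = rng.uniform(size=400)
        a = fcm(data, n=4, seed=9)
        b = fcm(data, n=4, seed=9)
        assert np.array_equal(a.centroids, b.centroids)
        assert np.array_equal(a.memberships, b.memberships)


class TestHardenAndSort:
    def test_hard_images_partition_the_domain(self, rng):
        img = rng.uniform(size=(20, 25))
        model = fcm(img.ravel(), n=4, seed=0)
        clusters = harden_and_sort(model, img.shape)
        total = np.zeros(img.shape, dtype=int)
        for im in clusters.images:
            total += im.astype(int)
        assert (total == 1).all()

    def test_zeroed_background_lands_in_first_cluster(self, rng):
        img = rng.uniform(0.3, 1.0, size=(30, 30))
        img[:15] = 0.0  # zeroed background half
        model = fcm(img.ravel(), n=4, seed=0)
        clusters = harden_and_sort(model, img.shape)
        assert clusters.images[0][:15].all()


class TestProcessC5:
    def test_three_blobs_reduced_to_two(self):
        m = np.zeros((128, 128), dtype=bool)
        m[10:30, 10:30] = True  # 400 px
        m[60:85, 60:85] = True  # 625 px
        m[110:114, 110:114] = True  # 16 px
        out = process_c5(m)
        lab, n = ndi.label(out, structure=np.ones((3, 3), int))
        assert n == 2

    def test_empty_cluster_falls_back_to_estimated_mask(self):
        l_mask = np.zeros((64, 64), dtype=bool)
        l_mask[20:40, 20:40] = True
        with pytest.warns(UserWarning):
            out = process_c5(np.zeros_like(l_mask), l_mask=l_mask)
        assert np.array_equal(out, l_mask)

    def test_solid_blob_roughly_preserved(self):
        m = np.zeros((128, 128), dtype=bool)
        m[30:90, 30:90] = True
        out = process_c5(m)
        # closing+fill on a solid blob is idempotent; only the final dilation
        # adds a 1-px ring
        assert (m <= out).all()
        assert not (out & ~ndi.binary_dilation(m, structure=disk(1).astype(bool))).any()


class TestGates:
    def test_inner_gate_is_intersection(self, rng):
        c2, c3, c4 = (rng.random((32, 32)) > 0.7 for _ in range(3))
        gate = rng.random((32, 32)) > 0.5
        out = gate_inner(c2, c3, c4, gate)
        assert np.array_equal(out, (c2 | c3 | c4) & gate)
        assert (out <= gate).all()

    def test_inner_gate_empty_inputs(self):
        z = np.zeros((16, 16), dtype=bool)
        assert not gate_inner(z, z, z, np.ones_like(z)).any()

    def test_outer_gate_discards_central_band(self):
        c0 = 100
        blob_mid = np.zeros((50, c0), dtype=bool)
        blob_mid[10:20, 45:55] = True  # entirely inside [0.4, 0.6]*c0
        z = np.zeros_like(blob_mid)
        assert not gate_outer(z, blob_mid, z).any()

    def test_outer_gate_keeps_lateral_blobs(self):
        c0 = 100
        blob = np.zeros((50, c0), dtype=bool)
        blob[10:20, 0:20] = True
        z = np.zeros_like(blob)
        out = gate_outer(z, blob, z)
        assert np.array_equal(out, blob)

    def test_outer_gate_erodes_c6(self):
        c6 = np.zeros((50, 100), dtype=bool)
        c6[10:20, 0:20] = True
        z = np.zeros_like(c6)
        out = gate_outer(c6, z, z)
        eroded = ndi.binary_erosion(c6, structure=disk(1).astype(bool))
        assert np.array_equal(out, eroded)

    def test_outer_gate_empty_inputs(self):
        z = np.zeros((16, 16), dtype=bool)
        assert not gate_outer(z, z, z).any()


class TestFinalize:
    def test_at_most_two_components(self, rng):
        m = rng.random((64, 64)) > 0.8
        l_mask = np.ones((64, 64), dtype=bool)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = finalize(m, m, m, l_mask)
        lab, n = ndi.label(out, structure=np.ones((3, 3), int))
        assert n <= 2

    def test_empty_union_returns_estimated_mask(self):
        z = np.zeros((64, 64), dtype=bool)
        l_mask = np.zeros_like(z)
        l_mask[20:44, 10:30] = True
        with pytest.warns(UserWarning):
            out = finalize(z, z, z, l_mask)
        assert np.array_equal(out, l_mask)

    def test_upsampling_to_requested_shape(self):
        m = np.zeros((64, 64), dtype=bool)
        m[16:48, 16:48] = True
        out = finalize(m, m, m, m, out_shape=(128, 128))
        assert out.shape == (128, 128)


class TestRefineEndToEnd:
    def test_refinement_never_catastrophically_degrades(
        self, pipeline_result, truth_work
    ):
        mask_score = evaluate(pipeline_result.l_mask, truth_work).overlap
        final_score = evaluate(pipeline_result.l_final_work, truth_work).overlap
        assert final_score >= mask_score - 0.05

    def test_final_mask_stays_within_estimated_mask_ring(self, pipeline_result):
        grown = ndi.binary_dilation(
            pipeline_result.l_mask, structure=disk(3).astype(bool)
        )
        assert (pipeline_result.l_final_work <= grown).all()

    def test_keep_largest_keeps_the_biggest(self):
        m = np.zeros((64, 64), dtype=bool)
        m[5:10, 5:10] = True
        m[20:40, 20:40] = True
        m[50:60, 50:62] = True
        out = keep_largest(m, 2)
        assert out[25, 25] and out[55, 55] and not out[7, 7]
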