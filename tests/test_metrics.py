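"""Overlap and surface metrics against exhaustive oracles; volume reassembly."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from dtmt.config import FrameworkConfig
from dtmt.metrics import (EmptyMaskError, binarize, boundary_mask, evaluate,
                          overlap_metrics, reassemble_volume,
                          surface_distance_metrics)
from dtmt.data import slice_volume
from dtmt.synthetic import Volume


def brute_boundary(mask):
    """Foreground voxels with a 6-neighbour background (outside = background)."""
    padded = np.pad(mask.astype(bool), 1)
    out = np.zeros_like(mask, dtype=bool)
    idx = np.argwhere(mask)
    for x, y, z in idx:
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            if not padded[x + 1 + d[0], y + 1 + d[1], z + 1 + d[2]]:
                out[x, y, z] = True
                break
    return out


def brute_surface_metrics(pred, label, spacing=(1.0, 1.0, 1.0)):
    """All-pairs boundary distances: O(|X| |Y|)."""
    bp = np.argwhere(brute_boundary(pred)) * np.asarray(spacing)
    bl = np.argwhere(brute_boundary(label)) * np.asarray(spacing)
    dmat = cdist(bp, bl)
    d_pred = dmat.min(axis=1)
    d_label = dmat.min(axis=0)
    asd = (d_pred.sum() + d_label.sum()) / (len(d_pred) + len(d_label))
    pooled = np.concatenate([d_pred, d_label])
    return asd, float(np.percentile(pooled, 95))


def random_mask(rng, shape=(16, 16, 16)):
    """A nonempty random blobby mask."""
    from scipy.ndimage import gaussian_filter

    field = gaussian_filter(rng.normal(size=shape), 2.0)
    mask = field > np.percentile(field, 70)
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    return mask.astype(np.uint8)


class TestOverlap:
    def test_identical_masks(self, rng):
        m = random_mask(rng)
        dice, jacc, _ = overlap_metrics(m, m)
        assert dice == 1.0 and jacc == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 2), dtype=np.uint8)
        b = np.zeros((4, 4, 2), dtype=np.uint8)
        a[0, 0, 0] = 1
        b[3, 3, 1] = 1
        dice, jacc, _ = overlap_metrics(a, b)
        assert dice == 0.0 and jacc == 0.0

    def test_printed_formulas_on_counted_confusion(self):
        # TP=6, FP=2, FN=2 on a 4x4x1 pair
        pred = np.zeros((4, 4, 1), dtype=np.uint8)
        label = np.zeros((4, 4, 1), dtype=np.uint8)
        pred[0:2, 0:4] = 1    # 8 predicted
        label[0:2, 0:3] = 1   # 6 overlap
        label[2, 0:2] = 1     # 2 missed
        dice, jacc, counts = overlap_metrics(pred, label)
        assert (counts.TP, counts.FP, counts.FN) == (6, 2, 2)
        assert dice == pytest.approx(0.75)
        assert jacc == pytest.approx(0.6)
        assert counts.total == pred.size

    def test_both_empty_convention(self):
        z = np.zeros((3, 3, 3), dtype=np.uint8)
        dice, jacc, _ = overlap_metrics(z, z)
        assert dice == 1.0 and jacc == 1.0

    def test_symmetry_and_duality(self, rng):
        for _ in range(10):
            a, b = random_mask(rng), random_mask(rng)
            d1, j1, _ = overlap_metrics(a, b)
            d2, j2, _ = overlap_metrics(b, a)
            assert d1 == d2 and j1 == j2
            assert d1 == pytest.approx(2 * j1 / (1 + j1), abs=1e-12)
            assert j1 <= d1 + 1e-12


class TestSurfaceDistances:
    def test_identical_masks_zero(self, rng):
        m = random_mask(rng)
        asd, hd95 = surface_distance_metrics(m, m)
        assert asd == 0.0 and hd95 == 0.0

    def test_two_voxels_three_apart(self):
        a = np.zeros((8, 8, 8), dtype=np.uint8)
        b = np.zeros((8, 8, 8), dtype=np.uint8)
        a[2, 2, 2] = 1
        b[2, 2, 5] = 1
        asd, hd95 = surface_distance_metrics(a, b)
        assert asd == pytest.approx(3.0)
        assert hd95 == pytest.approx(3.0)

    def test_matches_all_pairs_oracle_on_random_masks(self, rng):
        """50 random 16^3 mask pairs, exact agreement with the O(|X||Y|) oracle."""
        for _ in range(50):
            a, b = random_mask(rng), random_mask(rng)
            asd, hd95 = surface_distance_metrics(a, b)
            asd_ref, hd95_ref = brute_surface_metrics(a, b)
            assert asd == pytest.approx(asd_ref, abs=1e-9)
            assert hd95 == pytest.approx(hd95_ref, abs=1e-9)

    def test_anisotropic_spacing(self):
        a = np.zeros((8, 8, 8), dtype=np.uint8)
        b = np.zeros((8, 8, 8), dtype=np.uint8)
        a[2, 2, 2] = 1
        b[2, 2, 4] = 1
        asd, _ = surface_distance_metrics(a, b, spacing=(1, 1, 2.5))
        assert asd == pytest.approx(5.0)

    def test_symmetry_and_axis_permutation_invariance(self, rng):
        a, b = random_mask(rng), random_mask(rng)
        f = surface_distance_metrics
        assert f(a, b) == pytest.approx(f(b, a))
        perm = (2, 0, 1)
        assert f(a.transpose(perm), b.transpose(perm)) == pytest.approx(f(a, b))

    def test_empty_mask_raises_defined_failure(self):
        m = np.zeros((4, 4, 4), dtype=np.uint8)
        n = m.copy()
        n[1, 1, 1] = 1
        with pytest.raises(EmptyMaskError):
            surface_distance_metrics(m, n)

    def test_scaled_max_convention(self):
        a = np.zeros((8, 8, 8), dtype=np.uint8)
        b = np.zeros((8, 8, 8), dtype=np.uint8)
        a[2, 2, 2] = 1
        b[2, 2, 6] = 1
        _, hd = surface_distance_metrics(a, b, hd95_convention="scaled_max")
        assert hd == pytest.approx(0.95 * 4.0)

    def test_boundary_definition_matches_brute_force(self, rng):
        for _ in range(5):
            m = random_mask(rng)
            np.testing.assert_array_equal(boundary_mask(m), brute_boundary(m))


class TestReassembly:
    def test_slice_then_reassemble_identity(self, tiny_volumes):
        for vol in tiny_volumes[:3]:
            planes = [s.image for s in slice_volume(vol)]
            rebuilt = reassemble_volume(planes, vol.shape,
                                        z_indices=list(range(vol.shape[2])))
            np.testing.assert_array_equal(rebuilt, vol.intensities)

    def test_all_zero_slices(self):
        planes = [np.zeros((8, 8)) for _ in range(4)]
        out = reassemble_volume(planes, (8, 8, 4))
        assert out.sum() == 0

    def test_wrong_count_and_order_detected(self):
        planes = [np.zeros((8, 8))] * 4
        with pytest.raises(ValueError):
            reassemble_volume(planes[:3], (8, 8, 4))
        with pytest.raises(ValueError):
            reassemble_volume(planes, (8, 8, 4), z_indices=[0, 2, 1, 3])

    def test_mask_resize_back_preserves_binarity(self):
        planes = [(np.random.default_rng(0).random((16, 16)) > 0.5).astype(np.uint8)
                  for _ in range(2)]
        out = reassemble_volume(planes, (24, 24, 2), is_mask=True)
        assert set(np.unique(out)) <= {0, 1}


class TestBinarize:
    def test_boundary_convention_is_geq(self):
        assert binarize(np.full((3, 3), 0.5), 0.5).all()

    def test_extreme_thresholds(self, rng):
        p = rng.random((5, 5))
        assert binarize(p, 0.0).all()
        assert not binarize(p, 1.0001).any()

    def test_matches_elementwise_comparison(self, rng):
        p = rng.random((6, 6))
        np.testing.assert_array_equal(binarize(p, 0.4), (p >= 0.4).astype(np.uint8))


class TestEvaluate:
    def _cfg(self):
        return FrameworkConfig(input_size=32, depth=3, base_channels=8,
                               iterations=1, batch_size=4, labeled_per_batch=2)

    def test_perfect_oracle_model(self, tiny_volumes):
        """A model that returns the true label plane scores perfectly."""
        cfg = self._cfg()
        vol = tiny_volumes[0]

        class Oracle:
            def __init__(self):
                self.calls = 0

            def __call__(self, batch):
                n = batch.shape[0]
                out = np.stack([vol.label[:, :, self.calls + i].astype(np.float32)
                                for i in range(n)])
                self.calls += n
                return out

        report = evaluate(Oracle(), [vol], cfg)
        row = report.per_volume.iloc[0]
        assert row.dice == 1.0 and row.jaccard == 1.0
        assert row.asd == 0.0 and row.hd95 == 0.0

    def test_constant_zero_model_sentinel(self, tiny_volumes):
        cfg = self._cfg()
        report = evaluate(lambda b: np.zeros(b.shape, dtype=np.float32),
                          [tiny_volumes[0]], cfg)
        row = report.per_volume.iloc[0]
        assert row.dice == 0.0
        assert np.isnan(row.asd) and np.isnan(row.hd95)

    def test_unlabeled_test_volume_rejected(self, tiny_volumes):
        cfg = self._cfg()
        with pytest.raises(ValueError):
            evaluate(lambda b: np.zeros(b.shape), [tiny_volumes[0].without_label()], cfg)
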