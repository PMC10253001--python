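"""Slicing, preprocessing, pseudo-3D stacks, splits and batch assembly."""

import numpy as np
import pytest

from dtmt.config import FrameworkConfig
from dtmt.data import (BatchIterator, SemiSupervisedDataset, make_batch,
                       make_pseudo3d, prepare_volume, preprocess_slices,
                       slice_volume, split_dataset)
from dtmt.synthetic import PhantomParams, Volume, generate_phantom


@pytest.fixture
def vol32():
    return generate_phantom(PhantomParams(grid_shape=(32, 32, 32), seed=1,
                                          main_blob_radius_range=(8.0, 10.0)))


class TestSliceVolume:
    def test_slice_count_and_content(self, vol32):
        samples = slice_volume(vol32)
        assert len(samples) == 32
        for k, s in enumerate(samples):
            assert s.z_index == k
            np.testing.assert_array_equal(s.image, vol32.intensities[:, :, k])
            np.testing.assert_array_equal(s.label, vol32.label[:, :, k])

    def test_unlabeled_volume_gives_unlabeled_slices(self, vol32):
        for s in slice_volume(vol32.without_label()):
            assert s.label is None


class TestPreprocess:
    def test_empty_label_slices_dropped_in_training_only(self, vol32):
        cfg = FrameworkConfig(input_size=32, depth=3, base_channels=8)
        raw = slice_volume(vol32)
        n_nonempty = sum(1 for s in raw if s.label.any())
        assert n_nonempty < len(raw)  # phantom has empty end slices
        assert len(preprocess_slices(raw, cfg, training=True)) == n_nonempty
        assert len(preprocess_slices(raw, cfg, training=False)) == len(raw)

    def test_identity_settings_reduce_to_minmax(self, vol32):
        cfg = FrameworkConfig(input_size=32, depth=3, gamma=1.0)
        s = slice_volume(vol32)[16]
        out = preprocess_slices([s], cfg)[0]
        lo, hi = s.image.min(), s.image.max()
        np.testing.assert_allclose(out.image, (s.image - lo) / (hi - lo), atol=1e-6)

    def test_resize_keeps_labels_binary_and_range(self):
        rng = np.random.default_rng(0)
        img = rng.random((160, 160)).astype(np.float32)
        lbl = np.zeros((160, 160), dtype=np.uint8)
        lbl[40:100, 60:120] = 1
        from dtmt.data import SliceSample
        cfg = FrameworkConfig(input_size=128, depth=3)
        out = preprocess_slices([SliceSample(img, lbl, "v", 0)], cfg)[0]
        assert out.image.shape == (128, 128) and out.label.shape == (128, 128)
        assert out.image.min() >= 0 and out.image.max() <= 1
        assert set(np.unique(out.label)) <= {0, 1}
        assert out.label.any()

    def test_constant_slice_maps_to_zeros(self):
        from dtmt.data import SliceSample
        cfg = FrameworkConfig(input_size=32, depth=3)
        out = preprocess_slices([SliceSample(np.full((32, 32), 0.7), None, "v", 0)], cfg)
        assert out[0].image.sum() == 0

    def test_gamma_brightens(self, vol32):
        cfg = FrameworkConfig(input_size=32, depth=3, gamma=0.8)
        s = slice_volume(vol32)[16]
        bright = preprocess_slices([s], cfg)[0].image
        cfg1 = FrameworkConfig(input_size=32, depth=3, gamma=1.0)
        plain = preprocess_slices([s], cfg1)[0].image
        interior = (plain > 0) & (plain < 1)
        assert (bright[interior] >= plain[interior]).all()


class TestPseudo3d:
    def _slices(self, z=6, hw=8):
        from dtmt.data import SliceSample
        return [SliceSample(np.full((hw, hw), float(k)), None, "v", k)
                for k in range(z)]

    def test_interior_index(self):
        s = self._slices()
        stack = make_pseudo3d(s, 3, radius=1)
        np.testing.assert_array_equal(stack[:, 0, 0], [2.0, 3.0, 4.0])

    def test_boundary_replication(self):
        s = self._slices()
        np.testing.assert_array_equal(make_pseudo3d(s, 0, 1)[:, 0, 0], [0.0, 0.0, 1.0])
        np.testing.assert_array_equal(make_pseudo3d(s, 5, 1)[:, 0, 0], [4.0, 5.0, 5.0])

    def test_radius_two(self):
        s = self._slices()
        np.testing.assert_array_equal(make_pseudo3d(s, 1, 2)[:, 0, 0],
                                      [0.0, 0.0, 1.0, 2.0, 3.0])

    def test_centre_plane_is_the_slice(self, vol32):
        cfg = FrameworkConfig(input_size=32, depth=3)
        samples = prepare_volume(vol32, cfg, training=False)
        for s in samples[:5]:
            np.testing.assert_array_equal(s.stack[1], s.image)
            assert s.stack.shape == (3, 32, 32)

    def test_errors(self):
        with pytest.raises(ValueError):
            make_pseudo3d([], 0, 1)
        s = self._slices()
        with pytest.raises(IndexError):
            make_pseudo3d(s, 9, 1)
        with pytest.raises(ValueError):
            make_pseudo3d(s, 0, 0)


class TestSplit:
    def _cohort(self, n=10):
        return [generate_phantom(PhantomParams(grid_shape=(32, 32, 16),
                                               main_blob_radius_range=(5.0, 7.0),
                                               seed=i)) for i in range(n)]

    def _rename(self, vols):
        for i, v in enumerate(vols):
            v.id = f"v{i:02d}"
        return vols

    def test_counts_ten_volumes(self):
        vols = self._rename(self._cohort(10))
        cfg = FrameworkConfig(input_size=32, depth=3)
        ds = split_dataset(vols, 0.1, seed=0, test_fraction=0.2, cfg=cfg)
        assert len(ds.partition["labeled"]) == 1
        assert len(ds.partition["unlabeled"]) == 7
        assert len(ds.partition["test"]) == 2

    def test_volume_level_disjointness(self):
        vols = self._rename(self._cohort(10))
        cfg = FrameworkConfig(input_size=32, depth=3)
        ds = split_dataset(vols, 0.2, seed=3, test_fraction=0.2, cfg=cfg)
        groups = [set(ds.partition["labeled"]), set(ds.partition["unlabeled"]),
                  set(ds.partition["test"])]
        assert not (groups[0] & groups[1] | groups[0] & groups[2] | groups[1] & groups[2])
        assert {s.volume_id for s in ds.labeled} == groups[0]
        assert {s.volume_id for s in ds.unlabeled} == groups[1]

    def test_unlabeled_samples_stripped(self):
        vols = self._rename(self._cohort(6))
        cfg = FrameworkConfig(input_size=32, depth=3)
        ds = split_dataset(vols, 0.3, seed=1, test_fraction=0.2, cfg=cfg)
        assert all(s.label is None for s in ds.unlabeled)
        assert all(s.label is not None and s.label.any() for s in ds.labeled)

    def test_determinism(self):
        vols = self._rename(self._cohort(8))
        cfg = FrameworkConfig(input_size=32, depth=3)
        a = split_dataset(vols, 0.2, seed=5, test_fraction=0.25, cfg=cfg)
        b = split_dataset(vols, 0.2, seed=5, test_fraction=0.25, cfg=cfg)
        assert a.partition == b.partition

    def test_invalid_fractions(self):
        vols = self._rename(self._cohort(8))
        with pytest.raises(ValueError):
            split_dataset(vols, 0.0, seed=0)
        with pytest.raises(ValueError):
            split_dataset(vols, 1.2, seed=0)
        with pytest.raises(ValueError):
            split_dataset(vols, 0.01, seed=0, test_fraction=0.25)  # rounds to 0 labeled

    def test_partition_overlap_rejected(self, vol32):
        s = slice_volume(vol32)[:2]
        with pytest.raises(ValueError):
            SemiSupervisedDataset(labeled=s, unlabeled=s, test=[])


class TestBatching:
    def _dataset(self, tiny_volumes, cfg):
        return split_dataset(tiny_volumes, 0.25, seed=2, test_fraction=0.25, cfg=cfg)

    def test_batch_composition(self, tiny_volumes, tiny_cfg):
        ds = self._dataset(tiny_volumes, tiny_cfg)
        batch = make_batch(ds, tiny_cfg, np.random.default_rng(0))
        assert len(batch.labeled) == tiny_cfg.labeled_per_batch
        assert len(batch.unlabeled) == tiny_cfg.unlabeled_per_batch
        assert batch.unlabeled_stacks().shape == (
            tiny_cfg.unlabeled_per_batch, tiny_cfg.stack_planes,
            tiny_cfg.input_size, tiny_cfg.input_size)
        assert all(s.label is not None for s in batch.labeled)
        assert all(s.label is None for s in batch.unlabeled)

    def test_epoch_without_replacement(self, tiny_volumes, tiny_cfg):
        ds = self._dataset(tiny_volumes, tiny_cfg)
        it = BatchIterator(ds, tiny_cfg, np.random.default_rng(1))
        n = len(ds.unlabeled)
        per = tiny_cfg.unlabeled_per_batch
        seen = []
        for _ in range(n // per):
            batch = it.next_batch()
            seen.extend(id(s) for s in batch.unlabeled)
        assert len(set(seen)) == len(seen)  # no repeats within one epoch

    def test_reshuffled_between_epochs_and_deterministic(self, tiny_volumes, tiny_cfg):
        ds = self._dataset(tiny_volumes, tiny_cfg)
        def order(seed, batches=30):
            it = BatchIterator(ds, tiny_cfg, np.random.default_rng(seed))
            return [id(s) for _ in range(batches) for s in it.next_batch().unlabeled]
        assert order(1) == order(1)
        assert order(1) != order(2)

    def test_small_labeled_pool_reused(self, tiny_volumes, tiny_cfg):
        ds = self._dataset(tiny_volumes, tiny_cfg)
        ds_small = SemiSupervisedDataset(ds.labeled[:2], ds.unlabeled, ds.test)
        it = BatchIterator(ds_small, tiny_cfg, np.random.default_rng(0))
        batch = it.next_batch()
        assert len(batch.labeled) == tiny_cfg.labeled_per_batch
        assert len({id(s) for s in batch.labeled}) == 2

    def test_empty_pool_rejected(self, tiny_volumes, tiny_cfg):
        ds = self._dataset(tiny_volumes, tiny_cfg)
        with pytest.raises(ValueError):
            BatchIterator(SemiSupervisedDataset([], ds.unlabeled, ds.test),
                          tiny_cfg, np.random.default_rng(0))
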