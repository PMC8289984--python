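"""Image I/O, preprocessing, and the splitting protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image

from anodet.data_io import (LABEL_NORMAL, Manifest, SplitResult,
                            check_training_purity, load_image,
                            monte_carlo_splits, normalize_intensity,
                            resample_lanczos, split_dataset)
from anodet.exceptions import (ContractViolationError, FormatError,
                               InvalidSpecError, ShapeError)
from conftest import make_manifest


class TestLoadImage:
    def test_constant_8bit_png(self, tmp_path):
        path = tmp_path / "c.png"
        Image.fromarray(np.full((8, 8), 255, dtype=np.uint8)).save(path)
        grid = load_image(path)
        assert grid.shape == (8, 8)
        np.testing.assert_array_equal(grid, 255.0)

    def test_missing_path_raises(self, tmp_path):
        with pytest.raises(FormatError):
            load_image(tmp_path / "nope.png")

    def test_color_image_rejected(self, tmp_path):
        path = tmp_path / "rgb.png"
        Image.fromarray(np.zeros((4, 4, 3), dtype=np.uint8)).save(path)
        with pytest.raises(FormatError):
            load_image(path)

    def test_16bit_tiff_preserved(self, tmp_path):
        path = tmp_path / "x.tiff"
        data = (np.arange(16, dtype=np.uint16) * 4000).reshape(4, 4)
        Image.fromarray(data).save(path)
        np.testing.assert_array_equal(load_image(path), data.astype(float))


class TestResampleLanczos:
    def test_identity_resize_returns_input(self):
        grid = np.random.default_rng(0).uniform(-1, 1, (16, 16))
        np.testing.assert_array_equal(resample_lanczos(grid, 16),
                                      grid.astype(np.float32))

    def test_constant_grid_stays_constant(self):
        out = resample_lanczos(np.full((64, 64), 0.37), 16)
        assert np.abs(out - 0.37).max() < 1e-6

    def test_downsample_shape(self):
        out = resample_lanczos(np.zeros((1024, 1024)), 256)
        assert out.shape == (256, 256)

    def test_non_square_rejected(self):
        with pytest.raises(ShapeError):
            resample_lanczos(np.zeros((8, 16)), 4)


class TestNormalizeIntensity:
    def test_8bit_endpoints_and_midpoint(self):
        out = normalize_intensity(np.array([0.0, 127.5, 255.0]),
                                  source_range=(0, 255))
        np.testing.assert_allclose(out, [-1.0, 0.0, 1.0])

    def test_16bit_endpoint(self):
        out = normalize_intensity(np.array([65535], dtype=np.uint16))
        np.testing.assert_allclose(out, [1.0])

    def test_already_normalized_range_is_identity(self):
        grid = np.linspace(-1, 1, 7)
        np.testing.assert_allclose(
            normalize_intensity(grid, source_range=(-1, 1)), grid)

    def test_range_inferred_from_uint8_dtype(self):
        out = normalize_intensity(np.array([0, 255], dtype=np.uint8))
        np.testing.assert_allclose(out, [-1.0, 1.0])

    def test_float_without_range_rejected(self):
        with pytest.raises(InvalidSpecError):
            normalize_intensity(np.zeros(3))


class TestSplitDataset:
    def test_ten_normals_split_7_1_2(self):
        split = split_dataset(make_manifest(10), seed=0)
        assert (len(split.train_ids), len(split.val_ids),
                len(split.test_ids)) == (7, 1, 2)

    def test_mixed_small_manifest_follows_floor_rules(self):
        # 3 Normal: train floor(2.1)=2, leftover 1 -> val 0 / test 1;
        # 3 abnormal -> val 1 / test 2; totals val 1, test 3.
        split = split_dataset(make_manifest(3, n_opacity=2, n_not_normal=1),
                              seed=1)
        assert len(split.train_ids) == 2
        assert len(split.val_ids) == 1
        assert len(split.test_ids) == 3

    def test_train_is_normal_only(self):
        manifest = make_manifest(20, n_opacity=15, n_not_normal=15)
        split = split_dataset(manifest, seed=3)
        labels = manifest.labels_by_id()
        assert all(labels[i] == LABEL_NORMAL for i in split.train_ids)

    def test_deterministic_given_seed(self):
        manifest = make_manifest(15, n_opacity=5)
        assert split_dataset(manifest, 7) == split_dataset(manifest, 7)

    def test_empty_manifest_rejected(self):
        with pytest.raises(InvalidSpecError):
            split_dataset(Manifest([]), seed=0)

    @settings(max_examples=40, deadline=None)
    @given(n_normal=st.integers(1, 60), n_op=st.integers(0, 40),
           n_nn=st.integers(0, 40), seed=st.integers(0, 2**31 - 1))
    def test_partition_property(self, n_normal, n_op, n_nn, seed):
        manifest = make_manifest(n_normal, n_op, n_nn)
        split = split_dataset(manifest, seed)
        train, val, test = (set(split.train_ids), set(split.val_ids),
                            set(split.test_ids))
        assert not (train & val or train & test or val & test)
        assert train | val | test == {r.id for r in manifest}
        labels = manifest.labels_by_id()
        assert all(labels[i] == LABEL_NORMAL for i in train)
        # count formulas
        assert len(train) == int(0.7 * n_normal)
        rest_normal = n_normal - len(train)
        assert len(val) == rest_normal // 3 + (n_op + n_nn) // 3


class TestMonteCarloSplits:
    def test_repeat_count_and_determinism(self):
        manifest = make_manifest(12, n_opacity=6)
        a = monte_carlo_splits(manifest, 4, master_seed=5)
        b = monte_carlo_splits(manifest, 4, master_seed=5)
        assert len(a) == 4 and a == b
        assert len({s.seed for s in a}) == 4

    def test_single_repeat_matches_direct_split(self):
        manifest = make_manifest(12, n_opacity=6)
        (only,) = monte_carlo_splits(manifest, 1, master_seed=5)
        assert only == split_dataset(manifest, only.seed)

    def test_zero_repeats_rejected(self):
        with pytest.raises(InvalidSpecError):
            monte_carlo_splits(make_manifest(5), 0, master_seed=0)


class TestSerialization:
    def test_split_json_round_trip(self, tmp_path):
        split = split_dataset(make_manifest(9, n_opacity=3), seed=2)
        path = tmp_path / "split.json"
        split.to_json(path)
        assert SplitResult.from_json(path) == split

    def test_manifest_csv_round_trip(self, tmp_path):
        manifest = make_manifest(3, n_opacity=2)
        path = tmp_path / "manifest.csv"
        manifest.to_csv(path)
        loaded = Manifest.from_csv(path)
        assert [r.id for r in loaded] == [r.id for r in manifest]
        assert loaded.label_counts == manifest.label_counts


def test_training_purity_check():
    manifest = make_manifest(2, n_opacity=1)
    with pytest.raises(ContractViolationError):
        check_training_purity(manifest.records)
    check_training_purity([r for r in manifest if r.label == LABEL_NORMAL])
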