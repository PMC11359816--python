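"""Dataset-construction pipeline: resampling, normalization, windowing,
filtering, mirror augmentation, splitting, stitching and raster I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raftseg import (
    BandStack, TilePair, augment_tiles, filter_background_tiles,
    normalize_reflectance, resample_to_10m, sliding_window_tiles,
    split_dataset, stitch_predictions,
)
from raftseg.geotiff import read_geotiff, read_mask, write_geotiff, write_mask
from raftseg.tiling import read_tile_directory, write_tile_directory


class TestResample:
    def test_constant_plane_stays_constant(self):
        out = resample_to_10m(np.full((5, 5), 0.3), 2)
        assert out.shape == (10, 10)
        np.testing.assert_allclose(out, 0.3)

    def test_ramp_uses_half_pixel_bilinear_weights(self):
        out = resample_to_10m(np.array([[0.0, 1.0], [0.0, 1.0]]), 2)
        np.testing.assert_allclose(out, np.tile([0.0, 0.25, 0.75, 1.0], (4, 1)))

    def test_shape_doubles(self):
        assert resample_to_10m(np.zeros((50, 60)), 2).shape == (100, 120)

    def test_nodata_propagates(self):
        out = resample_to_10m(np.full((4, 4), np.nan), 2)
        assert np.isnan(out).all()

    def test_bad_factor(self):
        with pytest.raises(ValueError, match="factor"):
            resample_to_10m(np.zeros((4, 4)), 0)


class TestNormalize:
    @pytest.mark.parametrize("dn,expected", [(5000, 0.5), (12000, 1.0), (0, 0.0)])
    def test_scaling_and_clipping(self, dn, expected):
        assert normalize_reflectance(np.array([dn]))[0] == expected

    def test_nan_propagates(self):
        assert np.isnan(normalize_reflectance(np.array([np.nan]))[0])


def _stack(h, w, bands=10, seed=0):
    return BandStack(np.random.default_rng(seed).random((bands, h, w)).astype(np.float32))


class TestSlidingWindow:
    def test_1024_gives_nine_tiles(self):
        tiles = sliding_window_tiles(_stack(1024, 1024), None)
        assert len(tiles) == 9

    def test_exact_fit_gives_single_tile(self):
        tiles = sliding_window_tiles(_stack(512, 512), None)
        assert len(tiles) == 1 and tiles[0].origin == (0, 0)

    def test_edge_snapping_covers_every_pixel(self):
        stack = _stack(1000, 1000, bands=1)
        tiles = sliding_window_tiles(stack, None)
        offsets = sorted({t.origin[0] for t in tiles})
        assert offsets == [0, 256, 488] and len(tiles) == 9
        hit = np.zeros((1000, 1000), dtype=bool)
        for t in tiles:
            r, c = t.origin
            hit[r:r + 512, c:c + 512] = True
        assert hit.all()

    def test_small_raster_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            sliding_window_tiles(_stack(100, 100), None)

    def test_masks_cut_in_register(self):
        stack = _stack(600, 600, bands=1)
        mask = (np.arange(600 * 600).reshape(600, 600) % 7 == 0).astype(np.uint8)
        tiles = sliding_window_tiles(stack, mask)
        for t in tiles:
            r, c = t.origin
            assert np.array_equal(t.mask, mask[r:r + 512, c:c + 512])
            assert np.array_equal(t.image, stack.data[:, r:r + 512, c:c + 512])


def _mini_tiles(n, with_raft):
    tiles = []
    for i in range(n):
        mask = np.zeros((4, 4), dtype=np.uint8)
        if with_raft:
            mask[i % 4, (i * 2) % 4] = 1
        tiles.append(TilePair(image=np.zeros((2, 4, 4), dtype=np.float32),
                              mask=mask, tile_id=f"t{i}"))
    return tiles


class TestFilterBackground:
    def test_raft_tiles_always_retained(self):
        tiles = _mini_tiles(5, with_raft=True)
        assert len(filter_background_tiles(tiles, keep_p=0.0)) == 5

    def test_pure_background_dropped_at_zero_keep(self):
        tiles = _mini_tiles(5, with_raft=False)
        assert filter_background_tiles(tiles, keep_p=0.0) == []

    def test_keep_region_overrides_drop(self):
        tiles = _mini_tiles(1, with_raft=False)
        region = np.zeros((4, 4), dtype=np.uint8)
        region[0, 0] = 1
        assert len(filter_background_tiles(tiles, keep_region=region)) == 1

    def test_seeded_negative_sampling_replays(self):
        tiles = _mini_tiles(100, with_raft=False)
        kept = filter_background_tiles(tiles, keep_p=0.2, seed=33)
        replay = np.random.default_rng(33)
        expected = [t.tile_id for t in tiles if replay.uniform() < 0.2]
        assert [t.tile_id for t in kept] == expected


class TestAugment:
    def test_paper_scale_bookkeeping(self):
        tiles = [TilePair(image=np.zeros((1, 2, 2), dtype=np.float32),
                          mask=np.zeros((2, 2), dtype=np.uint8), tile_id=f"t{i}")
                 for i in range(2518)]
        assert len(augment_tiles(tiles)) == 10072

    def test_horizontal_flip_is_involution(self, rng):
        tile = TilePair(image=rng.random((3, 5, 5)).astype(np.float32),
                        mask=(rng.random((5, 5)) > 0.5).astype(np.uint8), tile_id="a")
        once = augment_tiles([tile])[1]
        twice = augment_tiles([once])[1]
        assert np.array_equal(twice.image, tile.image)
        assert np.array_equal(twice.mask, tile.mask)

    def test_asymmetric_probe_variants(self):
        probe = np.array([[1, 0, 0], [0, 0, 0], [0, 0, 2]], dtype=np.uint8)
        tile = TilePair(image=probe[None].astype(np.float32), mask=probe, tile_id="p")
        variants = {t.tile_id.split("_")[-1]: t.mask for t in augment_tiles([tile])}
        np.testing.assert_array_equal(variants["orig"], probe)
        np.testing.assert_array_equal(
            variants["hflip"], [[0, 0, 1], [0, 0, 0], [2, 0, 0]])
        np.testing.assert_array_equal(
            variants["vflip"], [[0, 0, 2], [0, 0, 0], [1, 0, 0]])
        np.testing.assert_array_equal(variants["diag"], probe.T)

    def test_images_and_masks_co_transform(self, rng):
        img = rng.random((2, 4, 4)).astype(np.float32)
        tile = TilePair(image=img, mask=(img[0] > 0.5).astype(np.uint8), tile_id="c")
        for v in augment_tiles([tile]):
            assert np.array_equal(v.mask, (v.image[0] > 0.5).astype(np.uint8))


class TestSplit:
    def test_paper_scale_counts(self):
        m = split_dataset(10072, seed=0)
        assert m.counts == (7051, 2014, 1007)

    def test_minimum_size(self):
        assert split_dataset(10, seed=1).counts == (7, 2, 1)
        with pytest.raises(ValueError, match="at least 10"):
            split_dataset(9, seed=1)

    @given(st.integers(10, 5000), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_partition_is_disjoint_and_exhaustive(self, n, seed):
        m = split_dataset(n, seed=seed)
        all_ids = m.train + m.test + m.validation
        assert len(all_ids) == n == len(set(all_ids))

    def test_seed_determinism_and_variation(self):
        a = split_dataset(100, seed=5)
        b = split_dataset(100, seed=5)
        c = split_dataset(100, seed=6)
        assert a.train == b.train and a.test == b.test
        assert a.counts == c.counts and a.train != c.train


class TestStitch:
    def test_single_tile_identity(self, rng):
        plane = rng.random((8, 8))
        out = stitch_predictions([plane], [(0, 0)], (8, 8))
        np.testing.assert_allclose(out, plane)

    def test_overlap_averages(self):
        a = np.full((4, 8), 0.2)
        b = np.full((4, 8), 0.8)
        out = stitch_predictions([a, b], [(0, 0), (4, 0)], (8, 8))
        np.testing.assert_allclose(out[:4], 0.2)
        np.testing.assert_allclose(out[4:], 0.8)
        out2 = stitch_predictions([a, b], [(0, 0), (2, 0)], (6, 8))
        np.testing.assert_allclose(out2[2:4], 0.5)

    def test_consistent_field_reconstructs_losslessly(self, rng):
        field = rng.random((20, 20))
        tiles, origins = [], []
        for r in (0, 6, 12):
            for c in (0, 6, 12):
                tiles.append(field[r:r + 8, c:c + 8])
                origins.append((r, c))
        np.testing.assert_allclose(
            stitch_predictions(tiles, origins, (20, 20)), field, atol=1e-12)

    def test_uncovered_pixel_raises(self):
        with pytest.raises(ValueError, match="no tile"):
            stitch_predictions([np.zeros((4, 4))], [(0, 0)], (8, 8))


class TestRasterIO:
    def test_geotiff_round_trip(self, tmp_path, rng):
        stack = BandStack(rng.random((10, 6, 7)).astype(np.float32),
                          transform=(500000.0, 10.0, 0.0, 4300000.0, 0.0, -10.0),
                          crs="EPSG:32650", nodata=-9999.0)
        write_geotiff(tmp_path / "s.tif", stack)
        back = read_geotiff(tmp_path / "s.tif")
        np.testing.assert_array_equal(back.data, stack.data)
        assert back.transform == stack.transform
        assert back.crs == "EPSG:32650" and back.nodata == -9999.0

    def test_mask_round_trip(self, tmp_path, rng):
        mask = (rng.random((9, 9)) > 0.5).astype(np.uint8)
        write_mask(tmp_path / "m.png", mask)
        assert np.array_equal(read_mask(tmp_path / "m.png"), mask)

    def test_tile_directory_round_trip(self, tmp_path, rng):
        tiles = [TilePair(image=rng.random((10, 4, 4)).astype(np.float32),
                          mask=(rng.random((4, 4)) > 0.5).astype(np.uint8),
                          origin=(i, 2 * i), source_id="src", tile_id=f"t{i}")
                 for i in range(3)]
        write_tile_directory(tmp_path / "tiles", tiles)
        back = read_tile_directory(tmp_path / "tiles")
        assert [t.tile_id for t in back] == ["t0", "t1", "t2"]
        for a, b in zip(tiles, back):
            np.testing.assert_array_equal(a.image, b.image)
            np.testing.assert_array_equal(a.mask, b.mask)
            assert a.origin == b.origin
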