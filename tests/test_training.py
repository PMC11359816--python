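"""Training loop, evaluation pooling, checkpoint resume and whole-raster
prediction."""

import numpy as np
import pytest

from raftseg import (
    BandStack, NetworkConfig, TrainConfig, build_model, cosine_lr, evaluate,
    generate_training_tiles, load_checkpoint, predict_raster, save_checkpoint,
    train,
)
from raftseg.metrics import compute_metrics, ConfusionCounts


class TestCosineSchedule:
    def test_endpoints_and_midpoint_exact(self):
        assert cosine_lr(0, 100, 1e-4) == 1e-4
        assert cosine_lr(100, 100, 1e-4) == pytest.approx(0.0, abs=1e-20)
        assert cosine_lr(50, 100, 1e-4) == pytest.approx(5e-5, abs=1e-19)

    def test_nonzero_floor(self):
        assert cosine_lr(10, 10, 1e-3, lr_min=1e-5) == pytest.approx(1e-5)

    def test_zero_total_steps_rejected(self):
        with pytest.raises(ValueError, match="total_steps"):
            cosine_lr(0, 0, 1e-4)

    def test_monotone_decrease(self):
        vals = [cosine_lr(s, 20, 1e-4) for s in range(21)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


def _quick_cfg(**kw):
    base = dict(lr=5e-3, epochs=2, batch_size=4, seed=3, augment=True,
                scale_range=(1.0, 1.0), shear_deg=0.0)
    base.update(kw)
    return TrainConfig(**base)


class TestTrainLoop:
    def test_fixed_seed_reproduces_loss_log(self, tiny_config, small_tiles):
        logs = []
        for _ in range(2):
            model = build_model(tiny_config, seed=1)
            result = train(model, small_tiles, None, _quick_cfg())
            logs.append([row["train_loss"] for row in result["log"]])
        assert logs[0] == logs[1]

    def test_loss_descends_on_small_problem(self, tiny_config):
        tiles = generate_training_tiles(16, size=32, seed=77)
        model = build_model(tiny_config, seed=2)
        result = train(model, tiles, None, _quick_cfg(epochs=5, lr=1e-2))
        assert result["log"][-1]["train_loss"] < result["log"][0]["train_loss"]

    def test_empty_training_set_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="empty"):
            train(tiny_model, [], None, _quick_cfg())

    def test_resume_replays_uninterrupted_run(self, tiny_config, small_tiles, tmp_path):
        cfg = _quick_cfg(epochs=2, checkpoint_dir=str(tmp_path / "a"))
        model_a = build_model(tiny_config, seed=4)
        full = train(model_a, small_tiles, small_tiles[:4], cfg)

        model_b = build_model(tiny_config, seed=4)
        cfg_b = _quick_cfg(epochs=2, checkpoint_dir=str(tmp_path / "b"))
        resumed = train(model_b, small_tiles, small_tiles[:4], cfg_b,
                        resume_from=tmp_path / "a" / "epoch_000.npz")
        assert len(resumed["log"]) == 1
        assert resumed["log"][0] == full["log"][1]
        for k, v in model_a.state_dict().items():
            assert np.array_equal(v, model_b.state_dict()[k]), k


class TestCheckpointRoundTrip:
    def test_state_survives_save_load(self, tiny_config, tmp_path, rng):
        model = build_model(tiny_config, seed=5)
        x = rng.normal(size=(1, 10, 32, 32)).astype(np.float32)
        before = model.predict(x)
        save_checkpoint(tmp_path / "ck.npz", model, epoch=3, global_step=12)
        restored, meta = load_checkpoint(tmp_path / "ck.npz")
        assert meta["epoch"] == 3 and meta["global_step"] == 12
        np.testing.assert_array_equal(restored.predict(x), before)

    def test_sidecar_metadata_written(self, tiny_config, tmp_path):
        model = build_model(tiny_config, seed=5)
        save_checkpoint(tmp_path / "ck.npz", model)
        text = (tmp_path / "ck.npz.meta.txt").read_text()
        assert "B8A" in text and "version" in text


class TestEvaluate:
    def test_oracle_model_scores_perfectly(self, small_tiles):
        masks = iter([t.mask for t in small_tiles])

        def oracle(batch):
            return np.stack([next(masks) for _ in range(len(batch))])[:, None].astype(float)

        rep = evaluate(oracle, small_tiles, batch_size=len(small_tiles))
        assert rep.metrics.f1 == rep.metrics.iou == rep.metrics.kappa == 1.0

    def test_constant_half_output_with_tie_rule(self):
        """p = 0.5 classifies positive everywhere: pooled counts are all
        raft pixels as TP and all background as FP."""
        tiles = generate_training_tiles(4, size=32, seed=9)
        rep = evaluate(lambda b: np.full((len(b), 1, 32, 32), 0.5), tiles)
        n_raft = int(sum(t.mask.sum() for t in tiles))
        n_all = 4 * 32 * 32
        assert (rep.counts.tp, rep.counts.fp, rep.counts.fn, rep.counts.tn) == \
            (n_raft, n_all - n_raft, 0, 0)
        hand = compute_metrics(ConfusionCounts(n_raft, n_all - n_raft, 0, 0))
        assert rep.metrics.as_dict() == hand.as_dict()

    def test_repeated_evaluation_is_identical(self, tiny_model, small_tiles):
        a = evaluate(tiny_model, small_tiles)
        b = evaluate(tiny_model, small_tiles)
        assert a.metrics.as_dict() == b.metrics.as_dict()

    def test_empty_set_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="empty"):
            evaluate(tiny_model, [])


class TestPredictRaster:
    def test_single_tile_raster_equals_direct_forward(self, tiny_model, rng):
        data = rng.random((10, 32, 32)).astype(np.float32)
        stack = BandStack(data)
        prob, mask = predict_raster(tiny_model, stack)
        direct = tiny_model.predict(data[None]).reshape(32, 32)
        np.testing.assert_allclose(prob, direct, atol=1e-7)
        np.testing.assert_array_equal(mask, (direct >= 0.5).astype(np.uint8))

    def test_oracle_model_recovers_ground_truth(self):
        from raftseg import SceneSpec, generate_scene

        spec = SceneSpec(size=(96, 96), seed=31, cloud_patches=0)
        stack, truth = generate_scene(spec)

        # an all-background model finds nothing
        _, mask = predict_raster(
            lambda b: np.zeros((len(b), 1, 32, 32)), stack, window=32)
        assert mask.sum() == 0

        # a lookup oracle that answers every tile with its ground truth
        # must reproduce the full mask through tiling + stitching
        tiles_seen = {}

        def truth_oracle(batch):
            out = []
            for img in batch:
                key = img.tobytes()
                out.append(tiles_seen[key])
            return np.stack(out)[:, None].astype(float)

        from raftseg.tiling import sliding_window_tiles

        for t in sliding_window_tiles(stack, truth, window=32, step=16):
            tiles_seen[t.image.astype(np.float32).tobytes()] = t.mask
        prob, mask = predict_raster(truth_oracle, stack, window=32, step=16)
        np.testing.assert_array_equal(mask, truth)

    def test_overlap_averaging_matches_stitch_oracle(self, rng):
        """predict_raster's averaging equals the standalone stitcher on a
        fabricated per-tile probability field."""
        from raftseg.tiling import sliding_window_tiles, stitch_predictions

        stack = BandStack(rng.random((10, 48, 48)).astype(np.float32))
        fab = {}

        def fabricated(batch):
            out = []
            for img in batch:
                key = img.tobytes()
                out.append(fab[key])
            return np.stack(out)[:, None]

        tiles = sliding_window_tiles(stack, None, window=32, step=16)
        r = np.random.default_rng(0)
        for t in tiles:
            fab[t.image.astype(np.float32).tobytes()] = r.random((32, 32))
        prob, _ = predict_raster(fabricated, stack, window=32, step=16)
        expect = stitch_predictions(
            [fab[t.image.astype(np.float32).tobytes()] for t in tiles],
            [t.origin for t in tiles], (48, 48))
        np.testing.assert_allclose(prob, expect, atol=1e-12)

    def test_band_count_mismatch_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="bands"):
            predict_raster(tiny_model, BandStack(np.zeros((4, 32, 32))))

    def test_nodata_forced_to_background(self, tiny_model, rng):
        data = rng.random((10, 32, 32)).astype(np.float32)
        data[:, :5, :5] = np.nan
        prob, mask = predict_raster(tiny_model, BandStack(data))
        assert (prob[:5, :5] == 0).all() and (mask[:5, :5] == 0).all()
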