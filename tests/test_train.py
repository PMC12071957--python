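"""Training loop, evaluation report, ablation harness, checkpoints, estimator
contract and CLI round trips (desk-scale problem sizes)."""

import dataclasses

import numpy as np
import pytest
from click.testing import CliRunner
from sklearn.base import clone

from nucleiseg.cli import main as cli_main
from nucleiseg.config import ArchConfig, TrainConfig
from nucleiseg.model import assemble_model, assemble_variant, count_parameters
from nucleiseg.segmenter import UNetSegmenter
from nucleiseg.synthetic import SceneSpec, render_scene
from nucleiseg.train import (evaluate, label_instances, load_checkpoint,
                             run_ablation, save_checkpoint, train)


@pytest.fixture(scope="module")
def tiny_records():
    specs = [SceneSpec(image_size=32, n_instances=3, axis_range=(3.0, 5.0),
                       seed=200 + i) for i in range(4)]
    return [render_scene(s) for s in specs]


def _tiny_config(epochs=1, seed=0):
    return TrainConfig(arch=ArchConfig(input_size=32, seed=seed), epochs=epochs,
                       seed=seed, augment=False, patience=10 ** 6)


class TestTrainLoop:
    def test_one_epoch_finite_history(self, tiny_records):
        handle, history = train(_tiny_config(epochs=1), tiny_records)
        assert len(history["train_loss"]) == 1
        assert np.isfinite(history["train_loss"][0])

    def test_seeded_training_is_reproducible(self, tiny_records):
        _, h1 = train(_tiny_config(epochs=2, seed=3), tiny_records)
        _, h2 = train(_tiny_config(epochs=2, seed=3), tiny_records)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["train_dice"] == h2["train_dice"]

    def test_validation_curves_logged(self, tiny_records):
        handle, history = train(_tiny_config(epochs=2), tiny_records[:3],
                                tiny_records[3:])
        assert len(history["val_loss"]) == len(history["train_loss"]) == 2

    def test_augmented_training_runs_and_is_seeded(self, tiny_records):
        cfg = _tiny_config(epochs=2)
        cfg.augment = True
        _, h1 = train(cfg, tiny_records)
        _, h2 = train(cfg, tiny_records)
        assert h1["train_loss"] == h2["train_loss"]


class TestEvaluate:
    def test_all_background_prediction_scores_zero_dice(self, tiny_records):
        handle = assemble_model(ArchConfig(input_size=32))
        handle.net.head_conv.weight.data[...] = 0.0
        handle.net.head_conv.bias.data[...] = -20.0  # sigmoid -> ~0 everywhere
        report = evaluate(handle, tiny_records)
        agg = report.aggregate()
        assert agg["dsc"] == 0.0
        assert agg["object_detection_rate"] == 0.0

    def test_report_obeys_dice_jaccard_identity(self, tiny_records):
        handle = assemble_model(ArchConfig(input_size=32, seed=1))
        report = evaluate(handle, tiny_records)
        for row in report.per_image:
            assert np.isclose(row["iou"] * (2 - row["dsc"]), row["dsc"])

    def test_unlabeled_record_rejected(self, tiny_records):
        handle = assemble_model(ArchConfig(input_size=32))
        bad = dataclasses.replace(tiny_records[0], merged_mask=None)
        with pytest.raises(ValueError, match="unlabeled"):
            evaluate(handle, [bad])

    def test_label_instances_splits_components(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[1:3, 1:3] = 1
        m[6:9, 6:9] = 1
        parts = label_instances(m)
        assert len(parts) == 2
        assert sum(p.sum() for p in parts) == m.sum()


class TestAblationHarness:
    def test_parameter_counts_match_builder_and_csv_shape(self, tmp_path):
        cfg = ArchConfig()
        csv_path = tmp_path / "ablation.csv"
        results = run_ablation(cfg, csv_path=csv_path)
        assert len(results) == 6
        for r in results:
            assert r.n_parameters == count_parameters(assemble_variant(cfg, r.variant))
        import pandas as pd
        frame = pd.read_csv(csv_path)
        assert list(frame.columns) == ["Model Variant", "DSC", "Accuracy",
                                       "Parameters", "Parameters (M)"]
        assert len(frame) == 6

    def test_no_attention_layer_table_diff_is_attention_only(self):
        cfg = ArchConfig()
        full = assemble_variant(cfg, "full")
        noatt = assemble_variant(cfg, "no_attention")
        diff = [t for t in full.layer_table if t not in noatt.layer_table]
        assert all(t.kind.startswith("attention") for t in diff)
        assert len(diff) == 2


class TestCheckpoints:
    def test_roundtrip_preserves_predictions(self, tiny_records, tmp_path):
        handle, _ = train(_tiny_config(epochs=1), tiny_records)
        path = tmp_path / "model.npz"
        save_checkpoint(handle, path)
        back = load_checkpoint(path)
        x = np.asarray(tiny_records[0].image, dtype=np.float32)[None, None]
        np.testing.assert_array_equal(handle.net.forward(x), back.net.forward(x))


class TestEstimatorContract:
    def test_get_set_params_and_clone(self):
        est = UNetSegmenter(epochs=3, learning_rate=5e-4, variant="no_residual")
        params = est.get_params()
        assert params["epochs"] == 3 and params["variant"] == "no_residual"
        est2 = clone(est)
        assert est2.get_params() == params
        est2.set_params(epochs=7)
        assert est2.epochs == 7 and est.epochs == 3

    def test_fit_sets_trailing_underscore_attributes(self, tiny_records):
        X = np.stack([r.image for r in tiny_records]).astype(np.float32)
        y = np.stack([r.merged_mask for r in tiny_records]).astype(np.float32)
        est = UNetSegmenter(epochs=1, seed=0,
                            arch_config=ArchConfig(input_size=32))
        est.fit(X, y)
        assert est.n_parameters_ == est.net_.n_parameters()
        assert est.n_epochs_run_ == 1
        pred = est.predict(X)
        assert pred.shape == X.shape and set(np.unique(pred)) <= {0, 1}
        assert 0.0 <= est.score(X, y) <= 1.0

    def test_rejects_non_binary_targets(self):
        X = np.zeros((1, 32, 32), dtype=np.float32)
        y = np.full((1, 32, 32), 0.5)
        with pytest.raises(ValueError, match="binary"):
            UNetSegmenter(epochs=1).fit(X, y)


class TestCli:
    def test_params_prints_layer_table_and_count(self):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["params", "--variant", "full"])
        assert res.exit_code == 0
        assert "total_parameters=2214703" in res.output
        assert "depthwise3x3" in res.output

    def test_unknown_subcommand_exits_2(self):
        res = CliRunner().invoke(cli_main, ["frobnicate"])
        assert res.exit_code == 2

    def test_synth_train_eval_roundtrip(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        res = runner.invoke(cli_main, ["synth", "--n-images", "4", "--out",
                                       str(data), "--seed", "3",
                                       "--image-size", "64"])
        assert res.exit_code == 0, res.output
        ckpt = tmp_path / "m.npz"
        res = runner.invoke(cli_main, ["train", "--data", str(data),
                                       "--input-size", "32", "--epochs", "1",
                                       "--checkpoint", str(ckpt)])
        assert res.exit_code == 0, res.output
        assert ckpt.exists()
        with runner.isolated_filesystem(temp_dir=tmp_path):
            res = runner.invoke(cli_main, ["eval", "--data", str(data),
                                           "--checkpoint", str(ckpt),
                                           "--out", "rep"])
            assert res.exit_code == 0, res.output
            assert "aggregate:" in res.output

    def test_rle_cli_roundtrip(self, tmp_path):
        import imageio.v3 as iio
        mask = (np.random.default_rng(0).random((9, 9)) > 0.5).astype(np.uint8)
        src = tmp_path / "m.png"
        iio.imwrite(src, mask * 255)
        runner = CliRunner()
        res = runner.invoke(cli_main, ["rle", "encode", str(src)])
        assert res.exit_code == 0
        h, w, *runs = res.output.split()
        out = tmp_path / "back.png"
        res = runner.invoke(cli_main, ["rle", "decode", h, w, *runs,
                                       "--out", str(out)])
        assert res.exit_code == 0
        np.testing.assert_array_equal((iio.imread(out) > 0).astype(np.uint8), mask)

    def test_ablate_prints_all_variants(self, tmp_path):
        res = CliRunner().invoke(cli_main, ["ablate", "--out",
                                            str(tmp_path / "a.csv")])
        assert res.exit_code == 0
        for v in ("full", "baseline_unet", "no_depthwise"):
            assert v in res.output
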