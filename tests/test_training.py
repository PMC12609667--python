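"""Training loop, evaluation, ablation table, bootstrap driver, CLI plumbing."""

import csv
import json
from pathlib import Path

import numpy as np
import pytest

from wavebisenet import (NetworkConfig, TrainConfig, evaluate, run_ablation,
                         train, compare_models)
from wavebisenet.network import save_checkpoint
from wavebisenet.synthetic import generate_set, micro_config, split_and_crop
from wavebisenet.training import write_history_csv


def tiny_cfg(epochs, seed=7, width=0.125, **kw):
    return TrainConfig(epochs=epochs, batch_size=8, seed=seed,
                       network=NetworkConfig(width_mult=width, input_size=(64, 64)),
                       **kw)


@pytest.fixture(scope="module")
def tiny_data():
    samples = generate_set(24, seed=50)
    return samples[:16], samples[16:20], samples[20:]


@pytest.fixture(scope="module")
def trained(tiny_data):
    tr, va, te = tiny_data
    return train(tiny_cfg(epochs=5), tr, va)


class TestTrainLoop:
    def test_zero_epochs_returns_initialized_net(self, tiny_data):
        tr, va, _ = tiny_data
        res = train(tiny_cfg(epochs=0), tr, va)
        assert res.history == [] and res.iter_log == []
        assert res.best_epoch is None

    def test_loss_decreases_over_short_run(self, trained):
        assert trained.history[-1]["total"] < trained.history[0]["total"]

    def test_iteration_log_columns_and_length(self, trained, tmp_path):
        assert len(trained.iter_log) == 5 * 2  # 16 samples / batch 8, 5 epochs
        write_history_csv(trained, tmp_path / "h.csv")
        with open(tmp_path / "h.csv") as f:
            rows = list(csv.DictReader(f))
        assert list(rows[0].keys()) == ["epoch", "iter", "ce", "dice", "total"]
        assert len(rows) == len(trained.iter_log)

    def test_reruns_are_bit_identical(self, tiny_data):
        tr, va, _ = tiny_data
        r1 = train(tiny_cfg(epochs=2), tr, va)
        r2 = train(tiny_cfg(epochs=2), tr, va)
        assert r1.history == r2.history
        assert r1.iter_log == r2.iter_log

    def test_empty_dataset_rejected(self, tiny_data):
        tr, va, _ = tiny_data
        with pytest.raises(ValueError, match="non-empty"):
            train(tiny_cfg(epochs=1), [], va)


class TestEvaluate:
    def test_report_consistent_with_serialized_confusion(self, trained, tiny_data):
        _, _, te = tiny_data
        rep, per_image = evaluate(trained.net, te)
        n = np.array(rep.confusion)
        assert rep.accuracy == pytest.approx(np.trace(n) / n.sum())
        assert len(per_image) == len(te)
        assert all(0.0 <= v <= 1.0 for v in per_image)

    def test_checkpoint_path_round_trip_gives_identical_report(
            self, trained, tiny_data, tmp_path):
        _, _, te = tiny_data
        rep_direct, scores_direct = evaluate(trained.net, te)
        path = tmp_path / "ckpt.zip"
        save_checkpoint(path, trained.net)
        rep_loaded, scores_loaded = evaluate(path, te)
        assert rep_direct.to_dict() == rep_loaded.to_dict()
        assert scores_direct == scores_loaded


class TestAblation:
    def test_table_shape_and_degenerate_sd(self, tiny_data, tmp_path):
        tr, va, te = tiny_data
        rows = run_ablation(tiny_cfg(epochs=1), ["wavebisenet", "bisenetv1"],
                            n_runs=1, train_set=tr, val_set=va, test_set=te,
                            out_csv=tmp_path / "ablation.csv")
        assert [r["variant"] for r in rows] == ["wavebisenet", "bisenetv1"]
        for r in rows:
            assert r["degenerate_sd"] is True
            for m in ("miou", "accuracy", "f1", "kappa"):
                assert f"{m}_mean" in r and r[f"{m}_sd"] == 0.0
        with open(tmp_path / "ablation.csv") as f:
            assert len(list(csv.DictReader(f))) == 2


class TestCompare:
    def test_identical_scores_not_significant(self):
        s = [0.5, 0.6, 0.7, 0.8]
        res = compare_models(s, s, n_resamples=200, seed=0)
        assert not res.significant and res.diff_ci == (0.0, 0.0)

    def test_resample_count_and_plot_artifact(self, tmp_path):
        a = list(np.linspace(0.4, 0.6, 12))
        b = [v + 0.05 for v in a]
        res = compare_models(a, b, n_resamples=10_000, seed=1,
                             plot_path=tmp_path / "diff.png")
        assert res.n_resamples == 10_000
        assert res.resampled_diffs.shape == (10_000,)
        assert (tmp_path / "diff.png").stat().st_size > 0

    def test_seeded_endpoints_reproduce(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.7, 0.05, size=30)
        b = a + 0.02
        r1 = compare_models(a, b, n_resamples=2000, seed=9)
        r2 = compare_models(a, b, n_resamples=2000, seed=9)
        assert r1.diff_ci == r2.diff_ci


class TestCLI:
    @pytest.fixture(scope="class")
    def workspace(self, tmp_path_factory):
        from click.testing import CliRunner
        from wavebisenet.cli import main

        root = tmp_path_factory.mktemp("cli")
        runner = CliRunner()
        res = runner.invoke(main, ["synth", "--out", str(root / "data"),
                                   "--n-images", "10", "--image-size", "64",
                                   "--patch", "64", "--regime", "dispersed",
                                   "--n-wires", "1", "3",
                                   "--wire-width", "8", "12", "--seed", "5"])
        assert res.exit_code == 0, res.output
        cfg = {"epochs": 1, "batch_size": 8, "seed": 1,
               "network": {"width_mult": 0.125, "input_size": [64, 64]}}
        import yaml
        (root / "cfg.yaml").write_text(yaml.safe_dump(cfg))
        return runner, main, root

    def test_synth_wrote_all_splits(self, workspace):
        _, _, root = workspace
        for split, n in (("train", 7), ("val", 2), ("test", 1)):
            manifest = json.loads((root / "data" / split / "manifest.json").read_text())
            assert manifest["n_samples"] == n

    def test_train_eval_predict_pipeline(self, workspace):
        runner, main, root = workspace
        res = runner.invoke(main, ["train", "--data", str(root / "data"),
                                   "--config", str(root / "cfg.yaml"),
                                   "--checkpoint", str(root / "ckpt.zip"),
                                   "--history", str(root / "hist.csv")])
        assert res.exit_code == 0, res.output
        assert (root / "ckpt.zip").exists() and (root / "hist.csv").exists()
        res = runner.invoke(main, ["eval", "--data", str(root / "data"),
                                   "--checkpoint", str(root / "ckpt.zip"),
                                   "--report", str(root / "report.json"),
                                   "--scores", str(root / "scores.json")])
        assert res.exit_code == 0, res.output
        rep = json.loads((root / "report.json").read_text())
        assert set(rep) >= {"miou", "accuracy", "f1", "kappa", "confusion"}
        img = next((root / "data" / "test").glob("*_image.png"))
        res = runner.invoke(main, ["predict", str(img),
                                   "--checkpoint", str(root / "ckpt.zip"),
                                   "--out", str(root / "pred.png")])
        assert res.exit_code == 0, res.output
        from PIL import Image
        pred = np.asarray(Image.open(root / "pred.png"))
        assert set(np.unique(pred)) <= {0, 255}

    def test_bad_config_exits_with_code_2(self, workspace, tmp_path):
        runner, main, root = workspace
        bad = tmp_path / "bad.yaml"
        bad.write_text("lr: -1\n")
        res = runner.invoke(main, ["train", "--data", str(root / "data"),
                                   "--config", str(bad),
                                   "--checkpoint", str(tmp_path / "c.zip")])
        assert res.exit_code == 2

    def test_missing_data_exits_with_code_3(self, workspace, tmp_path):
        runner, main, root = workspace
        empty = tmp_path / "empty"
        empty.mkdir()
        res = runner.invoke(main, ["eval", "--data", str(empty),
                                   "--checkpoint", str(root / "ckpt.zip"),
                                   "--report", str(tmp_path / "r.json")])
        assert res.exit_code == 3

    def test_compare_subcommand(self, workspace, tmp_path):
        runner, main, _ = workspace
        a = tmp_path / "a.json"
        b = tmp_path / "b.json"
        a.write_text(json.dumps([0.5, 0.6, 0.7]))
        b.write_text(json.dumps([0.6, 0.7, 0.8]))
        res = runner.invoke(main, ["compare", "--scores-a", str(a),
                                   "--scores-b", str(b), "--n-resamples", "500",
                                   "--out", str(tmp_path / "boot.json")])
        assert res.exit_code == 0, res.output
        assert json.loads((tmp_path / "boot.json").read_text())["n_resamples"] == 500
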