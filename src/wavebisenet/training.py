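"""Training, evaluation, ablation and model-comparison drivers.

The recipe: inputs normalized to [0, 1], He-initialized weights, Adam
(lr 0.01, betas (0.99, 0.99)) with L2 weight decay 0.001 folded into the
gradient, a plateau scheduler halving the learning rate when validation mIoU
stalls, batch size 16, compound 0.5*CE + 0.5*weighted-Dice loss.  The
best-validation-mIoU weights are restored at the end of training.

Everything is deterministic given the config seed: batch order, weight
initialization and the synthetic data all derive from it.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .losses import LossConfig, cross_entropy, weighted_dice
from .metrics import (BootstrapResult, ConfusionMatrix, MetricsReport,
                      bootstrap_compare, compute_report, miou, per_class_iou)
from .network import (BilateralSegNet, NetworkConfig, build_network,
                      load_checkpoint, predict_mask, save_checkpoint)
from .synthetic import Dataset, SegmentationSample


@dataclass
class TrainConfig:
    lr: float = 0.01
    betas: tuple[float, float] = (0.99, 0.99)
    weight_decay: float = 0.001
    batch_size: int = 16
    epochs: int = 300
    scheduler_factor: float = 0.5
    plateau_metric: str = "val_miou"
    plateau_patience: int = 10
    seed: int = 0
    n_runs: int = 5
    loss: LossConfig = field(default_factory=LossConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("lr must be positive, batch_size >= 1, epochs >= 0")
        if not (0.0 < self.scheduler_factor < 1.0):
            raise ValueError("scheduler factor must lie in (0, 1)")


@dataclass
class TrainResult:
    net: BilateralSegNet
    history: list[dict]          # per-epoch: epoch, lr, ce, dice, total, val_miou
    iter_log: list[dict]         # per-iteration: epoch, iter, ce, dice, total
    best_epoch: int | None
    best_val_miou: float | None


def _to_batch(samples: list[SegmentationSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into a normalized 3-channel NCHW batch plus mask batch."""
    imgs = np.stack([s.image for s in samples]).astype(np.float32) / 255.0
    x = np.repeat(imgs[:, None], 3, axis=1)
    y = np.stack([s.mask for s in samples]).astype(np.int64)
    return x, y


def _batch_loss(net, x, y, loss_cfg: LossConfig):
    logits = net(nn.Tensor(x))
    ce = cross_entropy(logits, y)
    probs = nn.softmax(logits, axis=1)
    dice = weighted_dice(probs, y, loss_cfg)
    total = nn.add(nn.mul(ce, loss_cfg.ce_weight), nn.mul(dice, loss_cfg.dice_weight))
    return total, ce, dice


def _validation_miou(net, samples: list[SegmentationSample], batch_size: int) -> float:
    net.eval()
    cm = ConfusionMatrix(2)
    with nn.no_grad():
        for i in range(0, len(samples), batch_size):
            x, y = _to_batch(samples[i : i + batch_size])
            pred = np.argmax(net(nn.Tensor(x)).data, axis=1)
            cm.accumulate(pred, y)
    return miou(cm)


def train(cfg: TrainConfig, train_set: Dataset | list[SegmentationSample],
          val_set: Dataset | list[SegmentationSample]) -> TrainResult:
    """Run the full training loop; returns the best-validation network."""
    train_samples = train_set.samples if isinstance(train_set, Dataset) else list(train_set)
    val_samples = val_set.samples if isinstance(val_set, Dataset) else list(val_set)
    if not train_samples or not val_samples:
        raise ValueError("datasets must be non-empty")
    net = build_network(cfg.network, seed=cfg.seed)
    if cfg.epochs == 0:
        return TrainResult(net, [], [], None, None)
    opt = nn.Adam(net.parameters(), lr=cfg.lr, betas=cfg.betas,
                  weight_decay=cfg.weight_decay)
    sched = nn.ReduceLROnPlateau(opt, mode="max", factor=cfg.scheduler_factor,
                                 patience=cfg.plateau_patience)
    rng = np.random.default_rng(cfg.seed + 1)
    history, iter_log = [], []
    best_state, best_miou, best_epoch = None, -math.inf, None
    n = len(train_samples)
    for epoch in range(1, cfg.epochs + 1):
        net.train()
        perm = rng.permutation(n)
        ep_ce = ep_dice = ep_total = 0.0
        n_batches = 0
        for it, start in enumerate(range(0, n, cfg.batch_size)):
            batch = [train_samples[j] for j in perm[start : start + cfg.batch_size]]
            x, y = _to_batch(batch)
            total, ce, dice = _batch_loss(net, x, y, cfg.loss)
            if not np.isfinite(total.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, iter {it}: "
                    f"lr={opt.lr:.3g}, batch mean={x.mean():.4f}, std={x.std():.4f}"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            iter_log.append({"epoch": epoch, "iter": it, "ce": ce.item(),
                             "dice": dice.item(), "total": total.item()})
            ep_ce += ce.item()
            ep_dice += dice.item()
            ep_total += total.item()
            n_batches += 1
        val_miou = _validation_miou(net, val_samples, cfg.batch_size)
        history.append({"epoch": epoch, "lr": opt.lr, "ce": ep_ce / n_batches,
                        "dice": ep_dice / n_batches, "total": ep_total / n_batches,
                        "val_miou": val_miou})
        if val_miou > best_miou:
            best_miou, best_epoch = val_miou, epoch
            best_state = net.state_dict()
        sched.step(val_miou)
    if best_state is not None:
        net.load_state_dict(best_state)
    return TrainResult(net, history, iter_log, best_epoch, best_miou)


def evaluate(model, test_set: Dataset | list[SegmentationSample],
             batch_size: int = 8) -> tuple[MetricsReport, list[float]]:
    """Global-confusion-matrix report plus the per-image mIoU list.

    ``model`` is a network or a checkpoint path.  Per-image scores use each
    image's own confusion matrix (zero-union classes excluded), feeding the
    bootstrap comparison.
    """
    if not isinstance(model, BilateralSegNet):
        model, _ = load_checkpoint(model)
    samples = test_set.samples if isinstance(test_set, Dataset) else list(test_set)
    model.eval()
    cm = ConfusionMatrix(2)
    per_image: list[float] = []
    with nn.no_grad():
        for i in range(0, len(samples), batch_size):
            x, y = _to_batch(samples[i : i + batch_size])
            pred = np.argmax(model(nn.Tensor(x)).data, axis=1)
            cm.accumulate(pred, y)
            for k in range(pred.shape[0]):
                img_cm = ConfusionMatrix(2).accumulate(pred[k], y[k])
                iou = per_class_iou(img_cm)
                per_image.append(float(np.nanmean(iou)))
    return compute_report(cm), per_image


def write_history_csv(result: TrainResult, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=["epoch", "iter", "ce", "dice", "total"])
        writer.writeheader()
        writer.writerows(result.iter_log)


METRIC_COLUMNS = ("miou", "accuracy", "f1", "kappa")


def run_ablation(base_cfg: TrainConfig, variants: list[str], n_runs: int,
                 train_set, val_set, test_set, out_csv=None) -> list[dict]:
    """Train each variant ``n_runs`` times (distinct seeds); report mean +/- sd.

    With ``n_runs == 1`` the sd is reported as 0 and flagged.  Rows mirror the
    ablation table: one per variant, four metric columns.
    """
    from dataclasses import replace

    rows = []
    for variant in variants:
        per_metric = {m: [] for m in METRIC_COLUMNS}
        for run in range(n_runs):
            cfg = replace(base_cfg, seed=base_cfg.seed + run,
                          network=replace(base_cfg.network, variant=variant))
            result = train(cfg, train_set, val_set)
            report, _ = evaluate(result.net, test_set)
            for m in per_metric:
                per_metric[m].append(getattr(report, m))
        row = {"variant": variant, "n_runs": n_runs, "degenerate_sd": n_runs == 1}
        for m, vals in per_metric.items():
            row[f"{m}_mean"] = float(np.mean(vals))
            row[f"{m}_sd"] = float(np.std(vals, ddof=1)) if n_runs > 1 else 0.0
        rows.append(row)
    if out_csv is not None:
        with Path(out_csv).open("w", newline="") as f:
            writer = csv.DictWriter(f, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
    return rows


def compare_models(scores_a: list[float], scores_b: list[float],
                   n_resamples: int = 10_000, seed: int = 0,
                   plot_path=None) -> BootstrapResult:
    """Paired bootstrap comparison with an optional difference histogram plot."""
    result = bootstrap_compare(scores_a, scores_b, n_resamples=n_resamples, seed=seed)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.hist(result.resampled_diffs, bins=60, color="lightblue", edgecolor="none")
        ax.axvline(0.0, color="black", label="no difference")
        for x in result.diff_ci:
            ax.axvline(x, color="orange", linestyle="--")
        ax.set_xlabel("mIoU difference (B - A)")
        ax.set_ylabel("bootstrap count")
        ax.legend()
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return result
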