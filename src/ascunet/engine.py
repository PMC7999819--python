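"""Training and evaluation loops.

The training recipe follows the reference setup for this architecture: AdamW
with initial learning rate 2e-4, momentum parameters (0.9, 0.999), batch size
8, 200 epochs, per-pixel binary cross-entropy loss, and horizontal/vertical
flip augmentation on the training split.  Everything is seeded — weight
initialization, shuffling, and augmentation — so two single-threaded CPU runs
with the same config produce identical logs.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import AdamW, Tensor
from .dataio import SegmentationDataset
from .loss_metrics import (EPS, METRIC_NAMES, aggregate_metrics, confusion,
                           dice, metrics_from_counts, write_report)
from .network import ASCUNet, NetworkConfig, ablation_suite, build_ascunet


@dataclass
class TrainConfig:
    """Optimization hyper-parameters; defaults are the reference recipe."""

    lr: float = 2e-4
    betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 8
    epochs: int = 200
    weight_decay: float = 1e-2
    seed: int = 0
    device: str = "cpu"
    variant: str = "Ours"
    threshold: float = 0.5
    checkpoint_dir: str | None = None
    log_path: str | None = None

    def __post_init__(self):
        if self.lr < 0:
            raise ValueError("lr must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if isinstance(self.betas, list):
            self.betas = tuple(self.betas)
        if self.device != "cpu":
            raise ValueError("only cpu execution is supported")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainResult:
    history: list[dict]
    steps: int
    best_checkpoint: Path | None = None
    last_checkpoint: Path | None = None


def bce_loss(pred: Tensor, gt: np.ndarray, eps: float = EPS) -> Tensor:
    """Differentiable mean binary cross-entropy between probabilities and {0,1}."""
    gt = np.asarray(gt, dtype=pred.dtype).reshape(pred.shape)
    p = ad.clip(pred, eps, 1.0 - eps)
    per_pixel = -(Tensor(1.0 - gt) * ad.log(1.0 - p) + Tensor(gt) * ad.log(p))
    return per_pixel.mean()


def save_checkpoint(model: ASCUNet, path: str | Path,
                    train_config: TrainConfig | None = None) -> Path:
    """Serialize weights (.npz) plus a JSON sidecar with config and seed.

    The sidecar makes any checkpoint reconstructable without code inspection.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = {"network": model.config.to_dict(), "seed": model.seed,
               "dtype": str(model.head.weight.dtype)}
    if train_config is not None:
        sidecar["train"] = train_config.to_dict()
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def load_checkpoint(path: str | Path) -> ASCUNet:
    """Rebuild a network from a weights file and its JSON sidecar."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = NetworkConfig.from_dict(sidecar["network"])
    model = build_ascunet(cfg, seed=sidecar.get("seed", 0),
                          dtype=np.dtype(sidecar.get("dtype", "float32")))
    with np.load(path) as data:
        model.load_state_dict(dict(data))
    return model


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train(model: ASCUNet, dataset: SegmentationDataset, cfg: TrainConfig,
          val_dataset: SegmentationDataset | None = None,
          max_steps: int | None = None,
          stop_dice: float | None = None) -> TrainResult:
    """Optimize ``model`` on ``dataset``; returns per-epoch history.

    ``max_steps`` caps total optimizer steps (useful for short runs);
    ``stop_dice`` stops early once the epoch's mean training Dice reaches the
    given value.  Checkpoints: the last epoch always, and the best epoch by
    validation F1 whenever a validation set is given.
    """
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5eed]))
    opt = AdamW(model.parameters(), lr=cfg.lr, betas=cfg.betas,
                weight_decay=cfg.weight_decay)
    history: list[dict] = []
    steps = 0
    best_f1 = -1.0
    best_path = last_path = None
    ckpt_dir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None
    done = False

    for epoch in range(cfg.epochs):
        model.train()
        losses, dices = [], []
        for batch_idx in _epoch_batches(len(dataset), cfg.batch_size, rng):
            images, masks = dataset.batch(batch_idx, rng)
            pred = model(Tensor(images))
            loss = bce_loss(pred, masks[:, None, :, :])
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch indices {batch_idx.tolist()}")
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            pred_bin = pred.data[:, 0] >= cfg.threshold
            dices.extend(dice(m, pb) for m, pb in zip(masks, pred_bin))
            steps += 1
            if max_steps is not None and steps >= max_steps:
                done = True
                break
        row = {"epoch": epoch, "loss": float(np.mean(losses)),
               "dice": float(np.mean(dices))}
        if val_dataset is not None:
            summary, _ = evaluate(model, val_dataset, threshold=cfg.threshold)
            row["val_F1"] = summary["F1"]
            if ckpt_dir and summary["F1"] > best_f1:
                best_f1 = summary["F1"]
                best_path = save_checkpoint(model, ckpt_dir / "best.npz", cfg)
        history.append(row)
        if stop_dice is not None and row["dice"] >= stop_dice:
            done = True
        if done:
            break

    if ckpt_dir:
        last_path = save_checkpoint(model, ckpt_dir / "last.npz", cfg)
    if cfg.log_path:
        log_path = Path(cfg.log_path)
        log_path.parent.mkdir(parents=True, exist_ok=True)
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(history[0].keys()))
            writer.writeheader()
            writer.writerows(history)
    return TrainResult(history=history, steps=steps,
                       best_checkpoint=best_path, last_checkpoint=last_path)


def evaluate(model: ASCUNet, dataset: SegmentationDataset, threshold: float = 0.5,
             pooled: bool = False, csv_path: str | Path | None = None,
             json_path: str | Path | None = None,
             eval_batch: int = 8) -> tuple[dict[str, float], list[dict]]:
    """Per-image metrics and their aggregate; never augments.

    Returns ``(summary, rows)`` where each row carries the image name and the
    six metrics; optionally writes the CSV report and JSON summary.
    """
    rows, per_image, counts = [], [], []
    for start in range(0, len(dataset), eval_batch):
        idx = np.arange(start, min(start + eval_batch, len(dataset)))
        images, masks = dataset.images[idx], dataset.masks[idx]
        pred_bin = model.predict_mask(images, threshold=threshold)
        for i, (gt, pb) in enumerate(zip(masks, pred_bin)):
            c = confusion(gt, pb)
            m = metrics_from_counts(c)
            counts.append(c)
            per_image.append(m)
            rows.append({"filename": dataset.names[start + i], **m})
    summary = aggregate_metrics(per_image, counts, pooled=pooled)
    if csv_path and json_path:
        write_report(rows, csv_path, json_path, summary)
    return summary, rows


def run_ablation(train_dataset: SegmentationDataset, eval_dataset: SegmentationDataset,
                 network_config: NetworkConfig, train_config: TrainConfig,
                 out_csv: str | Path | None = None,
                 max_steps: int | None = None) -> list[dict]:
    """Train and evaluate all eight attention variants under one master seed.

    Returns one row per variant (name + the six metrics), in the canonical
    order, and optionally writes them as a CSV shaped variant x metrics.
    """
    results = []
    for name, model in ablation_suite(network_config, seed=train_config.seed):
        cfg = TrainConfig(**{**train_config.to_dict(), "variant": name,
                             "checkpoint_dir": None, "log_path": None})
        train(model, train_dataset, cfg, max_steps=max_steps)
        summary, _ = evaluate(model, eval_dataset, threshold=cfg.threshold)
        results.append({"variant": name, **{k: summary[k] for k in METRIC_NAMES}})
    if out_csv:
        out_csv = Path(out_csv)
        out_csv.parent.mkdir(parents=True, exist_ok=True)
        with open(out_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["variant", *METRIC_NAMES])
            writer.writeheader()
            writer.writerows(results)
    return results
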