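"""Training loop, evaluation and whole-raster prediction.

Training follows the published recipe: Adam, batch size 8, equally
weighted BCE + Dice loss, per-step cosine annealing from the initial
learning rate to ``lr_min``, 50 epochs, with online random augmentation
(scaling, small affine shear, flips, uniform contrast gain) on top of
whatever offline mirror expansion the dataset already carries.

Reproducibility contract: all randomness derives from ``TrainConfig.seed``
and the epoch index, so a fixed seed reproduces loss logs bit for bit and
resuming from an epoch checkpoint replays the remaining epochs exactly.
"""

from __future__ import annotations

import hashlib
import json
import math
import csv as _csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .losses import combined_loss
from .metrics import ConfusionCounts, MetricsReport, compute_metrics, confusion_counts
from .network import MSSFNet, NetworkConfig, build_model
from .nn import Adam, Tensor
from .geotiff import BandStack, BAND_NAMES
from .tiling import TilePair, sliding_window_tiles, stitch_predictions

__all__ = ["TrainConfig", "EvalReport", "cosine_lr", "train", "evaluate",
           "predict_raster", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_VERSION = "1.0"


@dataclass
class TrainConfig:
    lr: float = 1e-4
    lr_min: float = 0.0
    batch_size: int = 8
    epochs: int = 50
    betas: tuple = (0.9, 0.999)
    weight_decay: float = 0.0
    seed: int = 0
    augment: bool = True
    scale_range: tuple = (0.75, 1.25)
    shear_deg: float = 5.0
    flip_p: float = 0.5
    contrast_range: tuple = (0.8, 1.2)
    dice_smooth: float = 1.0
    checkpoint_dir: str | None = None
    log_path: str | None = None
    device: str = "cpu"

    def validate(self) -> None:
        if self.lr <= 0:
            raise ValueError(f"lr must be > 0, got {self.lr}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.device != "cpu":
            raise ValueError("only the cpu backend is available")

    def fingerprint(self, net_cfg: NetworkConfig | None = None) -> str:
        blob = {"train": asdict(self)}
        if net_cfg is not None:
            blob["network"] = net_cfg.to_dict()
        return hashlib.sha256(json.dumps(blob, sort_keys=True, default=str)
                              .encode()).hexdigest()[:16]


@dataclass
class EvalReport:
    metrics: MetricsReport
    counts: ConfusionCounts
    tile_count: int
    config_fingerprint: str = ""
    checkpoint_id: str = ""


def cosine_lr(step: int, total_steps: int, lr0: float, lr_min: float = 0.0) -> float:
    """Cosine-annealed learning rate: lr_min + (lr0 - lr_min)(1 + cos(pi t/T))/2."""
    if total_steps == 0:
        raise ValueError("total_steps must be positive")
    if not 0 <= step <= total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + math.cos(math.pi * step / total_steps))


# ----------------------------------------------------------------------
def _augment_sample(img: np.ndarray, mask: np.ndarray, cfg: TrainConfig,
                    rng: np.random.Generator):
    """Online random scaling / shear / flips / contrast for one tile."""
    if rng.uniform() < cfg.flip_p:
        img, mask = img[:, :, ::-1], mask[:, ::-1]
    if rng.uniform() < cfg.flip_p:
        img, mask = img[:, ::-1, :], mask[::-1, :]
    s = rng.uniform(*cfg.scale_range)
    phi = np.deg2rad(rng.uniform(-cfg.shear_deg, cfg.shear_deg))
    fwd = np.array([[s, 0.0], [np.tan(phi) * s, s]])
    inv = np.linalg.inv(fwd)
    c = (np.array(mask.shape, dtype=float) - 1) / 2.0
    offset = c - inv @ c
    img = np.stack([
        ndimage.affine_transform(b, inv, offset=offset, order=1, mode="nearest")
        for b in img])
    mask = ndimage.affine_transform(mask.astype(float), inv, offset=offset,
                                    order=0, mode="nearest")
    gain = rng.uniform(*cfg.contrast_range)
    img = np.clip(img * gain, 0.0, 1.0)
    return np.ascontiguousarray(img), (mask > 0.5).astype(np.float32)


def _as_pairs(tiles) -> list:
    out = []
    for t in tiles:
        if isinstance(t, TilePair):
            out.append((np.asarray(t.image, dtype=np.float32), np.asarray(t.mask)))
        else:
            img, mask = t
            out.append((np.asarray(img, dtype=np.float32), np.asarray(mask)))
    return out


def save_checkpoint(path, model: MSSFNet, optimizer: Adam | None = None,
                    epoch: int = 0, global_step: int = 0,
                    best_iou: float = -1.0, seed: int = 0) -> None:
    path = Path(path)
    arrays = {f"model/{k}": v for k, v in model.state_dict().items()}
    if optimizer is not None:
        st = optimizer.state_dict()
        arrays["opt/t"] = np.array(st["t"])
        for i, a in enumerate(st["m"]):
            arrays[f"opt/m/{i}"] = a
        for i, a in enumerate(st["v"]):
            arrays[f"opt/v/{i}"] = a
    arrays["meta/epoch"] = np.array(epoch)
    arrays["meta/global_step"] = np.array(global_step)
    arrays["meta/best_iou"] = np.array(best_iou)
    arrays["meta/seed"] = np.array(seed)
    np.savez(path, **arrays)
    sidecar = path.with_suffix(path.suffix + ".meta.txt")
    sidecar.write_text(
        f"version\t{CHECKPOINT_VERSION}\n"
        f"band_order\t{','.join(BAND_NAMES)}\n"
        f"network\t{json.dumps(model.cfg.to_dict())}\n"
        f"epoch\t{epoch}\n")


def load_checkpoint(path, model: MSSFNet | None = None,
                    optimizer: Adam | None = None):
    """Restore a checkpoint; builds the model from the sidecar config when
    none is supplied.  Returns ``(model, meta)``."""
    path = Path(path)
    data = np.load(path if path.suffix == ".npz" else str(path), allow_pickle=False)
    if model is None:
        sidecar = path.with_suffix(path.suffix + ".meta.txt")
        net_cfg = None
        for line in sidecar.read_text().splitlines():
            key, _, val = line.partition("\t")
            if key == "network":
                net_cfg = NetworkConfig.from_dict(json.loads(val))
        model = build_model(net_cfg, seed=0)
    model.load_state_dict({k[len("model/"):]: data[k]
                           for k in data.files if k.startswith("model/")})
    if optimizer is not None and "opt/t" in data.files:
        n = len(optimizer.params)
        optimizer.load_state_dict({
            "t": data["opt/t"][()],
            "m": [data[f"opt/m/{i}"] for i in range(n)],
            "v": [data[f"opt/v/{i}"] for i in range(n)],
        })
    meta = {
        "epoch": int(data["meta/epoch"][()]),
        "global_step": int(data["meta/global_step"][()]),
        "best_iou": float(data["meta/best_iou"][()]),
        "seed": int(data["meta/seed"][()]),
    }
    return model, meta


def train(model: MSSFNet, train_tiles, val_tiles, cfg: TrainConfig,
          resume_from=None) -> dict:
    """Minimize the combined loss; returns ``{"log": [...], "best": path,
    "last": path}`` with one log row per epoch."""
    cfg.validate()
    pairs = _as_pairs(train_tiles)
    if not pairs:
        raise ValueError("training set is empty")
    val_pairs = _as_pairs(val_tiles) if val_tiles else []
    n = len(pairs)
    steps_per_epoch = math.ceil(n / cfg.batch_size)
    total_steps = cfg.epochs * steps_per_epoch

    opt = Adam(model.parameters(), lr=cfg.lr, betas=cfg.betas,
               weight_decay=cfg.weight_decay)
    start_epoch, global_step, best_iou = 0, 0, -1.0
    if resume_from is not None:
        _, meta = load_checkpoint(resume_from, model=model, optimizer=opt)
        start_epoch = meta["epoch"] + 1
        global_step = meta["global_step"]
        best_iou = meta["best_iou"]

    ckpt_dir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)
    log: list = []
    best_path = last_path = None

    for epoch in range(start_epoch, cfg.epochs):
        rng = np.random.default_rng([cfg.seed, epoch])
        order = rng.permutation(n)
        model.train()
        epoch_losses = []
        for b in range(steps_per_epoch):
            idx = order[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            imgs, masks = [], []
            for i in idx:
                img, mask = pairs[i]
                if cfg.augment:
                    img, mask = _augment_sample(img, mask, cfg, rng)
                imgs.append(img)
                masks.append(mask)
            x = np.stack(imgs).astype(np.float32)
            y = np.stack(masks).astype(np.float32)[:, None]
            opt.lr = cosine_lr(global_step, total_steps, cfg.lr, cfg.lr_min)
            pred = model(Tensor(x))
            loss = combined_loss(pred, Tensor(y), smooth=cfg.dice_smooth)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} step {b}: {loss.data}")
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
            global_step += 1
        row = {"epoch": epoch, "lr": opt.lr,
               "train_loss": float(np.mean(epoch_losses))}
        if val_pairs:
            rep = evaluate(model, val_pairs, batch_size=cfg.batch_size)
            row.update({f"val_{k}": v for k, v in rep.metrics.as_dict().items()})
            if ckpt_dir and rep.metrics.iou > best_iou:
                best_iou = rep.metrics.iou
                best_path = ckpt_dir / "best.npz"
                save_checkpoint(best_path, model, opt, epoch, global_step,
                                best_iou, cfg.seed)
        log.append(row)
        if ckpt_dir:
            last_path = ckpt_dir / "last.npz"
            save_checkpoint(last_path, model, opt, epoch, global_step,
                            best_iou, cfg.seed)
            save_checkpoint(ckpt_dir / f"epoch_{epoch:03d}.npz", model, opt,
                            epoch, global_step, best_iou, cfg.seed)
        if cfg.log_path:
            _append_log_row(cfg.log_path, row)
    return {"log": log, "best": best_path, "last": last_path,
            "best_iou": best_iou}


def _append_log_row(path, row: dict) -> None:
    path = Path(path)
    exists = path.exists()
    with open(path, "a", newline="") as fh:
        writer = _csv.DictWriter(fh, fieldnames=list(row))
        if not exists:
            writer.writeheader()
        writer.writerow(row)


def evaluate(model_or_fn, tiles, batch_size: int = 8, threshold: float = 0.5,
             config_fingerprint: str = "", checkpoint_id: str = "") -> EvalReport:
    """Pool confusion counts over all tiles at the 0.5 threshold (ties
    classify as positive) and compute the metric suite once.

    ``model_or_fn`` is an MSSFNet or any callable mapping a (B, bands, T, T)
    array to probabilities (B, 1, T, T).
    """
    pairs = _as_pairs(tiles)
    if not pairs:
        raise ValueError("evaluation set is empty")
    if isinstance(model_or_fn, MSSFNet):
        fn = model_or_fn.predict
    else:
        fn = model_or_fn
    total = ConfusionCounts()
    for b in range(0, len(pairs), batch_size):
        chunk = pairs[b:b + batch_size]
        x = np.stack([img for img, _ in chunk]).astype(np.float32)
        probs = np.asarray(fn(x))
        preds = (probs.reshape(len(chunk), *chunk[0][1].shape) >= threshold).astype(np.uint8)
        for p, (_, mask) in zip(preds, chunk):
            total = total + confusion_counts(p, (np.asarray(mask) > 0).astype(np.uint8))
    return EvalReport(metrics=compute_metrics(total), counts=total,
                      tile_count=len(pairs), config_fingerprint=config_fingerprint,
                      checkpoint_id=checkpoint_id)


def predict_raster(model_or_fn, stack: BandStack, step: int | None = None,
                   threshold: float = 0.5, window: int | None = None):
    """Tile a normalized 10-band raster, forward every tile, average the
    overlaps and threshold at 0.5 (ties positive).

    Returns ``(probability_plane, binary_mask)``; nodata pixels (NaN in
    any band) are forced to background.
    """
    if isinstance(model_or_fn, MSSFNet):
        if stack.data.shape[0] != model_or_fn.cfg.in_bands:
            raise ValueError(
                f"raster has {stack.data.shape[0]} bands, model expects "
                f"{model_or_fn.cfg.in_bands}")
        window = window or model_or_fn.cfg.tile_size
        fn = model_or_fn.predict
    else:
        if window is None:
            raise ValueError("window size required for a bare prediction callable")
        fn = model_or_fn
    step = step or window // 2
    nodata_mask = ~np.isfinite(stack.data).all(axis=0)
    clean = BandStack(np.nan_to_num(stack.data, nan=0.0),
                      transform=stack.transform, crs=stack.crs,
                      band_names=stack.band_names)
    tiles = sliding_window_tiles(clean, None, window=window, step=step)
    probs, origins = [], []
    for t in tiles:
        p = np.asarray(fn(t.image[None].astype(np.float32)))
        probs.append(p.reshape(window, window))
        origins.append(t.origin)
    plane = stitch_predictions(probs, origins, stack.data.shape[1:])
    plane[nodata_mask] = 0.0
    mask = (plane >= threshold).astype(np.uint8)
    mask[nodata_mask] = 0
    return plane, mask
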