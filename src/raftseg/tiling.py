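"""Dataset construction: resampling, normalization, tiling, filtering,
mirror augmentation, 7:2:1 splitting and prediction stitching.

Conventions: pixel coordinates are 0-based (row, col); a window of size
T anchored at (r, c) covers the half-open ranges [r, r+T) x [c, c+T).
Sliding windows advance by ``step``; when the final window would overrun
the raster, one extra window snapped flush to the edge is emitted so
every pixel is covered.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geotiff import BandStack, read_geotiff, read_mask, write_geotiff, write_mask

logger = logging.getLogger(__name__)

__all__ = [
    "TilePair", "SplitManifest", "resample_to_10m", "normalize_reflectance",
    "sliding_window_tiles", "filter_background_tiles", "augment_tiles",
    "split_dataset", "stitch_predictions", "write_tile_directory",
    "read_tile_directory",
]


@dataclass
class TilePair:
    """One image tile, its binary mask and provenance."""

    image: np.ndarray            # (bands, T, T)
    mask: np.ndarray | None      # (T, T) binary, or None for inference tiles
    origin: tuple = (0, 0)       # (row, col) in the source raster
    source_id: str = ""
    tile_id: str = ""
    keep_flag: bool = True

    @property
    def size(self) -> int:
        return self.image.shape[-1]


@dataclass
class SplitManifest:
    train: list
    test: list
    validation: list
    seed: int
    ratio: tuple = (7, 2, 1)

    @property
    def counts(self):
        return (len(self.train), len(self.test), len(self.validation))

    def split_of(self, tile_id) -> str:
        if tile_id in self._index():
            return self._index()[tile_id]
        raise KeyError(tile_id)

    def _index(self):
        if not hasattr(self, "_idx"):
            idx = {}
            for name, ids in (("train", self.train), ("test", self.test),
                              ("validation", self.validation)):
                for t in ids:
                    idx[t] = name
            object.__setattr__(self, "_idx", idx)
        return self._idx


def resample_to_10m(band: np.ndarray, factor: int = 2) -> np.ndarray:
    """Bilinear upsampling of a coarser band by an integer factor.

    Uses half-pixel-centre alignment (output pixel centres interpolate
    between the nearest input centres, clamped at the edges), the
    standard convention for resampling 20 m bands onto the 10 m grid.
    Nodata is represented as NaN and propagates through interpolation.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    band = np.asarray(band, dtype=float)
    if factor == 1:
        return band.copy()
    return ndimage.zoom(band, factor, order=1, mode="nearest", grid_mode=True)


def normalize_reflectance(dn: np.ndarray) -> np.ndarray:
    """L2A digital numbers to surface reflectance: DN / 10000, clipped to
    [0, 1].  NaN nodata propagates."""
    out = np.asarray(dn, dtype=float) / 10000.0
    return np.clip(out, 0.0, 1.0)


def _window_offsets(length: int, window: int, step: int) -> list:
    offsets = list(range(0, length - window + 1, step))
    if offsets[-1] + window < length:
        offsets.append(length - window)
    return offsets


def sliding_window_tiles(stack: BandStack, mask: np.ndarray | None = None,
                         window: int = 512, step: int = 256,
                         source_id: str = "") -> list:
    """Crop a raster (and optional mask) into overlapping tiles.

    Offsets are {0, step, 2 step, ...} per axis plus one edge-snapped
    window when needed; every in-raster pixel lands in at least one tile.
    """
    if step < 1 or window < step:
        raise ValueError(f"need window >= step >= 1, got window={window}, step={step}")
    _, h, w = stack.data.shape
    if h < window or w < window:
        raise ValueError(f"raster {h}x{w} is smaller than the {window}-pixel window")
    if mask is not None and mask.shape != (h, w):
        raise ValueError(f"mask shape {mask.shape} does not match raster {h}x{w}")
    tiles = []
    for r in _window_offsets(h, window, step):
        for c in _window_offsets(w, window, step):
            img = stack.data[:, r:r + window, c:c + window]
            msk = None if mask is None else mask[r:r + window, c:c + window]
            tiles.append(TilePair(
                image=img, mask=msk, origin=(r, c), source_id=source_id,
                tile_id=f"{source_id}_{r}_{c}" if source_id else f"{r}_{c}"))
    return tiles


def filter_background_tiles(tiles: list, keep_region: np.ndarray | None = None,
                            keep_p: float = 0.0, seed: int = 0) -> list:
    """Drop tiles whose mask contains no raft pixels.

    A zero-raft tile survives if it intersects ``keep_region`` (a raster
    of land/tidal-flat pixels aligned with the source) or, failing that,
    with probability ``keep_p`` (one seeded uniform draw per candidate,
    in tile order, so decisions replay exactly from the seed).
    """
    rng = np.random.default_rng(seed)
    kept = []
    for t in tiles:
        if t.mask is None or t.mask.any():
            kept.append(t)
            continue
        if keep_region is not None:
            r, c = t.origin
            T = t.size
            if keep_region[r:r + T, c:c + T].any():
                kept.append(replace(t, keep_flag=True))
                logger.info("tile %s kept: intersects keep region", t.tile_id)
                continue
        if rng.uniform() < keep_p:
            kept.append(replace(t, keep_flag=True))
            logger.info("tile %s kept: sampled negative", t.tile_id)
        else:
            logger.info("tile %s dropped: pure background", t.tile_id)
    return kept


def _mirror(arr: np.ndarray, op: str, anti_diagonal: bool) -> np.ndarray:
    if op == "orig":
        return arr.copy()
    if op == "hflip":
        return arr[..., :, ::-1].copy()
    if op == "vflip":
        return arr[..., ::-1, :].copy()
    if op == "diag":
        out = np.swapaxes(arr, -2, -1)
        if anti_diagonal:
            out = out[..., ::-1, ::-1]
        return out.copy()
    raise ValueError(op)


AUGMENT_OPS = ("orig", "hflip", "vflip", "diag")


def augment_tiles(tiles: list, anti_diagonal: bool = False) -> list:
    """Emit each tile plus its horizontal flip, vertical flip and diagonal
    mirror (transpose); images and masks co-transform.  4x expansion."""
    if not tiles:
        raise ValueError("no tiles to augment")
    out = []
    for t in tiles:
        for op in AUGMENT_OPS:
            out.append(TilePair(
                image=_mirror(t.image, op, anti_diagonal),
                mask=None if t.mask is None else _mirror(t.mask, op, anti_diagonal),
                origin=t.origin, source_id=t.source_id,
                tile_id=f"{t.tile_id}_{op}", keep_flag=t.keep_flag))
    return out


def split_dataset(tiles, seed: int, ratio: tuple = (7, 2, 1)) -> SplitManifest:
    """Random 7:2:1 train/test/validation split.

    ``tiles`` may be a count, a list of ids or a list of TilePairs.  The
    two smaller partitions are floored (test = floor(0.2 n), validation =
    floor(0.1 n)) and the remainder goes to training, so n = 10072 gives
    7051 / 2014 / 1007.
    """
    if isinstance(tiles, (int, np.integer)):
        ids = [str(i) for i in range(int(tiles))]
    else:
        ids = [t.tile_id if isinstance(t, TilePair) else str(t) for t in tiles]
    n = len(ids)
    if n < 10:
        raise ValueError(f"need at least 10 tiles to split, got {n}")
    total = sum(ratio)
    n_test = int(np.floor(n * ratio[1] / total))
    n_val = int(np.floor(n * ratio[2] / total))
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in order]
    test = shuffled[:n_test]
    validation = shuffled[n_test:n_test + n_val]
    train = shuffled[n_test + n_val:]
    return SplitManifest(train=train, test=test, validation=validation,
                         seed=seed, ratio=tuple(ratio))


def stitch_predictions(tile_probs: list, origins: list, shape: tuple) -> np.ndarray:
    """Average overlapping tile probability maps onto a full raster plane."""
    h, w = shape
    acc = np.zeros((h, w), dtype=np.float64)
    cnt = np.zeros((h, w), dtype=np.int64)
    for prob, (r, c) in zip(tile_probs, origins):
        prob = np.asarray(prob)
        th, tw = prob.shape[-2:]
        acc[r:r + th, c:c + tw] += prob.reshape(th, tw)
        cnt[r:r + th, c:c + tw] += 1
    if (cnt == 0).any():
        n_missing = int((cnt == 0).sum())
        raise ValueError(f"{n_missing} raster pixels are covered by no tile")
    return acc / cnt


# ----------------------------------------------------------------------
# tile directory interchange format
def write_tile_directory(out_dir, tiles: list, manifest: SplitManifest | None = None,
                         extra: dict | None = None) -> Path:
    """Write tiles as paired GeoTIFF/PNG files plus a CSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in tiles:
        img_name = f"{t.tile_id}_img.tif"
        write_geotiff(out_dir / img_name, BandStack(t.image))
        mask_name = ""
        if t.mask is not None:
            mask_name = f"{t.tile_id}_mask.png"
            write_mask(out_dir / mask_name, t.mask)
        split = ""
        if manifest is not None:
            try:
                split = manifest.split_of(t.tile_id)
            except KeyError:
                split = ""
        rows.append({
            "tile_id": t.tile_id, "source": t.source_id,
            "row": t.origin[0], "col": t.origin[1],
            "split": split, "keep_flag": int(t.keep_flag),
            "image": img_name, "mask": mask_name,
            "extra": json.dumps((extra or {}).get(t.tile_id, {})),
        })
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    return out_dir


def read_tile_directory(tile_dir, split: str | None = None) -> list:
    tile_dir = Path(tile_dir)
    tiles = []
    with open(tile_dir / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            if split is not None and row["split"] != split:
                continue
            image = read_geotiff(tile_dir / row["image"]).data
            mask = read_mask(tile_dir / row["mask"]) if row["mask"] else None
            tiles.append(TilePair(
                image=image, mask=mask,
                origin=(int(row["row"]), int(row["col"])),
                source_id=row["source"], tile_id=row["tile_id"],
                keep_flag=bool(int(row["keep_flag"]))))
    return tiles
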