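"""Georeferenced raster I/O for 10-band reflectance stacks.

Rasters are stored as multiband TIFFs with the GeoTIFF georeferencing
tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA) written directly and
the CRS identifier plus band order carried in the image description, so
files round-trip without a heavyweight GIS stack.  Label masks are plain
PNGs (0 = background, 255 = raft).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

BAND_NAMES = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12")

# GDAL-style geotransform: (x0, dx, 0, y0, 0, -dy); default 10 m pixels.
DEFAULT_TRANSFORM = (0.0, 10.0, 0.0, 0.0, 0.0, -10.0)

__all__ = ["BandStack", "BAND_NAMES", "read_geotiff", "write_geotiff",
           "read_mask", "write_mask", "DEFAULT_TRANSFORM"]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class BandStack:
    """A georeferenced multiband reflectance raster, channels-first."""

    data: np.ndarray                       # (bands, H, W), reflectance
    transform: tuple = DEFAULT_TRANSFORM   # GDAL geotransform
    crs: str = "EPSG:32651"
    nodata: float | None = None
    band_names: tuple = BAND_NAMES

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"band stack must be (bands, H, W), got {self.data.shape}")

    @property
    def shape(self):
        return self.data.shape

    @property
    def pixel_size(self) -> float:
        return abs(self.transform[1])

    def window_transform(self, row: int, col: int) -> tuple:
        """Geotransform of a window whose upper-left pixel is (row, col)."""
        x0, dx, rx, y0, ry, dy = self.transform
        return (x0 + col * dx + row * rx, dx, rx, y0 + col * ry + row * dy, ry, dy)


def write_geotiff(path, stack: BandStack) -> None:
    path = Path(path)
    x0, dx, _, y0, _, dy = stack.transform
    desc = json.dumps({"crs": stack.crs, "bands": list(stack.band_names)})
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (abs(dx), abs(dy), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
    ]
    if stack.nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(stack.nodata)))
    tifffile.imwrite(path, stack.data.astype(np.float32), photometric="minisblack",
                     description=desc, extratags=extratags)


def read_geotiff(path) -> BandStack:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        page = tf.pages[0]
        tags = page.tags
        scale = tags[_TAG_PIXEL_SCALE].value if _TAG_PIXEL_SCALE in tags else (10.0, 10.0, 0.0)
        tie = tags[_TAG_TIEPOINT].value if _TAG_TIEPOINT in tags else (0, 0, 0, 0.0, 0.0, 0.0)
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        crs, band_names = "EPSG:32651", BAND_NAMES
        desc = tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                crs = meta.get("crs", crs)
                band_names = tuple(meta.get("bands", band_names))
            except (json.JSONDecodeError, TypeError):
                pass
    if data.ndim == 2:
        data = data[None]
    transform = (float(tie[3]), float(scale[0]), 0.0, float(tie[4]), 0.0, -float(scale[1]))
    return BandStack(data=data, transform=transform, crs=crs,
                     nodata=nodata, band_names=band_names)


def write_mask(path, mask: np.ndarray) -> None:
    """Binary mask to PNG (0 / 255)."""
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask is not binary")
    iio.imwrite(Path(path), (m.astype(np.uint8) * 255))


def read_mask(path) -> np.ndarray:
    m = np.asarray(iio.imread(Path(path)))
    if m.ndim == 3:
        m = m[..., 0]
    return (m > 127).astype(np.uint8)
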