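"""Rasterize a 1D window into a binary 2D pixel image.

Each sample of an n-sample window in [0, 1] is quantized to a pixel row
(amplitude resolution ``r`` units per row, row 0 at amplitude 1) and
placed ``d`` empty "dummy" columns after its predecessor, so sample i
sits at column i*(d+1).  Consecutive sample pixels are joined with
Bresenham's line algorithm, which chooses the pixel chain closest to the
ideal segment using an integer decision variable only:

    D_0     = 2*db - da                  (da = major-axis span)
    D_{i+1} = D_i + 2*db - 2*da   if D_i >= 0  (diagonal step)
    D_{i+1} = D_i + 2*db          if D_i <  0  (axis step)

The D >= 0 tie resolves toward the diagonal step.  The image is
H x W = (1/r + 1) x ((n-1)*(d+1) + 1); with the defaults r = 0.0005 and
d = 20 a 56-sample window becomes 2001 x 1156 pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from PIL import Image

from .preprocess import WindowSet

__all__ = [
    "RasterConfig",
    "RasterImage",
    "bresenham_line",
    "window_to_image",
    "rasterize_windowset",
    "write_image",
    "read_image",
    "write_image_batch",
]


@dataclass(frozen=True)
class RasterConfig:
    """Rasterization geometry.

    resolution
        Amplitude units per pixel row; 1/resolution must be an integer.
        Image height is 1/resolution + 1 rows.
    dummy
        Count of empty columns between consecutive real samples.
    polarity
        Pixel value of the signal trace (background is 0).
    """

    resolution: float = 0.0005
    dummy: int = 20
    polarity: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.resolution <= 1.0):
            raise ValueError("resolution must be in (0, 1]")
        inv = 1.0 / self.resolution
        if abs(inv - round(inv)) > 1e-9:
            raise ValueError("1/resolution must be an integer")
        if self.dummy < 0:
            raise ValueError("dummy must be >= 0")

    @property
    def n_rows(self) -> int:
        return int(round(1.0 / self.resolution)) + 1

    def n_cols(self, n_samples: int) -> int:
        return (n_samples - 1) * (self.dummy + 1) + 1


@dataclass
class RasterImage:
    """Binary H x W pixel grid plus its provenance."""

    grid: np.ndarray
    config: RasterConfig
    label: str = ""
    source_id: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


def bresenham_line(p0: tuple[int, int], p1: tuple[int, int]) -> list[tuple[int, int]]:
    """Integer-only pixel chain from p0 to p1 (inclusive), any octant.

    Returns max(|dx|, |dy|) + 1 pixels; consecutive pixels are
    8-connected, with one pixel per major-axis step.  For steep lines
    (|dy| > |dx|) the axes swap roles; each axis steps with the sign of
    its span, so the first-octant decision logic covers all octants.
    """
    x0, y0 = p0
    x1, y1 = p1
    dx = abs(x1 - x0)
    dy = abs(y1 - y0)
    sx = 1 if x1 >= x0 else -1
    sy = 1 if y1 >= y0 else -1
    steep = dy > dx
    if steep:
        da, db = dy, dx
    else:
        da, db = dx, dy
    decision = 2 * db - da
    pts = [(x0, y0)]
    x, y = x0, y0
    for _ in range(da):
        if steep:
            y += sy
            if decision >= 0:
                x += sx
                decision += 2 * db - 2 * da
            else:
                decision += 2 * db
        else:
            x += sx
            if decision >= 0:
                y += sy
                decision += 2 * db - 2 * da
            else:
                decision += 2 * db
        pts.append((x, y))
    return pts


def quantize_row(value: float, resolution: float) -> int:
    """Amplitude in [0,1] -> pixel row, row 0 at amplitude 1, half rounds up."""
    inv = int(round(1.0 / resolution))
    return int(np.floor((1.0 - value) * inv + 0.5))


def window_to_image(values: np.ndarray, cfg: RasterConfig,
                    label: str = "", source_id: str = "") -> RasterImage:
    """Rasterize one window: place quantized samples, join them with lines."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 1:
        raise ValueError("window must be a non-empty 1D vector")
    if np.any(values < 0) or np.any(values > 1):
        raise ValueError("window values must lie in [0, 1]")
    h = cfg.n_rows
    w = cfg.n_cols(values.size)
    grid = np.zeros((h, w), dtype=np.uint8)
    cols = np.arange(values.size) * (cfg.dummy + 1)
    rows = np.array([quantize_row(v, cfg.resolution) for v in values])
    grid[rows[0], cols[0]] = cfg.polarity
    for i in range(values.size - 1):
        for x, y in bresenham_line((cols[i], rows[i]), (cols[i + 1], rows[i + 1])):
            grid[y, x] = cfg.polarity
    return RasterImage(grid=grid, config=cfg, label=label, source_id=source_id)


def rasterize_windowset(ws: WindowSet, cfg: RasterConfig) -> list[RasterImage]:
    """One RasterImage per window, preserving order and labels."""
    return [
        window_to_image(ws.values[i], cfg, label=ws.labels[i],
                        source_id=f"{ws.sources[i][0]}:{ws.sources[i][1]}")
        for i in range(len(ws))
    ]


def write_image(img: RasterImage, path: str | Path) -> None:
    """Lossless bilevel PNG plus a JSON sidecar (label, source, config)."""
    path = Path(path)
    Image.fromarray((img.grid > 0).astype(np.uint8) * 255, mode="L").save(path)
    sidecar = {
        "label": img.label,
        "source_id": img.source_id,
        "config": asdict(img.config),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_image(path: str | Path) -> RasterImage:
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot read raster image {path}: {exc}") from exc
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        cfg = RasterConfig(**meta["config"])
        label, source_id = meta["label"], meta["source_id"]
    else:
        raise ValueError(f"missing sidecar for {path}")
    grid = (arr > 0).astype(np.uint8) * cfg.polarity
    return RasterImage(grid=grid, config=cfg, label=label, source_id=source_id)


def write_image_batch(images: list[RasterImage], out_dir: str | Path,
                      prefix: str = "win") -> Path:
    """Write k images + a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["filename,label,source_id,height,width,resolution,dummy"]
    for i, img in enumerate(images):
        name = f"{prefix}{i:06d}.png"
        write_image(img, out_dir / name)
        h, w = img.shape
        lines.append(
            f"{name},{img.label},{img.source_id},{h},{w},"
            f"{img.config.resolution},{img.config.dummy}"
        )
    manifest = out_dir / "manifest.csv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
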