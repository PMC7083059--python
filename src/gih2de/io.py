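"""Image and table I/O for the gel pipeline.

Gels travel as single-channel grayscale TIFF or PNG; histograms, PDFs,
CDFs and gray-level mappings are exported as two-column CSV
(``level,value``); spot tables as CSV with one row per spot; real-valued
heat maps as floating-point TIFF plus an 8-bit color-mapped PNG.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .image import GrayImage

__all__ = [
    "read_image",
    "write_image",
    "write_level_csv",
    "read_level_csv",
    "write_spot_table",
    "read_spot_table",
    "write_heatmap",
    "write_run_summary",
]


def read_image(path: str | Path, *, rescale_to_8bit: bool = False) -> GrayImage:
    """Read a single-channel grayscale TIFF/PNG into a :class:`GrayImage`.

    The level count is inferred from the bit depth (uint8 -> 256,
    uint16 -> 65536).  With ``rescale_to_8bit`` higher-bit-depth data is
    linearly rescaled so the dtype maximum maps to 255.  Multi-channel
    images are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path} is not single-channel grayscale (shape {arr.shape})"
        )
    if arr.dtype == np.uint8:
        return GrayImage(arr, 256)
    if arr.dtype == np.uint16:
        if rescale_to_8bit:
            scaled = np.floor(arr.astype(np.float64) * 255.0 / 65535.0 + 0.5)
            return GrayImage(scaled.astype(np.uint8), 256)
        return GrayImage(arr, 65536)
    raise ValueError(f"unsupported image dtype {arr.dtype} in {path}")


def write_image(img: GrayImage, path: str | Path) -> None:
    """Write losslessly: ``read_image(write_image(x)) == x``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, img.astype_minimal())


def write_level_csv(values: np.ndarray, path: str | Path, name: str = "value") -> None:
    """Export a per-gray-level vector (histogram, pdf, cdf, mapping)."""
    values = np.asarray(values)
    df = pd.DataFrame({"level": np.arange(values.shape[0]), name: values})
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_level_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df.iloc[:, 1].to_numpy()


def write_spot_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_spot_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_heatmap(heat: np.ndarray, path_tiff: str | Path,
                  path_png: str | Path | None = None) -> None:
    """Write a real-valued heat map as float32 TIFF and optionally an
    8-bit color-mapped PNG (viridis)."""
    path_tiff = Path(path_tiff)
    path_tiff.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path_tiff, heat.astype(np.float32))
    if path_png is not None:
        from matplotlib import colormaps

        lo, hi = float(heat.min()), float(heat.max())
        norm = (heat - lo) / (hi - lo) if hi > lo else np.zeros_like(heat)
        rgba = colormaps["viridis"](norm)
        iio.imwrite(Path(path_png), (rgba[..., :3] * 255).astype(np.uint8))


def write_run_summary(out_dir: str | Path, config: dict, extra: dict | None = None
                      ) -> Path:
    """Persist a machine-readable run summary with a config hash.

    Every CLI run writes one of these so a result can be replayed
    exactly from its recorded configuration and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    summary = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    if extra:
        summary.update(extra)
    path = out_dir / "run_summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    return path
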