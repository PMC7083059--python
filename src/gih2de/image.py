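"""Integer gray-level image container shared by the whole pipeline.

2D electrophoresis gels are scanned as single-channel grayscale images:
a bright, slowly varying background with dark protein spots.  All
operations in this package work on :class:`GrayImage`, a thin validated
wrapper around a 2-D integer array together with its declared number of
gray levels ``L`` (256 for the usual 8-bit scans).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GrayImage"]


@dataclass(frozen=True)
class GrayImage:
    """A 2-D single-channel image with integer gray levels in ``[0, levels-1]``.

    Parameters
    ----------
    pixels:
        2-D integer array, shape ``(H, W)`` with ``H, W >= 1``.
    levels:
        Number of representable gray levels ``L`` (default 256).
    """

    pixels: np.ndarray
    levels: int = 256

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
        if arr.size == 0:
            raise ValueError("empty image (zero-sized axis)")
        if not np.issubdtype(arr.dtype, np.integer):
            if np.issubdtype(arr.dtype, np.floating) and np.allclose(
                arr, np.round(arr)
            ):
                arr = np.round(arr).astype(np.int64)
            else:
                raise TypeError(f"pixels must be integers, got dtype {arr.dtype}")
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if arr.min() < 0 or arr.max() > self.levels - 1:
            raise ValueError(
                f"pixel values outside [0, {self.levels - 1}]: "
                f"min={arr.min()}, max={arr.max()}"
            )
        object.__setattr__(self, "pixels", np.ascontiguousarray(arr))

    # -- convenience ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @classmethod
    def from_array(cls, arr: np.ndarray, levels: int | None = None) -> "GrayImage":
        """Wrap an integer array, inferring ``levels`` from the dtype.

        uint8 input implies 256 levels, uint16 implies 65536; anything
        else requires ``levels`` to be given explicitly.
        """
        arr = np.asarray(arr)
        if levels is None:
            if arr.dtype == np.uint8:
                levels = 256
            elif arr.dtype == np.uint16:
                levels = 65536
            else:
                raise ValueError(
                    "levels must be given explicitly for dtype "
                    f"{arr.dtype}"
                )
        return cls(arr, levels)

    def astype_minimal(self) -> np.ndarray:
        """Pixels as the smallest unsigned dtype that holds ``levels - 1``."""
        dtype = np.uint8 if self.levels <= 256 else np.uint16
        return self.pixels.astype(dtype)
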