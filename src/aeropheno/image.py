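"""Calibrated sensor rasters and their TIFF serialisation.

A :class:`SensorImage` carries an H x W x C float array plus channel
semantics ("R", "G", "B", "NIR", "T").  Optical channels hold 16-bit digital
numbers (stored as floats, 0..65535); the thermal channel holds degC.
NaN is the sentinel for invalid pixels (outside the warped source).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["SensorImage", "MAX_DN"]

#: Full scale of a 16-bit digital number.
MAX_DN = 65535.0


@dataclass
class SensorImage:
    pixels: np.ndarray  # H x W x C, float
    channel_names: tuple[str, ...]
    campaign_id: str = ""
    bit_depth: int = 16
    units: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3:
            raise ValueError("pixels must be H x W or H x W x C")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if px.shape[2] != len(self.channel_names):
            raise ValueError(
                f"{px.shape[2]} channels but {len(self.channel_names)} names"
            )
        self.pixels = px
        self.channel_names = tuple(self.channel_names)
        if not self.units:
            self.units = tuple(
                "degC" if n == "T" else "DN" for n in self.channel_names
            )
        if "T" in self.channel_names:
            t = self.channel(("T"))
            if np.isinf(t).any():
                raise ValueError("thermal channel contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def channel(self, name: str) -> np.ndarray:
        """A single channel as an H x W view."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.pixels[:, :, idx]

    def with_pixels(self, pixels: np.ndarray) -> "SensorImage":
        return replace(self, pixels=pixels)

    # ------------------------------------------------------------------ I/O
    def to_tiff(self, path: str | Path) -> None:
        """Write as TIFF: uint16 for DN images, float32 when thermal/NaN."""
        px = self.pixels
        arr = np.moveaxis(px, -1, 0) if px.shape[2] > 1 else px[:, :, 0]
        if "T" in self.channel_names or np.isnan(px).any():
            tifffile.imwrite(path, arr.astype(np.float32),
                             photometric="minisblack")
        else:
            tifffile.imwrite(path, np.clip(arr, 0, MAX_DN).astype(np.uint16),
                             photometric="minisblack")

    @classmethod
    def from_tiff(
        cls, path: str | Path, channel_names, campaign_id: str = ""
    ) -> "SensorImage":
        arr = tifffile.imread(path)
        if arr.ndim == 3 and arr.shape[0] == len(channel_names):
            arr = np.moveaxis(arr, 0, -1)
        return cls(
            pixels=np.asarray(arr, dtype=float),
            channel_names=tuple(channel_names),
            campaign_id=campaign_id,
        )
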