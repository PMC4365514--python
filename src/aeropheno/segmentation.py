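"""Plant/soil segmentation from the two-channel vegetation camera.

The vegetation index is a blue-band NDVI, (NIR - B)/(NIR + B), computed per
pixel from the modified consumer camera's blue and near-infrared channels.
Plant pixels are found in two steps: an NDVI threshold (default 0.1, strict
inequality, constant across the season) and a grey-intensity threshold that
removes deeply shaded areas (set per campaign, since it depends on the
radiation conditions at capture).  The two masks are combined by
multiplication (logical AND).  For plain RGB imagery an HSB (hue,
saturation, brightness) interval segmentation is provided instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .image import MAX_DN

__all__ = [
    "NdviRaster",
    "SegmentationConfig",
    "SegmentationMask",
    "compute_ndvi",
    "intensity_image",
    "segment_ndvi",
    "segment_hsb",
    "senescence_band",
]

#: Season-constant NDVI plant threshold; keeps green and senescent material.
NDVI_PLANT_THRESHOLD = 0.1
#: Stricter threshold that drops most senescent material.
NDVI_GREEN_THRESHOLD = 0.2


@dataclass
class NdviRaster:
    """Per-pixel NDVI in [-1, 1]; NaN marks invalid pixels."""

    values: np.ndarray
    campaign_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("NDVI values outside [-1, 1]")
        self.values = v

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class SegmentationConfig:
    """Thresholds for one campaign.

    ``intensity_threshold`` is on the [0, 1] monochrome reflection-intensity
    scale and must be set explicitly per campaign (it tracks radiation
    conditions); ``hsb_ranges`` are (hue degrees, saturation, brightness)
    intervals, the hue interval interpreted circularly.
    """

    ndvi_threshold: float = NDVI_PLANT_THRESHOLD
    intensity_threshold: float | None = None
    hsb_ranges: tuple | None = None
    mode: str = "ndvi"

    def __post_init__(self) -> None:
        if not -1.0 < self.ndvi_threshold < 1.0:
            raise ConfigurationError(
                f"ndvi_threshold {self.ndvi_threshold} outside (-1, 1)"
            )
        if self.mode not in ("ndvi", "hsb"):
            raise ConfigurationError(f"unknown segmentation mode {self.mode!r}")
        if self.hsb_ranges is not None:
            if len(self.hsb_ranges) != 3:
                raise ConfigurationError("hsb_ranges must be 3 intervals")
            for name, (lo, hi) in zip(("saturation", "brightness"),
                                      self.hsb_ranges[1:]):
                if lo > hi:
                    raise ConfigurationError(f"{name} interval bounds unordered")


@dataclass
class SegmentationMask:
    """Boolean plant raster plus the valid-pixel raster it was computed on."""

    plant: np.ndarray
    valid: np.ndarray
    config_used: SegmentationConfig = field(default_factory=SegmentationConfig)

    def __post_init__(self) -> None:
        self.plant = np.asarray(self.plant, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.plant.shape != self.valid.shape:
            raise ValueError("plant and valid rasters differ in shape")
        # no plant pixel may be invalid
        self.plant &= self.valid

    def to_uint8(self) -> np.ndarray:
        """8-bit encoding: 0 soil, 255 plant, 128 invalid."""
        out = np.zeros(self.plant.shape, dtype=np.uint8)
        out[~self.valid] = 128
        out[self.plant] = 255
        return out


def compute_ndvi(b: np.ndarray, nir: np.ndarray, campaign_id: str = "") -> NdviRaster:
    """Blue-band NDVI = (NIR - B)/(NIR + B), elementwise.

    Pixels where NIR + B == 0 (or either channel is NaN) are invalid.
    Channels may be digital numbers or reflectances; the index is invariant
    to a common positive scale.
    """
    b = np.asarray(b, dtype=float)
    nir = np.asarray(nir, dtype=float)
    if b.shape != nir.shape:
        raise ValueError(f"shape mismatch: B {b.shape} vs NIR {nir.shape}")
    total = nir + b
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(total != 0, (nir - b) / total, np.nan)
    return NdviRaster(values=ndvi, campaign_id=campaign_id)


def intensity_image(b: np.ndarray, nir: np.ndarray) -> np.ndarray:
    """Monochrome reflection intensity on [0, 1]: mean of B and NIR / full DN."""
    b = np.asarray(b, dtype=float)
    nir = np.asarray(nir, dtype=float)
    return (b + nir) / 2.0 / MAX_DN


def segment_ndvi(
    ndvi: NdviRaster, intensity: np.ndarray, cfg: SegmentationConfig
) -> SegmentationMask:
    """Two-step segmentation: NDVI > threshold AND intensity > threshold.

    Strict inequalities: ties at a threshold count as soil.  Invalid NDVI
    pixels are never plant.
    """
    if cfg.mode != "ndvi":
        raise ConfigurationError("segment_ndvi requires cfg.mode == 'ndvi'")
    if cfg.intensity_threshold is None:
        raise ConfigurationError(
            "no intensity_threshold configured for this campaign; the shade "
            "filter threshold must be set per campaign"
        )
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != ndvi.values.shape:
        raise ValueError("intensity raster shape mismatch")
    valid = ndvi.valid & np.isfinite(intensity)
    with np.errstate(invalid="ignore"):
        plant = valid & (ndvi.values > cfg.ndvi_threshold) & (
            intensity > cfg.intensity_threshold
        )
    return SegmentationMask(plant=plant, valid=valid, config_used=cfg)


def rgb_to_hsb(rgb: np.ndarray) -> np.ndarray:
    """HSB = HSV with hue in degrees [0, 360), S and B in [0, 1].

    Input is H x W x 3 on any common positive scale (DN or [0, 1]);
    brightness is max(R, G, B) rescaled by the array's full scale only if
    values exceed 1 (i.e. DN input is divided by the 16-bit full scale).
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an H x W x 3 raster")
    if np.nanmax(rgb) > 1.0:
        rgb = rgb / MAX_DN
    import matplotlib.colors as mcolors

    hsv = mcolors.rgb_to_hsv(np.clip(rgb, 0, 1))
    hsv[..., 0] *= 360.0
    return hsv


def segment_hsb(rgb: np.ndarray, cfg: SegmentationConfig) -> SegmentationMask:
    """Interval segmentation in HSB space (RGB route).

    A pixel is plant when hue, saturation and brightness each fall inside
    their configured interval; the hue interval is circular and may wrap
    through 360 -> 0 (lo > hi means [lo, 360) union [0, hi]).
    """
    if cfg.mode != "hsb":
        raise ConfigurationError("segment_hsb requires cfg.mode == 'hsb'")
    if cfg.hsb_ranges is None:
        raise ConfigurationError("hsb_ranges not configured for this campaign")
    rgb = np.asarray(rgb, dtype=float)
    valid = np.isfinite(rgb).all(axis=2)
    hsb = rgb_to_hsb(np.where(valid[..., None], rgb, 0.0))
    (h_lo, h_hi), (s_lo, s_hi), (b_lo, b_hi) = cfg.hsb_ranges
    hue = hsb[..., 0]
    if h_lo <= h_hi:
        hue_ok = (hue >= h_lo) & (hue <= h_hi)
    else:  # wraps through 0
        hue_ok = (hue >= h_lo) | (hue <= h_hi)
    plant = (
        valid
        & hue_ok
        & (hsb[..., 1] >= s_lo)
        & (hsb[..., 1] <= s_hi)
        & (hsb[..., 2] >= b_lo)
        & (hsb[..., 2] <= b_hi)
    )
    return SegmentationMask(plant=plant, valid=valid, config_used=cfg)


def senescence_band(ndvi: NdviRaster) -> np.ndarray:
    """Pixels with NDVI in (0.1, 0.2]: senescent plant material.

    The permissive plant threshold (0.1) keeps green plus senescent tissue
    while the stricter 0.2 keeps mostly green tissue; their set difference
    isolates the senescent band.
    """
    with np.errstate(invalid="ignore"):
        return (
            ndvi.valid
            & (ndvi.values > NDVI_PLANT_THRESHOLD)
            & (ndvi.values <= NDVI_GREEN_THRESHOLD)
        )
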