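"""Closed-form optics and flight arithmetic for the aerial sensor array.

Everything here is elementary similar-triangles optics: a sensor of physical
size ``s`` (mm) behind a lens of focal length ``f`` (mm), flown ``h`` metres
above the ground, images a ground swath of ``s/f * h`` metres; one pixel
covers ``(s/n_pixels)/f * h`` metres (the instantaneous field of view, IFoV).
Motion blur is ground speed times shutter time, expressed in ground pixels.

All functions return full-precision floats; table-style rounding is applied
only by :func:`round_footprint` so that derived quantities never accumulate
presentation rounding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .errors import InvalidSpecError

__all__ = [
    "SensorSpec",
    "FlightParams",
    "GroundFootprint",
    "compute_ifov",
    "compute_footprint",
    "compute_motion_blur",
    "survey_throughput",
    "round_footprint",
]


@dataclass(frozen=True)
class SensorSpec:
    """Physical description of one camera.

    Parameters
    ----------
    name : str
        Sensor label, e.g. ``"NIR"``, ``"RGB"`` or ``"IR"``.
    focal_length : float
        Lens focal length in mm.
    pixels_long, pixels_short : int
        Pixel counts along the long and short sensor axes.
    sensor_long, sensor_short : float
        Physical sensor dimensions in mm.
    shutter : float
        Shutter (integration) time in ms.
    pixel_pitch : float or None
        Optional physical pixel size in mm.  When given, it overrides
        ``sensor_dim / pixels`` in the IFoV formula (some vendors quote a
        pitch that differs slightly from the die dimensions).
    """

    name: str
    focal_length: float
    pixels_long: int
    pixels_short: int
    sensor_long: float
    sensor_short: float
    shutter: float = 0.0
    pixel_pitch: float | None = None

    def __post_init__(self) -> None:
        if self.focal_length <= 0:
            raise InvalidSpecError(f"{self.name}: focal length must be > 0")
        if self.pixels_long < 1 or self.pixels_short < 1:
            raise InvalidSpecError(f"{self.name}: pixel counts must be >= 1")
        if self.sensor_long <= 0 or self.sensor_short <= 0:
            raise InvalidSpecError(f"{self.name}: sensor dimensions must be > 0")
        if self.shutter < 0:
            raise InvalidSpecError(f"{self.name}: shutter must be >= 0")

    @classmethod
    def from_config(cls, cfg: dict) -> "SensorSpec":
        """Build a spec from a run-configuration dictionary.

        Expected keys: ``name``, ``focal_length_mm``, ``pixels`` ([long,
        short]), ``sensor_mm`` ([long, short]), ``shutter_ms`` (optional),
        ``pixel_pitch_mm`` (optional).
        """
        return cls(
            name=cfg["name"],
            focal_length=float(cfg["focal_length_mm"]),
            pixels_long=int(cfg["pixels"][0]),
            pixels_short=int(cfg["pixels"][1]),
            sensor_long=float(cfg["sensor_mm"][0]),
            sensor_short=float(cfg["sensor_mm"][1]),
            shutter=float(cfg.get("shutter_ms", 0.0)),
            pixel_pitch=(
                float(cfg["pixel_pitch_mm"]) if cfg.get("pixel_pitch_mm") else None
            ),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SensorSpec":
        with open(path) as fh:
            return cls.from_config(json.load(fh))


#: The three cameras of the handheld array (focal lengths in mm, pixel counts,
#: sensor die dimensions in mm, shutter in ms).
NIR_SPEC = SensorSpec("NIR", 60.0, 4282, 2848, 22.2, 14.8, shutter=1.0)
RGB_SPEC = SensorSpec("RGB", 60.0, 3898, 2595, 22.2, 14.8, shutter=1.0)
IR_SPEC = SensorSpec("IR", 75.0, 640, 480, 14.9, 11.2, shutter=50.0)

DEFAULT_SPECS = {"NIR": NIR_SPEC, "RGB": RGB_SPEC, "IR": IR_SPEC}


@dataclass(frozen=True)
class FlightParams:
    """Flight altitude (m) and ground speed (km/h)."""

    altitude: float
    ground_speed: float = 0.0

    def __post_init__(self) -> None:
        if self.altitude < 0:
            raise InvalidSpecError("altitude must be >= 0")
        if self.ground_speed < 0:
            raise InvalidSpecError("ground speed must be >= 0")


@dataclass(frozen=True)
class GroundFootprint:
    """Ground-projected image geometry at a given altitude (all metres)."""

    ifov: float
    length_ground: float
    width_ground: float
    blur_distance: float
    blur_pixels: int


def compute_ifov(spec: SensorSpec, altitude: float, axis: str = "long") -> float:
    """Ground size of one pixel: (pixel dimension x distance) / focal length.

    Parameters
    ----------
    spec : SensorSpec
    altitude : float
        Distance to the ground in metres (>= 0).
    axis : {"long", "short"}
        Which sensor axis the pixel dimension is taken along.  Irrelevant for
        square pixels but the two consumer cameras have slightly non-square
        effective pitches.

    Returns
    -------
    float
        IFoV in metres at the given altitude.
    """
    if altitude < 0:
        raise InvalidSpecError("altitude must be >= 0")
    if axis not in ("long", "short"):
        raise InvalidSpecError(f"axis must be 'long' or 'short', got {axis!r}")
    if spec.pixel_pitch is not None:
        pitch_mm = spec.pixel_pitch
    elif axis == "long":
        pitch_mm = spec.sensor_long / spec.pixels_long
    else:
        pitch_mm = spec.sensor_short / spec.pixels_short
    # mm cancels: (pitch_mm / focal_mm) is dimensionless, times metres.
    return pitch_mm / spec.focal_length * altitude


def compute_motion_blur(
    flight: FlightParams, shutter_ms: float, ground_pixel_m: float
) -> tuple[float, int]:
    """Distance travelled during the shutter opening, and in ground pixels.

    Returns ``(blur_distance_m, blur_pixels)`` where the pixel count is the
    distance divided by the ground pixel size, rounded to the nearest integer.
    """
    if shutter_ms < 0:
        raise InvalidSpecError("shutter must be >= 0")
    if ground_pixel_m <= 0:
        raise InvalidSpecError("ground pixel size must be > 0")
    speed_ms = flight.ground_speed * 1000.0 / 3600.0  # km/h -> m/s
    blur_distance = speed_ms * shutter_ms / 1000.0
    blur_pixels = int(round(blur_distance / ground_pixel_m))
    return blur_distance, blur_pixels


def compute_footprint(spec: SensorSpec, flight: FlightParams) -> GroundFootprint:
    """Ground footprint (length x width), IFoV and motion blur for a flight.

    ``length_ground`` uses the long sensor axis and ``width_ground`` the short
    one; both are ``sensor_dim / focal_length * altitude``.
    """
    h = flight.altitude
    length_ground = spec.sensor_long / spec.focal_length * h
    width_ground = spec.sensor_short / spec.focal_length * h
    ifov = compute_ifov(spec, h, axis="long")
    if ifov > 0:
        blur_distance, blur_pixels = compute_motion_blur(flight, spec.shutter, ifov)
    else:
        blur_distance, blur_pixels = 0.0, 0
    return GroundFootprint(
        ifov=ifov,
        length_ground=length_ground,
        width_ground=width_ground,
        blur_distance=blur_distance,
        blur_pixels=blur_pixels,
    )


def survey_throughput(
    plot_len: float,
    plot_wid: float,
    n_plots: int,
    reference_area: float,
    reference_time: float,
) -> tuple[float, float]:
    """Area (ha) of a hypothetical survey and its time extrapolated linearly.

    ``reference_area`` (m^2) was imaged in ``reference_time`` seconds; the
    target of ``n_plots`` plots of ``plot_len x plot_wid`` metres is assumed
    to scale linearly.  Returns ``(total_area_ha, total_time_min)`` with the
    time rounded to the nearest minute (raw seconds available by multiplying
    back).
    """
    if min(plot_len, plot_wid) <= 0 or n_plots <= 0:
        raise InvalidSpecError("plot dimensions and count must be positive")
    if reference_area <= 0:
        raise InvalidSpecError("reference area must be > 0")
    if reference_time < 0:
        raise InvalidSpecError("reference time must be >= 0")
    total_area_m2 = n_plots * plot_len * plot_wid
    total_time_s = reference_time * total_area_m2 / reference_area
    return total_area_m2 / 1e4, round(total_time_s / 60.0)


def round_footprint(fp: GroundFootprint, ifov_decimals: int = 4) -> dict:
    """Presentation rounding of a footprint, table style.

    Lengths/widths to one decimal metre, IFoV to ``ifov_decimals`` (trailing
    zeros stripped by float repr).  Also reports the footprint length implied
    by the *rounded* IFoV times the pixel count — the convention some summary
    tables use, which can differ from the direct formula in the last digit.
    """
    ifov_r = round(fp.ifov, ifov_decimals)
    return {
        "ifov": ifov_r,
        "length_ground": round(fp.length_ground, 1),
        "width_ground": round(fp.width_ground, 1),
        "blur_distance": round(fp.blur_distance, 2),
        "blur_pixels": fp.blur_pixels,
    }


def length_from_rounded_ifov(
    spec: SensorSpec, altitude: float, ifov_decimals: int = 3
) -> float:
    """Footprint length as rounded-IFoV x pixel count (alternate convention)."""
    ifov_r = round(compute_ifov(spec, altitude, "long"), ifov_decimals)
    return round(ifov_r * spec.pixels_long, 1)
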