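"""Weather-derived quantities for the trial.

Thermal time (growing degree days above a maize base temperature of 8 degC),
saturation vapour pressure by the Tetens-style formula
``SVP(Pa) = 610.7 * 10^(7.5 T / (237.3 + T))``, the vapour pressure deficit
``VPD = ((100 - rH)/100) * SVP``, and a linear leaf-area-index calibration
from specific leaf fresh weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError, InvalidSpecError

__all__ = [
    "DailyWeather",
    "WeatherSnapshot",
    "BiomassSample",
    "thermal_time",
    "svp",
    "vpd",
    "lai_from_biomass",
]

#: Maize base temperature for thermal time, degC.
T_BASE_MAIZE = 8.0

#: LAI calibration: LAI = (SLW - LAI_INTERCEPT) / LAI_SLOPE, with SLW in
#: mg/cm^2.  Fitted on a destructive sub-sample (n = 24, r^2 = 0.98).
LAI_INTERCEPT = 3.96
LAI_SLOPE = 27.4

#: Row distance used in the SLW ground-area normalisation, cm.
ROW_DISTANCE_CM = 70.0


@dataclass(frozen=True)
class DailyWeather:
    """One day of min/max air temperature (degC)."""

    date: object
    t_max: float
    t_min: float

    def __post_init__(self) -> None:
        if self.t_max < self.t_min:
            raise DataError(f"{self.date}: t_max ({self.t_max}) < t_min ({self.t_min})")


@dataclass
class WeatherSnapshot:
    """Instantaneous station reading with derived SVP/VPD."""

    t_air: float
    rh: float
    svp: float = field(init=False)
    vpd: float = field(init=False)

    def __post_init__(self) -> None:
        self.svp = svp(self.t_air)
        self.vpd = vpd(self.t_air, self.rh)


@dataclass(frozen=True)
class BiomassSample:
    """Destructive leaf-biomass sample from a sampling row.

    ``leaf_biomass`` in g over a ``sampling_length`` (cm) of row at
    ``row_distance`` cm spacing.
    """

    leaf_biomass: float
    sampling_length: float
    row_distance: float = ROW_DISTANCE_CM


def thermal_time(series, t_base: float = T_BASE_MAIZE) -> float:
    """Cumulative degree days: sum of max(0, (t_max + t_min)/2 - t_base).

    Days whose mean temperature is below the base contribute zero (they are
    clamped per day, not at the end), so thermal time is additive over
    concatenated date ranges and non-decreasing in series length.

    Parameters
    ----------
    series : iterable of DailyWeather
    t_base : float
        Base temperature in degC (default 8, maize).
    """
    series = list(series)
    if not series:
        raise DataError("thermal_time requires a non-empty series")
    return float(sum(max(0.0, (d.t_max + d.t_min) / 2.0 - t_base) for d in series))


def daily_weather_from_csv(path) -> list[DailyWeather]:
    """Read a daily weather CSV with columns date, t_max, t_min."""
    df = pd.read_csv(path)
    return [
        DailyWeather(date=row.date, t_max=float(row.t_max), t_min=float(row.t_min))
        for row in df.itertuples()
    ]


def svp(t: float) -> float:
    """Saturation vapour pressure in Pa: 610.7 * 10^(7.5 t / (237.3 + t))."""
    if t <= -237.3:
        raise InvalidSpecError(f"svp undefined at t = {t} degC (<= -237.3)")
    return 610.7 * 10.0 ** (7.5 * t / (237.3 + t))


def vpd(t: float, rh: float) -> float:
    """Vapour pressure deficit in kPa from air temperature and rel. humidity.

    ``((100 - rh)/100) * SVP(t)``, with SVP computed in Pa and the result
    converted to kPa.
    """
    if not 0.0 <= rh <= 100.0:
        raise InvalidSpecError(f"relative humidity {rh} outside [0, 100]")
    return (100.0 - rh) / 100.0 * svp(t) / 1000.0


def lai_from_biomass(sample: BiomassSample) -> tuple[float, float]:
    """Specific leaf weight (mg/cm^2) and LAI (m^2/m^2) from leaf biomass.

    SLW = biomass(g) / (sampling_length(cm) * row_distance(cm)) * 1000;
    LAI = (SLW - 3.96) / 27.4, clamped at 0 with a warning when the sample
    falls below the calibration intercept.
    """
    if sample.leaf_biomass <= 0:
        raise InvalidSpecError("leaf biomass must be > 0")
    if sample.sampling_length <= 0 or sample.row_distance <= 0:
        raise InvalidSpecError("sampling length and row distance must be > 0")
    slw = sample.leaf_biomass / (sample.sampling_length * sample.row_distance) * 1000.0
    lai = (slw - LAI_INTERCEPT) / LAI_SLOPE
    if lai < 0:
        warnings.warn(
            f"SLW {slw:.2f} mg/cm^2 below calibration intercept; LAI clamped to 0",
            stacklevel=2,
        )
        lai = 0.0
    return slw, lai
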