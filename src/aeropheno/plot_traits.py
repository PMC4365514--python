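"""Per-plot trait extraction from co-registered image stacks.

The plot map (plot polygons with genotype, row count and block) is
rasterized onto the AoI grid; for each plot the canopy cover (fraction of
plant pixels), the median NDVI over all pixels (NDVI_Plot) and over plant
pixels only (NDVI_Plant), the skewness of the NDVI histogram, the canopy
temperature T_C (median thermal signal, unsegmented — the thermal ground
pixel is too coarse for plant/soil separation) and its difference dT to the
air temperature at capture are computed.

Skewness is the third standardized population moment

    s = ((1/n) sum (x_i - mean)^3) / (sqrt((1/n) sum (x_i - mean)^2))^3

with no bias correction; it is zero for symmetric samples, and positive
NDVI_Plot skewness flags plots whose canopy cover is low (soil pixels pull
the bulk of the histogram below the mean plant signal).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .errors import ConfigurationError, UndefinedSkewnessError
from .segmentation import SegmentationMask

__all__ = [
    "PlotDefinition",
    "PlotMap",
    "PlotTraitRecord",
    "rasterize_plot_map",
    "skewness",
    "extract_plot_traits",
    "seasonal_table",
]

BACKGROUND = -1

#: Plots with fewer valid pixels than this fraction of their rasterized area
#: are flagged (kept, not dropped).
MIN_VALID_FRACTION = 0.8


@dataclass(frozen=True)
class PlotDefinition:
    plot_id: str
    genotype: str
    rows: int
    block: str
    polygon: tuple  # ((row, col), ...) AoI-frame vertices

    def __post_init__(self) -> None:
        if self.rows not in (1, 2, 3, 4):
            raise ConfigurationError(f"{self.plot_id}: rows must be 1-4")
        if len(self.polygon) < 3:
            raise ConfigurationError(f"{self.plot_id}: polygon needs >= 3 vertices")

    def shapely_polygon(self) -> shapely.Polygon:
        # shapely x = col, y = row
        return shapely.Polygon([(c, r) for r, c in self.polygon])


@dataclass
class PlotMap:
    plots: list[PlotDefinition]

    def __post_init__(self) -> None:
        seen = set()
        for p in self.plots:
            if p.plot_id in seen:
                raise ConfigurationError(f"duplicate plot_id {p.plot_id}")
            seen.add(p.plot_id)
            if not p.shapely_polygon().is_valid:
                raise ConfigurationError(f"{p.plot_id}: self-intersecting polygon")

    def to_csv(self, path) -> None:
        rows = [
            {
                "plot_id": p.plot_id,
                "genotype": p.genotype,
                "rows": p.rows,
                "block": p.block,
                "polygon": ";".join(f"{r:.4f} {c:.4f}" for r, c in p.polygon),
            }
            for p in self.plots
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PlotMap":
        df = pd.read_csv(path)
        plots = []
        for row in df.itertuples():
            verts = tuple(
                tuple(float(v) for v in pair.split()) for pair in row.polygon.split(";")
            )
            plots.append(
                PlotDefinition(
                    plot_id=str(row.plot_id),
                    genotype=str(row.genotype),
                    rows=int(row.rows),
                    block=str(row.block),
                    polygon=verts,
                )
            )
        return cls(plots=plots)

    @classmethod
    def from_json(cls, path) -> "PlotMap":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            plots=[
                PlotDefinition(
                    plot_id=str(p["plot_id"]),
                    genotype=str(p["genotype"]),
                    rows=int(p["rows"]),
                    block=str(p["block"]),
                    polygon=tuple(tuple(v) for v in p["polygon"]),
                )
                for p in data["plots"]
            ]
        )


@dataclass
class PlotTraitRecord:
    """One plot x campaign row of extracted traits (NaN = absent)."""

    plot_id: str
    campaign_id: str
    cc: float
    ndvi_plot: float
    ndvi_plant: float
    skew_plot: float
    skew_plant: float
    t_c: float
    dt: float
    n_pixels: int
    n_plant_pixels: int
    valid_fraction: float = 1.0
    low_coverage: bool = False
    error: str = ""


def rasterize_plot_map(plot_map: PlotMap, aoi_shape: tuple[int, int]) -> np.ndarray:
    """Label raster: pixel -> plot index (or -1 background).

    Pixel membership is decided by pixel-centre containment (pixel centres
    at integer (row, col)).  Overlapping polygons are an error naming the
    offending pair.
    """
    polys = [p.shapely_polygon() for p in plot_map.plots]
    tree = shapely.STRtree(polys)
    for i, poly in enumerate(polys):
        for j in tree.query(poly, predicate="intersects"):
            if j <= i:
                continue
            if polys[int(j)].intersection(poly).area > 1e-9:
                raise ConfigurationError(
                    f"plot polygons overlap: {plot_map.plots[i].plot_id} and "
                    f"{plot_map.plots[int(j)].plot_id}"
                )
    h, w = aoi_shape
    labels = np.full((h, w), BACKGROUND, dtype=np.int32)
    for i, poly in enumerate(polys):
        minx, miny, maxx, maxy = poly.bounds
        c0, c1 = max(0, math.floor(minx)), min(w - 1, math.ceil(maxx))
        r0, r1 = max(0, math.floor(miny)), min(h - 1, math.ceil(maxy))
        if c1 < c0 or r1 < r0:
            continue
        rr, cc = np.meshgrid(
            np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij"
        )
        inside = shapely.contains_xy(poly, cc.ravel(), rr.ravel()).reshape(rr.shape)
        labels[r0 : r1 + 1, c0 : c1 + 1][inside] = i
    return labels


def skewness(values) -> float:
    """Population skewness of a sample (no bias correction).

    Raises :class:`UndefinedSkewnessError` for n < 2 or zero variance.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise UndefinedSkewnessError(f"need >= 2 values, got {x.size}")
    d = x - x.mean()
    m2 = float((d**2).mean())
    if m2 == 0.0:
        raise UndefinedSkewnessError("zero variance sample")
    m3 = float((d**3).mean())
    return m3 / m2**1.5


def _safe_skew(values) -> float:
    try:
        return skewness(values)
    except UndefinedSkewnessError:
        return float("nan")


def _median(values: np.ndarray) -> float:
    """Median with even-size midpoint convention (numpy's default)."""
    return float(np.median(values)) if values.size else float("nan")


def extract_plot_traits(
    ndvi_values: np.ndarray,
    mask: SegmentationMask,
    labels: np.ndarray,
    plot_map: PlotMap,
    campaign_id: str = "",
    thermal: np.ndarray | None = None,
    air_temp: float | None = None,
    thermal_aggregate: str = "median",
    min_valid_fraction: float = MIN_VALID_FRACTION,
) -> list[PlotTraitRecord]:
    """Extract the trait set for every plot of a campaign.

    Parameters
    ----------
    ndvi_values : array
        AoI-frame NDVI raster (NaN invalid).
    mask : SegmentationMask
        Plant/soil mask in the same frame.
    labels : array
        Output of :func:`rasterize_plot_map`.
    plot_map : PlotMap
    thermal : array, optional
        AoI-frame thermal raster in degC; T_C is its median over *all* valid
        plot pixels (no segmentation — the thermal resolution mixes plant
        and soil).
    air_temp : float, optional
        Station air temperature at capture; dT = T_C - air_temp.

    Plots with zero valid pixels yield an error record (NaN traits, the
    ``error`` field set) and the run continues.
    """
    if ndvi_values.shape != labels.shape or mask.plant.shape != labels.shape:
        raise ValueError("all rasters must share the AoI shape")
    if thermal is not None and thermal.shape != labels.shape:
        raise ValueError("thermal raster shape mismatch")
    if thermal_aggregate not in ("median", "mean"):
        raise ConfigurationError("thermal_aggregate must be 'median' or 'mean'")
    agg = np.nanmedian if thermal_aggregate == "median" else np.nanmean

    records = []
    for i, plot in enumerate(plot_map.plots):
        in_plot = labels == i
        n_labelled = int(in_plot.sum())
        valid = in_plot & mask.valid & np.isfinite(ndvi_values)
        n_valid = int(valid.sum())
        if n_valid == 0:
            records.append(
                PlotTraitRecord(
                    plot_id=plot.plot_id,
                    campaign_id=campaign_id,
                    cc=float("nan"),
                    ndvi_plot=float("nan"),
                    ndvi_plant=float("nan"),
                    skew_plot=float("nan"),
                    skew_plant=float("nan"),
                    t_c=float("nan"),
                    dt=float("nan"),
                    n_pixels=0,
                    n_plant_pixels=0,
                    valid_fraction=0.0,
                    low_coverage=True,
                    error="empty plot: no valid pixels",
                )
            )
            continue
        plant = valid & mask.plant
        n_plant = int(plant.sum())
        plot_vals = ndvi_values[valid]
        plant_vals = ndvi_values[plant]
        t_c = float("nan")
        dt = float("nan")
        if thermal is not None:
            t_vals = thermal[in_plot]
            t_vals = t_vals[np.isfinite(t_vals)]
            if t_vals.size:
                t_c = float(agg(t_vals))
                if air_temp is not None:
                    dt = t_c - air_temp
        valid_fraction = n_valid / n_labelled if n_labelled else 0.0
        records.append(
            PlotTraitRecord(
                plot_id=plot.plot_id,
                campaign_id=campaign_id,
                cc=n_plant / n_valid,
                ndvi_plot=_median(plot_vals),
                ndvi_plant=_median(plant_vals) if n_plant else float("nan"),
                skew_plot=_safe_skew(plot_vals),
                skew_plant=_safe_skew(plant_vals) if n_plant else float("nan"),
                t_c=t_c,
                dt=dt,
                n_pixels=n_valid,
                n_plant_pixels=n_plant,
                valid_fraction=valid_fraction,
                low_coverage=valid_fraction < min_valid_fraction,
            )
        )
    n_err = sum(1 for r in records if r.error)
    if n_err:
        warnings.warn(f"{n_err} plot(s) had no valid pixels", stacklevel=2)
    return records


TRAIT_NAMES = ("cc", "ndvi_plot", "ndvi_plant", "skew_plot", "skew_plant", "t_c", "dt")


def seasonal_table(
    records: list[PlotTraitRecord],
    plot_map: PlotMap,
    campaigns: dict,
    traits: tuple[str, ...] = TRAIT_NAMES[:6],
) -> pd.DataFrame:
    """Long trait-by-time table for the statistics module.

    ``campaigns`` maps campaign_id -> thermal time (degree days).  Output
    columns: plot_id, genotype, rows_per_plot, block, campaign, degree_days,
    trait, value.
    """
    by_id = {p.plot_id: p for p in plot_map.plots}
    rows = []
    for rec in records:
        if rec.campaign_id not in campaigns:
            raise ConfigurationError(
                f"record for unknown campaign {rec.campaign_id!r}"
            )
        plot = by_id.get(rec.plot_id)
        if plot is None:
            raise ConfigurationError(f"record for unknown plot {rec.plot_id!r}")
        for trait in traits:
            rows.append(
                {
                    "plot_id": rec.plot_id,
                    "genotype": plot.genotype,
                    "rows_per_plot": plot.rows,
                    "block": plot.block,
                    "campaign": rec.campaign_id,
                    "degree_days": campaigns[rec.campaign_id],
                    "trait": trait,
                    "value": getattr(rec, trait),
                }
            )
    cols = [
        "plot_id", "genotype", "rows_per_plot", "block", "campaign",
        "degree_days", "trait", "value",
    ]
    return pd.DataFrame(rows, columns=cols)


def records_to_frame(records: list[PlotTraitRecord]) -> pd.DataFrame:
    """Flat one-row-per-plot DataFrame of trait records."""
    return pd.DataFrame([r.__dict__ for r in records])
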