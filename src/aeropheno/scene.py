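"""Seeded synthetic field-trial scenes with known ground truth.

The generator emulates the study conditions end to end: a split-plot maize
trial (16 genotypes — six hybrids, five dent and five flint inbred lines —
with the number of rows per plot, one to four, as the whole-plot factor,
replicated in four blocks; 4 m plots at 0.75 m row spacing), eight dark
circular fiducial markers around the field, genotype-specific seasonal
curves for canopy cover, plant NDVI and canopy-minus-air temperature, and a
rendered RGB / B+NIR / thermal raster triple per campaign, each distorted by
a known projective transform and sampled at its own ground pixel size.

Everything is deterministic given the master seed: per-purpose random
streams are derived from fixed offsets, so adding a campaign never perturbs
earlier draws.

Canopy geometry: each plot is drawn as crop rows (strips along the plot
length) whose width is set so that the plant-area fraction of the plot
equals the plot's true canopy cover; a small sinusoidal edge waviness
(+-1.5 cm) dithers the strip edges across pixel-quantization phases so the
rendered plant-pixel fraction tracks the true cover even at coarse ground
pixels.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .image import MAX_DN, SensorImage
from .plot_traits import PlotDefinition, PlotMap

__all__ = [
    "Campaign",
    "DEFAULT_CAMPAIGNS",
    "SceneConfig",
    "TrialDesign",
    "DesignPlot",
    "GenotypeProfile",
    "generate_design",
    "default_profiles",
    "simulate_traits",
    "render_scene",
    "simulate_balanced_trait",
    "SceneBundle",
]

# ---------------------------------------------------------------- constants
PLOT_LENGTH_M = 4.0
ROW_SPACING_M = 0.75
N_GENOTYPES = 16
N_BLOCKS = 4
ROW_COUNTS = (1, 2, 3, 4)
STRIP_ALLEY_M = 0.75
BLOCK_ALLEY_M = 1.5
PLOT_ALLEY_M = 0.5
FIELD_MARGIN_M = 2.0
MARKER_RADIUS_M = 0.35
#: Genotype index ranges: entries 0-5 hybrids, 6-10 dent, 11-15 flint.
GENOTYPE_GROUPS = {
    **{f"g{i:02d}": "hybrid" for i in range(6)},
    **{f"g{i:02d}": "dent" for i in range(6, 11)},
    **{f"g{i:02d}": "flint" for i in range(11, 16)},
}
#: Thermal-time milestones (degC days): canopy closure at the onset of
#: flowering, end of flowering / early senescence, late senescence.
TT_CLOSURE = 540.0
TT_SENESCENCE_ONSET = 892.0


@dataclass(frozen=True)
class Campaign:
    """One flight: identifier, thermal time, sensors flown, air temperature."""

    id: str
    degree_days: float
    sensors: tuple[str, ...] = ("BNIR", "RGB")
    air_temp: float | None = None
    date: str = ""


#: The nine seasonal campaigns (thermal times and air temperatures at the
#: thermal captures follow the acquisition schedule of the study design).
DEFAULT_CAMPAIGNS = (
    Campaign("c1", 371.0, ("BNIR", "RGB"), None, "2011-06-16"),
    Campaign("c2", 540.0, ("BNIR", "RGB"), None, "2011-07-05"),
    Campaign("c3", 612.0, ("BNIR", "RGB", "IR"), 25.95, "2011-07-11"),
    Campaign("c4", 727.0, ("BNIR", "RGB", "IR"), 24.40, "2011-07-26"),
    Campaign("c5", 793.0, ("BNIR", "RGB", "IR"), 27.52, "2011-08-02"),
    Campaign("c6", 893.0, ("BNIR", "RGB", "IR"), 24.40, "2011-08-12"),
    Campaign("c7", 940.0, ("BNIR", "RGB", "IR"), 24.01, "2011-08-16"),
    Campaign("c8", 1275.0, ("BNIR", "RGB", "IR"), 21.71, "2011-09-15"),
    Campaign("c9", 1366.0, ("BNIR", "RGB"), None, "2011-09-29"),
)


@dataclass
class SceneConfig:
    """All tunables of the generator; the seed fixes every random draw."""

    seed: int = 0
    #: Ground pixel per sensor (m); the optical defaults are the effective
    #: pixel sizes at 300 m altitude, thermal is coarser by design.
    ground_pixel: dict = field(
        default_factory=lambda: {"BNIR": 0.026, "RGB": 0.0285, "IR": 0.1}
    )
    #: Pixel NDVI distributions: mean/sd for plant (mean is per-genotype)
    #: and soil, clipped to [-1, 1].
    plant_ndvi_sd: float = 0.05
    #: Soil sits well below the 0.1 plant threshold, chosen so that mixed
    #: plant/soil edge pixels cross the threshold near the 50% mixing point
    #: (the plant/soil midpoint straddles 0.1) — edge pixels then round to
    #: plant and soil in equal measure instead of biasing canopy cover.
    soil_ndvi_mean: float = -0.35
    soil_ndvi_sd: float = 0.03
    #: Reflection-intensity (B+NIR sum) level on [0, 1]; equal for plant and
    #: soil so that mixed pixels mix NDVI linearly.
    illumination: float = 0.55
    illumination_sd: float = 0.03
    #: Fraction of soil pixels in deep shade and their attenuation.
    shade_fraction: float = 0.03
    shade_factor: float = 0.15
    #: Documented intensity threshold for the simulator's campaigns.
    intensity_threshold: float = 0.2
    #: Canopy-edge waviness (m): amplitude and period of the row-edge wobble
    #: (leaf-tip raggedness); the amplitude is folded at the row band edges
    #: so the plant-area fraction stays exactly the canopy cover.
    edge_wave_amplitude: float = 0.04
    edge_wave_period: float = 0.5
    #: Thermal scene: soil excess over air temperature and marker excess.
    soil_temp_offset: float = 3.0
    marker_temp_offset: float = 15.0
    thermal_noise_sd: float = 0.3
    #: Scale of the random projective perturbation (0 disables it).
    homography_perturbation: float = 1.0
    #: IR sub-sampling factor used to mix plant/soil inside a coarse pixel.
    ir_subsample: int = 4

    def __post_init__(self) -> None:
        gp = self.ground_pixel
        if gp["IR"] <= max(gp["BNIR"], gp["RGB"]):
            raise ConfigurationError(
                "thermal ground pixel must be coarser than the optical ones"
            )


@dataclass(frozen=True)
class DesignPlot:
    """One experimental plot in ground coordinates (metres).

    x spans the plot width (rows * row spacing), y the 4 m plot length.
    """

    plot_id: str
    genotype: str
    rows: int
    block: str
    sub_array: int
    x0: float
    x1: float
    y0: float
    y1: float

    @property
    def area_m2(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)


@dataclass
class TrialDesign:
    genotypes: tuple[str, ...]
    plots: list[DesignPlot]
    marker_positions_m: list[tuple[float, float]]  # (x, y)
    field_width_m: float
    field_length_m: float
    plot_length: float = PLOT_LENGTH_M
    row_spacing: float = ROW_SPACING_M
    #: Row-centre x offsets within each plot are implied by the row spacing.

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([p.__dict__ for p in self.plots])

    def plot_map_px(self, ground_pixel: float) -> PlotMap:
        """Plot polygons on the AoI pixel grid (pixel = ground/ground_pixel).

        Rectangles are half-open ([x0, x1) in ground coordinates); strict
        point-in-polygon containment would drop a pixel centre that falls
        exactly on the low edge, so the polygons are nudged by a micro-pixel
        towards the origin to realize low-edge-closed / high-edge-open.
        """
        eps = 1e-6
        defs = []
        for p in self.plots:
            # AoI row = y / gp, col = x / gp; half-open rectangles
            r0, r1 = p.y0 / ground_pixel - eps, p.y1 / ground_pixel - eps
            c0, c1 = p.x0 / ground_pixel - eps, p.x1 / ground_pixel - eps
            defs.append(
                PlotDefinition(
                    plot_id=p.plot_id,
                    genotype=p.genotype,
                    rows=p.rows,
                    block=p.block,
                    polygon=((r0, c0), (r0, c1), (r1, c1), (r1, c0)),
                )
            )
        return PlotMap(plots=defs)


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent stream ``stream`` of master ``seed`` (fixed offsets)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def generate_design(cfg: SceneConfig) -> TrialDesign:
    """Lay out the 256-plot split-plot trial and the eight field markers.

    Whole-plot strips (row counts 1-4, order randomized per block) run along
    the field length; each strip holds the 16 genotype plots, hybrids and
    inbreds randomized within separate sub-blocks.  The genotype sequence is
    cut into three sub-arrays (6/5/5 plots) mirroring the three separately
    imaged field rectangles; the markers sit at the left/right field edges
    at the four sub-array boundary lines, so every sub-array rectangle has
    four markers at its corners and the full field has eight.
    """
    rng = _rng(cfg.seed, 0)
    genotypes = tuple(sorted(GENOTYPE_GROUPS))
    hybrids = [g for g in genotypes if GENOTYPE_GROUPS[g] == "hybrid"]
    inbreds = [g for g in genotypes if GENOTYPE_GROUPS[g] != "hybrid"]

    # y slots for the 16 genotype plots
    y_slots = []
    y = FIELD_MARGIN_M
    for _ in range(N_GENOTYPES):
        y_slots.append((y, y + PLOT_LENGTH_M))
        y += PLOT_LENGTH_M + PLOT_ALLEY_M
    field_length = y - PLOT_ALLEY_M + FIELD_MARGIN_M
    # sub-array split of the genotype sequence: 6 / 5 / 5 plots
    sub_array_of_slot = [0] * 6 + [1] * 5 + [2] * 5

    plots: list[DesignPlot] = []
    x = FIELD_MARGIN_M
    for b in range(N_BLOCKS):
        block = f"b{b + 1}"
        strip_order = list(ROW_COUNTS)
        rng.shuffle(strip_order)
        for rows in strip_order:
            x0, x1 = x, x + rows * ROW_SPACING_M
            order = list(rng.permutation(hybrids)) + list(rng.permutation(inbreds))
            for slot, genotype in enumerate(order):
                y0, y1 = y_slots[slot]
                plots.append(
                    DesignPlot(
                        plot_id=f"{block}_r{rows}_{genotype}",
                        genotype=genotype,
                        rows=rows,
                        block=block,
                        sub_array=sub_array_of_slot[slot],
                        x0=x0,
                        x1=x1,
                        y0=y0,
                        y1=y1,
                    )
                )
            x = x1 + STRIP_ALLEY_M
        x += BLOCK_ALLEY_M - STRIP_ALLEY_M
    field_width = x - BLOCK_ALLEY_M + FIELD_MARGIN_M

    # sub-array boundary lines in y (start of field, two cuts, end of field)
    cut1 = (y_slots[5][1] + y_slots[6][0]) / 2.0
    cut2 = (y_slots[10][1] + y_slots[11][0]) / 2.0
    y_lines = [FIELD_MARGIN_M / 2.0, cut1, cut2, field_length - FIELD_MARGIN_M / 2.0]
    x_lines = [FIELD_MARGIN_M / 2.0, field_width - FIELD_MARGIN_M / 2.0]
    markers = [(xm, ym) for ym in y_lines for xm in x_lines]

    return TrialDesign(
        genotypes=genotypes,
        plots=plots,
        marker_positions_m=markers,
        field_width_m=field_width,
        field_length_m=field_length,
    )


# ------------------------------------------------------------------ traits
@dataclass(frozen=True)
class GenotypeProfile:
    """Seasonal trait curves for one genotype.

    Canopy cover rises logistically to a plateau (closed canopies near the
    onset of flowering for the hybrids) and declines linearly after the
    senescence onset; plant NDVI follows a similar rise/decline; the
    genotype's transpiration-cooling offset shifts dT.
    """

    genotype: str
    group: str
    cc_plateau: float
    cc_t50: float
    cc_slope: float
    senescence_onset: float
    cc_decline: float  # per degC day
    ndvi_peak: float
    ndvi_decline: float  # per degC day
    temp_offset: float  # degC, genotype dT effect

    def cc(self, tt: float) -> float:
        rise = self.cc_plateau / (1.0 + np.exp(-(tt - self.cc_t50) / self.cc_slope))
        if tt > self.senescence_onset:
            rise -= self.cc_decline * (tt - self.senescence_onset)
        return float(np.clip(rise, 0.02, 1.0))

    def ndvi_plant(self, tt: float) -> float:
        rise = self.ndvi_peak / (1.0 + np.exp(-(tt - self.cc_t50 * 0.8) / 80.0))
        if tt > self.senescence_onset:
            rise -= self.ndvi_decline * (tt - self.senescence_onset)
        return float(np.clip(rise, 0.12, 0.95))

    def dt(self, tt: float) -> float:
        """Canopy-minus-air temperature: transpiration cooling mid-season,
        slightly positive at late senescence."""
        base = float(
            np.interp(
                tt,
                [371.0, 612.0, 727.0, 793.0, 893.0, 940.0, 1275.0, 1366.0],
                [-0.5, -1.0, -1.8, -1.5, -1.0, -0.8, 0.5, 0.7],
            )
        )
        # cooling scales with how much canopy is transpiring
        return base + self.temp_offset * (1.0 if tt <= TT_SENESCENCE_ONSET else 0.3)


def default_profiles(cfg: SceneConfig) -> dict[str, GenotypeProfile]:
    """Genotype profiles drawn once from the seed (stream 1).

    Hybrids get larger, earlier-closing, greener canopies than the inbred
    lines; all spreads are artifact choices sized to give the repeatability
    levels typical of a well-run trial.
    """
    rng = _rng(cfg.seed, 1)
    profiles = {}
    for g in sorted(GENOTYPE_GROUPS):
        group = GENOTYPE_GROUPS[g]
        hybrid = group == "hybrid"
        plateau = np.clip(
            (0.98 if hybrid else 0.90) + rng.normal(0.0, 0.03), 0.6, 1.0
        )
        profiles[g] = GenotypeProfile(
            genotype=g,
            group=group,
            cc_plateau=float(plateau),
            cc_t50=float(rng.normal(290.0 if hybrid else 320.0, 15.0)),
            cc_slope=float(rng.uniform(50.0, 70.0)),
            senescence_onset=float(rng.normal(TT_SENESCENCE_ONSET, 30.0)),
            cc_decline=float(rng.uniform(4e-4, 9e-4)),
            ndvi_peak=float(
                np.clip((0.68 if hybrid else 0.62) + rng.normal(0.0, 0.03), 0.4, 0.9)
            ),
            ndvi_decline=float(rng.uniform(4e-4, 8e-4)),
            temp_offset=float(rng.normal(0.0, 0.3)),
        )
    return profiles


#: Plot-level residual standard deviations for a one-row plot; the residual
#: variance scales as 1/rows_per_plot (larger plots average more canopy),
#: which is the generator's mechanism for the plot-size repeatability effect.
RESIDUAL_SD_1ROW = {"cc": 0.05, "ndvi_plant": 0.03, "t_c": 0.6}


def simulate_traits(
    design: TrialDesign,
    profiles: dict[str, GenotypeProfile],
    campaigns=DEFAULT_CAMPAIGNS,
    seed: int | None = None,
    residual_sd=None,
) -> pd.DataFrame:
    """Ground-truth plot x campaign trait table (stream 2 of the seed).

    Columns: plot_id, genotype, rows, block, campaign, degree_days,
    true_cc, true_ndvi_plant, true_dt, true_t_c, air_temp.  Residual noise
    has standard deviation ``residual_sd[trait] / sqrt(rows)``.
    """
    missing = [g for g in {p.genotype for p in design.plots} if g not in profiles]
    if missing:
        raise ConfigurationError(f"profiles missing for genotypes {missing}")
    if seed is None:
        seed = 0
    if residual_sd is None:
        residual_sd = RESIDUAL_SD_1ROW
    rng = _rng(seed, 2)
    rows = []
    for camp in campaigns:
        for p in design.plots:
            prof = profiles[p.genotype]
            scale = 1.0 / np.sqrt(p.rows)
            cc = float(
                np.clip(prof.cc(camp.degree_days)
                        + rng.normal(0.0, residual_sd["cc"]) * scale, 0.01, 1.0)
            )
            ndvi = float(
                np.clip(
                    prof.ndvi_plant(camp.degree_days)
                    + rng.normal(0.0, residual_sd["ndvi_plant"]) * scale,
                    0.12,
                    0.95,
                )
            )
            dt = prof.dt(camp.degree_days) + rng.normal(
                0.0, residual_sd["t_c"]
            ) * scale
            t_c = camp.air_temp + dt if camp.air_temp is not None else np.nan
            rows.append(
                {
                    "plot_id": p.plot_id,
                    "genotype": p.genotype,
                    "rows": p.rows,
                    "block": p.block,
                    "campaign": camp.id,
                    "degree_days": camp.degree_days,
                    "true_cc": cc,
                    "true_ndvi_plant": ndvi,
                    "true_dt": float(dt),
                    "true_t_c": float(t_c),
                    "air_temp": camp.air_temp,
                }
            )
    return pd.DataFrame(rows)


def simulate_balanced_trait(
    n_genotypes: int,
    n_blocks: int,
    sigma2_gen: float,
    sigma2_eps: float,
    rng: np.random.Generator,
    mean: float = 0.0,
    block_effect_sd: float = 0.0,
) -> pd.DataFrame:
    """Balanced genotype x block table under the random-genotype model.

    y_gb = mean + block_b + G_g + e_gb with G ~ N(0, sigma2_gen) and
    e ~ N(0, sigma2_eps); the simulation oracle for the repeatability
    estimator's parameter-recovery checks.
    """
    g_eff = rng.normal(0.0, np.sqrt(sigma2_gen), n_genotypes)
    b_eff = rng.normal(0.0, block_effect_sd, n_blocks) if block_effect_sd else np.zeros(n_blocks)
    rows = []
    for gi in range(n_genotypes):
        for bi in range(n_blocks):
            rows.append(
                {
                    "genotype": f"g{gi:02d}",
                    "block": f"b{bi + 1}",
                    "rows_per_plot": 4,
                    "campaign": "sim",
                    "trait": "y",
                    "value": mean + g_eff[gi] + b_eff[bi]
                    + rng.normal(0.0, np.sqrt(sigma2_eps)),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------- rendering
@dataclass
class SceneBundle:
    """One campaign's rendered sensors plus every piece of ground truth."""

    campaign: Campaign
    images: dict  # sensor -> SensorImage (raw, distorted frames)
    true_H: dict  # sensor -> 3x3 (row, col) homography sensor -> AoI px
    aoi_shape: tuple[int, int]
    plot_map: PlotMap  # polygons on the AoI pixel grid
    marker_positions_aoi: np.ndarray  # (8, 2) (row, col) AoI px
    truth_labels: np.ndarray  # AoI plot-index raster (-1 background)
    truth_plant: np.ndarray  # AoI boolean plant raster (noise-free)
    truth_thermal: np.ndarray | None  # AoI noise-free plant/soil temperature
    truth_table: pd.DataFrame  # per-plot true traits for this campaign
    config: SceneConfig


def _wave_base(target: float, amp: float, band: float) -> float:
    """Base half-width so the clipped triangle wave has mean ``target``.

    The wavy canopy edge sits at ``clip(base + amp * tri, 0, band)`` with
    ``tri`` uniform on [-1, 1]; clipping at a band edge (bare or fully
    closed rows part of the time) would bias the mean, so the base is
    adjusted in closed form to keep the expected half-width — and with it
    the plant-area fraction — exactly at the target.
    """
    if amp <= 0:
        return target
    if target <= amp:  # clipped at 0 part of the time
        return 2.0 * np.sqrt(amp * target) - amp
    if target >= band - amp:  # clipped at the closed-canopy edge
        return amp + band - 2.0 * np.sqrt(amp * (band - target))
    return target


def _classify_ground(
    x: np.ndarray,
    y: np.ndarray,
    design: TrialDesign,
    cc_by_index: np.ndarray,
    cfg: SceneConfig,
):
    """Vectorized scene lookup at ground coordinates (metres).

    Returns (plot_index, is_plant, is_marker); plot_index is -1 off-plot.
    Exploits the rectangular layout: interval lookup in x for the strips and
    in y for the genotype slots; within a plot a pixel is plant when it lies
    within the wavy canopy strip around one of the plot's crop rows.
    """
    flat_x = x.ravel()
    flat_y = y.ravel()
    plot_idx = np.full(flat_x.shape, -1, dtype=np.int32)
    is_plant = np.zeros(flat_x.shape, dtype=bool)

    # group plots by strip (shared x interval)
    strips: dict[tuple[float, float], list[int]] = {}
    for i, p in enumerate(design.plots):
        strips.setdefault((p.x0, p.x1), []).append(i)

    # closed canopies overhang the plot edges: evaluate the canopy strip on
    # a slightly expanded box so the plant/soil transition of a closed plot
    # falls in the alley, outside the plot polygon
    ext = 2.0 * cfg.edge_wave_amplitude
    for (x0, x1), indices in strips.items():
        in_strip = (flat_x >= x0 - ext) & (flat_x < x1 + ext)
        if not in_strip.any():
            continue
        sel = np.flatnonzero(in_strip)
        xs = flat_x[sel]
        ys = flat_y[sel]
        for i in indices:
            p = design.plots[i]
            in_box = (ys >= p.y0 - ext) & (ys < p.y1 + ext)
            if not in_box.any():
                continue
            psel = sel[in_box]
            px = flat_x[psel]
            py = flat_y[psel]
            core = (px >= x0) & (px < x1) & (py >= p.y0) & (py < p.y1)
            plot_idx[psel[core]] = i
            cc = cc_by_index[i]
            # distance to the nearest crop-row centre
            rel = px - p.x0
            k = np.clip(np.floor(rel / ROW_SPACING_M), 0, p.rows - 1)
            dist = np.abs(rel - (k + 0.5) * ROW_SPACING_M)
            phase = (i * 0.381966)  # decorrelate plots (golden-ratio steps)
            target_half = cc * ROW_SPACING_M / 2.0
            amp = cfg.edge_wave_amplitude
            base = _wave_base(target_half, amp, ROW_SPACING_M / 2.0)
            # triangle wave: the edge position is uniformly dithered, so
            # pixel quantization of the canopy fraction averages out; the
            # wave is not clipped at the band edge (overhang into the alley)
            frac = (py / cfg.edge_wave_period + phase + 0.37 * k) % 1.0
            tri = 4.0 * np.abs(frac - 0.5) - 1.0
            half = np.clip(base + amp * tri, 0.0, None)
            # along the plot length the canopy ends with the sown rows, but
            # a closed canopy leans out: allow the same overhang in y
            y_ok = (py >= p.y0 - np.minimum(half, ext)) & (
                py < p.y1 + np.minimum(half, ext)
            )
            is_plant[psel] |= (dist < half) & y_ok
    is_marker = np.zeros(flat_x.shape, dtype=bool)
    for mx, my in design.marker_positions_m:
        is_marker |= (flat_x - mx) ** 2 + (flat_y - my) ** 2 <= MARKER_RADIUS_M**2
    plot_idx[is_marker] = -1
    is_plant &= ~is_marker
    return (
        plot_idx.reshape(x.shape),
        is_plant.reshape(x.shape),
        is_marker.reshape(x.shape),
    )


def _true_homography(
    sensor: str, cfg: SceneConfig, rng: np.random.Generator, pad_px: float = 12.0
) -> np.ndarray:
    """Random mild projective map sensor px -> AoI px ((row, col) convention).

    Base: uniform scale (ground-pixel ratio) plus a pad so the AoI pre-image
    stays inside the sensor frame; perturbation: small rotation, translation
    and perspective terms, scaled by ``cfg.homography_perturbation``.
    """
    k = cfg.ground_pixel[sensor] / cfg.ground_pixel["BNIR"]
    base = np.array([[k, 0.0, -k * pad_px], [0.0, k, -k * pad_px], [0.0, 0.0, 1.0]])
    amp = cfg.homography_perturbation
    theta = rng.normal(0.0, np.deg2rad(0.4)) * amp
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s, rng.normal(0.0, 3.0) * amp],
                    [s, c, rng.normal(0.0, 3.0) * amp],
                    [0.0, 0.0, 1.0]])
    persp = np.eye(3)
    persp[2, 0] = rng.normal(0.0, 1e-6) * amp
    persp[2, 1] = rng.normal(0.0, 1e-6) * amp
    H = persp @ rot @ base
    return H / H[2, 2]


def _sensor_frame_shape(H: np.ndarray, aoi_shape: tuple[int, int]) -> tuple[int, int]:
    """Smallest sensor frame containing the AoI pre-image plus a margin."""
    h, w = aoi_shape
    corners = np.array(
        [[0.0, 0.0, 1.0], [0.0, w - 1.0, 1.0], [h - 1.0, 0.0, 1.0],
         [h - 1.0, w - 1.0, 1.0]]
    )
    pre = corners @ np.linalg.inv(H).T
    pre = pre[:, :2] / pre[:, 2:3]
    return (int(np.ceil(pre[:, 0].max())) + 6, int(np.ceil(pre[:, 1].max())) + 6)


def _sensor_ground_coords(
    H: np.ndarray, shape: tuple[int, int], gp_aoi: float, subsample: int = 1
):
    """Ground (x, y) metres seen by each (sub)pixel of a sensor frame."""
    hh, ww = shape
    rr = (np.arange(hh * subsample) + 0.5) / subsample - 0.5
    cc = (np.arange(ww * subsample) + 0.5) / subsample - 0.5
    R, C = np.meshgrid(rr, cc, indexing="ij")
    denom = H[2, 0] * R + H[2, 1] * C + H[2, 2]
    aoi_r = (H[0, 0] * R + H[0, 1] * C + H[0, 2]) / denom
    aoi_c = (H[1, 0] * R + H[1, 1] * C + H[1, 2]) / denom
    return aoi_c * gp_aoi, aoi_r * gp_aoi  # x = col * gp, y = row * gp


def _ndvi_to_dn(ndvi, intensity):
    """Back-compute B/NIR digital numbers from target NDVI and B+NIR sum."""
    nir = intensity * (1.0 + ndvi) / 2.0 * MAX_DN
    b = intensity * (1.0 - ndvi) / 2.0 * MAX_DN
    return b, nir


def render_scene(
    design: TrialDesign,
    truth: pd.DataFrame,
    campaign: Campaign,
    cfg: SceneConfig,
    profiles: dict[str, GenotypeProfile] | None = None,
) -> SceneBundle:
    """Render the three sensors for one campaign.

    ``truth`` is the output of :func:`simulate_traits` (all campaigns; the
    relevant rows are selected here).  Each sensor sees the same ground
    scene through its own true homography and ground pixel; per-pixel noise
    uses stream ``100 + campaign index`` so campaigns are independent.
    """
    camp_truth = truth[truth["campaign"] == campaign.id]
    if camp_truth.empty:
        raise ConfigurationError(f"truth table has no rows for {campaign.id!r}")
    order = {p.plot_id: i for i, p in enumerate(design.plots)}
    cc_by_index = np.zeros(len(design.plots))
    ndvi_by_index = np.zeros(len(design.plots))
    dt_by_index = np.zeros(len(design.plots))
    for row in camp_truth.itertuples():
        i = order[row.plot_id]
        cc_by_index[i] = row.true_cc
        ndvi_by_index[i] = row.true_ndvi_plant
        dt_by_index[i] = row.true_dt

    for mx, my in design.marker_positions_m:
        if not (0 <= mx <= design.field_width_m and 0 <= my <= design.field_length_m):
            raise ConfigurationError(f"marker ({mx}, {my}) outside the field AoI")

    gp_aoi = cfg.ground_pixel["BNIR"]
    aoi_shape = (
        int(np.ceil(design.field_length_m / gp_aoi)),
        int(np.ceil(design.field_width_m / gp_aoi)),
    )
    stream = 100 + zlib.crc32(campaign.id.encode()) % 100_000
    rng = _rng(cfg.seed, stream)

    # --- AoI-frame noise-free truth rasters
    rr, cc_px = np.meshgrid(
        np.arange(aoi_shape[0], dtype=float), np.arange(aoi_shape[1], dtype=float),
        indexing="ij",
    )
    gx, gy = cc_px * gp_aoi, rr * gp_aoi
    truth_labels, truth_plant, _ = _classify_ground(gx, gy, design, cc_by_index, cfg)
    air = campaign.air_temp
    truth_thermal = None
    if "IR" in campaign.sensors and air is not None:
        truth_thermal = np.where(
            truth_plant,
            air + dt_by_index[np.clip(truth_labels, 0, None)],
            air + cfg.soil_temp_offset,
        )

    images: dict[str, SensorImage] = {}
    true_H: dict[str, np.ndarray] = {}
    for sensor in campaign.sensors:
        H = _true_homography(sensor, cfg, rng)
        true_H[sensor] = H
        shape = _sensor_frame_shape(H, aoi_shape)
        sub = cfg.ir_subsample if sensor == "IR" else 1
        sx, sy = _sensor_ground_coords(H, shape, gp_aoi, subsample=sub)
        labels, plant, marker = _classify_ground(sx, sy, design, cc_by_index, cfg)
        n = sx.shape

        if sensor == "IR":
            temp = np.where(
                plant,
                air + dt_by_index[np.clip(labels, 0, None)],
                air + cfg.soil_temp_offset,
            )
            temp = np.where(marker, air + cfg.marker_temp_offset, temp)
            temp = temp + rng.normal(0.0, cfg.thermal_noise_sd, n)
            if sub > 1:  # average sub-samples into the coarse thermal pixel
                temp = temp.reshape(shape[0], sub, shape[1], sub).mean(axis=(1, 3))
            images[sensor] = SensorImage(
                pixels=temp, channel_names=("T",), campaign_id=campaign.id
            )
            continue

        intensity = np.clip(
            rng.normal(cfg.illumination, cfg.illumination_sd, n), 0.05, 1.0
        )
        shade = (~plant) & (rng.random(n) < cfg.shade_fraction)
        intensity = np.where(shade, intensity * cfg.shade_factor, intensity)
        if sensor == "BNIR":
            ndvi = np.where(
                plant,
                rng.normal(ndvi_by_index[np.clip(labels, 0, None)], cfg.plant_ndvi_sd),
                rng.normal(cfg.soil_ndvi_mean, cfg.soil_ndvi_sd, n),
            )
            ndvi = np.clip(ndvi, -1.0, 1.0)
            b, nir = _ndvi_to_dn(ndvi, intensity)
            dark = 0.02 * MAX_DN
            b = np.where(marker, dark, b)
            nir = np.where(marker, dark, nir)
            images[sensor] = SensorImage(
                pixels=np.stack([b, nir], axis=-1),
                channel_names=("B", "NIR"),
                campaign_id=campaign.id,
            )
        else:  # RGB
            base = np.where(
                plant[..., None],
                np.array([0.20, 0.45, 0.15]),
                np.array([0.45, 0.38, 0.30]),
            )
            px = base * intensity[..., None] / 0.55
            px = px + rng.normal(0.0, 0.01, px.shape)
            px = np.where(marker[..., None], 0.03, px)
            images[sensor] = SensorImage(
                pixels=np.clip(px, 0.0, 1.0) * MAX_DN,
                channel_names=("R", "G", "B"),
                campaign_id=campaign.id,
            )

    marker_aoi = np.array(
        [(my / gp_aoi, mx / gp_aoi) for mx, my in design.marker_positions_m]
    )
    return SceneBundle(
        campaign=campaign,
        images=images,
        true_H=true_H,
        aoi_shape=aoi_shape,
        plot_map=design.plot_map_px(gp_aoi),
        marker_positions_aoi=marker_aoi,
        truth_labels=truth_labels,
        truth_plant=truth_plant,
        truth_thermal=truth_thermal,
        truth_table=camp_truth.reset_index(drop=True),
        config=cfg,
    )
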