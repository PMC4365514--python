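"""Pipeline orchestration: register -> segment -> extract -> stats.

Two layers:

* in-memory helpers (:func:`register_campaign`, :func:`run_campaign`) that
  take a rendered :class:`~aeropheno.scene.SceneBundle` (or raw images plus
  marker geometry) and run the stages without touching disk — the route the
  tests and the acceptance checks use;
* a file-based runner (:class:`RunConfig`, :func:`run_pipeline`,
  :func:`simulate_run`) that consumes a JSON/YAML run configuration, reads
  and writes TIFF/CSV/JSON artefacts and records a manifest with per-stage
  checksums so that re-runs on unchanged inputs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError
from .image import SensorImage
from .plot_traits import (
    PlotMap,
    extract_plot_traits,
    rasterize_plot_map,
    records_to_frame,
    seasonal_table,
)
from .registration import (
    MarkerObservation,
    detect_markers,
    fit_projective,
    match_to_reference,
    refine_by_ncc,
    upscale_thermal,
    warp_to_aoi,
)
from .segmentation import (
    SegmentationConfig,
    compute_ndvi,
    intensity_image,
    segment_ndvi,
)

log = logging.getLogger("aeropheno")

__all__ = [
    "RegisteredCampaign",
    "register_campaign",
    "run_campaign",
    "RunConfig",
    "validate_config",
    "run_pipeline",
    "simulate_run",
]


@dataclass
class RegisteredCampaign:
    """Co-registered AoI-frame stack for one campaign."""

    campaign_id: str
    warped: dict  # sensor -> SensorImage in the AoI frame
    models: dict  # sensor -> RegistrationModel
    markers: dict  # sensor -> list[MarkerObservation]


def _marker_radius_px(marker_radius_m: float, ground_pixel: float) -> float:
    return marker_radius_m / ground_pixel


def register_campaign(
    images: dict,
    marker_positions_aoi,
    aoi_shape: tuple[int, int],
    ground_pixel: dict,
    marker_radius_m: float = 0.35,
    reference_sensor: str = "BNIR",
    manual_markers: dict | None = None,
    ncc_window_factor: float = 2.0,
) -> RegisteredCampaign:
    """Detect markers, fit per-sensor homographies, warp into the AoI frame.

    The thermal sensor is first up-scaled to the optical resolution; marker
    detection runs on the blue channel for the optical sensors and with
    bright polarity on the thermal channel (the plates are warmer than
    canopy and soil).  Detections are paired with the known AoI marker
    positions by a scale-initialized optimal assignment.  When the
    reference (vegetation camera) and another optical sensor share the same
    ground pixel, marker positions in that sensor are additionally refined
    by normalized cross-correlation with the reference marker regions as
    templates.  ``manual_markers`` (sensor -> list of (row, col)) overrides
    automatic detection, mirroring the manual-adjustment path of field
    practice.
    """
    gp_ref = ground_pixel[reference_sensor]
    marker_positions_aoi = np.asarray(marker_positions_aoi, dtype=float)
    warped: dict[str, SensorImage] = {}
    models: dict = {}
    markers_out: dict = {}
    ref_markers: list[MarkerObservation] | None = None
    ref_img: SensorImage | None = None

    order = [reference_sensor] + [s for s in images if s != reference_sensor]
    for sensor in order:
        img = images[sensor]
        gp = ground_pixel[sensor]
        scale_to_ref = gp / gp_ref
        work_img = img
        coord_scale = (1.0, 1.0)
        if "T" in img.channel_names and scale_to_ref > 1.0 + 1e-9:
            target = (
                int(np.ceil(img.shape[0] * scale_to_ref)),
                int(np.ceil(img.shape[1] * scale_to_ref)),
            )
            work_img = upscale_thermal(img, target)
            coord_scale = (
                (target[0] - 1) / max(1, img.shape[0] - 1),
                (target[1] - 1) / max(1, img.shape[1] - 1),
            )
            scale_to_ref = 1.0  # now at reference resolution
        polarity = "bright" if "T" in img.channel_names else "dark"
        r_px = _marker_radius_px(marker_radius_m, gp if polarity == "dark" else gp_ref)
        if manual_markers and sensor in manual_markers:
            detections = [
                MarkerObservation(center=tuple(p), radius=r_px, score=None,
                                  source_channel="manual")
                for p in manual_markers[sensor]
            ]
        else:
            detections = detect_markers(
                work_img,
                polarity=polarity,
                expected_radius_px=(0.55 * r_px, 1.8 * r_px),
                max_markers=len(marker_positions_aoi),
            )
        if (
            ref_markers is not None
            and ref_img is not None
            and polarity == "dark"
            and abs(gp / gp_ref - 1.0) < 0.02
        ):
            # same scale as the reference: refine by NCC with the reference
            # marker regions as templates
            refined = []
            for det in detections:
                nearest = min(
                    ref_markers,
                    key=lambda m: (m.center[0] - det.center[0]) ** 2
                    + (m.center[1] - det.center[1]) ** 2,
                )
                window = max(3, int(round(ncc_window_factor * nearest.radius)))
                try:
                    refined.append(
                        refine_by_ncc(
                            ref_img, work_img, nearest, window,
                            search_center=det.center,
                        )
                    )
                except Exception:  # keep the centroid detection
                    refined.append(det)
            detections = refined
        markers_out[sensor] = detections
        pairs = match_to_reference(
            detections, marker_positions_aoi, init_scale=1.0 / scale_to_ref
            if scale_to_ref != 0 else 1.0,
        )
        model = fit_projective(pairs)
        log.info(
            "register %s/%s: %d markers, rmse %.3f px",
            img.campaign_id, sensor, len(pairs), model.rmse,
        )
        warped[sensor] = warp_to_aoi(work_img, model, aoi_shape)
        models[sensor] = model
        if sensor == reference_sensor:
            ref_markers, ref_img = detections, work_img
    return RegisteredCampaign(
        campaign_id=next(iter(images.values())).campaign_id,
        warped=warped,
        models=models,
        markers=markers_out,
    )


def run_campaign(
    bundle,
    seg_cfg: SegmentationConfig | None = None,
    plot_map: PlotMap | None = None,
):
    """Full in-memory pipeline on a rendered scene bundle.

    Returns ``(records, registered, ndvi, mask, labels)`` where records are
    the per-plot trait records of the campaign.
    """
    if seg_cfg is None:
        seg_cfg = SegmentationConfig(
            intensity_threshold=bundle.config.intensity_threshold
        )
    if plot_map is None:
        plot_map = bundle.plot_map
    reg = register_campaign(
        bundle.images,
        bundle.marker_positions_aoi,
        bundle.aoi_shape,
        bundle.config.ground_pixel,
    )
    bnir = reg.warped["BNIR"]
    ndvi = compute_ndvi(
        bnir.channel("B"), bnir.channel("NIR"), campaign_id=bundle.campaign.id
    )
    intensity = intensity_image(bnir.channel("B"), bnir.channel("NIR"))
    mask = segment_ndvi(ndvi, intensity, seg_cfg)
    labels = rasterize_plot_map(plot_map, bundle.aoi_shape)
    thermal = (
        reg.warped["IR"].channel("T") if "IR" in reg.warped else None
    )
    records = extract_plot_traits(
        ndvi.values,
        mask,
        labels,
        plot_map,
        campaign_id=bundle.campaign.id,
        thermal=thermal,
        air_temp=bundle.campaign.air_temp,
    )
    return records, reg, ndvi, mask, labels


# ----------------------------------------------------------- file pipeline
@dataclass
class CampaignConfig:
    id: str
    degree_days: float
    images: dict  # sensor -> path
    air_temp: float | None = None
    intensity_threshold: float | None = None
    date: str = ""


@dataclass
class RunConfig:
    """Validated run configuration (paths resolved relative to the file)."""

    campaigns: list[CampaignConfig]
    plot_map: str
    output_dir: str
    aoi_shape: tuple[int, int]
    marker_positions_aoi: list
    ground_pixel: dict
    seed: int = 0
    ndvi_threshold: float = 0.1
    segmentation_mode: str = "ndvi"
    marker_radius_m: float = 0.35
    base_dir: Path = field(default_factory=Path)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        campaigns = [CampaignConfig(**c) for c in raw.pop("campaigns")]
        return cls(campaigns=campaigns, base_dir=path.parent, **raw)

    def resolve(self, rel) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.base_dir / p


SENSOR_CHANNELS = {"BNIR": ("B", "NIR"), "RGB": ("R", "G", "B"), "IR": ("T",)}


def validate_config(cfg: RunConfig) -> list[str]:
    """Report-only validation: returns a list of problem descriptions."""
    issues: list[str] = []
    ids = [c.id for c in cfg.campaigns]
    if len(set(ids)) != len(ids):
        issues.append("duplicate campaign ids")
    if not -1.0 < cfg.ndvi_threshold < 1.0:
        issues.append(f"ndvi_threshold {cfg.ndvi_threshold} outside (-1, 1)")
    if not cfg.resolve(cfg.plot_map).exists():
        issues.append(f"plot map file missing: {cfg.plot_map}")
    for c in cfg.campaigns:
        for sensor, rel in c.images.items():
            if sensor not in SENSOR_CHANNELS:
                issues.append(f"{c.id}: unknown sensor {sensor!r}")
            elif not cfg.resolve(rel).exists():
                issues.append(f"{c.id}: image missing: {rel}")
        if "IR" in c.images and c.air_temp is None:
            issues.append(f"{c.id}: thermal present but no air_temp — dT uncomputable")
        if c.intensity_threshold is None:
            issues.append(f"{c.id}: no intensity_threshold for the shade filter")
        elif not 0.0 <= c.intensity_threshold <= 1.0:
            issues.append(f"{c.id}: intensity_threshold outside [0, 1]")
    return issues


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


STAGES = ("register", "segment", "extract", "stats")


def run_pipeline(cfg: RunConfig, stages=STAGES) -> dict:
    """Execute the requested stages for every campaign; return the manifest.

    Stage outputs land under ``cfg.output_dir``.  A failure in one campaign
    is logged and isolated; the remaining campaigns still run.  The manifest
    records the configuration hash, the software version and a checksum for
    every written file, so re-running on unchanged inputs reproduces
    identical checksums for the deterministic stages.
    """
    issues = validate_config(cfg)
    if issues:
        raise ConfigurationError("invalid run configuration:\n  " + "\n  ".join(issues))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages {sorted(unknown)}")
    out = cfg.resolve(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    plot_map = PlotMap.from_csv(cfg.resolve(cfg.plot_map))
    labels = rasterize_plot_map(plot_map, tuple(cfg.aoi_shape))
    manifest: dict = {
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(
                dataclasses.asdict(cfg), default=str, sort_keys=True
            ).encode()
        ).hexdigest(),
        "stages": list(stages),
        "outputs": {},
        "errors": {},
    }

    def record(stage: str, path: Path) -> None:
        manifest["outputs"].setdefault(stage, {})[path.name] = _sha256(path)

    all_records = []
    campaign_dd = {}
    for camp in cfg.campaigns:
        campaign_dd[camp.id] = camp.degree_days
        try:
            stack_path = out / f"{camp.id}_stack.tif"
            if "register" in stages:
                images = {
                    s: SensorImage.from_tiff(
                        cfg.resolve(p), SENSOR_CHANNELS[s], campaign_id=camp.id
                    )
                    for s, p in camp.images.items()
                }
                reg = register_campaign(
                    images,
                    cfg.marker_positions_aoi,
                    tuple(cfg.aoi_shape),
                    cfg.ground_pixel,
                    marker_radius_m=cfg.marker_radius_m,
                )
                stack_px = np.concatenate(
                    [reg.warped[s].pixels for s in sorted(reg.warped)], axis=-1
                )
                names = sum(
                    (list(SENSOR_CHANNELS[s]) for s in sorted(reg.warped)), []
                )
                SensorImage(stack_px, tuple(names), camp.id).to_tiff(stack_path)
                pd.DataFrame(
                    [
                        {
                            "campaign": camp.id,
                            "sensor": s,
                            "marker_id": i,
                            "row": m.center[0],
                            "col": m.center[1],
                            "score": m.score,
                        }
                        for s, ms in reg.markers.items()
                        for i, m in enumerate(ms)
                    ]
                ).to_csv(out / f"{camp.id}_markers.csv", index=False)
                with open(out / f"{camp.id}_models.json", "w") as fh:
                    json.dump(
                        {
                            s: {"H": m.H.tolist(), "rmse": m.rmse}
                            for s, m in reg.models.items()
                        },
                        fh,
                        indent=1,
                    )
                for name in ("_stack.tif", "_markers.csv", "_models.json"):
                    record("register", out / f"{camp.id}{name}")
            if "segment" in stages or "extract" in stages:
                if not stack_path.exists():
                    raise ConfigurationError(
                        f"{camp.id}: no registered stack at {stack_path}; "
                        f"run the register stage first"
                    )
                names = sum(
                    (list(SENSOR_CHANNELS[s]) for s in sorted(camp.images)), []
                )
                stack = SensorImage.from_tiff(stack_path, names, camp.id)
            if "segment" in stages:
                ndvi = compute_ndvi(stack.channel("B"), stack.channel("NIR"),
                                    campaign_id=camp.id)
                intensity = intensity_image(stack.channel("B"), stack.channel("NIR"))
                seg_cfg = SegmentationConfig(
                    ndvi_threshold=cfg.ndvi_threshold,
                    intensity_threshold=camp.intensity_threshold,
                )
                mask = segment_ndvi(ndvi, intensity, seg_cfg)
                import tifffile

                tifffile.imwrite(
                    out / f"{camp.id}_ndvi.tif", ndvi.values.astype(np.float32)
                )
                tifffile.imwrite(out / f"{camp.id}_mask.tif", mask.to_uint8())
                record("segment", out / f"{camp.id}_ndvi.tif")
                record("segment", out / f"{camp.id}_mask.tif")
            if "extract" in stages:
                mask_path = out / f"{camp.id}_mask.tif"
                ndvi_path = out / f"{camp.id}_ndvi.tif"
                if not (mask_path.exists() and ndvi_path.exists()):
                    raise ConfigurationError(
                        f"{camp.id}: no segmentation outputs; run segment first"
                    )
                import tifffile

                ndvi_vals = tifffile.imread(ndvi_path).astype(float)
                mask_u8 = tifffile.imread(mask_path)
                from .segmentation import SegmentationMask

                mask = SegmentationMask(
                    plant=mask_u8 == 255, valid=mask_u8 != 128
                )
                thermal = stack.channel("T") if "T" in stack.channel_names else None
                records = extract_plot_traits(
                    ndvi_vals,
                    mask,
                    labels,
                    plot_map,
                    campaign_id=camp.id,
                    thermal=thermal,
                    air_temp=camp.air_temp,
                )
                records_to_frame(records).to_csv(
                    out / f"{camp.id}_traits.csv", index=False
                )
                record("extract", out / f"{camp.id}_traits.csv")
                all_records.extend(records)
        except Exception as exc:  # isolate the failing campaign
            log.error("campaign %s failed: %s", camp.id, exc)
            manifest["errors"][camp.id] = str(exc)

    if "stats" in stages and all_records:
        table = seasonal_table(all_records, plot_map, campaign_dd)
        table.to_csv(out / "seasonal_table.csv", index=False)
        record("stats", out / "seasonal_table.csv")
        from .field_stats import repeatability_profile

        reps = []
        for trait in ("cc", "ndvi_plot", "ndvi_plant", "t_c"):
            prof = repeatability_profile(table, trait, campaign_dd)
            if not prof.empty:
                prof.insert(0, "trait", trait)
                reps.append(prof)
        if reps:
            pd.concat(reps, ignore_index=True).to_csv(
                out / "repeatability.csv", index=False
            )
            record("stats", out / "repeatability.csv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def simulate_run(
    seed: int,
    out_dir,
    campaigns=None,
    scene_config=None,
) -> Path:
    """Write a complete synthetic fixture set plus a ready-to-run config.

    Produces, under ``out_dir``: the design and ground-truth CSVs, the
    per-campaign sensor TIFFs, the true-homography JSON, the plot-map CSV
    and ``run.json`` — the canonical on-disk fixture for the file pipeline.
    Returns the path of the run configuration.
    """
    from .scene import (
        DEFAULT_CAMPAIGNS,
        SceneConfig,
        default_profiles,
        generate_design,
        render_scene,
        simulate_traits,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = scene_config or SceneConfig(seed=seed)
    if campaigns is None:
        campaigns = DEFAULT_CAMPAIGNS
    design = generate_design(cfg)
    profiles = default_profiles(cfg)
    truth = simulate_traits(design, profiles, campaigns, seed=cfg.seed)
    design.to_frame().to_csv(out / "design.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)

    camp_entries = []
    true_h: dict = {}
    marker_aoi = None
    aoi_shape = None
    plot_map_path = out / "plots.csv"
    for camp in campaigns:
        bundle = render_scene(design, truth, camp, cfg)
        if marker_aoi is None:
            marker_aoi = bundle.marker_positions_aoi
            aoi_shape = bundle.aoi_shape
            bundle.plot_map.to_csv(plot_map_path)
        entry_images = {}
        for sensor, img in bundle.images.items():
            rel = f"{camp.id}_{sensor.lower()}.tif"
            img.to_tiff(out / rel)
            entry_images[sensor] = rel
        true_h[camp.id] = {s: H.tolist() for s, H in bundle.true_H.items()}
        camp_entries.append(
            {
                "id": camp.id,
                "degree_days": camp.degree_days,
                "date": camp.date,
                "air_temp": camp.air_temp,
                "intensity_threshold": cfg.intensity_threshold,
                "images": entry_images,
            }
        )
    with open(out / "true_homographies.json", "w") as fh:
        json.dump(true_h, fh, indent=1)
    run_cfg = {
        "seed": seed,
        "output_dir": "out",
        "plot_map": "plots.csv",
        "aoi_shape": list(aoi_shape),
        "marker_positions_aoi": np.asarray(marker_aoi).tolist(),
        "ground_pixel": cfg.ground_pixel,
        "ndvi_threshold": 0.1,
        "campaigns": camp_entries,
    }
    cfg_path = out / "run.json"
    with open(cfg_path, "w") as fh:
        json.dump(run_cfg, fh, indent=1)
    with open(out / "manifest_fixture.json", "w") as fh:
        json.dump(
            {
                "seed": seed,
                "files": {
                    p.name: _sha256(p)
                    for p in sorted(out.iterdir())
                    if p.is_file() and p.name != "manifest_fixture.json"
                },
            },
            fh,
            indent=1,
        )
    return cfg_path
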