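"""Shared fixtures: one coarse synthetic trial reused across the suite.

The scene is sampled at a 0.075 m optical / 0.3 m thermal ground pixel — a
divisor of the 0.75 m row spacing, so plot boundaries align with the pixel
grid and rasterization bias does not contaminate pipeline-accuracy checks.
"""

import numpy as np
import pytest

from aeropheno.scene import (
    DEFAULT_CAMPAIGNS,
    SceneConfig,
    default_profiles,
    generate_design,
    render_scene,
    simulate_traits,
)

COARSE_GP = {"BNIR": 0.075, "RGB": 0.0825, "IR": 0.3}
FINE_GP = {"BNIR": 0.025, "RGB": 0.0275, "IR": 0.1}  # native pixels, 290 m


@pytest.fixture(scope="session")
def coarse_cfg():
    return SceneConfig(seed=11, ground_pixel=dict(COARSE_GP))


@pytest.fixture(scope="session")
def design(coarse_cfg):
    return generate_design(coarse_cfg)


@pytest.fixture(scope="session")
def profiles(coarse_cfg):
    return default_profiles(coarse_cfg)


@pytest.fixture(scope="session")
def truth(design, profiles, coarse_cfg):
    return simulate_traits(design, profiles, DEFAULT_CAMPAIGNS, seed=coarse_cfg.seed)


@pytest.fixture(scope="session")
def bundle_c4(design, truth, coarse_cfg):
    """Mid-season campaign (727 degC days) with all three sensors."""
    return render_scene(design, truth, DEFAULT_CAMPAIGNS[3], coarse_cfg)


@pytest.fixture(scope="session")
def pipeline_c4(bundle_c4):
    """Full in-memory pipeline run on the shared campaign."""
    from aeropheno.pipeline import run_campaign

    records, reg, ndvi, mask, labels = run_campaign(bundle_c4)
    return {
        "records": records,
        "reg": reg,
        "ndvi": ndvi,
        "mask": mask,
        "labels": labels,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
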