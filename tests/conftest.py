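"""Shared fixtures: small, fast synthetic scenes.

The default simulator scenario (768 px whole-section scan) is what the
acceptance suite exercises; unit tests mostly run on the smaller scenes
defined here to stay fast.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True)
settings.load_profile("stable")

from eduquant.synthetic import (  # noqa: E402
    NoiseModel,
    RegionGeometry,
    SimulationScenario,
    render_section,
    sample_cells,
    sample_region_mask,
)


@pytest.fixture()
def small_scenario() -> SimulationScenario:
    """A 256 px scene with a mid-sized region and clean contrast."""
    return SimulationScenario(
        image_height_px=256,
        image_width_px=256,
        pixel_size_um=4.0,
        region_geometry=RegionGeometry(
            n_blobs=2, blob_radius_range_px=(50.0, 80.0), smoothing_sigma_px=10.0
        ),
        lambda_edu_in=400.0,
        lambda_edu_out=5.0,
        lambda_prot_in=400.0,
        lambda_prot_out=10.0,
        seed=7,
    )


@pytest.fixture()
def rendered_section(small_scenario):
    """One rendered section plus its ground-truth mask and points."""
    rng = np.random.default_rng(small_scenario.seed)
    mask = sample_region_mask(small_scenario, rng)
    edu = sample_cells(
        mask, small_scenario.lambda_edu_in, small_scenario.lambda_edu_out,
        small_scenario.pixel_size_um, rng,
    )
    prot = sample_cells(
        mask, small_scenario.lambda_prot_in, small_scenario.lambda_prot_out,
        small_scenario.pixel_size_um, rng,
    )
    section = render_section(mask, edu, prot, small_scenario, rng, sample_id="unit")
    return section, mask, edu, prot


@pytest.fixture()
def noiseless_scenario() -> SimulationScenario:
    return SimulationScenario(
        image_height_px=128,
        image_width_px=128,
        region_geometry=RegionGeometry(
            n_blobs=1, blob_radius_range_px=(40.0, 40.0), smoothing_sigma_px=5.0
        ),
        noise_model=NoiseModel(gaussian_sigma=0.0, poisson=False),
        seed=3,
    )
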