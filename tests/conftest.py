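"""Shared fixtures: small, deterministic synthetic scenes.

Everything is generated at test time; image sizes are kept small enough
for a desk-scale run while preserving the geometry the pipeline needs
(peak plus a disjoint subpeak window).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import dabquant as dq


@pytest.fixture(scope="session")
def unit_params() -> dq.SimulationParams:
    """Small unclustered scene at 1 µm/px for detection-level tests."""
    return dq.SimulationParams(
        image_size_px=(960, 960), mpp=1.0, patchiness=None, seed=0
    )


@pytest.fixture(scope="session")
def rendered_scene(unit_params):
    """One default-condition render: points, image, ground truth."""
    pts = dq.sample_cell_positions(unit_params, 12345, rates=(0.6, 600.0))
    img, gt = dq.render_image(
        pts, unit_params, noise_rng=np.random.default_rng(12346)
    )
    return pts, img, gt


@pytest.fixture()
def noiseless_params(unit_params) -> dq.SimulationParams:
    return dataclasses.replace(
        unit_params,
        stain=dataclasses.replace(unit_params.stain, noise_od_sd=0.0),
    )


@pytest.fixture(scope="session")
def smoke_config() -> dq.PipelineConfig:
    """Tiny three-group cohort with a 0.01 mm² window for pipeline tests."""
    cfg = dq.PipelineConfig()
    cfg.simulation = dataclasses.replace(
        cfg.simulation,
        groups=[
            dq.GroupSpec("HV", 3, 0.20, 0.10, 600.0, 150.0),
            dq.GroupSpec("GERD", 3, 0.50, 0.15, 600.0, 150.0),
            dq.GroupSpec("EoE", 3, 0.70, 0.10, 600.0, 150.0),
        ],
        image_size_px=(448, 448),
        mpp=1.0,
        roi_area_mm2=0.01,
        seed=99,
    )
    cfg.roi_area_mm2 = 0.01
    cfg.validate()
    return cfg
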