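"""Parameter containers and YAML configuration.

All tunable quantities of the pipeline live here: the synthetic-cohort
generator parameters, the stain model, cell-detection parameters and the
ROI geometry. Every field is addressable from a YAML file, so a run is
fully described by (config, master seed).

Units: lengths in µm, areas in µm² (ROI area in mm²), densities per mm²,
optical densities are dimensionless (base-10 absorbance).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

#: Side of the scoring square, derived from its area: sqrt(0.1 mm²) ≈ 316.23 µm.
DEFAULT_ROI_AREA_MM2 = 0.1

#: Unit-norm H-DAB absorbance vectors (RGB components). The residual is the
#: nonnegative complement channel (see stains.default_stain_vectors).
HEMATOXYLIN_OD_RGB = (0.650, 0.704, 0.286)
DAB_OD_RGB = (0.269, 0.568, 0.778)


class ConfigError(ValueError):
    """A parameter failed validation; the message names the parameter."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class GroupSpec:
    """One subject group of the simulated cohort.

    ``positive_fraction_*`` describe the across-subject distribution of the
    true fraction of immunopositive cells (Beta, moment-matched);
    ``cell_density_*`` the across-subject total cell density per mm²
    (Gamma, moment-matched).
    """

    label: str
    n_subjects: int
    positive_fraction_mean: float
    positive_fraction_sd: float
    cell_density_mean: float
    cell_density_sd: float

    def validate(self) -> None:
        _require(self.n_subjects >= 1, f"group {self.label}: n_subjects must be >= 1")
        _require(
            0.0 <= self.positive_fraction_mean <= 1.0,
            f"group {self.label}: positive_fraction_mean must lie in [0, 1]",
        )
        _require(
            self.positive_fraction_sd >= 0.0,
            f"group {self.label}: positive_fraction_sd must be >= 0",
        )
        _require(
            self.cell_density_mean >= 0.0 and self.cell_density_sd >= 0.0,
            f"group {self.label}: cell densities must be >= 0",
        )


@dataclass
class PatchinessParams:
    """Thomas (Neyman–Scott) cluster process for immunopositive cells.

    Parents form a homogeneous Poisson process of ``parent_intensity`` per
    mm²; offspring scatter isotropically around their parent with Gaussian
    sd ``cluster_radius_um``. The mean offspring count per parent is derived
    from the subject's positive-cell intensity, so the configured total
    intensity is honoured regardless of the parent intensity.
    """

    parent_intensity_per_mm2: float = 2.0
    cluster_radius_um: float = 60.0

    def validate(self) -> None:
        _require(self.parent_intensity_per_mm2 > 0, "parent_intensity_per_mm2 must be > 0")
        _require(self.cluster_radius_um > 0, "cluster_radius_um must be > 0")


@dataclass
class StainParams:
    """Forward stain model for rendering: per-cell absorbance amplitudes."""

    hematoxylin_od: float = 0.7
    dab_od_positive: float = 0.6
    dab_od_negative: float = 0.05
    noise_od_sd: float = 0.02

    def validate(self) -> None:
        _require(self.hematoxylin_od >= 0, "hematoxylin_od must be >= 0")
        _require(self.dab_od_positive >= 0, "dab_od_positive must be >= 0")
        _require(self.dab_od_negative >= 0, "dab_od_negative must be >= 0")
        _require(self.noise_od_sd >= 0, "noise_od_sd must be >= 0")


@dataclass
class SimulationParams:
    """Everything the synthetic-cohort generator needs.

    The default cohort mirrors a three-group esophagitis study: healthy
    volunteers, reflux patients and eosinophilic-esophagitis patients, with
    group positive-fraction means/SDs of 0.38/0.31, 0.59/0.28 and 0.63/0.29.
    ``patchiness=None`` selects the unclustered limit of the positive-cell
    process (homogeneous Poisson), used when an unbiased spatial layout is
    wanted.
    """

    groups: list[GroupSpec] = field(
        default_factory=lambda: [
            GroupSpec("HV", 15, 0.38, 0.31, 600.0, 200.0),
            GroupSpec("GERD", 21, 0.59, 0.28, 600.0, 200.0),
            GroupSpec("EoE", 20, 0.63, 0.29, 600.0, 200.0),
        ]
    )
    patchiness: Optional[PatchinessParams] = field(default_factory=PatchinessParams)
    image_size_px: tuple[int, int] = (2048, 2048)  # (width, height)
    mpp: float = 0.5
    stain: StainParams = field(default_factory=StainParams)
    nucleus_radius_mean_um: float = 3.5
    nucleus_radius_sd_um: float = 0.5
    roi_area_mm2: float = DEFAULT_ROI_AREA_MM2
    seed: int = 0

    @property
    def image_area_mm2(self) -> float:
        w, h = self.image_size_px
        return w * h * self.mpp**2 / 1e6

    def validate(self) -> None:
        _require(len(self.groups) >= 1, "at least one group is required")
        for g in self.groups:
            g.validate()
        if self.patchiness is not None:
            self.patchiness.validate()
        self.stain.validate()
        _require(self.mpp > 0, "mpp must be > 0")
        w, h = self.image_size_px
        _require(w >= 1 and h >= 1, "image_size_px must be positive")
        _require(
            self.nucleus_radius_mean_um > 0 and self.nucleus_radius_sd_um >= 0,
            "nucleus radius mean must be > 0 and sd >= 0",
        )
        _require(self.roi_area_mm2 > 0, "roi_area_mm2 must be > 0")
        # peak and a disjoint subpeak window must both fit in the image
        _require(
            self.image_area_mm2 >= 4.0 * self.roi_area_mm2,
            f"image area {self.image_area_mm2:.3f} mm² is below 4x the ROI "
            f"area ({4 * self.roi_area_mm2:.3f} mm²); enlarge image_size_px or mpp",
        )


@dataclass
class DetectionParams:
    """Cell detection and DAB-positivity parameters.

    ``dab_positivity_threshold`` is the "arbitrary limit" of the scoring
    protocol: a cell is positive iff its mean DAB optical density strictly
    exceeds it.
    """

    smoothing_sigma_um: float = 1.5
    nuclear_od_threshold: float = 0.1
    min_cell_area_um2: float = 16.0
    max_cell_area_um2: float = 250.0
    dab_positivity_threshold: float = 0.2
    seed_separation_um: float = 3.5

    def validate(self) -> None:
        _require(self.smoothing_sigma_um >= 0, "smoothing_sigma_um must be >= 0")
        _require(self.nuclear_od_threshold >= 0, "nuclear_od_threshold must be >= 0")
        _require(
            0 < self.min_cell_area_um2 < self.max_cell_area_um2,
            "require 0 < min_cell_area_um2 < max_cell_area_um2",
        )
        _require(self.dab_positivity_threshold >= 0, "dab_positivity_threshold must be >= 0")
        _require(self.seed_separation_um > 0, "seed_separation_um must be > 0")


@dataclass
class PipelineConfig:
    """Top-level run configuration: simulation + detection + analysis."""

    simulation: SimulationParams = field(default_factory=SimulationParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    roi_area_mm2: float = DEFAULT_ROI_AREA_MM2
    roi_stride_fraction: float = 0.1  # grid stride as a fraction of the ROI side
    alpha: float = 0.05
    stain_vectors: Optional[list[list[float]]] = None  # 3x3 column matrix override

    def validate(self) -> None:
        self.simulation.validate()
        self.detection.validate()
        _require(self.roi_area_mm2 > 0, "roi_area_mm2 must be > 0")
        _require(0 < self.roi_stride_fraction <= 1.0, "roi_stride_fraction must be in (0, 1]")
        _require(0 < self.alpha < 1, "alpha must be in (0, 1)")
        if self.stain_vectors is not None:
            arr = np.asarray(self.stain_vectors, dtype=float)
            _require(arr.shape == (3, 3), "stain_vectors must be a 3x3 matrix")


# ---------------------------------------------------------------------------
# YAML round-trip


def _params_from_dict(d: dict) -> PipelineConfig:
    sim_d = dict(d.get("simulation", {}))
    if "groups" in sim_d:
        sim_d["groups"] = [GroupSpec(**g) for g in sim_d["groups"]]
    if "patchiness" in sim_d:
        p = sim_d["patchiness"]
        sim_d["patchiness"] = None if p is None else PatchinessParams(**p)
    if "stain" in sim_d:
        sim_d["stain"] = StainParams(**sim_d["stain"])
    if "image_size_px" in sim_d:
        sim_d["image_size_px"] = tuple(sim_d["image_size_px"])
    det_d = dict(d.get("detection", {}))
    top = {k: v for k, v in d.items() if k not in ("simulation", "detection")}
    cfg = PipelineConfig(
        simulation=SimulationParams(**sim_d),
        detection=DetectionParams(**det_d),
        **top,
    )
    cfg.validate()
    return cfg


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Read a pipeline configuration from YAML and validate it."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _params_from_dict(data)


def save_config(cfg: PipelineConfig, path: Union[str, Path]) -> None:
    """Write a configuration back to YAML (lossless for load_config)."""
    d = asdict(cfg)
    d["simulation"]["image_size_px"] = list(cfg.simulation.image_size_px)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
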