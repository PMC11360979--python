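"""End-to-end orchestration: simulate → separate → detect → score → compare.

Every stage is reusable on its own; run_pipeline wires them for a full
blinded analysis of a (synthetic or externally supplied) cohort and writes
all intermediate tables plus a run log to an output directory. All
randomness derives from the configured master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .detect import CellObject, cells_to_dataframe, detect_cells
from .io import BlindingKey, blind_manifest, read_image, read_manifest
from .roi import ROIGeometry, SubjectResult, subject_result, subject_results_to_dataframe
from .simulate import simulate_cohort
from .stains import StainVectors, deconvolve, rgb_to_od, stain_vectors_from_columns
from .stats import build_comparison_table

logger = logging.getLogger(__name__)


def _stains(cfg: PipelineConfig) -> Optional[StainVectors]:
    if cfg.stain_vectors is None:
        return None
    return stain_vectors_from_columns(np.asarray(cfg.stain_vectors, dtype=float))


def analyze_image(
    image: np.ndarray,
    mpp: float,
    cfg: PipelineConfig,
    subject_id: str = "",
    group: Optional[str] = None,
) -> tuple[list[CellObject], SubjectResult, float]:
    """One section through the measurement chain.

    Returns (cells, peak/subpeak result, clamped-negative pixel fraction).
    """
    od = rgb_to_od(image, mpp=mpp)
    conc = deconvolve(od, _stains(cfg))
    cells = detect_cells(conc.hematoxylin, conc.dab, cfg.detection, mpp)
    h, w = image.shape[:2]
    geometry = ROIGeometry(
        roi_area_mm2=cfg.roi_area_mm2,
        stride_um=cfg.roi_stride_fraction * (cfg.roi_area_mm2**0.5 * 1000.0),
    )
    res = subject_result(subject_id, cells, (w * mpp, h * mpp), geometry, group=group)
    return cells, res, conc.clamped_fraction


@dataclass
class PipelineOutput:
    """Everything run_pipeline computed, plus where it was written."""

    manifest: pd.DataFrame
    blinded_manifest: pd.DataFrame
    key: BlindingKey
    roi_table: pd.DataFrame
    summaries: pd.DataFrame
    comparisons: pd.DataFrame
    out_dir: Path


def run_pipeline(
    cfg: PipelineConfig,
    out_dir: Union[str, Path],
    manifest: Optional[pd.DataFrame] = None,
    mpp: Optional[float] = None,
) -> PipelineOutput:
    """Run the full blinded analysis and write all outputs under out_dir.

    Without a ``manifest`` a synthetic cohort is simulated from
    ``cfg.simulation`` into ``out_dir/images``. Per-image cell tables, the
    per-subject ROI table, group summaries, pairwise comparisons and a run
    log (parameters, seeds, clamp/drop accounting) are written as CSV/JSON.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if mpp is None:
        mpp = cfg.simulation.mpp

    if manifest is None:
        cohort = simulate_cohort(cfg.simulation, out / "images")
        manifest = cohort.manifest
    else:
        manifest = manifest.copy()
        if "group" not in manifest.columns:
            raise ValueError("manifest must carry a group column for the statistics stage")

    blinded, key = blind_manifest(manifest, seed=cfg.simulation.seed)
    blinded.to_csv(out / "manifest_blinded.csv", index=False)
    key.save(out / "blinding_key.csv")

    # image analysis in blinded presentation order, labels withheld
    cells_dir = out / "cells"
    cells_dir.mkdir(exist_ok=True)
    path_by_blinded = dict(zip(blinded["blinded_id"], blinded["image_path"]))
    mpp_by_blinded = (
        dict(zip(blinded["blinded_id"], blinded["mpp"])) if "mpp" in blinded.columns else {}
    )
    blind_results: list[SubjectResult] = []
    clamp_fracs: dict[str, float] = {}
    for bid in blinded["blinded_id"]:
        img = read_image(path_by_blinded[bid])
        img_mpp = float(mpp_by_blinded.get(bid, mpp))
        cells, res, clamp = analyze_image(img, img_mpp, cfg, subject_id=bid)
        cells_to_dataframe(cells).to_csv(cells_dir / f"{bid}_cells.csv", index=False)
        clamp_fracs[bid] = clamp
        blind_results.append(res)

    # unblind: reattach subject ids and groups, then aggregate
    lookup = key.table.set_index("blinded_id")
    results = [
        SubjectResult(
            subject_id=str(lookup.loc[r.subject_id, "subject_id"]),
            peak=r.peak,
            subpeak=r.subpeak,
            group=str(lookup.loc[r.subject_id, "group"]),
        )
        for r in blind_results
    ]
    roi_table = subject_results_to_dataframe(results)
    roi_table.to_csv(out / "roi_table.csv", index=False)
    summaries, comparisons = build_comparison_table(results, alpha=cfg.alpha)
    summaries.to_csv(out / "group_summaries.csv", index=False)
    comparisons.to_csv(out / "comparisons.csv", index=False)
    with open(out / "tables.json", "w") as fh:
        json.dump(
            {
                "summaries": summaries.to_dict(orient="records"),
                "comparisons": comparisons.to_dict(orient="records"),
            },
            fh,
            indent=1,
        )

    import dataclasses

    log = {
        "master_seed": cfg.simulation.seed,
        "mpp": mpp,
        "n_subjects": len(manifest),
        "detection": dataclasses.asdict(cfg.detection),
        "roi_area_mm2": cfg.roi_area_mm2,
        "alpha": cfg.alpha,
        "clamped_negative_fraction": clamp_fracs,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1)
    logger.info("pipeline complete: %d subjects -> %s", len(manifest), out)

    return PipelineOutput(
        manifest=manifest,
        blinded_manifest=blinded,
        key=key,
        roi_table=roi_table,
        summaries=summaries,
        comparisons=comparisons,
        out_dir=out,
    )
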