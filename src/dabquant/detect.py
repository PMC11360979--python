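"""Nucleus detection and DAB-positivity classification.

Pipeline: Gaussian-smooth the hematoxylin+DAB summed OD (strong DAB can
mask hematoxylin, and such cells still count), threshold at the nuclear OD
threshold, fill holes, drop specks below the minimum area, split merged
blobs by watershed on the (lightly smoothed) distance transform with
distance peaks as seeds, then score each object's mean DAB OD on the
*unsmoothed* DAB map. A cell is positive iff its mean DAB OD strictly
exceeds the positivity threshold τ — the protocol's "arbitrary limit".
Objects touching the border are retained; window membership is decided
later from centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import blob_log
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .config import DetectionParams


@dataclass(frozen=True)
class CellObject:
    """One detected cell (centroid in µm from the image origin)."""

    x_um: float
    y_um: float
    area_um2: float
    dab_od: float
    hema_od: float
    positive: bool


def detect_cells(
    hema_od: np.ndarray,
    dab_od: np.ndarray,
    params: DetectionParams,
    mpp: float,
) -> list[CellObject]:
    """Detect cells on deconvolved OD maps and flag DAB positivity.

    ``hema_od`` and ``dab_od`` are same-shape 2-D concentration maps from
    stain separation; ``mpp`` is the µm/pixel calibration. Returns one
    CellObject per segmented nucleus with area inside the configured
    [min, max] µm² band (after watershed splitting).
    """
    params.validate()
    if mpp <= 0:
        raise ValueError("mpp must be > 0")
    hema_od = np.asarray(hema_od, dtype=float)
    dab_od = np.asarray(dab_od, dtype=float)
    if hema_od.shape != dab_od.shape or hema_od.ndim != 2:
        raise ValueError("hematoxylin and DAB maps must be 2-D and share a shape")

    detection = hema_od + dab_od
    sigma_px = params.smoothing_sigma_um / mpp
    if sigma_px > 0:
        detection = ndi.gaussian_filter(detection, sigma_px)
    mask = detection > params.nuclear_od_threshold
    if not mask.any():
        return []
    mask = ndi.binary_fill_holes(mask)

    px_area = mpp * mpp
    min_px = max(1, int(round(params.min_cell_area_um2 / px_area)))
    labels, _ = ndi.label(mask)
    sizes = np.bincount(labels.ravel())
    too_small = sizes < min_px
    too_small[0] = False
    mask[too_small[labels]] = False
    if not mask.any():
        return []

    # split merged nuclei by watershed. Seeds are scale-normalized
    # Laplacian-of-Gaussian peaks on the unsmoothed detection channel — a
    # matched filter for disc-shaped nuclei that keeps one peak per nucleus
    # even when thresholding has merged neighbours into one blob. The scale
    # range brackets the expected nucleus radius (seed_separation_um).
    blobs, _ = ndi.label(mask)
    r_px = params.seed_separation_um / mpp
    seeds = blob_log(
        hema_od + dab_od,
        min_sigma=max(0.7, 0.45 * r_px / np.sqrt(2.0)),
        max_sigma=1.4 * r_px / np.sqrt(2.0),
        num_sigma=5,
        threshold=0.5 * params.nuclear_od_threshold,
    )
    coords = seeds[:, :2].astype(int) if len(seeds) else np.empty((0, 2), dtype=int)
    inside = mask[coords[:, 0], coords[:, 1]] if len(coords) else np.zeros(0, bool)
    coords = coords[inside]
    # every blob keeps at least one seed: fall back to its innermost pixel
    distance = ndi.distance_transform_edt(mask)
    seeded = np.zeros(blobs.max() + 1, dtype=bool)
    if len(coords):
        seeded[blobs[coords[:, 0], coords[:, 1]]] = True
    missing = np.nonzero(~seeded[1:])[0] + 1
    extra = []
    for lab in missing:
        idx = np.unravel_index(np.argmax(np.where(blobs == lab, distance, -1.0)), mask.shape)
        extra.append(idx)
    if extra:
        coords = np.vstack([coords, np.asarray(extra, dtype=int)])
    if len(coords) == 0:
        return []
    markers = np.zeros_like(blobs)
    markers[coords[:, 0], coords[:, 1]] = np.arange(1, len(coords) + 1)
    segmented = watershed(-ndi.gaussian_filter(distance, 0.7), markers, mask=mask)
    n_seeds_per_blob = np.bincount(blobs[coords[:, 0], coords[:, 1]], minlength=blobs.max() + 1)
    seed_of_marker = {i + 1: tuple(c) for i, c in enumerate(coords)}

    # intensity is scored on the segment core: thresholding the smoothed
    # image adds a low-OD halo around each nucleus that would dilute the
    # mean DAB towards the positivity threshold, so the halo (about one
    # smoothing sigma wide) is eroded away before averaging
    halo_px = max(1, int(round(1.1 * sigma_px))) if sigma_px > 0 else 0
    core = ndi.binary_erosion(mask, iterations=halo_px) if halo_px else mask

    cells: list[CellObject] = []
    for prop in regionprops(segmented, intensity_image=dab_od):
        area_um2 = prop.area * px_area
        if not (params.min_cell_area_um2 <= area_um2 <= params.max_cell_area_um2):
            continue
        # isolated nuclei: sub-pixel mask centroid. Split nuclei: the mask
        # halo of a merged blob biases piece centroids, so the matched-filter
        # seed is the better centre estimate.
        seed = seed_of_marker[prop.label]
        if n_seeds_per_blob[blobs[seed]] > 1:
            cy, cx = float(seed[0]), float(seed[1])
        else:
            cy, cx = prop.centroid
        sl = prop.slice
        region = segmented[sl] == prop.label
        core_region = region & core[sl]
        scored = core_region if core_region.any() else region
        mean_dab = float(dab_od[sl][scored].mean())
        mean_hema = float(hema_od[sl][scored].mean())
        cells.append(
            CellObject(
                x_um=(cx + 0.5) * mpp,
                y_um=(cy + 0.5) * mpp,
                area_um2=area_um2,
                dab_od=mean_dab,
                hema_od=mean_hema,
                positive=mean_dab > params.dab_positivity_threshold,
            )
        )
    return cells


def classify_positive(cells: list[CellObject], tau: float) -> list[CellObject]:
    """Re-flag positivity at threshold τ: positive ⇔ mean DAB OD > τ.

    Strict inequality; idempotent; no other inputs enter the rule.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    return [replace(c, positive=c.dab_od > tau) for c in cells]


def cells_to_dataframe(cells: list[CellObject]) -> pd.DataFrame:
    """Cell table with columns x_um, y_um, area_um2, dab_od, hema_od, positive."""
    return pd.DataFrame(
        [
            {
                "x_um": c.x_um,
                "y_um": c.y_um,
                "area_um2": c.area_um2,
                "dab_od": c.dab_od,
                "hema_od": c.hema_od,
                "positive": c.positive,
            }
            for c in cells
        ],
        columns=["x_um", "y_um", "area_um2", "dab_od", "hema_od", "positive"],
    )


def cells_from_dataframe(df: pd.DataFrame) -> list[CellObject]:
    """Inverse of cells_to_dataframe."""
    return [
        CellObject(
            x_um=float(r.x_um),
            y_um=float(r.y_um),
            area_um2=float(r.area_um2),
            dab_od=float(r.dab_od),
            hema_od=float(r.hema_od),
            positive=bool(r.positive),
        )
        for r in df.itertuples(index=False)
    ]
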