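"""Peak / subpeak square-ROI placement and per-ROI metrics.

The scoring protocol reads two fixed-area square windows per section: the
"peak" window over the most affected tissue and a disjoint "subpeak" over
the next most affected. Manual by-eye placement is replaced by a grid
search maximizing the positive-cell count (positives/mm² at fixed area);
ties prefer the higher positive percentage, then the smallest (y, x)
origin. Membership is centroid-based on half-open bounds, so each cell
belongs to exactly one window of a tiling.

Two metrics per window: percent positive cells (missing when the window is
empty) and positive cells per mm² (count divided by the nominal window
area).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .config import DEFAULT_ROI_AREA_MM2
from .detect import CellObject


@dataclass(frozen=True)
class ROIGeometry:
    """Square scoring window: area in mm², search-grid stride in µm."""

    roi_area_mm2: float = DEFAULT_ROI_AREA_MM2
    stride_um: Optional[float] = None  # default: side / 10

    @property
    def side_um(self) -> float:
        return math.sqrt(self.roi_area_mm2) * 1000.0

    @property
    def grid_stride_um(self) -> float:
        return self.stride_um if self.stride_um is not None else self.side_um / 10.0

    def __post_init__(self) -> None:
        if self.roi_area_mm2 <= 0:
            raise ValueError("roi_area_mm2 must be > 0")
        if self.stride_um is not None and self.stride_um <= 0:
            raise ValueError("stride_um must be > 0")


@dataclass(frozen=True)
class ROIResult:
    """Metrics of one placed window. pos_percent is None for empty windows."""

    x_um: float
    y_um: float
    side_um: float
    roi_area_mm2: float
    n_cells: int
    n_positive: int

    @property
    def pos_percent(self) -> Optional[float]:
        if self.n_cells == 0:
            return None
        return 100.0 * self.n_positive / self.n_cells

    @property
    def pos_per_mm2(self) -> float:
        return self.n_positive / self.roi_area_mm2


@dataclass(frozen=True)
class SubjectResult:
    """Peak and subpeak windows of one stained section."""

    subject_id: str
    peak: ROIResult
    subpeak: Optional[ROIResult] = None
    group: Optional[str] = None

    def mean_of_two(self, metric: str) -> Optional[float]:
        """Arithmetic mean of peak and subpeak for 'pos_percent' or
        'pos_per_mm2'; missing values propagate."""
        if self.subpeak is None:
            return None
        a = getattr(self.peak, metric)
        b = getattr(self.subpeak, metric)
        if a is None or b is None:
            return None
        return 0.5 * (a + b)


Cells = Union[Sequence[CellObject], pd.DataFrame]


def _cell_arrays(cells: Cells) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(cells, pd.DataFrame):
        return (
            cells["x_um"].to_numpy(float),
            cells["y_um"].to_numpy(float),
            cells["positive"].to_numpy(bool),
        )
    xs = np.array([c.x_um for c in cells], dtype=float)
    ys = np.array([c.y_um for c in cells], dtype=float)
    pos = np.array([c.positive for c in cells], dtype=bool)
    return xs, ys, pos


def score_window(cells: Cells, x_um: float, y_um: float, side_um: float) -> int:
    """Positive-cell count with centroid in [x, x+side) × [y, y+side)."""
    xs, ys, pos = _cell_arrays(cells)
    inside = (
        (xs >= x_um) & (xs < x_um + side_um) & (ys >= y_um) & (ys < y_um + side_um)
    )
    return int(np.count_nonzero(inside & pos))


def roi_metrics(
    cells: Cells,
    x_um: float,
    y_um: float,
    geometry: ROIGeometry = ROIGeometry(),
) -> ROIResult:
    """Metrics of the window with origin (x, y): half-open, centroid-based."""
    xs, ys, pos = _cell_arrays(cells)
    side = geometry.side_um
    inside = (xs >= x_um) & (xs < x_um + side) & (ys >= y_um) & (ys < y_um + side)
    n = int(np.count_nonzero(inside))
    npos = int(np.count_nonzero(inside & pos))
    return ROIResult(
        x_um=x_um,
        y_um=y_um,
        side_um=side,
        roi_area_mm2=geometry.roi_area_mm2,
        n_cells=n,
        n_positive=npos,
    )


def _grid_positions(extent_um: float, side_um: float, stride_um: float) -> np.ndarray:
    """Window origins 0, stride, 2·stride, …, plus the flush-end position."""
    max_origin = extent_um - side_um
    if max_origin < 0:
        raise ValueError(
            f"image extent {extent_um:.1f} µm is smaller than the ROI side {side_um:.1f} µm"
        )
    pos = list(np.arange(0.0, max_origin + 1e-9, stride_um))
    if not pos or pos[-1] < max_origin - 1e-9:
        pos.append(max_origin)
    return np.asarray(pos)


def find_peak_rois(
    cells: Cells,
    image_size_um: tuple[float, float],
    geometry: ROIGeometry = ROIGeometry(),
    k: int = 2,
) -> list[ROIResult]:
    """Grid-search the peak window and (k=2) a disjoint subpeak window.

    Peak = argmax of the positive-cell count over the stride grid; subpeak =
    argmax over grid windows with zero area overlap with the peak. Raises if
    the image cannot host k disjoint windows.
    """
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    w_um, h_um = image_size_um
    side = geometry.side_um
    gx = _grid_positions(w_um, side, geometry.grid_stride_um)
    gy = _grid_positions(h_um, side, geometry.grid_stride_um)
    xs, ys, posf = _cell_arrays(cells)

    # counts[i, j] for window origin (gx[i], gy[j]) via boolean matmul
    in_x = (xs[None, :] >= gx[:, None]) & (xs[None, :] < gx[:, None] + side)
    in_y = (ys[None, :] >= gy[:, None]) & (ys[None, :] < gy[:, None] + side)
    tot = in_x.astype(np.int64) @ in_y.astype(np.int64).T
    pos = (in_x & posf[None, :]).astype(np.int64) @ in_y.astype(np.int64).T

    ix, iy = np.meshgrid(np.arange(gx.size), np.arange(gy.size), indexing="ij")
    ix, iy = ix.ravel(), iy.ravel()
    score = pos.ravel()
    total = tot.ravel()
    # empty windows rank with 0%-positive windows, so a score-0 tie falls
    # through to the lexicographic (y, x) rule
    pct = np.where(total > 0, score / np.maximum(total, 1), 0.0)
    order = np.lexsort((gx[ix], gy[iy], -pct, -score))

    def result(j: int) -> ROIResult:
        return ROIResult(
            x_um=float(gx[ix[j]]),
            y_um=float(gy[iy[j]]),
            side_um=side,
            roi_area_mm2=geometry.roi_area_mm2,
            n_cells=int(total[j]),
            n_positive=int(score[j]),
        )

    peak_j = order[0]
    out = [result(peak_j)]
    if k == 2:
        px, py = gx[ix[peak_j]], gy[iy[peak_j]]
        disjoint = (np.abs(gx[ix[order]] - px) >= side - 1e-9) | (
            np.abs(gy[iy[order]] - py) >= side - 1e-9
        )
        cand = order[disjoint]
        if cand.size == 0:
            raise ValueError(
                "image too small to place a subpeak window disjoint from the peak"
            )
        out.append(result(cand[0]))
    return out


def subject_result(
    subject_id: str,
    cells: Cells,
    image_size_um: tuple[float, float],
    geometry: ROIGeometry = ROIGeometry(),
    group: Optional[str] = None,
) -> SubjectResult:
    """Convenience: run the peak/subpeak search for one section."""
    peak, subpeak = find_peak_rois(cells, image_size_um, geometry, k=2)
    return SubjectResult(subject_id=subject_id, peak=peak, subpeak=subpeak, group=group)


def subject_results_to_dataframe(results: Sequence[SubjectResult]) -> pd.DataFrame:
    """Long-format per-ROI table (roi_rank 1 = peak, 2 = subpeak)."""
    rows = []
    for res in results:
        for rank, roi in ((1, res.peak), (2, res.subpeak)):
            if roi is None:
                continue
            rows.append(
                {
                    "subject_id": res.subject_id,
                    "group": res.group,
                    "roi_rank": rank,
                    "x_um": roi.x_um,
                    "y_um": roi.y_um,
                    "side_um": roi.side_um,
                    "n_cells": roi.n_cells,
                    "n_positive": roi.n_positive,
                    "pos_percent": np.nan if roi.pos_percent is None else roi.pos_percent,
                    "pos_per_mm2": roi.pos_per_mm2,
                }
            )
    return pd.DataFrame(rows)
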