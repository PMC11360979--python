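"""Synthetic H-DAB cohort generator with per-cell ground truth.

Emulates the statistical structure the scoring pipeline assumes: three
subject groups whose per-subject positive-cell fraction ``f`` (Beta,
moment-matched to the group mean/SD) and total cell density ``d`` per mm²
(Gamma, moment-matched) vary across subjects. Within a section, negative
cells form a homogeneous Poisson process of intensity ``d·(1−f)`` while
positive cells form a Thomas (Neyman–Scott) cluster process of total
intensity ``d·f`` — inflamed tissue is "patchy", and the clustering is what
peak-ROI scoring exploits. ``patchiness=None`` selects the unclustered
limit (positives homogeneous too), used to validate the measurement chain
without hotspot enrichment.

Nuclei are rendered as flat discs of stain concentration (hematoxylin for
every nucleus; a high DAB amplitude for positives, a faint background DAB
for negatives); the RGB image is the Beer–Lambert forward model
``255·10^(−M·c)`` with Gaussian pixel noise added in OD space.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile

from .config import ConfigError, GroupSpec, SimulationParams
from .stains import StainVectors, default_stain_vectors

_MAX_POINT_TRIES = 200
_OVERLAP_FACTOR = 0.8  # nuclei closer than 0.8x the sum of radii are rejected


@dataclass
class CellPoints:
    """Sampled nucleus centres with labels, before rendering. Lengths agree."""

    x_um: np.ndarray
    y_um: np.ndarray
    radius_um: np.ndarray
    positive: np.ndarray  # bool
    true_positive_fraction: float  # the subject's sampled f
    true_density_per_mm2: float  # the subject's sampled d

    def __len__(self) -> int:
        return self.x_um.size


@dataclass
class GroundTruth:
    """Per-cell truth for one rendered section (the validation oracle)."""

    cells: pd.DataFrame  # columns: x_um, y_um, radius_um, positive
    true_positive_fraction: float
    true_density_per_mm2: float

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def observed_positive_fraction(self) -> float:
        """(n positive)/(n total) of the actually rendered cells."""
        if self.n_cells == 0:
            return float("nan")
        return float(self.cells["positive"].sum() / self.n_cells)


def _beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta(a, b) parameters matching a mean/SD; errors if infeasible."""
    var = sd * sd
    limit = mean * (1.0 - mean)
    if var >= limit:
        raise ConfigError(
            f"positive_fraction_sd={sd} infeasible for a Beta with mean {mean} "
            f"(requires sd² < mean·(1−mean) = {limit:.4f})"
        )
    k = limit / var - 1.0
    return mean * k, (1.0 - mean) * k


def sample_subject_rates(group: GroupSpec, rng: np.random.Generator) -> tuple[float, float]:
    """Draw one subject's (positive fraction f, cell density d per mm²)."""
    if group.positive_fraction_sd == 0 or group.positive_fraction_mean in (0.0, 1.0):
        f = group.positive_fraction_mean
    else:
        a, b = _beta_moments(group.positive_fraction_mean, group.positive_fraction_sd)
        f = float(rng.beta(a, b))
    if group.cell_density_sd == 0 or group.cell_density_mean == 0:
        d = group.cell_density_mean
    else:
        shape = (group.cell_density_mean / group.cell_density_sd) ** 2
        scale = group.cell_density_sd**2 / group.cell_density_mean
        d = float(rng.gamma(shape, scale))
    return f, d


class _OverlapGrid:
    """Spatial hash for the minimum-distance rejection rule."""

    def __init__(self, cell_um: float):
        self.cell = cell_um
        self.buckets: dict[tuple[int, int], list[tuple[float, float, float]]] = {}

    def _key(self, x: float, y: float) -> tuple[int, int]:
        return (int(x // self.cell), int(y // self.cell))

    def ok(self, x: float, y: float, r: float) -> bool:
        kx, ky = self._key(x, y)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for ox, oy, orad in self.buckets.get((kx + dx, ky + dy), ()):
                    lim = _OVERLAP_FACTOR * (r + orad)
                    if (x - ox) ** 2 + (y - oy) ** 2 < lim * lim:
                        return False
        return True

    def add(self, x: float, y: float, r: float) -> None:
        self.buckets.setdefault(self._key(x, y), []).append((x, y, r))


def sample_cell_positions(
    params: SimulationParams,
    subject_seed: int,
    group: Optional[GroupSpec] = None,
    rates: Optional[tuple[float, float]] = None,
) -> CellPoints:
    """Sample nucleus centres and positivity labels for one subject.

    ``rates=(f, d)`` fixes the subject's positive fraction and density;
    otherwise they are drawn from ``group`` (defaulting to the first group).
    Points violating the minimum-distance rule are resampled a bounded
    number of times; exhaustion raises, naming the density parameter.
    """
    params.validate()
    rng = np.random.default_rng(subject_seed)
    if rates is None:
        if group is None:
            group = params.groups[0]
        f, d = sample_subject_rates(group, rng)
    else:
        f, d = rates
        if not (0.0 <= f <= 1.0) or d < 0:
            raise ConfigError("rates must satisfy 0 <= f <= 1 and d >= 0")

    w_um = params.image_size_px[0] * params.mpp
    h_um = params.image_size_px[1] * params.mpp
    area_mm2 = params.image_area_mm2
    radius_dist = lambda n: np.clip(  # noqa: E731
        rng.normal(params.nucleus_radius_mean_um, params.nucleus_radius_sd_um, n),
        0.5,
        None,
    )
    grid = _OverlapGrid(cell_um=2.0 * (params.nucleus_radius_mean_um + 4 * params.nucleus_radius_sd_um))
    xs: list[float] = []
    ys: list[float] = []
    rs: list[float] = []
    labels: list[bool] = []

    def place(propose, r: float, what: str, first=None) -> tuple[float, float]:
        # out-of-bounds proposals (cluster mass outside the image) do not
        # count against the overlap-retry budget, which tracks saturation
        overlap_tries = 0
        pending = first
        for _ in range(25 * _MAX_POINT_TRIES):
            x, y = pending if pending is not None else propose()
            pending = None
            if not (0.0 <= x < w_um and 0.0 <= y < h_um):
                continue
            if grid.ok(x, y, r):
                grid.add(x, y, r)
                return x, y
            overlap_tries += 1
            if overlap_tries >= _MAX_POINT_TRIES:
                break
        raise ConfigError(
            f"could not place a {what} cell after {_MAX_POINT_TRIES} rejections; "
            "cell_density_mean (or patchiness) is unsatisfiable for the image area"
        )

    # positives first: the cluster process needs room at hotspot cores
    if params.patchiness is None:
        # unclustered limit: homogeneous Poisson positives
        n_pos = rng.poisson(f * d * area_mm2)
        for r in radius_dist(n_pos):
            x, y = place(lambda: (rng.uniform(0, w_um), rng.uniform(0, h_um)), r, "positive")
            xs.append(x), ys.append(y), rs.append(r), labels.append(True)
    elif f > 0 and d > 0:
        # Thomas process: Poisson parents on the dilated window, Poisson
        # offspring per parent (mean f·d/kappa keeps total intensity f·d);
        # offspring falling outside the image are dropped, offspring
        # violating the overlap rule are redrawn around their parent
        sigma = params.patchiness.cluster_radius_um
        kappa = params.patchiness.parent_intensity_per_mm2
        pad = 3.0 * sigma
        dil_area_mm2 = (w_um + 2 * pad) * (h_um + 2 * pad) / 1e6
        mu = f * d / kappa
        n_parents = rng.poisson(kappa * dil_area_mm2)
        for _ in range(n_parents):
            px = rng.uniform(-pad, w_um + pad)
            py = rng.uniform(-pad, h_um + pad)
            for _ in range(rng.poisson(mu)):
                x = px + rng.normal(0.0, sigma)
                y = py + rng.normal(0.0, sigma)
                if not (0.0 <= x < w_um and 0.0 <= y < h_um):
                    continue
                r = float(radius_dist(1)[0])
                x, y = place(
                    lambda: (px + rng.normal(0.0, sigma), py + rng.normal(0.0, sigma)),
                    r,
                    "positive",
                    first=(x, y),
                )
                xs.append(x), ys.append(y), rs.append(r), labels.append(True)

    n_neg = rng.poisson((1.0 - f) * d * area_mm2)
    if n_neg > 0:
        neg_radii = radius_dist(n_neg)
        for r in neg_radii:
            x, y = place(lambda: (rng.uniform(0, w_um), rng.uniform(0, h_um)), r, "negative")
            xs.append(x), ys.append(y), rs.append(r), labels.append(False)

    return CellPoints(
        x_um=np.asarray(xs, dtype=float),
        y_um=np.asarray(ys, dtype=float),
        radius_um=np.asarray(rs, dtype=float),
        positive=np.asarray(labels, dtype=bool),
        true_positive_fraction=float(f),
        true_density_per_mm2=float(d),
    )


def render_image(
    points: CellPoints,
    params: SimulationParams,
    noise_rng: Optional[np.random.Generator] = None,
    stains: Optional[StainVectors] = None,
    quantize: bool = True,
) -> tuple[np.ndarray, GroundTruth]:
    """Render sampled nuclei to an RGB image plus its ground truth.

    Each nucleus is a filled disc of flat stain concentration (overlaps take
    the per-stain maximum); RGB is the base-10 Beer–Lambert forward model
    with optional Gaussian OD-space noise. ``quantize=False`` returns the
    float image (exact for round-trip checks); the default is 8-bit.
    """
    params.validate()
    if stains is None:
        stains = default_stain_vectors()
    w, h = params.image_size_px
    mpp = params.mpp
    if len(points) and (
        points.x_um.min() < 0
        or points.y_um.min() < 0
        or points.x_um.max() >= w * mpp
        or points.y_um.max() >= h * mpp
    ):
        raise ValueError("point set extends outside the image bounds")

    c_hema = np.zeros((h, w), dtype=float)
    c_dab = np.zeros((h, w), dtype=float)
    st = params.stain
    for x, y, r, pos in zip(points.x_um, points.y_um, points.radius_um, points.positive):
        cx, cy, rp = x / mpp, y / mpp, r / mpp
        c0 = max(0, int(np.floor(cx - rp - 1)))
        c1 = min(w, int(np.ceil(cx + rp + 2)))
        r0 = max(0, int(np.floor(cy - rp - 1)))
        r1 = min(h, int(np.ceil(cy + rp + 2)))
        if c0 >= c1 or r0 >= r1:
            continue
        cols = np.arange(c0, c1) + 0.5
        rows = np.arange(r0, r1) + 0.5
        disc = (cols[None, :] - cx) ** 2 + (rows[:, None] - cy) ** 2 <= rp * rp
        patch_h = c_hema[r0:r1, c0:c1]
        np.maximum(patch_h, np.where(disc, st.hematoxylin_od, 0.0), out=patch_h)
        dab_amp = st.dab_od_positive if pos else st.dab_od_negative
        patch_d = c_dab[r0:r1, c0:c1]
        np.maximum(patch_d, np.where(disc, dab_amp, 0.0), out=patch_d)

    conc = np.stack([c_hema, c_dab, np.zeros_like(c_hema)], axis=-1)
    od = np.einsum("ij,hwj->hwi", stains.matrix, conc)
    if st.noise_od_sd > 0:
        if noise_rng is None:
            noise_rng = np.random.default_rng(0)
        od = od + noise_rng.normal(0.0, st.noise_od_sd, od.shape)
    rgb = np.clip(255.0 * np.power(10.0, -od), 0.0, 255.0)
    if quantize:
        rgb = np.round(rgb).astype(np.uint8)

    gt = GroundTruth(
        cells=pd.DataFrame(
            {
                "x_um": points.x_um,
                "y_um": points.y_um,
                "radius_um": points.radius_um,
                "positive": points.positive,
            }
        ),
        true_positive_fraction=points.true_positive_fraction,
        true_density_per_mm2=points.true_density_per_mm2,
    )
    return rgb, gt


@dataclass
class SimulatedCohort:
    """Output of simulate_cohort: manifest plus per-subject ground truth."""

    manifest: pd.DataFrame  # subject_id, group, image_path, seed
    ground_truth: dict[str, GroundTruth]
    params: SimulationParams


def simulate_cohort(
    params: SimulationParams,
    out_dir: Union[str, Path],
    image_format: str = "tiff",
) -> SimulatedCohort:
    """Simulate one image per subject for every group and write them out.

    The master seed deterministically derives per-subject seeds (recorded in
    the manifest), so the same parameters reproduce bit-identical cohorts.
    Writes ``<subject>.tif``/``.png``, per-subject ground-truth CSVs and
    ``manifest.csv`` under ``out_dir``.
    """
    params.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_total = sum(g.n_subjects for g in params.groups)
    children = np.random.SeedSequence(params.seed).spawn(n_total)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]

    rows = []
    gts: dict[str, GroundTruth] = {}
    i = 0
    for grp in params.groups:
        for j in range(grp.n_subjects):
            subject_id = f"{grp.label}_{j + 1:02d}"
            seed = seeds[i]
            i += 1
            pts = sample_cell_positions(params, seed, group=grp)
            noise_rng = np.random.default_rng(seed + 1)
            img, gt = render_image(pts, params, noise_rng=noise_rng)
            if image_format == "png":
                from PIL import Image

                path = out / f"{subject_id}.png"
                Image.fromarray(img).save(path)
            else:
                path = out / f"{subject_id}.tif"
                tifffile.imwrite(path, img, compression="deflate")
            gt.cells.to_csv(out / f"{subject_id}_truth.csv", index=False)
            gts[subject_id] = gt
            rows.append(
                {
                    "subject_id": subject_id,
                    "group": grp.label,
                    "image_path": str(path),
                    "seed": seed,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return SimulatedCohort(manifest=manifest, ground_truth=gts, params=params)
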