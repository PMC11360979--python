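"""Optical-density transform and colour deconvolution for H-DAB images.

Brightfield absorbance follows Beer–Lambert: a pixel transmitting value
``v`` out of incident intensity ``i0`` has optical density
``OD = -log10(v / i0)`` per channel, and the OD vector is linear in the
stain concentrations, ``OD = M @ c`` with ``M`` the 3x3 matrix whose
columns are the unit-norm absorbance spectra of hematoxylin, DAB and a
residual channel. Deconvolution inverts ``M`` per pixel to recover the
concentration (equivalently, stain-specific OD) maps, from which the DAB
signal of each cell is scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import HEMATOXYLIN_OD_RGB, DAB_OD_RGB

_MAX_CONDITION = 1e6


class StainMatrixError(ValueError):
    """Stain matrix failed validation (norms, shape or conditioning)."""


@dataclass(frozen=True)
class StainVectors:
    """3x3 matrix of unit-norm stain OD column vectors (H, DAB, residual)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise StainMatrixError(f"stain matrix must be 3x3, got {m.shape}")
        norms = np.linalg.norm(m, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise StainMatrixError(f"stain columns must have unit norm, got {norms}")
        cond = np.linalg.cond(m)
        if not np.isfinite(cond) or cond > _MAX_CONDITION:
            raise StainMatrixError(f"stain matrix is ill-conditioned (cond={cond:.3g})")
        object.__setattr__(self, "matrix", m)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


def default_stain_vectors() -> StainVectors:
    """Standard H-DAB reference vectors with a nonnegative residual.

    Hematoxylin and DAB are the published reference spectra; the residual
    channel is the per-channel complement sqrt(1 - h_c² - d_c²) (clipped at
    zero), normalized — the construction used by the classical colour
    deconvolution plugins, which keeps every component nonnegative.
    """
    h = np.asarray(HEMATOXYLIN_OD_RGB, dtype=float)
    d = np.asarray(DAB_OD_RGB, dtype=float)
    h = h / np.linalg.norm(h)
    d = d / np.linalg.norm(d)
    r = np.sqrt(np.clip(1.0 - h**2 - d**2, 0.0, None))
    r = r / np.linalg.norm(r)
    return StainVectors(np.column_stack([h, d, r]))


def stain_vectors_from_columns(columns: np.ndarray) -> StainVectors:
    """Build StainVectors from arbitrary (not necessarily unit) columns."""
    m = np.asarray(columns, dtype=float)
    if m.shape != (3, 3):
        raise StainMatrixError(f"stain matrix must be 3x3, got {m.shape}")
    norms = np.linalg.norm(m, axis=0)
    if np.any(norms == 0):
        raise StainMatrixError("stain columns must be nonzero")
    return StainVectors(m / norms)


@dataclass
class ODImage:
    """Per-pixel optical-density stack (H, W, 3) with its µm/px calibration."""

    od: np.ndarray
    mpp: float

    def __post_init__(self) -> None:
        od = np.asarray(self.od, dtype=float)
        if od.ndim != 3 or od.shape[2] != 3:
            raise ValueError(f"OD stack must be (H, W, 3), got {od.shape}")
        if self.mpp <= 0:
            raise ValueError("mpp must be > 0")
        self.od = od


def rgb_to_od(image: np.ndarray, i0: float = 255.0, mpp: float = 1.0) -> ODImage:
    """Beer–Lambert inverse: RGB image -> optical-density stack.

    For integer images a +1 offset guards the log at zero; floating-point
    images (e.g. a pre-quantization forward model) are converted without
    the offset so the transform is exactly invertible. Negative OD values
    (pixels brighter than ``i0``) are clamped to 0.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    if np.issubdtype(img.dtype, np.integer):
        v = img.astype(float) + 1.0
    else:
        v = np.maximum(img.astype(float), 1e-10)
    od = -np.log10(v / i0)
    return ODImage(np.clip(od, 0.0, None), mpp=mpp)


@dataclass
class StainConcentrations:
    """Deconvolved per-stain concentration maps plus clamp accounting."""

    hematoxylin: np.ndarray
    dab: np.ndarray
    residual: np.ndarray
    clamped_fraction: float
    mpp: float


def deconvolve(od: ODImage, stains: StainVectors | None = None) -> StainConcentrations:
    """Unmix an OD stack into hematoxylin / DAB / residual concentration maps.

    Per pixel: ``c = M⁻¹ @ OD``. Negative concentrations (noise pushing a
    pixel outside the stain simplex) are clamped to zero; the fraction of
    clamped pixel-channels is reported for quality control.
    """
    if stains is None:
        stains = default_stain_vectors()
    conc = np.einsum("ij,hwj->hwi", stains.inverse, od.od)
    n_neg = int(np.count_nonzero(conc < 0))
    frac = n_neg / conc.size
    conc = np.clip(conc, 0.0, None)
    return StainConcentrations(
        hematoxylin=conc[..., 0],
        dab=conc[..., 1],
        residual=conc[..., 2],
        clamped_fraction=frac,
        mpp=od.mpp,
    )


def concentrations_to_rgb(
    conc: np.ndarray, stains: StainVectors | None = None, i0: float = 255.0
) -> np.ndarray:
    """Forward Beer–Lambert model: concentration stack (H, W, 3) -> float RGB.

    ``rgb = i0 * 10^(-M @ c)``, the exact inverse of rgb_to_od on float
    images. Quantization to 8 bits is the caller's decision.
    """
    if stains is None:
        stains = default_stain_vectors()
    od = np.einsum("ij,hwj->hwi", stains.matrix, np.asarray(conc, dtype=float))
    return i0 * np.power(10.0, -od)
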