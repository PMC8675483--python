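"""Low-level image operators shared by the viability and fusion pipelines.

These mirror the classic interactive image-analysis steps used for nuclei
segmentation in fluorescence micrographs: brightness multiplication with
saturation, automatic (iterative-intermeans / IsoData) thresholding on a
256-bin histogram, binary median filtering, hole filling, and Gaussian
smoothing.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi

from .errors import DegenerateImageError, ParameterError

__all__ = [
    "PipelineParams",
    "multiply_saturating",
    "default_threshold",
    "median_filter_mask",
    "fill_holes",
    "gaussian_blur",
    "intensity_ceiling",
]

_ROUNDING_MODES = ("nearest", "floor", "fractional")


@dataclasses.dataclass(frozen=True)
class PipelineParams:
    """Tunable parameters of the two pipelines.

    Defaults follow the standard workflow for this assay: no brightness
    multiplication, a radius-1 median filter, a sigma-2 Gaussian blur for the
    myotube (MYH) channel, and the 50–250 µm² singleton-nucleus size window
    (anything larger is a nuclear clump).
    """

    multiply_dapi: float = 1.0
    multiply_myh: float = 1.0
    median_radius_px: int = 1
    gaussian_sigma_px: float = 2.0
    singles_min_um2: float = 50.0
    singles_max_um2: float = 250.0
    clump_rounding: str = "nearest"

    def __post_init__(self) -> None:
        if self.multiply_dapi < 1 or self.multiply_myh < 1:
            raise ParameterError("multiplication factors must be >= 1")
        if self.median_radius_px < 1:
            raise ParameterError("median_radius_px must be >= 1")
        if self.gaussian_sigma_px <= 0:
            raise ParameterError("gaussian_sigma_px must be > 0")
        if not 0 < self.singles_min_um2 < self.singles_max_um2:
            raise ParameterError("need 0 < singles_min_um2 < singles_max_um2")
        if self.clump_rounding not in _ROUNDING_MODES:
            raise ParameterError(f"clump_rounding must be one of {_ROUNDING_MODES}")


def intensity_ceiling(img: np.ndarray) -> float:
    """Maximum representable intensity for an image array.

    Integer dtypes use the dtype maximum; float arrays fall back to 255 unless
    their values exceed it (calibrated float data keeps its own scale).
    """
    img = np.asarray(img)
    if np.issubdtype(img.dtype, np.integer):
        return float(np.iinfo(img.dtype).max)
    mx = float(img.max()) if img.size else 255.0
    return max(255.0, mx)


def multiply_saturating(img: np.ndarray, factor: float, bit_depth_max: float) -> np.ndarray:
    """Multiply intensities by ``factor`` (>= 1), rounding half away from zero
    and saturating at ``bit_depth_max``. The dtype is preserved."""
    if factor < 1:
        raise ParameterError("multiplication factor must be >= 1")
    img = np.asarray(img)
    out = np.floor(img.astype(np.float64) * factor + 0.5)
    np.minimum(out, bit_depth_max, out=out)
    if np.issubdtype(img.dtype, np.integer):
        return out.astype(img.dtype)
    return out


def default_threshold(img: np.ndarray, nbins: int = 256) -> tuple[float, np.ndarray]:
    """Automatic threshold by iterative intermeans (the IsoData variant).

    The histogram spans the image's own intensity range with ``nbins`` bins.
    The threshold t is the fixed point of ``t <- (mean(values <= t) +
    mean(values > t)) / 2``; the returned mask is ``img > t`` (background
    exactly at t stays out of the foreground).

    Returns ``(t, mask)``. Raises :class:`DegenerateImageError` when the image
    holds fewer than two distinct values.
    """
    vals = np.asarray(img, dtype=np.float64)
    vmin = float(vals.min())
    vmax = float(vals.max())
    if not vmax > vmin:
        raise DegenerateImageError("constant image: no threshold exists")

    hist, edges = np.histogram(vals, bins=nbins, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    csum = np.cumsum(hist)
    cmom = np.cumsum(hist * centers)
    total = csum[-1]
    tmom = cmom[-1]

    k = nbins // 2
    t = centers[k]
    for _ in range(1000):
        n_lo = csum[k]
        n_hi = total - n_lo
        if n_lo == 0:
            k += 1
            continue
        if n_hi == 0:
            k -= 1
            continue
        m_lo = cmom[k] / n_lo
        m_hi = (tmom - cmom[k]) / n_hi
        t = 0.5 * (m_lo + m_hi)
        k_new = int(np.clip((t - vmin) / width, 0, nbins - 1))
        if k_new == k:
            break
        k = k_new
    return float(t), vals > t


def median_filter_mask(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Binary median (majority vote) over a square (2r+1)×(2r+1) window.

    Radius 1 is the full 3×3 neighbourhood; the window holds an odd number of
    samples so ties cannot occur. Borders are edge-replicated.
    """
    if radius_px < 1:
        raise ParameterError("median radius must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    size = 2 * int(radius_px) + 1
    out = ndi.median_filter(mask.astype(np.uint8), size=size, mode="nearest")
    return out.astype(bool)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background holes: 4-connected background components not reachable
    from the image border become foreground; existing foreground is kept."""
    return ndi.binary_fill_holes(np.asarray(mask, dtype=bool))


def gaussian_blur(img: np.ndarray, sigma_px: float) -> np.ndarray:
    """Isotropic Gaussian smoothing (reflective boundary), returned as float."""
    if sigma_px <= 0:
        raise ParameterError("sigma must be > 0")
    return ndi.gaussian_filter(np.asarray(img, dtype=np.float64), sigma_px, mode="reflect")
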