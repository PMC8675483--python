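"""Myotube fusion-index pipeline.

The MYH (myosin heavy chain) channel defines myotube area: multiply ->
Gaussian blur (sigma 2 px) -> auto-threshold -> median filter -> fill holes.
Subtracting the myotube mask from the watershed-split DAPI segmentation
leaves the nuclei outside MYH-positive cells, which are counted with the same
two-bin / clump-division scheme (the modal area comes from the outside image
itself). The fusion index is then

    (total - outside - small) / total * 100

where ``small`` is the nuclei in MYH-positive cells with only one or two
nuclei: by the strict differentiation criterion such cells are not myotubes,
and their nuclei are counted by the user (or, optionally, by the automated
estimator in this module).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as _label_regions

from .errors import (
    DegenerateImageError,
    GeometryError,
    InconsistencyError,
    NoSingletonsError,
    RequiredInputError,
    UndefinedIndexError,
)
from .io import ChannelStack, write_overlay, write_results_csv
from .preprocess import (
    PipelineParams,
    default_threshold,
    fill_holes,
    gaussian_blur,
    intensity_ceiling,
    median_filter_mask,
    multiply_saturating,
)
from .viability import (
    NucleiCount,
    ViabilityResult,
    area_mode,
    bin_particles,
    clump_nuclei_count,
    count_total_nuclei,
    measure_particles,
)

__all__ = [
    "FusionResult",
    "myotube_mask",
    "subtract_mask",
    "count_outside_nuclei",
    "fusion_index",
    "estimate_small_myh_nuclei",
    "run_fusion",
    "fusion_results_table",
]

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclasses.dataclass
class FusionResult:
    total_nuclei: int
    outside_nuclei: int
    small_myh_nuclei: int
    fusion_index_pct: float
    outside_count_detail: NucleiCount
    viability: ViabilityResult | None = dataclasses.field(default=None, repr=False)


def myotube_mask(
    myh: np.ndarray,
    params: PipelineParams | None = None,
    bit_depth_max: float | None = None,
) -> np.ndarray:
    """MYH-positive area: multiply -> Gaussian blur -> threshold (on the
    blurred intensities' own histogram) -> median filter -> fill holes.

    A channel with no signal yields an empty mask with a warning."""
    params = params or PipelineParams()
    myh = np.asarray(myh)
    bmax = bit_depth_max if bit_depth_max is not None else intensity_ceiling(myh)
    work = multiply_saturating(myh, params.multiply_myh, bmax)
    smooth = gaussian_blur(work, params.gaussian_sigma_px)
    try:
        _, mask = default_threshold(smooth)
    except DegenerateImageError:
        warnings.warn(
            "no MYH signal: myotube mask is empty", RuntimeWarning, stacklevel=2
        )
        return np.zeros(myh.shape, dtype=bool)
    mask = median_filter_mask(mask, params.median_radius_px)
    return fill_holes(mask)


def subtract_mask(dapi_mask: np.ndarray, myh_mask: np.ndarray) -> np.ndarray:
    """Pixelwise ``dapi AND NOT myh``: the outside-nuclei mask."""
    dapi_mask = np.asarray(dapi_mask, dtype=bool)
    myh_mask = np.asarray(myh_mask, dtype=bool)
    if dapi_mask.shape != myh_mask.shape:
        raise GeometryError("mask shapes do not match")
    return dapi_mask & ~myh_mask


def _outside_count(
    dapi_labels: np.ndarray,
    myh_mask: np.ndarray,
    pixel_size_um: float,
    params: PipelineParams,
    fallback_mode: float | None,
) -> tuple[NucleiCount, np.ndarray]:
    """Count nuclei on the outside image, preserving watershed divisions.

    Pixels under the myotube mask are removed from the label map; the
    remainder is re-labelled, with watershed boundaries kept (adjacent pixels
    carrying different parent labels stay separate objects).
    """
    if dapi_labels.shape != np.asarray(myh_mask).shape:
        raise GeometryError("label map and myotube mask shapes do not match")
    outside = np.where(np.asarray(myh_mask, bool), 0, dapi_labels)
    relabeled = _label_regions(outside, background=0, connectivity=2)
    particles = measure_particles(relabeled, pixel_size_um)
    singles, clumps, _ = bin_particles(particles, params)

    if len(clumps):
        if len(singles):
            mode = area_mode(singles.areas)
        elif fallback_mode is not None:
            warnings.warn(
                "outside image has clumps but no singleton nuclei; "
                "falling back to the whole-image modal area",
                RuntimeWarning,
                stacklevel=2,
            )
            mode = fallback_mode
        else:
            raise NoSingletonsError(
                "no singleton nuclei anywhere: cannot resolve outside clumps"
            )
        n_clump = clump_nuclei_count(clumps.areas, mode, params.clump_rounding)
    else:
        mode = area_mode(singles.areas) if len(singles) else None
        n_clump = 0

    count = NucleiCount(
        n_singles=len(singles),
        singleton_areas=singles.areas,
        clump_areas=clumps.areas,
        mode_area_um2=mode,
        n_clump_nuclei=n_clump,
        total=len(singles) + n_clump,
    )
    return count, relabeled


def count_outside_nuclei(
    dapi: np.ndarray,
    myh: np.ndarray,
    pixel_size_um: float,
    params: PipelineParams | None = None,
) -> NucleiCount:
    """Count nuclei outside MYH-positive cells.

    The DAPI channel is processed exactly as in the viability pipeline
    (through watershed), the myotube mask is subtracted, and the outside
    particles are binned and clump-divided using the outside image's own
    modal singleton area (whole-image mode as fallback, with a warning).
    """
    if np.asarray(dapi).shape != np.asarray(myh).shape:
        raise GeometryError("DAPI and MYH channels must share dimensions")
    params = params or PipelineParams()
    via = count_total_nuclei(dapi, pixel_size_um, params)
    tube = myotube_mask(myh, params)
    count, _ = _outside_count(
        via.labels, tube, pixel_size_um, params, via.count.mode_area_um2
    )
    return count


def fusion_index(total: int, outside: int, small_myh_nuclei: int) -> float:
    """Fusion index in percent: (total - outside - small) / total * 100."""
    if min(total, outside, small_myh_nuclei) < 0:
        raise InconsistencyError("counts must be non-negative")
    if total == 0:
        raise UndefinedIndexError("fusion index undefined when total nuclei is 0")
    if outside + small_myh_nuclei > total:
        raise InconsistencyError(
            f"outside ({outside}) + small ({small_myh_nuclei}) exceeds total ({total})"
        )
    return (total - outside - small_myh_nuclei) / total * 100.0


def estimate_small_myh_nuclei(myh_mask: np.ndarray, nuclei_labels: np.ndarray) -> int:
    """Automated substitute for the manual count of nuclei in MYH-positive
    cells with 1–2 nuclei (off by default in :func:`run_fusion`).

    Each 8-connected MYH-positive component is assigned the nuclei whose
    centroid lies inside it; components holding 1 or 2 nuclei contribute
    those nuclei to the returned sum.
    """
    myh_mask = np.asarray(myh_mask, dtype=bool)
    nuclei_labels = np.asarray(nuclei_labels)
    if myh_mask.shape != nuclei_labels.shape:
        raise GeometryError("mask and label map shapes do not match")
    components, n_comp = ndi.label(myh_mask, structure=_EIGHT)
    if n_comp == 0:
        return 0
    tally = np.zeros(n_comp + 1, dtype=int)
    for particle in measure_particles(nuclei_labels, 1.0):
        r = int(round(particle.centroid[0]))
        c = int(round(particle.centroid[1]))
        r = min(max(r, 0), myh_mask.shape[0] - 1)
        c = min(max(c, 0), myh_mask.shape[1] - 1)
        tally[components[r, c]] += 1
    return int(sum(t for t in tally[1:] if t in (1, 2)))


def run_fusion(
    stack: ChannelStack,
    params: PipelineParams | None = None,
    small_myh_nuclei: int | None = None,
    auto_small: bool = False,
    out_prefix=None,
) -> FusionResult:
    """End-to-end fusion-index computation on a two-channel stack.

    ``small_myh_nuclei`` is the user-counted number of nuclei in MYH-positive
    cells with 1–2 nuclei (the faithful mode); with ``auto_small=True`` it is
    estimated from the segmentation instead (logged as automated). When
    ``out_prefix`` is given, ``<prefix>.csv`` and ``<prefix>.png`` are written.
    """
    params = params or PipelineParams()
    dapi = stack.channel("dapi")
    myh = stack.channel("myh")

    if params.multiply_myh * float(np.mean(myh)) < params.multiply_dapi * float(
        np.mean(dapi)
    ):
        logger.warning(
            "MYH channel is dimmer than DAPI after multiplication; the myotube "
            "mask may under-cover — consider raising the MYH multiplication"
        )

    via = count_total_nuclei(dapi, stack.pixel_size_um, params, stack.bit_depth_max)
    tube = myotube_mask(myh, params, stack.bit_depth_max)
    outside, _ = _outside_count(
        via.labels, tube, stack.pixel_size_um, params, via.count.mode_area_um2
    )

    if small_myh_nuclei is None:
        if not auto_small:
            raise RequiredInputError(
                "small_myh_nuclei (nuclei in 1–2-nucleus MYH-positive cells) must "
                "be supplied, or auto_small enabled"
            )
        small_myh_nuclei = estimate_small_myh_nuclei(tube, via.labels)
        logger.info("small_myh_nuclei estimated automatically: %d", small_myh_nuclei)

    index = fusion_index(via.count.total, outside.total, small_myh_nuclei)
    result = FusionResult(
        total_nuclei=via.count.total,
        outside_nuclei=outside.total,
        small_myh_nuclei=int(small_myh_nuclei),
        fusion_index_pct=index,
        outside_count_detail=outside,
        viability=via,
    )
    if out_prefix is not None:
        prefix = str(out_prefix)
        write_results_csv(fusion_results_table(result), prefix + ".csv")
        write_overlay(stack, via.labels, tube, prefix + ".png")
    return result


def fusion_results_table(result: FusionResult):
    """Assemble the fusion-index result fields for CSV export."""
    from .io import ResultsTable

    detail = result.outside_count_detail
    mode = detail.mode_area_um2
    table = ResultsTable()
    table.add("outside_clump_areas_um2", list(detail.clump_areas))
    table.add("n_outside_singles", detail.n_singles)
    table.add("outside_mode_area_um2", float("nan") if mode is None else mode)
    table.add("n_outside_clump_nuclei", detail.n_clump_nuclei)
    table.add("outside_total", detail.total)
    table.add("total_nuclei", result.total_nuclei)
    table.add("small_myh_nuclei", result.small_myh_nuclei)
    table.add("fusion_index_pct", result.fusion_index_pct)
    return table
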