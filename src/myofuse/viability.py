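"""Nuclei counting and density ("viability") pipeline.

The DAPI channel is multiplied, auto-thresholded, median-filtered,
hole-filled, and watershed-split to separate touching nuclei. Particles are
measured and partitioned into debris (< 50 µm²), singleton nuclei
(50–250 µm²), and nuclear clumps (> 250 µm²). Each clump's nucleus content is
estimated by dividing its area by the modal singleton area; the grand total
divided by the image area in mm² gives the nuclei density, the assay's
proxy for cell viability/growth.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import h_maxima
from skimage.segmentation import relabel_sequential, watershed

from .errors import LabelMapError, NoSingletonsError, ParameterError
from .preprocess import (
    PipelineParams,
    default_threshold,
    fill_holes,
    intensity_ceiling,
    median_filter_mask,
    multiply_saturating,
)
from .errors import DegenerateImageError

__all__ = [
    "Particle",
    "ParticleSet",
    "NucleiCount",
    "ViabilityResult",
    "watershed_split",
    "measure_particles",
    "bin_particles",
    "area_mode",
    "clump_nuclei_estimates",
    "clump_nuclei_count",
    "count_total_nuclei",
    "viability_results_table",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclasses.dataclass(frozen=True)
class Particle:
    label: int
    pixel_count: int
    area_um2: float
    centroid: tuple[float, float]  # (row, col), pixel coordinates


@dataclasses.dataclass
class ParticleSet:
    particles: list[Particle]
    pixel_size_um: float

    def __len__(self) -> int:
        return len(self.particles)

    def __iter__(self):
        return iter(self.particles)

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area_um2 for p in self.particles], dtype=float)


@dataclasses.dataclass
class NucleiCount:
    """Two-bin nuclei bookkeeping: singletons counted directly, clumps
    resolved by area / modal-area division."""

    n_singles: int
    singleton_areas: np.ndarray
    clump_areas: np.ndarray
    mode_area_um2: float | None
    n_clump_nuclei: int
    total: int


@dataclasses.dataclass
class ViabilityResult:
    count: NucleiCount
    image_area_mm2: float
    density_per_mm2: float
    threshold: float | None = None
    n_debris: int = 0
    labels: np.ndarray | None = dataclasses.field(default=None, repr=False)


def watershed_split(mask: np.ndarray) -> np.ndarray:
    """Split touching nuclei along valleys of the Euclidean distance transform.

    The distance map is lightly smoothed (sigma 1 px) and its maxima are
    h-suppressed at h = 1 px of distance; the surviving maxima seed a
    marker-based watershed restricted to the foreground. Every foreground
    pixel receives a label (divide pixels join an adjacent region; components
    too thin to seed a maximum are labelled as their own objects). Labels are
    consecutive 1..n.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)

    dist = ndi.distance_transform_edt(mask)
    smooth = ndi.gaussian_filter(dist, 1.0)
    smooth[~mask] = 0.0
    peaks = h_maxima(smooth, 1.0).astype(bool) & mask
    markers, n_markers = ndi.label(peaks, structure=_EIGHT)
    if n_markers == 0:
        labels, _ = ndi.label(mask, structure=_EIGHT)
        return labels.astype(np.int32)

    labels = watershed(-smooth, markers, mask=mask)
    leftover = mask & (labels == 0)
    if leftover.any():
        extra, _ = ndi.label(leftover, structure=_EIGHT)
        labels = np.where(leftover, extra + n_markers, labels)
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def measure_particles(labels: np.ndarray, pixel_size_um: float) -> ParticleSet:
    """One :class:`Particle` per label: exact pixel count, area in µm²,
    centroid (mean pixel coordinate). Edge-touching particles are included."""
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    n = len(ids)
    if n and not np.array_equal(ids, np.arange(1, n + 1)):
        raise LabelMapError("labels must be consecutive 1..n")
    if n == 0:
        return ParticleSet([], pixel_size_um)

    flat = labels.ravel()
    counts = np.bincount(flat, minlength=n + 1)[1:]
    rr, cc = np.nonzero(labels)
    lab = labels[rr, cc]
    r_sum = np.bincount(lab, weights=rr, minlength=n + 1)[1:]
    c_sum = np.bincount(lab, weights=cc, minlength=n + 1)[1:]
    px2 = pixel_size_um**2
    particles = [
        Particle(
            label=int(i + 1),
            pixel_count=int(counts[i]),
            area_um2=float(counts[i] * px2),
            centroid=(float(r_sum[i] / counts[i]), float(c_sum[i] / counts[i])),
        )
        for i in range(n)
    ]
    return ParticleSet(particles, pixel_size_um)


def bin_particles(
    particles: ParticleSet, params: PipelineParams
) -> tuple[ParticleSet, ParticleSet, ParticleSet]:
    """Partition particles into (singletons, clumps, debris) by area.

    Debris: area < singles_min. Singletons: singles_min <= area <= singles_max.
    Clumps: area > singles_max (so nothing falls into the published
    250-vs-251 µm² gap). The partition is exhaustive and disjoint.
    """
    singles, clumps, debris = [], [], []
    for p in particles:
        if p.area_um2 < params.singles_min_um2:
            debris.append(p)
        elif p.area_um2 <= params.singles_max_um2:
            singles.append(p)
        else:
            clumps.append(p)
    px = particles.pixel_size_um
    return (
        ParticleSet(singles, px),
        ParticleSet(clumps, px),
        ParticleSet(debris, px),
    )


def area_mode(singleton_areas) -> float:
    """Modal singleton area on 1-µm² bins (bin k covers [k-0.5, k+0.5); ties
    break toward the smallest bin). This is the clump divisor."""
    areas = np.asarray(singleton_areas, dtype=float)
    if areas.size == 0:
        raise NoSingletonsError("no singleton nuclei: modal area undefined")
    bins = np.floor(areas + 0.5).astype(int)
    counts = np.bincount(bins)
    return float(np.argmax(counts))


def clump_nuclei_estimates(clump_areas, mode_area: float) -> np.ndarray:
    """Per-clump nucleus estimates: max(1, round-half-up(area / mode))."""
    if mode_area <= 0:
        raise ParameterError("mode_area must be > 0")
    q = np.asarray(clump_areas, dtype=float) / mode_area
    return np.maximum(1, np.floor(q + 0.5)).astype(int)


def clump_nuclei_count(clump_areas, mode_area: float, rounding: str = "nearest") -> int:
    """Total nuclei attributed to clumps by area / modal-area division.

    ``nearest`` (default): per clump max(1, round-half-up(q)). ``floor``:
    per clump max(1, floor(q)). ``fractional``: sum the raw quotients and
    round once at the end.
    """
    if mode_area <= 0:
        raise ParameterError("mode_area must be > 0")
    q = np.asarray(clump_areas, dtype=float) / mode_area
    if q.size == 0:
        return 0
    if rounding == "nearest":
        return int(np.maximum(1, np.floor(q + 0.5)).sum())
    if rounding == "floor":
        return int(np.maximum(1, np.floor(q)).sum())
    if rounding == "fractional":
        return int(np.floor(q.sum() + 0.5))
    raise ParameterError(f"unknown rounding rule {rounding!r}")


def count_total_nuclei(
    dapi: np.ndarray,
    pixel_size_um: float,
    params: PipelineParams | None = None,
    bit_depth_max: float | None = None,
) -> ViabilityResult:
    """Full nuclei-counting pipeline on a calibrated DAPI channel.

    Order: multiply -> threshold -> median filter -> fill holes -> watershed
    -> measure -> size-bin -> modal area -> clump division -> total ->
    density. A field with no signal (constant image after multiplication)
    yields total 0 with a warning rather than an error.
    """
    params = params or PipelineParams()
    dapi = np.asarray(dapi)
    bmax = bit_depth_max if bit_depth_max is not None else intensity_ceiling(dapi)

    work = multiply_saturating(dapi, params.multiply_dapi, bmax)
    threshold: float | None
    try:
        threshold, mask = default_threshold(work)
    except DegenerateImageError:
        warnings.warn(
            "degenerate histogram: treating field as empty (total = 0)",
            RuntimeWarning,
            stacklevel=2,
        )
        threshold = None
        mask = np.zeros(work.shape, dtype=bool)

    mask = median_filter_mask(mask, params.median_radius_px)
    mask = fill_holes(mask)
    labels = watershed_split(mask)
    particles = measure_particles(labels, pixel_size_um)
    singles, clumps, debris = bin_particles(particles, params)

    if len(clumps):
        mode = area_mode(singles.areas)  # NoSingletonsError if none
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
    area_mm2 = dapi.shape[0] * dapi.shape[1] * pixel_size_um**2 / 1e6
    return ViabilityResult(
        count=count,
        image_area_mm2=area_mm2,
        density_per_mm2=count.total / area_mm2,
        threshold=threshold,
        n_debris=len(debris),
        labels=labels,
    )


def viability_results_table(result: ViabilityResult):
    """Assemble the nuclei-count result fields for CSV export."""
    from .io import ResultsTable

    mode = result.count.mode_area_um2
    table = ResultsTable()
    table.add("clump_areas_um2", list(result.count.clump_areas))
    table.add("n_singles", result.count.n_singles)
    table.add("mode_area_um2", float("nan") if mode is None else mode)
    table.add("image_area_mm2", result.image_area_mm2)
    table.add("n_clump_nuclei", result.count.n_clump_nuclei)
    table.add("total_nuclei", result.count.total)
    table.add("density_per_mm2", result.density_per_mm2)
    return table
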