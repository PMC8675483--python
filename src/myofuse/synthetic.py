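"""Synthetic two-channel fluorescence scenes with exact ground truth.

Scenes emulate the object classes of the fusion-index assay: elliptical
nuclei (areas mostly 50–250 µm²) in the DAPI channel; nuclear clumps drawn as
mutually-overlapping ellipse rosettes whose blob area targets k × the modal
singleton area (so area-division recovers k exactly on clean scenes);
capsule-shaped MYH-positive myotubes enclosing >= 3 nuclei; round/short MYH
cells with 1–2 nuclei; and additive Gaussian background noise. Each scene
records exact per-category counts and the true fusion index.

Not emulated: the optical point-spread function, uneven illumination, and
stitching seams of real confocal montages — recovery on these scenes bounds
segmentation logic, not microscope physics.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw

from .errors import FeasibilityError, ParameterError
from .io import ChannelStack

__all__ = [
    "SceneSpec",
    "SceneObject",
    "GroundTruth",
    "generate_viability_scene",
    "generate_fusion_scene",
]

_SEP_PX = 3  # minimum background gap between placed structures
_MAX_TRIES = 5000


@dataclasses.dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic scene; identical spec + seed reproduce the
    scene bit-for-bit."""

    height_px: int = 1024
    width_px: int = 1024
    pixel_size_um: float = 0.8
    n_single_nuclei: int = 100
    nucleus_area_range_um2: tuple[float, float] = (120.0, 200.0)
    clumps: tuple[int, ...] = ()
    myotubes: tuple[int, ...] = ()
    small_myh_cells: tuple[int, ...] = ()
    noise_sd: float = 0.0
    intensity_levels: tuple[float, float, float] = (20.0, 200.0, 230.0)
    seed: int = 0
    clump_modal_area_um2: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.nucleus_area_range_um2
        if not 0 < lo <= hi:
            raise ParameterError("nucleus area range must satisfy 0 < low <= high")
        if any(m < 3 for m in self.myotubes):
            raise ParameterError("every myotube must enclose >= 3 nuclei")
        if any(s not in (1, 2) for s in self.small_myh_cells):
            raise ParameterError("small MYH cells hold 1 or 2 nuclei")
        if any(k < 2 for k in self.clumps):
            raise ParameterError("a clump holds >= 2 nuclei")
        modal = self.modal_area_um2
        # rough footprint bound: capsules cost ~8x a nucleus per enclosed nucleus
        occupied = (
            self.n_single_nuclei * 0.5 * (lo + hi)
            + sum(self.clumps) * modal
            + sum(self.myotubes) * modal * 8
            + sum(self.small_myh_cells) * modal * 8
        )
        image_um2 = self.height_px * self.width_px * self.pixel_size_um**2
        if occupied > 0.6 * image_um2:
            raise FeasibilityError(
                f"objects would occupy ~{occupied / image_um2:.0%} of the image "
                "(limit 60%)"
            )

    @property
    def modal_area_um2(self) -> float:
        if self.clump_modal_area_um2 is not None:
            return self.clump_modal_area_um2
        lo, hi = self.nucleus_area_range_um2
        return 0.5 * (lo + hi)


@dataclasses.dataclass(frozen=True)
class SceneObject:
    kind: str  # "nucleus" | "clump"
    center: tuple[float, float]
    area_um2: float
    n_nuclei: int
    structure: str  # "outside" | "myotube-<i>" | "small-<i>"


@dataclasses.dataclass
class GroundTruth:
    true_total_nuclei: int
    true_outside_nuclei: int
    true_small_myh_nuclei: int
    true_fusion_index_pct: float
    objects: list[SceneObject]


def _disk_structure(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    return (r[:, None] ** 2 + r[None, :] ** 2) <= radius**2


class _Builder:
    def __init__(self, spec: SceneSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        H, W = spec.height_px, spec.width_px
        bg = spec.intensity_levels[0]
        self.occ = np.zeros((H, W), dtype=bool)
        self.dapi = np.full((H, W), bg, dtype=np.float64)
        self.myh = np.full((H, W), bg, dtype=np.float64)
        self.objects: list[SceneObject] = []
        self.px2 = spec.pixel_size_um**2
        self._sep = _disk_structure(_SEP_PX)

    # -- geometry helpers ---------------------------------------------------

    def _nucleus_patch(self, area_um2: float) -> np.ndarray:
        area_px = area_um2 / self.px2
        q = self.rng.uniform(1.0, 1.8)
        minor = math.sqrt(area_px / (math.pi * q))
        major = q * minor
        theta = self.rng.uniform(0, math.pi)
        half = int(math.ceil(major)) + 2
        size = 2 * half + 1
        patch = np.zeros((size, size), dtype=bool)
        rr, cc = skdraw.ellipse(half, half, major, minor, shape=(size, size), rotation=theta)
        patch[rr, cc] = True
        return patch

    def _clump_patch(self, k: int) -> np.ndarray:
        """Rosette of k overlapping disks whose union area targets
        k x the modal singleton area (sharp test for area division)."""
        modal_px = self.spec.modal_area_um2 / self.px2
        target = k * modal_px
        r_single = math.sqrt(modal_px / math.pi)
        offset = 0.55 * r_single
        rot = self.rng.uniform(0, 2 * math.pi)
        radius = math.sqrt(target / math.pi)

        def render(radius: float) -> np.ndarray:
            half = int(math.ceil(radius + offset)) + 2
            size = 2 * half + 1
            patch = np.zeros((size, size), dtype=bool)
            for i in range(k):
                ang = rot + 2 * math.pi * i / k
                r0 = half + offset * math.sin(ang)
                c0 = half + offset * math.cos(ang)
                rr, cc = skdraw.disk((r0, c0), radius, shape=(size, size))
                patch[rr, cc] = True
            return patch

        for _ in range(4):
            patch = render(radius)
            actual = patch.sum()
            radius *= math.sqrt(target / actual)
        return render(radius)

    def _capsule_patch(self, half_len: float, radius: float, theta: float) -> np.ndarray:
        """Points within ``radius`` of the segment of half-length ``half_len``
        through the patch centre at angle ``theta``."""
        half = int(math.ceil(half_len + radius)) + 2
        size = 2 * half + 1
        yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
        ux, uy = math.cos(theta), math.sin(theta)
        proj = np.clip(xx * ux + yy * uy, -half_len, half_len)
        dx = xx - proj * ux
        dy = yy - proj * uy
        return dx**2 + dy**2 <= radius**2

    # -- placement ----------------------------------------------------------

    def _place(self, patch: np.ndarray) -> tuple[int, int]:
        """Rejection-sample a position where ``patch`` keeps a >= _SEP_PX gap
        to everything already placed. Returns the top-left corner of the
        padded patch and stamps the occupancy grid."""
        padded = np.pad(patch, _SEP_PX)
        grown = ndi.binary_dilation(padded, structure=self._sep)
        ph, pw = padded.shape
        H, W = self.occ.shape
        if ph >= H or pw >= W:
            raise FeasibilityError("object larger than the image")
        for _ in range(_MAX_TRIES):
            r0 = int(self.rng.integers(0, H - ph + 1))
            c0 = int(self.rng.integers(0, W - pw + 1))
            window = self.occ[r0 : r0 + ph, c0 : c0 + pw]
            if not (window & grown).any():
                window |= padded
                return r0, c0
        raise FeasibilityError(
            f"could not place an object after {_MAX_TRIES} attempts; "
            "reduce object count or enlarge the scene"
        )

    def _stamp(self, channel: np.ndarray, patch: np.ndarray, r0: int, c0: int, level: float) -> None:
        padded = np.pad(patch, _SEP_PX)
        window = channel[r0 : r0 + padded.shape[0], c0 : c0 + padded.shape[1]]
        window[padded] = level

    def _stamp_at(self, channel: np.ndarray, patch: np.ndarray, center: tuple[int, int], level: float) -> None:
        half_h, half_w = patch.shape[0] // 2, patch.shape[1] // 2
        r0, c0 = center[0] - half_h, center[1] - half_w
        window = channel[r0 : r0 + patch.shape[0], c0 : c0 + patch.shape[1]]
        window[patch] = level
        self.occ[r0 : r0 + patch.shape[0], c0 : c0 + patch.shape[1]] |= patch

    # -- object classes -----------------------------------------------------

    def add_single_nucleus(self, structure: str = "outside") -> None:
        lo, hi = self.spec.nucleus_area_range_um2
        patch = self._nucleus_patch(self.rng.uniform(lo, hi))
        r0, c0 = self._place(patch)
        self._stamp(self.dapi, patch, r0, c0, self.spec.intensity_levels[1])
        center = (r0 + patch.shape[0] / 2 + _SEP_PX, c0 + patch.shape[1] / 2 + _SEP_PX)
        self.objects.append(
            SceneObject("nucleus", center, patch.sum() * self.px2, 1, structure)
        )

    def add_clump(self, k: int) -> None:
        patch = self._clump_patch(k)
        r0, c0 = self._place(patch)
        self._stamp(self.dapi, patch, r0, c0, self.spec.intensity_levels[1])
        center = (r0 + patch.shape[0] / 2 + _SEP_PX, c0 + patch.shape[1] / 2 + _SEP_PX)
        self.objects.append(
            SceneObject("clump", center, patch.sum() * self.px2, k, structure="outside")
        )

    def _nucleus_major_bound(self) -> float:
        lo, hi = self.spec.nucleus_area_range_um2
        return math.sqrt(hi / self.px2 * 1.8 / math.pi)

    def add_myh_cell(self, n_nuclei: int, structure: str) -> None:
        """A capsule-shaped MYH-positive cell fully enclosing ``n_nuclei``
        nuclei with a comfortable (>= 4 px) interior margin."""
        major = self._nucleus_major_bound()
        spacing = 2 * major + 4
        radius = major + 6
        half_len = (n_nuclei - 1) * spacing / 2
        theta = self.rng.uniform(0, math.pi)
        capsule = self._capsule_patch(half_len, radius, theta)
        r0, c0 = self._place(capsule)
        self._stamp(self.myh, capsule, r0, c0, self.spec.intensity_levels[2])

        half = capsule.shape[0] // 2
        center_r = r0 + _SEP_PX + half
        center_c = c0 + _SEP_PX + half
        ur, uc = math.sin(theta), math.cos(theta)
        lo_a, hi_a = self.spec.nucleus_area_range_um2
        for i in range(n_nuclei):
            along = (i - (n_nuclei - 1) / 2) * spacing
            jitter = self.rng.uniform(-2.0, 2.0)
            nr = int(round(center_r + along * ur + jitter * uc))
            nc = int(round(center_c + along * uc - jitter * ur))
            patch = self._nucleus_patch(self.rng.uniform(lo_a, hi_a))
            self._stamp_at(self.dapi, patch, (nr, nc), self.spec.intensity_levels[1])
            self.objects.append(
                SceneObject("nucleus", (nr, nc), patch.sum() * self.px2, 1, structure)
            )

    # -- finalisation -------------------------------------------------------

    def finish_channel(self, channel: np.ndarray) -> np.ndarray:
        if self.spec.noise_sd > 0:
            channel = channel + self.rng.normal(0.0, self.spec.noise_sd, channel.shape)
        return np.clip(np.rint(channel), 0, 255).astype(np.uint8)


def _truth(spec: SceneSpec, objects: list[SceneObject]) -> GroundTruth:
    total = spec.n_single_nuclei + sum(spec.clumps) + sum(spec.myotubes) + sum(
        spec.small_myh_cells
    )
    outside = spec.n_single_nuclei + sum(spec.clumps)
    small = sum(spec.small_myh_cells)
    index = 0.0 if total == 0 else (total - outside - small) / total * 100.0
    return GroundTruth(total, outside, small, index, objects)


def generate_viability_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a DAPI-only scene (singles + clumps); returns the uint8 image
    and its ground truth."""
    builder = _Builder(spec)
    for k in spec.clumps:
        builder.add_clump(k)
    for _ in range(spec.n_single_nuclei):
        builder.add_single_nucleus()
    dapi = builder.finish_channel(builder.dapi)
    return dapi, _truth(spec, builder.objects)


def generate_fusion_scene(spec: SceneSpec) -> tuple[ChannelStack, GroundTruth]:
    """Render a two-channel (DAPI, MYH) fusion scene: myotubes (>= 3 nuclei
    each), 1–2-nucleus MYH cells, clumps, and outside singles."""
    builder = _Builder(spec)
    for i, m in enumerate(spec.myotubes):
        builder.add_myh_cell(m, structure=f"myotube-{i}")
    for i, s in enumerate(spec.small_myh_cells):
        builder.add_myh_cell(s, structure=f"small-{i}")
    for k in spec.clumps:
        builder.add_clump(k)
    for _ in range(spec.n_single_nuclei):
        builder.add_single_nucleus()
    dapi = builder.finish_channel(builder.dapi)
    myh = builder.finish_channel(builder.myh)
    stack = ChannelStack(
        [dapi, myh], spec.pixel_size_um, 255.0, {"dapi": 0, "myh": 1}
    )
    return stack, _truth(spec, builder.objects)
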