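"""Calibrated image input/output, CSV result tables, and QC overlays.

Images are single- or multi-page grayscale TIFFs (one page per channel; LSM
files readable as TIFF dialects work the same way). The µm/pixel calibration
is taken from TIFF resolution metadata or supplied explicitly — it is never
silently defaulted, because every area downstream is ``pixels × µm²``.
"""

from __future__ import annotations

import csv
import dataclasses

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage.segmentation import find_boundaries

from .errors import CalibrationError, ConfigurationError, FormatError, GeometryError

__all__ = [
    "ChannelStack",
    "ResultsTable",
    "load_stack",
    "save_stack",
    "write_results_csv",
    "read_results_csv",
    "write_overlay",
]

DEFAULT_CHANNEL_ORDER = {"dapi": 0, "myh": 1}

_UNIT_TO_UM = {2: 25400.0, 3: 10000.0}  # ResolutionUnit: inch, centimetre


@dataclasses.dataclass
class ChannelStack:
    """An ordered set of same-shaped 2-D intensity channels with isotropic
    µm/pixel calibration.

    ``channel_order`` maps a role name (``"dapi"``, ``"myh"``) to a channel
    index; :meth:`channel` retrieves a channel by role.
    """

    channels: list[np.ndarray]
    pixel_size_um: float
    bit_depth_max: float
    channel_order: dict[str, int] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise FormatError("stack holds no channels")
        shape = self.channels[0].shape
        for ch in self.channels:
            if ch.ndim != 2 or ch.shape != shape:
                raise GeometryError("all channels must be 2-D with identical shape")
        if not self.pixel_size_um > 0:
            raise CalibrationError("pixel_size_um must be > 0")
        for ch in self.channels:
            if ch.size and (float(ch.min()) < 0 or float(ch.max()) > self.bit_depth_max):
                raise FormatError("intensities outside [0, bit_depth_max]")
        if not self.channel_order:
            order = {"dapi": 0}
            if len(self.channels) > 1:
                order["myh"] = 1
            self.channel_order = order
        for role, idx in self.channel_order.items():
            if not 0 <= idx < len(self.channels):
                raise ConfigurationError(
                    f"channel_order[{role!r}] = {idx} out of range for "
                    f"{len(self.channels)} channel(s)"
                )

    @property
    def height_px(self) -> int:
        return self.channels[0].shape[0]

    @property
    def width_px(self) -> int:
        return self.channels[0].shape[1]

    @property
    def image_area_mm2(self) -> float:
        return self.height_px * self.width_px * self.pixel_size_um**2 / 1e6

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channel_order:
            raise ConfigurationError(f"no channel with role {role!r} in stack")
        return self.channels[self.channel_order[role]]


@dataclasses.dataclass
class ResultsTable:
    """Ordered (field, value) rows; values may be scalars or lists of numbers."""

    rows: list[tuple[str, object]] = dataclasses.field(default_factory=list)

    def add(self, name: str, value) -> "ResultsTable":
        if any(name == n for n, _ in self.rows):
            raise ValueError(f"duplicate field {name!r}")
        self.rows.append((name, value))
        return self


def _pixel_size_from_tiff(tf: tifffile.TiffFile) -> float | None:
    page = tf.pages[0]
    tags = page.tags
    xres = tags.get("XResolution")
    yres = tags.get("YResolution")
    if xres is None or yres is None:
        return None

    def per_unit(tag) -> float | None:
        num, den = tag.value
        if num == 0:
            return None
        return num / den

    px_per_unit_x = per_unit(xres)
    px_per_unit_y = per_unit(yres)
    if px_per_unit_x is None or px_per_unit_y is None:
        return None

    unit_tag = tags.get("ResolutionUnit")
    unit = int(unit_tag.value) if unit_tag is not None else 1
    if unit in _UNIT_TO_UM:
        scale = _UNIT_TO_UM[unit]
    else:
        # ImageJ-style TIFFs: unit NONE with a metadata unit of microns.
        ij = tf.imagej_metadata or {}
        if str(ij.get("unit", "")).lower() in {"um", "micron", "microns", "µm"}:
            scale = 1.0
        else:
            return None
    px_x = scale / px_per_unit_x
    px_y = scale / px_per_unit_y
    if abs(px_x - px_y) > 1e-6 * max(px_x, px_y):
        raise CalibrationError(
            f"anisotropic pixel size ({px_x:g} x {px_y:g} um); areas assume isotropy"
        )
    return px_x


def load_stack(
    path,
    pixel_size_override: float | None = None,
    channel_order: dict[str, int] | None = None,
) -> ChannelStack:
    """Read a TIFF into a :class:`ChannelStack`, one channel per page.

    ``pixel_size_override`` (µm/px) wins over file metadata. A file without
    resolution metadata and without an override raises
    :class:`CalibrationError`.
    """
    try:
        with tifffile.TiffFile(path) as tf:
            channels = [np.asarray(p.asarray()) for p in tf.pages]
            meta_px = _pixel_size_from_tiff(tf)
    except CalibrationError:
        raise
    except FileNotFoundError as exc:
        raise FormatError(f"no such file: {path}") from exc
    except Exception as exc:  # tifffile raises several format-specific types
        raise FormatError(f"unreadable TIFF {path}: {exc}") from exc

    for ch in channels:
        if ch.ndim != 2:
            raise FormatError("only single-plane grayscale pages are supported")

    if pixel_size_override is not None:
        if not pixel_size_override > 0:
            raise CalibrationError("pixel size override must be > 0")
        px = float(pixel_size_override)
    elif meta_px is not None:
        px = float(meta_px)
    else:
        raise CalibrationError(
            f"no pixel size in metadata of {path} and no override given; "
            "supply the um/px calibration explicitly"
        )

    dtype = channels[0].dtype
    if np.issubdtype(dtype, np.integer):
        bmax = float(np.iinfo(dtype).max)
    else:
        bmax = max(255.0, max(float(ch.max()) for ch in channels))
    return ChannelStack(channels, px, bmax, dict(channel_order or {}))


def save_stack(stack: ChannelStack, path) -> None:
    """Write a stack as a multi-page grayscale TIFF with µm calibration
    (stored as pixels-per-centimetre resolution). Lossless for intensities."""
    data = np.stack(stack.channels)
    res = 10000.0 / stack.pixel_size_um  # pixels per centimetre
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        resolution=(res, res),
        resolutionunit=3,
    )


def _format_number(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return str(int(v))
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return format(float(v), ".10g")


def write_results_csv(table: ResultsTable, path) -> None:
    """Serialize a :class:`ResultsTable` to CSV with a ``field,value`` header.

    List-valued fields expand to one row per element. Numbers are written with
    10 significant digits.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["field", "value"])
        for name, value in table.rows:
            if isinstance(value, (list, tuple, np.ndarray)):
                for elem in np.asarray(value).ravel():
                    writer.writerow([name, _format_number(elem)])
            else:
                writer.writerow([name, _format_number(value)])


def read_results_csv(path) -> dict[str, float | list[float]]:
    """Inverse of :func:`write_results_csv`: repeated field names regroup into
    lists, single rows stay scalar."""
    grouped: dict[str, list[float]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:2] != ["field", "value"]:
            raise FormatError(f"{path} is not a myofuse results CSV")
        for name, value in reader:
            if name not in grouped:
                grouped[name] = []
                order.append(name)
            grouped[name].append(float(value))
    return {n: (grouped[n][0] if len(grouped[n]) == 1 else grouped[n]) for n in order}


NUCLEI_OUTLINE_RGB = (0, 0, 255)
MYOTUBE_OUTLINE_RGB = (255, 255, 0)


def write_overlay(
    stack: ChannelStack,
    nuclei_labels: np.ndarray,
    myotube_mask: np.ndarray | None,
    path,
) -> None:
    """Write a PNG of the merged channels with nuclei outlines (pure blue) and,
    when given, the myotube mask outline (yellow).

    The merged base image uses only the red (DAPI) and green (MYH) planes and
    is scaled to at most 250, so outline pixels are exact-color and can be
    recovered from the written file.
    """
    nuclei_labels = np.asarray(nuclei_labels)
    shape = (stack.height_px, stack.width_px)
    if nuclei_labels.shape != shape:
        raise GeometryError("label map shape does not match stack")
    if myotube_mask is not None and np.asarray(myotube_mask).shape != shape:
        raise GeometryError("myotube mask shape does not match stack")

    scale = 250.0 / stack.bit_depth_max
    rgb = np.zeros(shape + (3,), dtype=np.uint8)
    rgb[..., 0] = np.clip(stack.channel("dapi") * scale, 0, 250).astype(np.uint8)
    if "myh" in stack.channel_order:
        rgb[..., 1] = np.clip(stack.channel("myh") * scale, 0, 250).astype(np.uint8)

    if myotube_mask is not None:
        tube_edge = find_boundaries(np.asarray(myotube_mask, bool), mode="inner")
        rgb[tube_edge] = MYOTUBE_OUTLINE_RGB
    if nuclei_labels.max() > 0:
        nuc_edge = find_boundaries(nuclei_labels, mode="inner") & (nuclei_labels > 0)
        rgb[nuc_edge] = NUCLEI_OUTLINE_RGB
    iio.imwrite(path, rgb, extension=".png")
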