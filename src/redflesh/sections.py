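"""Fruit-section detection on flatbed-scanner images.

A scan shows up to four fruit sections on the bright white scanner field.
Segmentation is intentionally simple and deterministic: Otsu's threshold on
the BT.601 luminance separates flesh from background, 8-connected component
labelling isolates each section, and small specks are dropped by an area
filter.  Touching sections are not split; the acquisition protocol spaces
the fruits on the scanner glass.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.measure import label, regionprops

__all__ = [
    "ScanImage",
    "SectionObject",
    "load_scan",
    "otsu_threshold",
    "extract_sections",
    "save_sections",
]


@dataclass
class ScanImage:
    """An 8-bit sRGB scanner image of H×W pixels."""

    pixels: np.ndarray  # (H, W, 3) uint8
    source_id: str
    dpi: float | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[-1] != 3:
            raise ValueError("ScanImage.pixels must have shape (H, W, 3)")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("empty image")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class SectionObject:
    """One segmented fruit section, cropped to its bounding box.

    ``bbox`` is half-open ``(row0, col0, row1, col1)`` in parent-image
    coordinates; ``mask`` and ``pixels`` are aligned to the crop.
    """

    label: int
    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    pixels: np.ndarray
    area_px: int


class ScanFormatError(ValueError):
    pass


def load_scan(path: str | Path) -> ScanImage:
    """Read a PNG scan as 8-bit RGB.

    16-bit inputs are rescaled to 8-bit; an alpha channel is dropped.
    Grayscale-only files are rejected — the pipeline needs colour.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # truncated / undecodable file
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if arr.ndim == 2:
        raise ScanFormatError(f"{path} is grayscale; an RGB scan is required")
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.shape[-1] != 3:
        raise ScanFormatError(f"{path}: unsupported channel count {arr.shape[-1]}")
    if arr.dtype == np.uint16:
        arr = (arr >> 8).astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return ScanImage(pixels=arr, source_id=path.stem)


def luminance(rgb: np.ndarray) -> np.ndarray:
    """BT.601 luma of an 8-bit RGB array, as float in [0, 255]."""
    arr = np.asarray(rgb, dtype=float)
    return arr[..., 0] * 0.299 + arr[..., 1] * 0.587 + arr[..., 2] * 0.114


class DegenerateImageError(ValueError):
    pass


def otsu_threshold(gray: np.ndarray) -> int:
    """Otsu's threshold over the 256-bin histogram of an 8-bit grayscale image.

    Returns the integer ``t`` in [1, 255] maximising the between-class
    variance ω₀ω₁(µ₀−µ₁)² of the split {v < t} vs {v ≥ t}; the smallest
    maximiser wins ties.  Computed by exhaustive evaluation of all split
    points via cumulative sums.
    """
    vals = np.asarray(gray)
    if np.issubdtype(vals.dtype, np.floating):
        vals = np.clip(np.round(vals), 0, 255).astype(np.intp)
    hist = np.bincount(vals.ravel(), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError("constant image: no separable classes")
    total = hist.sum()
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist)[:-1]            # weight of {v < t} for t = 1..255
    w1 = total - w0
    cum_mean = np.cumsum(hist * levels)[:-1]
    mu0 = np.where(w0 > 0, cum_mean / np.where(w0 > 0, w0, 1), 0.0)
    grand = (hist * levels).sum()
    mu1 = np.where(w1 > 0, (grand - cum_mean) / np.where(w1 > 0, w1, 1), 0.0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    return int(np.argmax(between)) + 1


def extract_sections(
    scan: ScanImage,
    min_area: int | None = None,
    *,
    invert: bool = False,
) -> list[SectionObject]:
    """Segment and crop the fruit sections in a scan.

    Foreground is everything strictly darker than the Otsu threshold
    (``invert=True`` flips the polarity for dark backgrounds).  Components
    are 8-connected; those smaller than ``min_area`` (default 1% of the
    image) are discarded as dust.  Sections are returned row-major by
    bounding-box origin so replicate numbering is deterministic.
    """
    h, w = scan.shape
    if min_area is None:
        min_area = max(1, int(0.01 * h * w))
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    gray = luminance(scan.pixels)
    t = otsu_threshold(gray)
    fg = gray >= t if invert else gray < t
    labelled = label(fg, connectivity=2)
    out = []
    for region in regionprops(labelled):
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        out.append(
            (
                (r0, c0),
                SectionObject(
                    label=0,  # assigned after ordering
                    mask=labelled[r0:r1, c0:c1] == region.label,
                    bbox=(r0, c0, r1, c1),
                    pixels=scan.pixels[r0:r1, c0:c1].copy(),
                    area_px=int(region.area),
                ),
            )
        )
    out.sort(key=lambda item: item[0])
    sections = []
    for k, (_, sec) in enumerate(out, start=1):
        sec.label = k
        sections.append(sec)
    return sections


def save_sections(
    scan: ScanImage, sections: list[SectionObject], out_dir: str | Path
) -> list[Path]:
    """Write per-section PNG crops named ``<scan_id>_s<k>.png``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sec in sections:
        p = out_dir / f"{scan.source_id}_s{sec.label}.png"
        iio.imwrite(p, sec.pixels)
        paths.append(p)
    return paths
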