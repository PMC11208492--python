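"""Particle analysis of binarized mitochondria.

Per-object measurements mirror the ImageJ particle analyzer: count (c),
area (a), perimeter (p), minor/major fitted-ellipse axes (x, y), and the
two shape descriptors built from them,

    aspect ratio   AR = y / x
    form factor    FF = p^2 / (4*pi*a)

AR = FF = 1 for a circle; elongation raises AR, boundary irregularity and
elongation raise FF.

The perimeter uses the 4-direction Crofton estimator rather than a raw
pixel-edge count: FF is quadratic in p, and the raw edge count biases FF
of digitized disks high by ~27%.  Documented bias band of the Crofton
perimeter: within about +4% for digitized disks of r >= 10 px (shrinking
as r grows, so disk FF decreases monotonically toward 1) and about -6%
for right-angled corners (it rounds them), hence FF of sharp-cornered
polygons reads up to ~12% below the ideal-measure arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import perimeter_crofton, regionprops


@dataclass
class MorphRecord:
    """Measurements of one labeled particle.  Lengths in px, areas in px²;
    physical variants derived with ``pixel_size`` (nm)."""

    object_id: int
    area_px: float
    perimeter_px: float
    minor_px: float
    major_px: float
    aspect_ratio: float
    form_factor: float
    centroid: tuple[float, float]
    pixel_size: float

    @property
    def area_um2(self) -> float:
        return self.area_px * (self.pixel_size / 1000.0) ** 2

    @property
    def perimeter_um(self) -> float:
        return self.perimeter_px * self.pixel_size / 1000.0


def binarize(image: np.ndarray, nbins: int = 256) -> tuple[np.ndarray, float]:
    """Otsu-threshold a background-subtracted image.

    Returns ``(mask, threshold)``.  Constant images have no foreground and
    raise.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.max() == img.min():
        raise ValueError("cannot binarize a constant image")
    thr = float(threshold_otsu(img, nbins=nbins))
    return img > thr, thr


def label_particles(
    mask: np.ndarray, connectivity: int = 8, min_area_px: int = 4
) -> tuple[np.ndarray, int]:
    """Label connected components, discarding specks below ``min_area_px``.

    Returns ``(labeled, count)``; surviving labels are renumbered 1..count.
    An empty mask yields count 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=bool)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValueError("connectivity must be 4 or 8")
    labeled, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return labeled, 0
    sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_area_px) + 1
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    return remap[labeled], int(len(keep))


def _fit_ellipse_axes(region) -> tuple[float, float]:
    """Minor/major axes of the second-moment ellipse, rescaled so the
    ellipse area equals the particle area (ImageJ 'Fit Ellipse')."""
    major = region.axis_major_length
    minor = region.axis_minor_length
    if minor <= 0 or major <= 0:
        # degenerate (line-like) object: fall back to bbox extents
        h = region.bbox[2] - region.bbox[0]
        w = region.bbox[3] - region.bbox[1]
        major, minor = float(max(h, w)), float(max(min(h, w), 1))
    moment_area = np.pi * major * minor / 4.0
    scale = np.sqrt(region.area / moment_area)
    return minor * scale, major * scale


def measure(labeled: np.ndarray, pixel_size: float = 32.0) -> list[MorphRecord]:
    """Measure every labeled particle.

    Area is the pixel count; perimeter the 4-direction Crofton contour
    length; axes follow the area-matched moment-ellipse convention.  AR
    and FF are computed from these per the definitions in the module
    docstring.
    """
    labeled = np.asarray(labeled)
    records: list[MorphRecord] = []
    for region in regionprops(labeled):
        a = float(region.area)
        p = float(perimeter_crofton(labeled == region.label, directions=4))
        if p <= 0:  # single-pixel object
            p = 4.0
        minor, major = _fit_ellipse_axes(region)
        records.append(
            MorphRecord(
                object_id=int(region.label),
                area_px=a,
                perimeter_px=p,
                minor_px=minor,
                major_px=major,
                aspect_ratio=aspect_ratio(minor, major),
                form_factor=form_factor(p, a),
                centroid=tuple(region.centroid),
                pixel_size=pixel_size,
            )
        )
    return records


def aspect_ratio(x: float, y: float) -> float:
    """AR = y/x with the axes ordered so y >= x > 0."""
    if x <= 0 or y <= 0:
        raise ValueError(f"axes must be positive, got ({x}, {y})")
    x, y = sorted((x, y))
    return y / x


def form_factor(p: float, a: float) -> float:
    """FF = p² / (4·π·a)."""
    if p <= 0 or a <= 0:
        raise ValueError(f"perimeter and area must be positive, got ({p}, {a})")
    return p * p / (4.0 * np.pi * a)


def frame_summary(records: list[MorphRecord]) -> dict[str, float]:
    """Per-frame aggregate: count and unweighted means of a, AR, FF."""
    if not records:
        return {"c": 0, "mean_area_px": np.nan, "mean_AR": np.nan, "mean_FF": np.nan}
    return {
        "c": len(records),
        "mean_area_px": float(np.mean([r.area_px for r in records])),
        "mean_AR": float(np.mean([r.aspect_ratio for r in records])),
        "mean_FF": float(np.mean([r.form_factor for r in records])),
    }
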