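"""Image preprocessing shared by all metrics.

Background subtraction follows the sliding-window local-statistic idea:
a local median (or minimum) is evaluated on a coarse grid with a stride of
a quarter window, bilinearly interpolated to full resolution, subtracted,
and the result clamped at zero.  Structures much smaller than the window
survive essentially unchanged; smooth background larger than the window is
removed.

Also provides the overlay of raw structured-illumination pattern frames
into a pseudo-widefield image, reference/object ratio images, histogram
matching of foreground medians, and the Beer–Lambert helper used to
re-calibrate dye stock concentrations from absorbance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from skimage.filters import threshold_otsu


@dataclass
class BackgroundModel:
    """A smooth background surface estimated from one image."""

    window_diameter: int
    estimator: str
    surface: np.ndarray


def estimate_background(
    image: np.ndarray,
    window_diameter: int = 50,
    estimator: str = "local-median",
) -> BackgroundModel:
    """Estimate a smooth background surface by a sliding-window statistic.

    The statistic (median or minimum) is computed over ``window_diameter``
    squares centred on a grid with quarter-window stride, then bilinearly
    interpolated back to full resolution.  If the window exceeds both image
    dimensions the estimate degrades to a single global scalar (with a
    warning).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("background estimation expects a 2D image")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    if window_diameter < 3:
        raise ValueError("window_diameter must be >= 3 px")
    stat = {"local-median": np.median, "local-minimum": np.min}.get(estimator)
    if stat is None:
        raise ValueError(f"unknown estimator {estimator!r}")

    h, w = img.shape
    if window_diameter > h and window_diameter > w:
        warnings.warn(
            "background window larger than the image; using a global scalar",
            stacklevel=2,
        )
        surface = np.full_like(img, float(stat(img)))
        return BackgroundModel(window_diameter, estimator, surface)

    half = window_diameter / 2.0
    stride = max(1, window_diameter // 4)
    rows = np.arange(0, h, stride, dtype=float)
    cols = np.arange(0, w, stride, dtype=float)
    if rows[-1] != h - 1:
        rows = np.append(rows, h - 1)
    if cols[-1] != w - 1:
        cols = np.append(cols, w - 1)
    grid = np.empty((len(rows), len(cols)))
    for i, r in enumerate(rows):
        r0, r1 = max(0, int(np.floor(r - half))), min(h, int(np.ceil(r + half)) + 1)
        for j, c in enumerate(cols):
            c0, c1 = max(0, int(np.floor(c - half))), min(w, int(np.ceil(c + half)) + 1)
            grid[i, j] = stat(img[r0:r1, c0:c1])
    interp = RegularGridInterpolator(
        (rows, cols), grid, method="linear", bounds_error=False, fill_value=None
    )
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    surface = interp(np.stack([rr.ravel(), cc.ravel()], axis=1)).reshape(h, w)
    surface = np.maximum(surface, 0.0)
    return BackgroundModel(window_diameter, estimator, surface)


def subtract_background(
    image: np.ndarray,
    window_diameter: int = 50,
    estimator: str = "local-median",
) -> np.ndarray:
    """Subtract a smooth local background and clamp at zero.

    Foreground objects much smaller than the window retain their
    background-free amplitude; constant images map to (numerically) zero.
    """
    model = estimate_background(image, window_diameter, estimator)
    return np.maximum(np.asarray(image, dtype=np.float64) - model.surface, 0.0)


def sim_overlay(stack: np.ndarray, expected_frames: int = 15, mode: str = "mean") -> np.ndarray:
    """Collapse a raw SIM pattern stack into a pseudo-widefield image.

    Structured illumination acquires ``expected_frames`` (15 on the
    reference instrument) differently patterned exposures per plane; their
    pixel-wise mean is a conventional widefield image usable for
    intensiometric readouts.  ``mode="sum"`` gives the additive variant.
    The frame count is enforced unless ``expected_frames=None``.
    """
    arr = np.asarray(stack, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("expected a stack of 2D pattern frames")
    if expected_frames is not None and len(arr) != expected_frames:
        raise ValueError(
            f"expected {expected_frames} pattern images, got {len(arr)}"
        )
    if mode == "mean":
        return arr.mean(axis=0)
    if mode == "sum":
        return arr.sum(axis=0)
    raise ValueError(f"unknown overlay mode {mode!r}")


def foreground_median(image: np.ndarray) -> float:
    """Median intensity over the Otsu-positive foreground."""
    img = np.asarray(image, dtype=np.float64)
    if img.max() == img.min():
        raise ValueError("image has no foreground (constant intensities)")
    mask = img > threshold_otsu(img, nbins=256)
    if not mask.any():
        raise ValueError("empty Otsu foreground")
    return float(np.median(img[mask]))


def ratio_image(
    numerator: np.ndarray,
    denominator: np.ndarray,
    floor: float | None = None,
    floor_frac: float = 0.01,
) -> np.ndarray:
    """Element-wise ratio with a positive floor on the denominator.

    The denominator is clipped below at ``floor`` before dividing; pixels
    where *both* channels fall below the floor are set to 0 (undefined
    region, typically background).  By default the floor is ``floor_frac``
    of the denominator's foreground median, which keeps the rim ("halo")
    of dim-object frames finite without masking it out.
    """
    num = np.asarray(numerator, dtype=np.float64)
    den = np.asarray(denominator, dtype=np.float64)
    if num.shape != den.shape:
        raise ValueError("ratio channels must share a shape")
    if floor is None:
        floor = floor_frac * foreground_median(den)
    if not floor > 0:
        raise ValueError(f"ratio floor must be positive, got {floor}")
    out = num / np.maximum(den, floor)
    out[(num < floor) & (den < floor)] = 0.0
    return out


def match_intensity(image: np.ndarray, target_median: float) -> tuple[np.ndarray, float]:
    """Scale an image so its Otsu-foreground median equals ``target_median``.

    Returns ``(scaled_image, factor)``.  Mirrors the acquisition-side
    practice of adjusting excitation power so intensity histograms match
    across dye loads; provided for post-hoc use and off by default in the
    pipeline.
    """
    med = foreground_median(image)
    if med <= 0:
        raise ValueError("foreground median is zero; cannot match intensity")
    factor = target_median / med
    return np.asarray(image, dtype=np.float64) * factor, factor


def tmrm_concentration(A: float, epsilon: float, l: float) -> tuple[float, float]:
    """Molar dye concentration from absorbance via Beer–Lambert, c = A/(ε·l).

    Parameters
    ----------
    A : float
        Absorbance at 550 nm (dimensionless, >= 0).
    epsilon : float
        Molar extinction coefficient at 550 nm in the solvent used
        (M^-1 cm^-1, > 0).  Instrument/lot specific; must be supplied.
    l : float
        Optical path length (cm, > 0).

    Returns
    -------
    (c_molar, c_nanomolar)
    """
    if not epsilon > 0:
        raise ValueError(f"extinction coefficient must be > 0, got {epsilon}")
    if not l > 0:
        raise ValueError(f"path length must be > 0, got {l}")
    if A < 0:
        raise ValueError(f"absorbance must be >= 0, got {A}")
    c = A / (epsilon * l)
    return c, c * 1e9
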