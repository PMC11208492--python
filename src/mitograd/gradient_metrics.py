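"""The two membrane-potential-gradient readouts.

Both metrics compare a potential-dependent *object* dye (TMRM) against a
geometric *reference* dye (MTG) on the same mitochondrion:

* **IBM association index** — the reference channel is Otsu-thresholded;
  one binary erosion gives a *core* mask (proxy for the cristae-membrane
  region), two dilations minus the core give a hollow *rim* mask (proxy
  for the inner boundary membrane).  The index is the ratio of mean
  object-channel intensity over rim to that over core: higher means more
  dye at the IBM, i.e. a shallower cristae-vs-IBM potential gradient.

* **ΔFWHM** — width-averaged cross-section intensity profiles are taken
  perpendicular to the tube axis in both channels at identical
  coordinates; the full width at half maximum of each is found with
  subpixel linear interpolation.  ``delta = FWHM_obj − FWHM_ref``: the
  more negative, the more the object dye is concentrated in the cristae
  (narrower than the reference envelope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

SQUARE_3x3 = np.ones((3, 3), dtype=bool)  # ImageJ default binary element


class ProfileNotResolvedError(ValueError):
    """A profile does not cross half-maximum on both sides of its peak."""


@dataclass
class MitoMasks:
    """Whole/core/rim masks derived from the reference channel."""

    whole: np.ndarray
    core: np.ndarray
    rim: np.ndarray
    erode_iters: int
    dilate_iters: int
    threshold: float
    structuring_element: str = "3x3 square (8-connected)"

    def __post_init__(self) -> None:
        assert self.core.dtype == bool and self.rim.dtype == bool
        assert not (self.core & self.rim).any(), "core and rim overlap"


@dataclass
class IbmIndexResult:
    mean_rim: float
    mean_core: float
    index: float
    n_rim_px: int
    n_core_px: int


@dataclass
class LineProfile:
    """Width-averaged cross-section profile sampled in both channels."""

    positions: np.ndarray          # px along the section, uniformly spaced
    values_ref: np.ndarray
    values_obj: np.ndarray
    width: float                   # averaging width, px
    endpoints: tuple[tuple[float, float], tuple[float, float]]
    pixel_size: float              # nm per px

    @property
    def positions_nm(self) -> np.ndarray:
        return self.positions * self.pixel_size


@dataclass
class FwhmResult:
    fwhm_ref: float                # px
    fwhm_obj: float                # px
    delta: float                   # px, sign per convention
    pixel_size: float
    crossings: tuple[float, float, float, float] = field(default=(np.nan,) * 4)

    @property
    def delta_nm(self) -> float:
        return self.delta * self.pixel_size


def reference_masks(
    reference_image: np.ndarray,
    erode_iters: int = 1,
    dilate_iters: int = 2,
    otsu_bins: int = 256,
) -> MitoMasks:
    """Build whole/core/rim masks from a background-subtracted reference.

    whole = Otsu foreground; core = whole eroded ``erode_iters`` times;
    rim = (whole dilated ``dilate_iters`` times) minus core — the hollow
    structure tracing the mitochondrial periphery.  Raises if the
    foreground is empty or if erosion removes every object entirely.
    """
    img = np.asarray(reference_image, dtype=np.float64)
    if img.max() == img.min():
        raise ValueError("no reference foreground (constant image)")
    thr = float(threshold_otsu(img, nbins=otsu_bins))
    whole = img > thr
    if not whole.any():
        raise ValueError("no reference foreground (empty Otsu mask)")
    core = whole.copy()
    for _ in range(erode_iters):
        core = ndimage.binary_erosion(core, structure=SQUARE_3x3, border_value=0)
    dilated = whole.copy()
    for _ in range(dilate_iters):
        dilated = ndimage.binary_dilation(dilated, structure=SQUARE_3x3, border_value=0)
    if erode_iters > 0 and not core.any():
        labels, n = ndimage.label(whole, structure=SQUARE_3x3)
        sizes = ndimage.sum_labels(whole, labels, index=range(1, n + 1))
        raise ValueError(
            f"erosion emptied the core mask: all {n} objects thinner than "
            f"{2 * erode_iters + 1} px (sizes {sizes.astype(int).tolist()})"
        )
    rim = dilated & ~core
    return MitoMasks(whole, core, rim, erode_iters, dilate_iters, thr)


def ibm_association_index(object_image: np.ndarray, masks: MitoMasks) -> IbmIndexResult:
    """Ratio of mean object intensity over rim to that over core.

    Values above the resting baseline indicate relative redistribution of
    the potential-dependent dye toward the inner boundary membrane.
    """
    obj = np.asarray(object_image, dtype=np.float64)
    if obj.shape != masks.whole.shape:
        raise ValueError("object image and masks differ in shape")
    n_core = int(masks.core.sum())
    n_rim = int(masks.rim.sum())
    if n_core == 0:
        raise ValueError("core mask is empty; index undefined")
    mean_core = float(obj[masks.core].mean())
    mean_rim = float(obj[masks.rim].mean()) if n_rim else 0.0
    if mean_core <= 0:
        raise ValueError("mean core intensity is zero; index undefined")
    return IbmIndexResult(mean_rim, mean_core, mean_rim / mean_core, n_rim, n_core)


def cross_profile(
    reference: np.ndarray,
    obj: np.ndarray,
    endpoints: tuple[tuple[float, float], tuple[float, float]],
    width: float = 50.0,
    spacing: float = 0.5,
    pixel_size: float = 32.0,
) -> LineProfile:
    """Width-averaged intensity profile along a segment, both channels.

    At each sample position along the segment from ``endpoints[0]`` to
    ``endpoints[1]`` (row, col pixel coordinates), intensity is the mean
    of bilinear samples taken along the perpendicular over ±width/2, at
    1 px steps.  Both channels are sampled at identical coordinates, so
    their FWHMs are directly comparable.
    """
    (r0, c0), (r1, c1) = endpoints
    ref = np.asarray(reference, dtype=np.float64)
    obj = np.asarray(obj, dtype=np.float64)
    h, w = ref.shape
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
            raise ValueError(f"endpoint ({r}, {c}) outside the image")
    if width < 1:
        raise ValueError("profile width must be >= 1 px")
    dr, dc = r1 - r0, c1 - c0
    length = float(np.hypot(dr, dc))
    if length < 4:
        raise ValueError("profile segment shorter than 4 px")
    ur, uc = dr / length, dc / length       # along-section unit vector
    pr, pc = -uc, ur                        # perpendicular unit vector
    n_samples = int(np.floor(length / spacing)) + 1
    positions = np.arange(n_samples) * spacing
    n_side = int(np.floor(width / 2))
    offsets = np.arange(-n_side, n_side + 1, dtype=np.float64)
    rows = r0 + positions[:, None] * ur + offsets[None, :] * pr
    cols = c0 + positions[:, None] * uc + offsets[None, :] * pc
    coords = np.stack([rows.ravel(), cols.ravel()])
    vals_ref = ndimage.map_coordinates(ref, coords, order=1, mode="nearest")
    vals_obj = ndimage.map_coordinates(obj, coords, order=1, mode="nearest")
    shape = (n_samples, len(offsets))
    return LineProfile(
        positions=positions,
        values_ref=vals_ref.reshape(shape).mean(axis=1),
        values_obj=vals_obj.reshape(shape).mean(axis=1),
        width=width,
        endpoints=endpoints,
        pixel_size=pixel_size,
    )


def fwhm_subpixel(
    positions: np.ndarray,
    values: np.ndarray,
    baseline: str | float = "zero",
) -> tuple[float, tuple[float, float]]:
    """Full width at half maximum with subpixel linear interpolation.

    Half-maximum is ``baseline + (max − baseline)/2``; the two crossings
    bracketing the peak are located by linear interpolation between the
    neighbouring samples.  ``baseline`` is 0 by default (appropriate after
    background subtraction), ``"minimum"`` uses the profile minimum, or a
    number fixes it explicitly.

    Returns ``(fwhm, (left_crossing, right_crossing))`` in the units of
    ``positions``.
    """
    x = np.asarray(positions, dtype=np.float64)
    y = np.asarray(values, dtype=np.float64)
    if x.ndim != 1 or x.shape != y.shape or len(x) < 3:
        raise ValueError("positions and values must be matching 1D arrays, n >= 3")
    if np.any(np.diff(x) <= 0):
        raise ValueError("positions must be strictly increasing")
    if baseline == "zero":
        base = 0.0
    elif baseline == "minimum":
        base = float(y.min())
    else:
        base = float(baseline)
    i_peak = int(np.argmax(y))
    if i_peak == 0 or i_peak == len(y) - 1:
        raise ProfileNotResolvedError("profile not resolved: maximum at an endpoint")
    half = base + (y[i_peak] - base) / 2.0

    def _crossing(step: int, side: str) -> float:
        # walk outward from the peak to the first sample at or below half
        prev = i_peak
        i = i_peak + step
        while 0 <= i < len(y):
            if y[i] < half:
                t = (half - y[prev]) / (y[i] - y[prev])
                return float(x[prev] + t * (x[i] - x[prev]))
            if y[i] == half:
                j = i  # plateau exactly at half: take its midpoint
                while 0 <= j + step < len(y) and y[j + step] == half:
                    j += step
                if j != i:
                    warnings.warn(
                        "plateau at half-maximum; using its midpoint", stacklevel=3
                    )
                return float((x[i] + x[j]) / 2.0)
            prev = i
            i += step
        raise ProfileNotResolvedError(
            f"profile not resolved: no half-maximum crossing on the {side} side"
        )

    left = _crossing(-1, "left")
    right = _crossing(+1, "right")
    return right - left, (left, right)


def delta_fwhm(
    profile: LineProfile,
    baseline: str | float = "zero",
    sign: str = "obj-ref",
) -> FwhmResult:
    """FWHM of both channels of a profile and their signed difference.

    Default sign convention ``obj-ref`` (TMRM minus MTG): a *negative*
    delta means the object dye is narrower than the reference envelope,
    i.e. concentrated in the cristae; ``sign="ref-obj"`` flips it and all
    downstream interpretation.
    """
    try:
        fw_ref, (l_r, r_r) = fwhm_subpixel(profile.positions, profile.values_ref, baseline)
    except ProfileNotResolvedError as e:
        raise ProfileNotResolvedError(f"reference channel: {e}") from e
    try:
        fw_obj, (l_o, r_o) = fwhm_subpixel(profile.positions, profile.values_obj, baseline)
    except ProfileNotResolvedError as e:
        raise ProfileNotResolvedError(f"object channel: {e}") from e
    if sign not in ("obj-ref", "ref-obj"):
        raise ValueError(f"unknown sign convention {sign!r}")
    delta = fw_obj - fw_ref if sign == "obj-ref" else fw_ref - fw_obj
    return FwhmResult(fw_ref, fw_obj, delta, profile.pixel_size, (l_r, r_r, l_o, r_o))


# --------------------------------------------------------------------------
# automated profile placement

def auto_profiles(
    masks: MitoMasks,
    step_px: float = 8.0,
    half_length_px: float = 10.0,
    min_skeleton_px: int = 5,
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Place cross-sections perpendicular to each object's skeleton.

    For every connected component of the whole mask, the skeleton is
    computed and sections are dropped every ``step_px`` of arc length,
    oriented perpendicular to the local skeleton direction and extending
    ``half_length_px`` to either side.  This reproducible placement stands
    in for the manual sections drawn in interactive analysis.
    """
    labels, n = ndimage.label(masks.whole, structure=SQUARE_3x3)
    h, w = masks.whole.shape
    out: list[tuple[tuple[float, float], tuple[float, float]]] = []
    for lab in range(1, n + 1):
        comp = labels == lab
        skel = skeletonize(comp)
        pts = np.argwhere(skel)
        if len(pts) < min_skeleton_px:
            continue
        path = _order_skeleton(skel)
        if path is None or len(path) < min_skeleton_px:
            continue
        path = np.asarray(path, dtype=np.float64)
        seglen = np.hypot(*np.diff(path, axis=0).T)
        arc = np.concatenate([[0.0], np.cumsum(seglen)])
        # keep sections away from the tips where orientation is unstable
        targets = np.arange(step_px, arc[-1] - step_px / 2, step_px)
        if len(targets) == 0 and arc[-1] > 2:
            targets = np.array([arc[-1] / 2])
        for s in targets:
            i = int(np.searchsorted(arc, s))
            i = min(max(i, 2), len(path) - 3)
            tangent = path[i + 2] - path[i - 2]
            norm = np.hypot(*tangent)
            if norm == 0:
                continue
            ur, uc = tangent / norm
            pr, pc = -uc, ur
            p = path[i]
            a = (p[0] - pr * half_length_px, p[1] - pc * half_length_px)
            b = (p[0] + pr * half_length_px, p[1] + pc * half_length_px)
            if all(0 <= r <= h - 1 and 0 <= c <= w - 1 for r, c in (a, b)):
                out.append((a, b))
    return out


def _order_skeleton(skel: np.ndarray) -> list[tuple[int, int]] | None:
    """Order skeleton pixels along the longest simple path from a tip.

    Returns None for skeletons without a free end (loops)."""
    pts = {tuple(p) for p in np.argwhere(skel)}

    def neighbors(p):
        r, c = p
        return [
            (r + dr, c + dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr or dc) and (r + dr, c + dc) in pts
        ]

    tips = [p for p in pts if len(neighbors(p)) == 1]
    if not tips:
        return None
    start = min(tips)
    path = [start]
    seen = {start}
    cur = start
    while True:
        nxt = [q for q in neighbors(cur) if q not in seen]
        if not nxt:
            break
        # prefer continuing straight through junctions
        cur = nxt[0]
        path.append(cur)
        seen.add(cur)
    return path
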