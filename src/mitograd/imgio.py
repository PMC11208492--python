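"""Image, trace and configuration I/O.

Establishes the conventions every other module relies on: row-major arrays
with the origin at the top-left and pixel centers on integer coordinates;
intensities as non-negative floats in arbitrary units; lengths carried in
pixels with a per-frame physical pixel size (nm) for conversion.

Two-channel frames pair a geometric *reference* channel (typically the
potential-insensitive dye MTG) with an *object* channel (the
potential-dependent dye TMRM).  Channel roles are fixed by name, not page
order, because every metric treats the two channels asymmetrically.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

DEFAULT_PIXEL_SIZE_NM = 32.0  # 50 px == 1.6 um in the reference protocol
DEFAULT_CHANNELS = ("MTG", "TMRM")


class ImageFormatError(ValueError):
    """Raised when an image file violates the two-channel stack contract."""


@dataclass
class TwoChannelFrame:
    """A registered reference/object image pair with pixel-size metadata.

    Parameters
    ----------
    reference : ndarray
        2D intensity grid of the geometric reference channel (a.u., >= 0).
    object : ndarray
        2D intensity grid of the object channel, same shape as `reference`.
    pixel_size : float
        Physical size of one pixel in nanometres (> 0).
    time : float
        Acquisition time in seconds.
    labels : tuple of str
        Channel names, default ``("MTG", "TMRM")``.
    """

    reference: np.ndarray
    object: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_NM
    time: float = 0.0
    labels: tuple[str, str] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=np.float64)
        self.object = np.asarray(self.object, dtype=np.float64)
        if self.reference.ndim != 2 or self.object.ndim != 2:
            raise ImageFormatError("channels must be 2D images")
        if self.reference.shape != self.object.shape:
            raise ImageFormatError(
                f"channel shape mismatch: reference {self.reference.shape} "
                f"vs object {self.object.shape}"
            )
        if not (np.isfinite(self.reference).all() and np.isfinite(self.object).all()):
            raise ImageFormatError("non-finite intensities in loaded frame")
        if self.reference.min() < 0 or self.object.min() < 0:
            raise ImageFormatError("negative intensities in loaded frame")
        if not self.pixel_size > 0:
            raise ImageFormatError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.reference.shape

    def to_physical(self, length_px: float) -> float:
        """Convert a length in pixels to nanometres."""
        return length_px * self.pixel_size


@dataclass
class TimeLapse:
    """Ordered sequence of frames with a shared pixel size.

    `stimulus_time` (seconds) marks an external perturbation such as
    agonist addition; ``None`` for unstimulated acquisitions.
    """

    frames: list[TwoChannelFrame]
    stimulus_time: float | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ImageFormatError("time-lapse contains no frames")
        times = [f.time for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ImageFormatError("frame times must be strictly increasing")
        sizes = {f.pixel_size for f in self.frames}
        if len(sizes) != 1:
            raise ImageFormatError(f"pixel_size varies across frames: {sorted(sizes)}")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[TwoChannelFrame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> TwoChannelFrame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def pixel_size(self) -> float:
        return self.frames[0].pixel_size


_UNIT_RE = re.compile(r"^(?P<name>.*?)\s*\[(?P<unit>[^\]]*)\]$")


class ResultsTable:
    """Per-frame or per-object records with a unit recorded per column.

    Thin wrapper over a :class:`pandas.DataFrame`; units travel in the CSV
    header as a ``name [unit]`` suffix so that no column mixes units
    silently.
    """

    def __init__(self, data: pd.DataFrame | Mapping[str, Sequence], units: Mapping[str, str] | None = None):
        self.data = pd.DataFrame(data)
        self.units = dict(units or {})
        unknown = set(self.units) - set(self.data.columns)
        if unknown:
            raise ValueError(f"units given for absent columns: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ResultsTable)
            and self.units == other.units
            and self.data.equals(other.data)
        )

    def header(self) -> list[str]:
        return [
            f"{c} [{self.units[c]}]" if c in self.units else str(c)
            for c in self.data.columns
        ]


def write_traces(table: ResultsTable, path: str | Path) -> Path:
    """Write a results table as CSV with units in the header.

    Floats are written with 17 significant digits so the round trip is
    lossless for float64.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty results table")
    path = Path(path)
    out = table.data.copy()
    out.columns = table.header()
    out.to_csv(path, index=False, float_format="%.17g")
    return path


def read_traces(path: str | Path) -> ResultsTable:
    """Read a CSV written by :func:`write_traces`, recovering units."""
    df = pd.read_csv(path)
    units: dict[str, str] = {}
    names = []
    for col in df.columns:
        m = _UNIT_RE.match(str(col))
        if m:
            names.append(m.group("name"))
            units[m.group("name")] = m.group("unit")
        else:
            names.append(str(col))
    df.columns = names
    return ResultsTable(df, units)


# --------------------------------------------------------------------------
# configuration

@dataclass
class AnalysisConfig:
    """Validated parameter set shared across the pipeline.

    Every field carries the unit in its name or docstring; defaults follow
    the reference protocol (ImageJ-style processing of SIM reconstructions
    at 32 nm pixels).
    """

    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    window_diameter: int = 50      # background-subtraction window, px
    background_estimator: str = "local-median"
    background_subtract: bool = True
    erode_iters: int = 1           # CM-proxy core mask
    dilate_iters: int = 2          # IBM-proxy rim mask
    otsu_bins: int = 256
    profile_width: float = 50.0    # manual cross-profile averaging width, px
    auto_profile_width: float = 10.0  # averaging width for auto-placed sections, px
    profile_spacing: float = 0.5   # sample spacing along profile, px
    fwhm_baseline: str = "zero"    # or "minimum"
    delta_sign: str = "obj-ref"    # or "ref-obj"
    ratio_floor_frac: float = 0.01  # floor as fraction of foreground median
    overlay_mode: str = "mean"     # or "sum"
    overlay_frames: int = 15
    connectivity: int = 8
    min_area_px: int = 4
    per_object_index: bool = False
    lock_masks: bool = False       # reuse first-frame masks across a time-lapse
    fission_overlap: float = 0.25
    fission_lookback: int = 2

    def __post_init__(self) -> None:
        positive = [
            "pixel_size_nm", "window_diameter", "otsu_bins", "profile_width",
            "auto_profile_width",
            "profile_spacing", "ratio_floor_frac", "overlay_frames",
            "min_area_px", "fission_lookback",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("erode_iters", "dilate_iters"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.window_diameter < 3:
            raise ValueError("window_diameter must be >= 3 px")
        if self.background_estimator not in ("local-median", "local-minimum"):
            raise ValueError(f"unknown background estimator {self.background_estimator!r}")
        if self.fwhm_baseline not in ("zero", "minimum"):
            raise ValueError(f"unknown fwhm_baseline {self.fwhm_baseline!r}")
        if self.delta_sign not in ("obj-ref", "ref-obj"):
            raise ValueError(f"unknown delta_sign {self.delta_sign!r}")
        if self.overlay_mode not in ("mean", "sum"):
            raise ValueError(f"unknown overlay_mode {self.overlay_mode!r}")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if not 0 < self.fission_overlap <= 1:
            raise ValueError("fission_overlap must be in (0, 1]")


def load_config(source: str | Path | Mapping | None = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file, mapping or ``None``.

    Unknown keys are rejected (strict mode) so typos never silently fall
    back to defaults.
    """
    if source is None:
        return AnalysisConfig()
    if isinstance(source, Mapping):
        data = dict(source)
    else:
        text = Path(source).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**data)


# --------------------------------------------------------------------------
# TIFF stacks

def _read_pixel_size_nm(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" in tags:
        num, den = tags["XResolution"].value
        if num:
            unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else None
            px = den / num  # pixels per unit -> unit per pixel
            unit_nm = {2: 2.54e7, 3: 1e7}  # inch, cm
            code = getattr(unit, "value", unit)
            if code in unit_nm:
                return px * unit_nm[code]
    return None


def load_stack(
    path: str | Path | Sequence[str | Path],
    channel_order: tuple[str, str] = DEFAULT_CHANNELS,
    pixel_size: float | None = None,
    frame_interval: float = 1.0,
    stimulus_time: float | None = None,
) -> TimeLapse:
    """Load a two-channel time-lapse from TIFF.

    `path` is either one multi-page TIFF with channels interleaved per
    frame (reference page first within each pair, per `channel_order`), or
    a pair of single-channel stacks ``(reference_path, object_path)``.
    Integer pixel data are promoted to float64 without rescaling.

    `pixel_size` (nm per pixel) overrides any TIFF resolution metadata; if
    neither is available loading fails.
    """
    def _as_stack(arr: np.ndarray) -> np.ndarray:
        if arr.ndim == 2:
            return arr[None]
        if arr.ndim != 3:
            raise ImageFormatError(f"expected a stack of 2D pages, got ndim={arr.ndim}")
        return arr

    if isinstance(path, (str, Path)):
        with tifffile.TiffFile(path) as tif:
            pages = _as_stack(tif.asarray())
            meta_px = _read_pixel_size_nm(tif)
        if len(pages) % 2 != 0:
            raise ImageFormatError(
                f"{path}: {len(pages)} pages — channel pairing impossible "
                "(interleaved stacks need an even page count)"
            )
        ref_pages = pages[0::2]
        obj_pages = pages[1::2]
    else:
        ref_path, obj_path = path
        ref_pages = _as_stack(tifffile.imread(ref_path))
        obj_pages = _as_stack(tifffile.imread(obj_path))
        with tifffile.TiffFile(ref_path) as tif:
            meta_px = _read_pixel_size_nm(tif)
        if ref_pages.shape != obj_pages.shape:
            raise ImageFormatError(
                f"channel stacks disagree: {ref_pages.shape} vs {obj_pages.shape}"
            )
    px = pixel_size if pixel_size is not None else meta_px
    if px is None:
        raise ImageFormatError(
            "no pixel size in TIFF metadata and no override given"
        )
    frames = [
        TwoChannelFrame(
            reference=r.astype(np.float64),
            object=o.astype(np.float64),
            pixel_size=float(px),
            time=i * frame_interval,
            labels=channel_order,
        )
        for i, (r, o) in enumerate(zip(ref_pages, obj_pages))
    ]
    return TimeLapse(frames, stimulus_time=stimulus_time)


def write_stack(timelapse: TimeLapse, path: str | Path, dtype=np.float32) -> Path:
    """Write a time-lapse as an interleaved multi-page TIFF.

    Pages alternate reference/object per frame; the pixel size is stored
    in the TIFF resolution tags (pixels per centimetre).
    """
    path = Path(path)
    px_cm = 1e7 / timelapse.pixel_size  # pixels per cm
    pages = []
    for f in timelapse:
        pages.append(f.reference.astype(dtype))
        pages.append(f.object.astype(dtype))
    tifffile.imwrite(
        path,
        np.stack(pages),
        photometric="minisblack",
        resolution=(px_cm, px_cm),
        resolutionunit="CENTIMETER",
    )
    return path
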