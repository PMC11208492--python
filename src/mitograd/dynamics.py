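"""Per-frame metric traces, baseline normalization, correlation and
fission detection for stimulated time-lapses.

The pipeline per frame is: background subtraction → reference masks →
IBM association index → automated cross-profiles → ΔFWHM → particle
morphometrics.  Single-frame failures (e.g. an unresolvable profile) are
recorded as missing values with a reason, never silently dropped, so a
20-frame acquisition always yields a 20-row trace table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import gradient_metrics as gm
from . import morphometrics as mm
from . import preprocess as pp
from .imgio import AnalysisConfig, ResultsTable, TimeLapse

TRACE_UNITS = {
    "t": "s",
    "ibm_index": "1",
    "delta_fwhm_px": "px",
    "delta_fwhm_nm": "nm",
    "total_ref_intensity": "a.u.",
    "total_obj_intensity": "a.u.",
    "c": "count",
    "mean_area_px": "px^2",
    "mean_AR": "1",
    "mean_FF": "1",
    "atp_proxy": "a.u.",
}


@dataclass
class CorrelationResult:
    """Ordinary least-squares fit of y on x."""

    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int


@dataclass
class FissionEvent:
    """A labeled object splitting into >= 2 overlapping children."""

    frame_index: int          # frame of the split (children present)
    parent_id: int
    child_ids: tuple[int, ...]
    site: tuple[float, float]  # split site, px (mean child-boundary centroid)
    local_drop: float          # fractional pre-split object-channel dimming


def compute_traces(
    timelapse: TimeLapse,
    config: AnalysisConfig | None = None,
    atp_trace: tuple[np.ndarray, np.ndarray] | None = None,
) -> ResultsTable:
    """Run the full metric pipeline on every frame of a time-lapse.

    ``atp_trace`` is an optional ``(t_seconds, value)`` pair sampled on
    its own clock (the ATP sensor is typically recorded on a separate
    instrument); it is aligned onto the imaging timebase by linear
    interpolation.  Returns one row per frame; metrics that fail on a
    frame are NaN there with the reason collected in the table's
    ``attrs["failures"]``.
    """
    cfg = config or AnalysisConfig()
    rows = []
    failures: list[str] = []
    locked_masks = None
    for i, frame in enumerate(timelapse):
        ref, obj = frame.reference, frame.object
        if cfg.background_subtract:
            ref = pp.subtract_background(ref, cfg.window_diameter, cfg.background_estimator)
            obj = pp.subtract_background(obj, cfg.window_diameter, cfg.background_estimator)
        row: dict[str, float] = {
            "t": frame.time,
            "total_ref_intensity": float(ref.sum()),
            "total_obj_intensity": float(obj.sum()),
        }
        masks = None
        try:
            if cfg.lock_masks and locked_masks is not None:
                masks = locked_masks
            else:
                masks = gm.reference_masks(
                    ref, cfg.erode_iters, cfg.dilate_iters, cfg.otsu_bins
                )
                if cfg.lock_masks and locked_masks is None:
                    locked_masks = masks
            row["ibm_index"] = gm.ibm_association_index(obj, masks).index
        except ValueError as e:
            row["ibm_index"] = np.nan
            failures.append(f"frame {i}: ibm_index: {e}")
        try:
            if masks is None:
                raise ValueError("no masks")
            row["delta_fwhm_px"] = _frame_delta_fwhm(ref, obj, masks, cfg, frame.pixel_size)
            row["delta_fwhm_nm"] = row["delta_fwhm_px"] * frame.pixel_size
        except ValueError as e:
            row["delta_fwhm_px"] = row["delta_fwhm_nm"] = np.nan
            failures.append(f"frame {i}: delta_fwhm: {e}")
        try:
            mask, _ = mm.binarize(ref, cfg.otsu_bins)
            labeled, _ = mm.label_particles(mask, cfg.connectivity, cfg.min_area_px)
            row.update(mm.frame_summary(mm.measure(labeled, frame.pixel_size)))
        except ValueError as e:
            row.update({"c": np.nan, "mean_area_px": np.nan, "mean_AR": np.nan, "mean_FF": np.nan})
            failures.append(f"frame {i}: morphometrics: {e}")
        rows.append(row)

    df = pd.DataFrame(rows)
    for col in ("ibm_index", "delta_fwhm_px", "c"):
        if df[col].isna().all():
            raise ValueError(f"metric {col!r} failed on every frame")
    if atp_trace is not None:
        t_atp, v_atp = np.asarray(atp_trace[0], float), np.asarray(atp_trace[1], float)
        df["atp_proxy"] = np.interp(df["t"], t_atp, v_atp)
    table = ResultsTable(df, {k: v for k, v in TRACE_UNITS.items() if k in df.columns})
    table.data.attrs["failures"] = failures
    return table


def _frame_delta_fwhm(
    ref: np.ndarray,
    obj: np.ndarray,
    masks: gm.MitoMasks,
    cfg: AnalysisConfig,
    pixel_size: float,
) -> float:
    """Median ΔFWHM over automatically placed cross-sections."""
    profiles = gm.auto_profiles(masks)
    deltas = []
    for ep in profiles:
        try:
            prof = gm.cross_profile(
                ref, obj, ep,
                width=cfg.auto_profile_width,
                spacing=cfg.profile_spacing,
                pixel_size=pixel_size,
            )
            deltas.append(gm.delta_fwhm(prof, cfg.fwhm_baseline, cfg.delta_sign).delta)
        except (gm.ProfileNotResolvedError, ValueError):
            continue
    if not deltas:
        raise ValueError("no resolvable cross-profile in frame")
    return float(np.median(deltas))


def normalize_delta(
    trace: np.ndarray,
    t: np.ndarray,
    stimulus_time: float,
    mode: str = "additive",
) -> tuple[np.ndarray, dict[str, float]]:
    """Express a trace relative to its pre-stimulus baseline.

    ``additive`` subtracts the baseline mean; ``fractional`` divides by it
    and subtracts 1.  The baseline window is every frame strictly before
    ``stimulus_time`` and must contain at least 2 frames.
    Returns ``(normalized, stats)`` with the baseline mean/sd/n reported.
    """
    trace = np.asarray(trace, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    base = trace[t < stimulus_time]
    base = base[np.isfinite(base)]
    if len(base) < 2:
        raise ValueError("baseline window needs >= 2 pre-stimulus frames")
    mu = float(base.mean())
    info = {"baseline_mean": mu, "baseline_sd": float(base.std(ddof=1)), "n_baseline": len(base)}
    if mode == "additive":
        return trace - mu, info
    if mode == "fractional":
        if mu == 0:
            raise ValueError("fractional normalization undefined: baseline mean is 0")
        return trace / mu - 1.0, info
    raise ValueError(f"unknown normalization mode {mode!r}")


def linear_fit(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Ordinary least squares of y on x with R² and a two-sided p-value
    for the slope (t statistic, n−2 degrees of freedom).

    NaN pairs are dropped; fewer than 3 finite pairs, or zero variance in
    either trace, is an error.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need >= 3 finite pairs, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x; slope undefined")
    if np.ptp(y) == 0:
        raise ValueError("zero variance in y; r_squared undefined")
    res = stats.linregress(x, y)
    return CorrelationResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_slope=float(res.pvalue),
        n=len(x),
    )


def bootstrap_slope_ci(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the OLS slope."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    rng = np.random.default_rng(seed)
    slopes = np.empty(n_boot)
    n = len(x)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0:
            slopes[b] = np.nan
            continue
        slopes[b] = stats.linregress(xb, yb).slope
    slopes = slopes[np.isfinite(slopes)]
    lo, hi = np.quantile(slopes, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def drop_then_rise(trace: np.ndarray, t: np.ndarray, stimulus_time: float) -> bool:
    """Change-point sign test for an initial drop followed by a rise.

    Scans every post-stimulus change point and asks whether some split
    gives a mean decline from baseline to the first segment and a mean
    rise from the first to the second segment, each supported by the
    majority sign of the frame-to-frame differences.
    """
    trace = np.asarray(trace, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    ok = np.isfinite(trace)
    trace, t = trace[ok], t[ok]
    pre = trace[t < stimulus_time]
    post = trace[t >= stimulus_time]
    if len(pre) < 1 or len(post) < 4:
        raise ValueError("need >= 1 baseline and >= 4 post-stimulus frames")
    base = pre.mean()
    for cp in range(1, len(post) - 1):
        seg1, seg2 = post[: cp + 1], post[cp:]
        if seg1.min() >= base:
            continue
        if seg1[-1] > seg1[0] or seg2[-1] < seg2[0]:
            continue
        d1, d2 = np.diff(seg1), np.diff(seg2)
        down = (d1 < 0).sum() >= max((d1 > 0).sum(), 1) if len(d1) else True
        up = (d2 > 0).sum() > (d2 < 0).sum()
        if down and up:
            return True
    return False


def detect_fission(
    labeled_frames: list[np.ndarray],
    object_frames: list[np.ndarray],
    overlap_frac: float = 0.25,
    lookback: int = 2,
    window: int = 5,
    min_child_px: int = 20,
) -> list[FissionEvent]:
    """Detect splitting objects between consecutive labeled frames.

    A fission event is a parent label in frame k whose footprint overlaps
    at least two labels in frame k+1, each child sharing at least
    ``overlap_frac`` of its own area with the parent.  The event records
    the fractional object-channel intensity change in a ``window``×
    ``window`` px region at the split site over the preceding ``lookback``
    frames — the local-depolarization signature that precedes fission.
    Children smaller than ``min_child_px`` are ignored, so noise-induced
    crumbs at an object's edge do not masquerade as fission products.
    """
    if len(labeled_frames) != len(object_frames):
        raise ValueError("label and intensity stacks differ in length")
    events: list[FissionEvent] = []
    for k in range(len(labeled_frames) - 1):
        lab0, lab1 = labeled_frames[k], labeled_frames[k + 1]
        for parent in np.unique(lab0):
            if parent == 0:
                continue
            footprint = lab0 == parent
            children = []
            for child in np.unique(lab1[footprint]):
                if child == 0:
                    continue
                child_mask = lab1 == child
                if child_mask.sum() < min_child_px:
                    continue
                if (child_mask & footprint).sum() >= overlap_frac * child_mask.sum():
                    children.append(int(child))
            if len(children) < 2:
                continue
            site = _split_site(footprint, lab1, children)
            drop = _local_drop(object_frames, k, site, lookback, window)
            events.append(
                FissionEvent(
                    frame_index=k + 1,
                    parent_id=int(parent),
                    child_ids=tuple(children),
                    site=site,
                    local_drop=drop,
                )
            )
    return events


def _split_site(parent_mask: np.ndarray, lab1: np.ndarray, children: list[int]) -> tuple[float, float]:
    """Locate the split: parent pixels claimed by no child (the new gap),
    falling back to the midpoint between child centroids."""
    child_any = np.isin(lab1, children)
    gap = parent_mask & ~child_any
    if gap.any():
        rr, cc = np.nonzero(gap)
        return float(rr.mean()), float(cc.mean())
    cents = ndimage.center_of_mass(np.ones_like(lab1), lab1, children)
    arr = np.asarray(cents)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def _local_drop(
    object_frames: list[np.ndarray],
    split_prev_frame: int,
    site: tuple[float, float],
    lookback: int,
    window: int,
) -> float:
    """Fractional intensity decrease at the site between ``lookback``
    frames before the split and the frame just before it."""
    r, c = int(round(site[0])), int(round(site[1]))
    half = window // 2
    ref_frame = max(split_prev_frame - lookback + 1, 0)

    def box(img):
        h, w = img.shape
        return img[max(r - half, 0): min(r + half + 1, h),
                   max(c - half, 0): min(c + half + 1, w)]

    before = float(box(object_frames[ref_frame]).mean())
    at = float(box(object_frames[split_prev_frame]).mean())
    if before <= 0:
        return np.nan
    return (before - at) / before


def label_stack(
    timelapse: TimeLapse, config: AnalysisConfig | None = None
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Background-subtract, binarize and label every frame.

    Returns ``(labeled_frames, object_frames)`` ready for
    :func:`detect_fission`.
    """
    cfg = config or AnalysisConfig()
    labels, objs = [], []
    for frame in timelapse:
        ref, obj = frame.reference, frame.object
        if cfg.background_subtract:
            ref = pp.subtract_background(ref, cfg.window_diameter, cfg.background_estimator)
            obj = pp.subtract_background(obj, cfg.window_diameter, cfg.background_estimator)
        mask, _ = mm.binarize(ref, cfg.otsu_bins)
        labeled, _ = mm.label_particles(mask, cfg.connectivity, cfg.min_area_px)
        labels.append(labeled)
        objs.append(obj)
    return labels, objs
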