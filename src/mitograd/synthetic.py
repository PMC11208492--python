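"""Synthetic two-channel mitochondria scenes with exact ground truth.

The generator emulates what the dual-dye experiment sees: barrel-shaped
mitochondria (tubes of 200–300 nm diameter) whose inner membrane carries
two distinct potentials — a cristae-membrane potential ``psi_c`` and an
inner-boundary-membrane potential ``psi_ibm`` (both negative, cristae
usually more so).  A cationic dye distributes between the two compartments
with Nernstian weights and a saturable cristae capacity, is rendered as
the 2D projection of the 3D geometry (chord-length line densities of the
cylindrical IBM shell and of transverse cristae disks), blurred by a
Gaussian PSF at structured-illumination scale, and corrupted by photon
(Poisson) and read (Gaussian) noise.  The reference channel is rendered
from the same geometry with a potential-independent surface density,
mimicking MTG.

Every frame returns the exact generative state (rim dye fraction, the two
potentials, event log, pre-optics morphometrics, ATP proxy) so parameter
recovery can be tested against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import constants, ndimage

from .imgio import TimeLapse, TwoChannelFrame

#: thermal voltage RT/F in millivolts at temperature T (kelvin)
def thermal_voltage_mv(temperature: float = 310.0) -> float:
    return 1000.0 * constants.R * temperature / constants.value("Faraday constant")


@dataclass
class Mitochondrion:
    """A tube following ``centerline`` (row, col pixel coords) with
    cylindrical IBM shell and transverse cristae disks."""

    centerline: np.ndarray          # (N, 2) float px
    radius_nm: float = 125.0        # tube radius (diameter 200-300 nm)
    crista_spacing_nm: float = 70.0
    crista_width_nm: float = 30.0
    shell_thickness_nm: float = 20.0
    cj_gap_nm: float = 40.0         # crista-edge to IBM gap (crista junction)

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=np.float64)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 2 or len(self.centerline) < 2:
            raise ValueError("centerline must be an (N>=2, 2) array")
        if not self.radius_nm > 0:
            raise ValueError("radius must be positive")

    def length_px(self) -> float:
        return float(np.hypot(*np.diff(self.centerline, axis=0).T).sum())

    def crista_radius_nm(self) -> float:
        return max(self.radius_nm - self.cj_gap_nm, 1.0)

    def membrane_areas_nm2(self, pixel_size_nm: float) -> tuple[float, float]:
        """(A_cm, A_ibm): cristae and boundary membrane areas of this tube."""
        L = self.length_px() * pixel_size_nm
        a_ibm = 2.0 * math.pi * self.radius_nm * L
        n_cristae = max(L / self.crista_spacing_nm, 1.0)
        a_cm = n_cristae * 2.0 * math.pi * self.crista_radius_nm() ** 2
        return a_cm, a_ibm

    def true_morphometrics(self, pixel_size_nm: float) -> dict[str, float]:
        """AR and FF of the pre-optics silhouette (a stadium shape)."""
        L = self.length_px() * pixel_size_nm
        r = self.radius_nm
        a = 2 * r * L + math.pi * r * r
        p = 2 * L + 2 * math.pi * r
        return {
            "AR": (L + 2 * r) / (2 * r),
            "FF": p * p / (4 * math.pi * a),
            "area_nm2": a,
        }


@dataclass
class SyntheticScene:
    """Generative parameters for one field of view.

    Defaults place the reference study conditions: 32 nm pixels, a 120 nm
    FWHM PSF, potentials with the cristae ~40 mV more polarized than the
    boundary membrane, and a dye load / capacity pair that sits mid-way
    into cristae saturation (the regime of a 13.5 nM TMRM stain).
    """

    mitochondria: list[Mitochondrion]
    shape: tuple[int, int] = (128, 128)   # px
    psi_c: float = -160.0                 # mV, cristae membrane
    psi_ibm: float = -120.0               # mV, inner boundary membrane
    dye_total: float = 13.5               # a.u., mirrors the nM load scale
    k_sat: float = 15.0                   # cristae capacity, same units
    temperature: float = 310.0            # K
    psf_fwhm: float = 120.0               # nm
    pixel_size: float = 32.0              # nm
    photon_scale: float = 1.0             # photons per intensity unit
    read_sigma: float = 2.0               # read noise, intensity units
    noise: bool = True
    seed: int = 0
    supersample: int = 4
    ref_total: float = 2.0e6              # integrated reference intensity (a.u.)
    obj_gain: float = 1.5e5               # integrated object intensity per dye unit
    rim_fraction_override: float | None = None  # bypass partitioning, fix f

    def __post_init__(self) -> None:
        if not self.mitochondria:
            raise ValueError("scene needs at least one mitochondrion")
        if self.psi_c > 0 or self.psi_ibm > 0:
            raise ValueError("membrane potentials must be <= 0 mV")
        if not (self.dye_total > 0 and self.k_sat > 0):
            raise ValueError("dye_total and k_sat must be positive")
        if not self.psf_fwhm >= 0:
            raise ValueError("psf_fwhm must be >= 0")

    @property
    def rendering_gain(self) -> float:
        """Integrated object-channel intensity per unit of total dye at the
        final pixel grid (pre-noise)."""
        return self.obj_gain / self.supersample**2


@dataclass
class GroundTruth:
    """Exact generative state attached to each rendered frame."""

    time: float
    rim_fraction: float                  # f = IBM dye / total dye
    psi_c: float
    psi_ibm: float
    cm_amount: float
    ibm_amount: float
    n_objects: int
    atp_proxy: float = np.nan
    events: list[dict] = field(default_factory=list)
    object_morphometrics: list[dict] = field(default_factory=list)


def partition_dye(
    dye_total: float,
    psi_c: float,
    psi_ibm: float,
    k_sat: float,
    area_cm: float = 1.0,
    area_ibm: float = 1.0,
    temperature: float = 310.0,
) -> tuple[float, float, float]:
    """Distribute dye between cristae and boundary membrane.

    Unsaturated allocation follows Nernst weights for a monovalent cation,
    ``w_i ∝ area_i · exp(−ψ_i·F/(R·T))`` (ψ in volts; more negative
    potential, larger weight).  The cristae allocation is then passed
    through a Langmuir cap of capacity ``k_sat`` — bound = K·c/(K+c) —
    and the overflow is reassigned to the boundary membrane, which is what
    makes the rim fraction grow with dye load.

    Returns ``(cm_density, ibm_density, f)`` where densities are amounts
    per unit membrane area and ``f = ibm_amount / dye_total``.
    """
    if not dye_total > 0:
        raise ValueError("dye_total must be positive")
    if not k_sat > 0:
        raise ValueError("k_sat must be positive")
    if not (area_cm > 0 and area_ibm > 0):
        raise ValueError("membrane areas must be positive")
    vt = thermal_voltage_mv(temperature)
    # subtract the common factor for numerical stability
    m = max(-psi_c, -psi_ibm)
    w_cm = area_cm * math.exp((-psi_c - m) / vt)
    w_ibm = area_ibm * math.exp((-psi_ibm - m) / vt)
    cm_raw = dye_total * w_cm / (w_cm + w_ibm)
    cm_amount = k_sat * cm_raw / (k_sat + cm_raw)
    ibm_amount = dye_total - cm_amount
    f = ibm_amount / dye_total
    return cm_amount / area_cm, ibm_amount / area_ibm, f


# --------------------------------------------------------------------------
# rasterization

def _polyline_dist_arc(
    points: np.ndarray, polyline: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Distance from each point to a polyline and arc length of the
    nearest point, vectorized over points."""
    p0 = polyline[:-1]
    seg = np.diff(polyline, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    arc0 = np.concatenate([[0.0], np.cumsum(seglen)])[:-1]
    best_d = np.full(len(points), np.inf)
    best_s = np.zeros(len(points))
    for i in range(len(p0)):
        if seglen[i] == 0:
            continue
        rel = points - p0[i]
        t = np.clip((rel @ seg[i]) / (seglen[i] ** 2), 0.0, 1.0)
        proj = p0[i] + t[:, None] * seg[i]
        d = np.hypot(points[:, 0] - proj[:, 0], points[:, 1] - proj[:, 1])
        closer = d < best_d
        best_d[closer] = d[closer]
        best_s[closer] = arc0[i] + t[closer] * seglen[i]
    return best_d, best_s


def _chord(r: float, d: np.ndarray) -> np.ndarray:
    return 2.0 * np.sqrt(np.maximum(r * r - d * d, 0.0))


def _rasterize(
    scene: SyntheticScene,
    dim_windows: list[tuple[int, float, float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Pre-optics density maps on the supersampled grid.

    Returns ``(ref_map, obj_map, cm_amount, ibm_amount)``; the object map
    integrates to ``obj_gain * dye_total`` exactly, the reference map to
    ``ref_total``.  ``dim_windows`` lists (mito_index, s_center_nm,
    s_half_nm, factor) local object-channel attenuations (pre-fission
    depolarization signature); dimmed dye is removed, not redistributed.
    """
    ss = scene.supersample
    h, w = scene.shape
    sub_nm = scene.pixel_size / ss
    H, W = h * ss, w * ss
    rr, cc = np.meshgrid(np.arange(H) + 0.5, np.arange(W) + 0.5, indexing="ij")
    pts_all = np.stack([rr.ravel(), cc.ravel()], axis=1) / ss  # px coords

    areas = [m.membrane_areas_nm2(scene.pixel_size) for m in scene.mitochondria]
    a_cm_tot = sum(a for a, _ in areas)
    a_ibm_tot = sum(b for _, b in areas)
    if scene.rim_fraction_override is not None:
        f = float(scene.rim_fraction_override)
        if not 0 <= f <= 1:
            raise ValueError("rim_fraction_override must lie in [0, 1]")
    else:
        _, _, f = partition_dye(
            scene.dye_total, scene.psi_c, scene.psi_ibm, scene.k_sat,
            a_cm_tot, a_ibm_tot, scene.temperature,
        )
    ibm_amount = f * scene.dye_total
    cm_amount = scene.dye_total - ibm_amount

    ref_map = np.zeros(H * W)
    obj_map = np.zeros(H * W)
    for k, mito in enumerate(scene.mitochondria):
        a = mito.radius_nm
        rc = mito.crista_radius_nm()
        margin_px = (a + scene.psf_fwhm) / scene.pixel_size + 2
        lo = np.maximum(mito.centerline.min(axis=0) - margin_px, 0)
        hi = np.minimum(mito.centerline.max(axis=0) + margin_px, [h, w])
        sel = (
            (pts_all[:, 0] >= lo[0]) & (pts_all[:, 0] <= hi[0])
            & (pts_all[:, 1] >= lo[1]) & (pts_all[:, 1] <= hi[1])
        )
        pts = pts_all[sel]
        if not len(pts):
            raise ValueError(f"mitochondrion {k} outside the field of view")
        d_px, s_px = _polyline_dist_arc(pts, mito.centerline)
        d_nm = d_px * scene.pixel_size
        s_nm = s_px * scene.pixel_size
        shell = _chord(a, d_nm) - _chord(a - mito.shell_thickness_nm, d_nm)
        duty = np.mod(s_nm, mito.crista_spacing_nm) < mito.crista_width_nm
        crista = _chord(rc, d_nm) * duty
        if shell.sum() == 0 or crista.sum() == 0:
            raise ValueError(f"mitochondrion {k} rasterized to nothing")
        dim = np.ones(len(pts))
        if dim_windows:
            for mk, s_c, s_half, factor in dim_windows:
                if mk == k:
                    dim[np.abs(s_nm - s_c) <= s_half] *= factor
        a_cm_k, a_ibm_k = areas[k]
        # per-mitochondrion dye share proportional to its membrane area
        cm_k = cm_amount * a_cm_k / a_cm_tot
        ibm_k = ibm_amount * a_ibm_k / a_ibm_tot
        ref_k = scene.ref_total * (a_cm_k + a_ibm_k) / (a_cm_tot + a_ibm_tot)
        shell_n = shell / shell.sum()
        crista_n = crista / crista.sum()
        ref_map[sel] += ref_k * (
            a_ibm_k / (a_cm_k + a_ibm_k) * shell_n
            + a_cm_k / (a_cm_k + a_ibm_k) * crista_n
        )
        obj_map[sel] += scene.obj_gain * (ibm_k * shell_n + cm_k * crista_n) * dim
    return ref_map.reshape(H, W), obj_map.reshape(H, W), cm_amount, ibm_amount


def _optics_and_noise(
    scene: SyntheticScene, density: np.ndarray, rng: np.random.Generator | None
) -> np.ndarray:
    ss = scene.supersample
    if scene.psf_fwhm > 0:
        sigma = scene.psf_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        sigma_sub = sigma / (scene.pixel_size / ss)
        density = ndimage.gaussian_filter(density, sigma_sub, mode="constant")
    h, w = scene.shape
    img = density.reshape(h, ss, w, ss).mean(axis=(1, 3))
    if rng is not None:
        counts = rng.poisson(np.maximum(img, 0.0) * scene.photon_scale)
        img = counts / scene.photon_scale + rng.normal(0.0, scene.read_sigma, img.shape)
        img = np.maximum(img, 0.0)
    return img


def render_frame(
    scene: SyntheticScene,
    t: float = 0.0,
    frame_index: int = 0,
    dim_windows: list[tuple[int, float, float, float]] | None = None,
    atp_proxy: float = np.nan,
    events: list[dict] | None = None,
) -> tuple[TwoChannelFrame, GroundTruth]:
    """Render one two-channel frame plus its exact ground truth.

    Noise (if enabled) is drawn from a generator seeded by
    ``(scene.seed, frame_index)``, so identical scenes render
    bit-identically.
    """
    ref_map, obj_map, cm_amt, ibm_amt = _rasterize(scene, dim_windows)
    rng = np.random.default_rng([scene.seed, frame_index]) if scene.noise else None
    ref = _optics_and_noise(scene, ref_map, rng)
    obj = _optics_and_noise(scene, obj_map, rng)
    truth = GroundTruth(
        time=t,
        rim_fraction=ibm_amt / scene.dye_total,
        psi_c=scene.psi_c,
        psi_ibm=scene.psi_ibm,
        cm_amount=cm_amt,
        ibm_amount=ibm_amt,
        n_objects=len(scene.mitochondria),
        atp_proxy=atp_proxy,
        events=list(events or []),
        object_morphometrics=[
            m.true_morphometrics(scene.pixel_size) for m in scene.mitochondria
        ],
    )
    frame = TwoChannelFrame(
        reference=ref, object=obj, pixel_size=scene.pixel_size, time=t
    )
    return frame, truth


def rasterized_object_map(scene: SyntheticScene) -> np.ndarray:
    """The pre-optics, pre-noise object density at the final pixel grid
    (exposed for dye-conservation checks)."""
    _, obj_map, _, _ = _rasterize(scene)
    ss = scene.supersample
    h, w = scene.shape
    return obj_map.reshape(h, ss, w, ss).mean(axis=(1, 3))


# --------------------------------------------------------------------------
# scene construction and time-lapse protocols

def default_scene(
    seed: int = 0,
    n_mito: int = 3,
    shape: tuple[int, int] = (128, 128),
    **overrides,
) -> SyntheticScene:
    """A reproducible field of gently curved tubes of 1.3–2.4 µm length."""
    rng = np.random.default_rng(seed)
    h, w = shape
    mitos: list[Mitochondrion] = []
    margin = 18
    max_len = min(65.0, 0.55 * min(h, w))
    for _ in range(n_mito):
        length_px = rng.uniform(0.6 * max_len, max_len)
        angle = rng.uniform(0, math.pi)
        curve = rng.uniform(-0.004, 0.004)
        for _attempt in range(300):
            c0 = rng.uniform([margin, margin], [h - margin, w - margin])
            s = np.linspace(-length_px / 2, length_px / 2, 24)
            rows = c0[0] + s * math.sin(angle) + curve * s**2 * math.cos(angle)
            cols = c0[1] + s * math.cos(angle) - curve * s**2 * math.sin(angle)
            line = np.stack([rows, cols], axis=1)
            if line.min() < margin / 2 or (line[:, 0] > h - margin / 2).any() or (
                line[:, 1] > w - margin / 2
            ).any():
                continue
            cand = Mitochondrion(line)
            if all(_polyline_gap(cand.centerline, m.centerline) > 14 for m in mitos):
                mitos.append(cand)
                break
        else:
            raise RuntimeError("could not place mitochondria without overlap")
    return SyntheticScene(mitochondria=mitos, shape=shape, seed=seed, **overrides)


def _polyline_gap(a: np.ndarray, b: np.ndarray) -> float:
    d, _ = _polyline_dist_arc(a, b)
    return float(d.min())


@dataclass
class Protocol:
    """A stimulation protocol for :func:`simulate_timelapse`.

    ``kind``:

    * ``"null"`` — no events; every truth trace is constant.
    * ``"histamine"`` — at ``stimulus_time`` the cristae potential steps
      ``psi_c_step`` more negative over ``rise_time`` (rim fraction falls),
      the ATP proxy rises logistically after ``atp_lag``, and each entry
      of ``fission_times`` splits one tube, preceded one frame earlier by
      local object-channel dimming at the split site.
    * ``"oligomycin"`` — the cristae potential ramps more negative at
      ``psi_ramp`` from the stimulus until ``cj_open_time``, when the two
      potentials equalize (crista-junction opening; rim fraction rises
      above baseline) and tubes progressively shorten (aspect ratio
      falls); the ATP proxy declines.
    """

    kind: str = "null"
    n_frames: int = 16
    frame_interval: float = 5.0        # s
    stimulus_time: float | None = 20.0  # s
    psi_c_step: float = -40.0          # mV (histamine)
    rise_time: float = 10.0            # s
    atp_baseline: float = 1.0
    atp_amplitude: float = 0.3
    atp_lag: float = 10.0              # s
    atp_tau: float = 8.0               # s
    atp_noise_sigma: float = 0.0
    fission_times: tuple[float, ...] = ()
    fission_dimming: float = 0.4       # fractional local intensity drop
    psi_ramp: float = -0.5             # mV/s (oligomycin)
    cj_open_time: float | None = None  # s (oligomycin)
    cj_tau: float = 40.0               # s, potential-equalization time constant
    shrink_rate: float = 0.01          # fractional length loss /s after CJ opening

    def __post_init__(self) -> None:
        if self.kind not in ("null", "histamine", "oligomycin"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        t_end = (self.n_frames - 1) * self.frame_interval
        for ft in self.fission_times:
            if not 0 < ft <= t_end:
                raise ValueError(f"fission event at t={ft}s outside the simulated interval")
        if self.kind == "oligomycin" and self.cj_open_time is not None:
            if not 0 < self.cj_open_time <= t_end:
                raise ValueError("cj_open_time outside the simulated interval")


def _split_mito(mito: Mitochondrion, gap_px: float = 12.0) -> tuple[Mitochondrion, Mitochondrion, np.ndarray]:
    """Split a tube at mid-arc into two with a gap; returns both halves and
    the split site (px coords).

    The gap is between centerline endpoints; the clear dark gap is smaller
    by twice the tube radius (the rounded end caps), so the default leaves
    ~4 px of genuine background between the daughters at 32 nm pixels.
    """
    line = mito.centerline
    seglen = np.hypot(*np.diff(line, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    mid = arc[-1] / 2
    i = int(np.searchsorted(arc, mid))
    site = line[min(i, len(line) - 1)]
    keep_a = arc <= mid - gap_px / 2
    keep_b = arc >= mid + gap_px / 2
    if keep_a.sum() < 2 or keep_b.sum() < 2:
        raise ValueError("tube too short to split")
    a = replace(mito, centerline=line[keep_a].copy())
    b = replace(mito, centerline=line[keep_b].copy())
    return a, b, site


def _shrink_mito(mito: Mitochondrion, factor: float) -> Mitochondrion:
    """Contract a tube toward its midpoint by ``factor`` in length."""
    line = mito.centerline
    mid = line.mean(axis=0)
    return replace(mito, centerline=mid + (line - mid) * factor)


def simulate_timelapse(
    scene: SyntheticScene, protocol: Protocol
) -> tuple[TimeLapse, list[GroundTruth]]:
    """Render a stimulated time-lapse with per-frame ground truth.

    Fission is rendered as a two-frame sequence: the frame before the
    split shows a local object-channel dimming at the future split site,
    the split frame separates the tube into two objects.
    """
    times = np.arange(protocol.n_frames) * protocol.frame_interval
    t_stim = protocol.stimulus_time
    rng = np.random.default_rng([scene.seed, 987654321])

    # assign each fission event to a distinct mitochondrion (longest first)
    order = np.argsort([-m.length_px() for m in scene.mitochondria])
    fission_plan = []
    for j, ft in enumerate(sorted(protocol.fission_times)):
        if j >= len(scene.mitochondria):
            raise ValueError("more fission events than mitochondria")
        fission_plan.append({"time": ft, "mito": int(order[j])})

    frames: list[TwoChannelFrame] = []
    truths: list[GroundTruth] = []
    for idx, t in enumerate(times):
        dt = t - t_stim if t_stim is not None else -1.0
        psi_c = scene.psi_c
        psi_ibm = scene.psi_ibm
        atp = protocol.atp_baseline
        if protocol.kind == "histamine" and dt >= 0:
            ramp = min(dt / protocol.rise_time, 1.0) if protocol.rise_time > 0 else 1.0
            psi_c = scene.psi_c + protocol.psi_c_step * ramp
            atp += protocol.atp_amplitude / (
                1.0 + math.exp(-(dt - protocol.atp_lag) / protocol.atp_tau)
            )
        elif protocol.kind == "oligomycin" and dt >= 0:
            open_dt = (
                t - protocol.cj_open_time if protocol.cj_open_time is not None else -1.0
            )
            if open_dt < 0:
                psi_c = scene.psi_c + protocol.psi_ramp * dt
            else:
                # crista junctions open: the cristae potential relaxes toward
                # the IBM level, so the rim fraction rises progressively
                dt_open = protocol.cj_open_time - t_stim
                psi_at_open = scene.psi_c + protocol.psi_ramp * max(dt_open, 0.0)
                psi_c = scene.psi_ibm + (psi_at_open - scene.psi_ibm) * math.exp(
                    -open_dt / max(protocol.cj_tau, 1e-9)
                )
            atp -= protocol.atp_amplitude * min(dt / max(protocol.rise_time, 1e-9), 1.0)
        if protocol.atp_noise_sigma > 0:
            atp += rng.normal(0.0, protocol.atp_noise_sigma)

        # geometry state at time t
        mitos = list(scene.mitochondria)
        events_now: list[dict] = []
        dim_windows: list[tuple[int, float, float, float]] = []
        done_splits: list[dict] = []
        for plan in fission_plan:
            m_idx = plan["mito"]
            if t >= plan["time"]:
                done_splits.append(plan)
                if times[max(idx - 1, 0)] < plan["time"] <= t:
                    events_now.append(
                        {"time": float(t), "kind": "fission", "mito": m_idx}
                    )
            elif idx + 1 < len(times) and times[idx + 1] >= plan["time"]:
                # frame immediately preceding the split: local dimming
                mito = scene.mitochondria[m_idx]
                s_mid = mito.length_px() * scene.pixel_size / 2
                dim_windows.append(
                    (m_idx, s_mid, 4 * scene.pixel_size, 1.0 - protocol.fission_dimming)
                )
                events_now.append(
                    {"time": float(t), "kind": "hyperpolarization", "mito": m_idx,
                     "dimming": protocol.fission_dimming}
                )
        # apply splits (replace parents by halves, preserving indexing of
        # un-split tubes for the dim windows)
        split_sites = {}
        new_mitos: list[Mitochondrion] = []
        index_map: dict[int, int] = {}  # original index -> index in new_mitos
        for k, m in enumerate(mitos):
            plan = next((p for p in done_splits if p["mito"] == k), None)
            if plan is None:
                index_map[k] = len(new_mitos)
                new_mitos.append(m)
            else:
                a, b, site = _split_mito(m)
                split_sites[k] = site
                new_mitos.extend([a, b])
        dim_windows = [
            (index_map[k], s_c, s_half, fac)
            for k, s_c, s_half, fac in dim_windows
            if k in index_map
        ]
        for ev in events_now:
            if ev["kind"] == "fission":
                ev["site_px"] = split_sites.get(ev["mito"], None)
            else:
                mito = scene.mitochondria[ev["mito"]]
                ev["site_px"] = mito.centerline[len(mito.centerline) // 2]
        if protocol.kind == "oligomycin" and protocol.cj_open_time is not None:
            open_dt = t - protocol.cj_open_time
            if open_dt > 0:
                factor = max(1.0 - protocol.shrink_rate * open_dt, 0.4)
                new_mitos = [_shrink_mito(m, factor) for m in new_mitos]

        frame_scene = replace(
            scene, mitochondria=new_mitos, psi_c=psi_c, psi_ibm=psi_ibm
        )
        frame, truth = render_frame(
            frame_scene, t=float(t), frame_index=idx,
            dim_windows=dim_windows or None, atp_proxy=atp, events=events_now,
        )
        frames.append(frame)
        truths.append(truth)
    return TimeLapse(frames, stimulus_time=t_stim), truths
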