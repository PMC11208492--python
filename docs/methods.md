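# Methods

## The measurement problem

The inner mitochondrial membrane (IMM) is not electrically homogeneous: the
cristae membrane (CM), which houses the respiratory-chain proton pumps,
can hold a different (usually more negative) potential ΔΨ_C than the inner
boundary membrane (IBM, potential ΔΨ_IBM), with the crista junctions acting
as diffusion barriers between the two. A cationic, Nernstian dye such as
TMRM partitions between the two IMM compartments according to those
potentials, but its cristae pool saturates at high load, so the *spatial
pattern* of TMRM relative to a geometry reference dye (MTG, which loads
into the IMM and is thereafter potential-insensitive) reports the CM/IBM
potential gradient. At structured-illumination (SIM) resolution
(≈100–140 nm) individual cristae are unresolved, so the package measures
two compartment-averaged readouts rather than anything crista-by-crista:

* **IBM association index** — Otsu-threshold the reference channel; erode
  the foreground once to get a *core* mask (CM proxy); dilate it twice and
  subtract the eroded mask to get a hollow *rim* mask (IBM proxy); the
  index is mean object intensity over rim divided by mean over core.
  Higher index ⇒ more dye at the IBM ⇒ shallower CM-vs-IBM gradient.
* **ΔFWHM** — width-averaged intensity profiles are taken across the tube
  in both channels at identical coordinates, each profile's full width at
  half maximum is found with subpixel linear interpolation, and
  ΔFWHM = FWHM_object − FWHM_reference. Negative values mean the object
  dye is narrower than the reference envelope, i.e. concentrated in the
  cristae. The sign convention is switchable (`delta_sign: ref-obj`)
  because both conventions appear in practice; the default is chosen so
  that cristae hyperpolarization (dye moving inward) makes ΔFWHM *fall*.

Morphometrics (count c, area a, perimeter p, fitted-ellipse axes x ≤ y,
AR = y/x, FF = p²/4πa) and an external ATP-proxy trace complete the
multi-parameter picture; per-frame traces of all quantities are assembled,
baseline-normalized, and correlated pairwise by OLS.

## Processing parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| pixel size | 32 | nm | 50 px ≡ 1.6 µm in the reference protocol; overridable |
| background window | 50 | px | sliding-window local median on a quarter-window grid, bilinearly interpolated, clamped at 0; removes structure larger than the window |
| erode / dilate iterations | 1 / 2 | – | the mask recipe defining core and rim |
| structuring element | 3×3 square | – | 8-connected, the common default of interactive tools; configurable |
| Otsu bins | 256 | – | histogram binning for thresholding |
| manual profile width | 50 | px | averaging width for user-drawn sections (1.6 µm) |
| auto profile width | 10 | px | automated skeleton-perpendicular sections; simulated tubes are only ~1.5–2 µm long, so a 50 px (1.6 µm) averaging span would run past their ends |
| profile spacing | 0.5 | px | subpixel sampling along the section |
| FWHM baseline | 0 | a.u. | appropriate after background subtraction; `minimum` mode for raw inputs |
| particle filter | 4 | px² | minimum area, 8-connectivity |
| fission overlap | 25 % of child area | – | parent/child footprint test, 2-frame dimming lookback, 5×5 px site window |

Background subtraction is applied before both metrics by default
(`background_subtract: false` disables it). The index is pooled over the
whole field per frame by default; per-object mode and first-frame mask
locking are available for time-lapses where per-frame re-thresholding is
undesirable.

## Numerical choices

* **FWHM crossings.** Half-maximum is baseline + (max − baseline)/2. From
  the peak outward, the first sample pair straddling that level is
  interpolated linearly; this is exact for piecewise-linear profiles. A
  run of samples exactly at half-maximum is resolved to its midpoint with
  a warning; a profile whose maximum sits at an endpoint, or that never
  crosses half-maximum on one side, raises "profile not resolved" rather
  than guessing. Sampled Gaussians with σ ≥ 1.5 px at ≤ 1 px spacing
  measure within 1 % of 2√(2 ln 2)·σ.
* **Perimeter.** The 4-direction Crofton estimator. A raw pixel-edge count
  would bias FF of digitized disks high by ~27 % (FF is quadratic in p).
  Crofton's bias band is documented and pinned in tests: within about +4 %
  for disks of r ≥ 10 px (shrinking with r, so disk FF decreases
  monotonically toward 1) and about −6 % at right-angled corners, hence FF
  of sharp-cornered polygons reads up to ~12 % low against ideal-measure
  arithmetic.
* **Fitted ellipse.** Axes come from the second central moments, rescaled
  so the ellipse area equals the particle area (the convention of the
  common interactive particle analyzers); for a rectangle the axis ratio
  equals the side ratio.
* **Otsu invariance.** The threshold is computed on a 256-bin histogram of
  the actual intensity range, so masks are invariant under positive
  rescaling of the image.
* **Ratio images.** The denominator is floored at 1 % of its foreground
  median before dividing; pixels where both channels sit below the floor
  are set to 0 (undefined background) instead of amplifying noise.

## The synthetic scene generator

No reference microscopy data are distributed with the package, so the
generator is a first-class module that renders ground-truthed two-channel
scenes under the study conditions the metrics are meant for.

**Geometry.** Mitochondria are tubes of radius 125 nm (diameter in the
200–300 nm range) following gently curved centerlines of ~1.3–2 µm,
placed without overlap in a 128×128 px field at 32 nm pixels. Cristae are
transverse disks of radius 85 nm (tube radius minus a 40 nm junction gap)
every 70 nm along the axis, 30 nm wide — deliberately below the simulated
PSF, because the readouts average over cristae rather than resolving them.
The IBM is a 20 nm cylindrical shell at the tube surface.

**Dye physics.** A monovalent cationic dye is split between CM and IBM
with Nernst weights w_i ∝ A_i·exp(−ψ_i F/RT) (RT/F = 26.7 mV at 310 K,
membrane areas A_i from the geometry), after which the CM allocation
passes through a Langmuir cap of capacity K_sat and the overflow is
reassigned to the IBM. This is the minimal model with the two required
behaviours: CM preference at low load, IBM spill-over once the cristae
saturate. Defaults ψ_C = −160 mV, ψ_IBM = −120 mV, dye_total = 13.5,
K_sat = 15 put the default load mid-way into saturation (rim fraction
f ≈ 0.54) with the six-step 1.35–81 load series straddling the capacity on
both sides; these are explicit scene parameters, not biological claims.

**Rendering.** Intensities are the 2D projection of the 3D geometry:
chord-length line densities through the cylindrical shell and through the
cristae disks, evaluated on a 4× supersampled grid, normalized per
compartment so the integrated object channel equals dye_total times the
rendering gain exactly (dye conservation is tested at 0.1 %). Projection
matters: a flat 2D annulus for the IBM would make high-rim-fraction cross
profiles strongly bimodal and break the FWHM readout, whereas the
projected shell keeps a substantial central column (two membrane
crossings) and profiles stay effectively unimodal at the default 120 nm
FWHM Gaussian PSF. The reference channel uses the same geometry with
potential-independent per-area density. After PSF blurring and 4× block
averaging, Poisson photon noise and Gaussian read noise (σ = 2) are
applied from a generator seeded by (scene seed, frame index), making
stacks bit-reproducible.

**Protocols.** `histamine`: at the stimulus the CM potential steps −40 mV
over 10 s (rim fraction falls ≈ 0.53 → 0.47), the ATP proxy rises
logistically with a 10 s lag, and programmed fission events split a tube
into two — rendered as one frame of 40 % local object-channel dimming at
the future split site followed by the topological split (centerline gap
12 px, leaving ~4 px of true background between daughters after the end
caps). `oligomycin`: the CM potential ramps −0.5…−0.8 mV/s until the
crista-junction-opening event, when it relaxes exponentially (τ = 40 s)
to the IBM level — the rim fraction first falls, then rises above
baseline, producing the characteristic drop-then-rise of the index —
while tubes progressively shorten (AR falls) and the ATP proxy declines.
`null`: every truth trace constant.

**What the generator does not emulate,** and hence what passing tests do
not show about real data: 3D optical sectioning and out-of-focus light,
SIM reconstruction artifacts, dye photobleaching and flicker, organelle
motion between channel exposures, heterogeneous per-mitochondrion
potentials within one field, and fusion events. Parameter-recovery
results on these scenes demonstrate that the metrics respond monotonically
to the programmed rim fraction under realistic optics and noise — not
that any particular index value maps to a particular potential in cells
(an absolute mV readout via the Nernst equation is explicitly out of
scope at this resolution).

## Problem sizes

The test suite and the acceptance script use 128×128 px fields with 2–3
mitochondria, 12–24-frame time-lapses, 20 replicate runs for the
stimulation-direction check, and 200 random 64×64 images for the
pixel-exact morphology oracle; these sizes keep the full suite at a few
minutes on one CPU while leaving every check's statistics comfortable.

## Known limitations

* The automated profile placement assumes simple (non-looping) skeletons;
  ring-shaped mitochondria are skipped.
* The index is undefined when erosion empties every object (all tubes
  thinner than 3 px at the chosen scale); the error lists offending
  objects instead of rescaling the masks silently.
* Baseline-anchored trace normalization requires ≥ 2 pre-stimulus frames.
* OLS p-values assume independent residuals; frames of a time-lapse are
  autocorrelated, so reported p-values on traces are descriptive, as is
  usual for this kind of per-cell regression.
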