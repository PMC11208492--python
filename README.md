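# mitograd

Analysis of **sub-mitochondrial membrane-potential gradients** from
dual-channel fluorescence microscopy, for cell biologists quantifying how
a potential-dependent dye (TMRM) distributes between the **cristae
membrane (CM)** and the **inner boundary membrane (IBM)** relative to a
geometric reference dye (MTG) in super-resolution (SIM-scale) images.

The IMM carries two potentials — ΔΨ_C at the cristae and ΔΨ_IBM at the
boundary membrane — and a Nernstian cation like TMRM reports their
difference through its spatial pattern: at low load it concentrates in
the cristae, at high load the cristae saturate and the dye spills toward
the IBM. `mitograd` turns that pattern into two per-frame numbers:

* **IBM association index** = mean(object intensity over *rim*) /
  mean(object intensity over *core*), where the rim and core masks come
  from the Otsu-thresholded reference channel (1 erosion for the core,
  2 dilations minus the eroded mask for the hollow rim). Higher ⇒ more
  dye at the IBM.
* **ΔFWHM** = FWHM(object) − FWHM(reference) of width-averaged
  cross-section profiles with subpixel linear interpolation. Negative ⇒
  object dye narrower than the reference envelope ⇒ cristae-concentrated.

Around these it provides background subtraction (sliding-window local
median), SIM-pattern-stack overlay to pseudo-widefield, ratio images,
ImageJ-convention particle morphometrics (count, area, perimeter,
aspect ratio AR = y/x, form factor FF = p²/4πa), trace assembly with
baseline normalization, OLS correlation of metric pairs, label-overlap
fission detection — and a fully ground-truthed **synthetic scene
generator** (Nernst partitioning with saturable cristae capacity,
projected 3D tube geometry, Gaussian PSF, Poisson + read noise) that
serves as the test bed in place of non-deposited microscopy data.

## Worked example

Simulate a histamine-style stimulation (Ca²⁺-driven cristae
hyperpolarization at t = 20 s, rising ATP proxy) and recompute the
readouts from the rendered images:

```python
import numpy as np
from mitograd import synthetic as syn, dynamics as dyn

scene = syn.default_scene(seed=1)                      # 3 tubes, 128x128 px, 32 nm px
protocol = syn.Protocol(kind="histamine", n_frames=12,
                        frame_interval=5.0, stimulus_time=20.0)
tl, truth = syn.simulate_timelapse(scene, protocol)
traces = dyn.compute_traces(
    tl, atp_trace=(tl.times, np.array([t.atp_proxy for t in truth]))
)
print(traces.data[["t", "ibm_index", "delta_fwhm_px", "c",
                   "mean_AR", "atp_proxy"]].round(3).to_string(index=False))
fit = dyn.linear_fit(traces.data["atp_proxy"], traces.data["ibm_index"])
print(f"index vs ATP: slope={fit.slope:.3f}, R^2={fit.r_squared:.2f}, "
      f"p={fit.p_slope:.4f}")
```

Output:

```
   t  ibm_index  delta_fwhm_px  c  mean_AR  atp_proxy
 0.0      0.327          0.046  3    6.872      1.000
 5.0      0.328          0.002  3    6.865      1.000
10.0      0.334         -0.059  3    6.884      1.000
15.0      0.333         -0.028  3    6.937      1.000
20.0      0.323         -0.046  3    6.898      1.067
25.0      0.314         -0.130  3    6.833      1.105
30.0      0.309         -0.248  3    6.900      1.150
35.0      0.314         -0.131  3    6.857      1.195
40.0      0.317         -0.190  3    6.914      1.233
45.0      0.315         -0.261  3    6.881      1.260
50.0      0.300         -0.232  3    6.839      1.277
55.0      0.308         -0.292  3    6.874      1.287
index vs ATP: slope=-0.079, R^2=0.75, p=0.0002
```

Read: before the stimulus the index sits at ≈ 0.33 and ΔFWHM at ≈ 0;
after it the index falls toward 0.30 and ΔFWHM goes negative — the dye
moves into the cristae as they hyperpolarize — while the ATP proxy rises,
giving the expected negative index-vs-ATP correlation. Object count `c`
and aspect ratio stay flat (no fission was programmed here).

The same pipeline runs from the shell on any interleaved two-channel
TIFF:

```sh
mitograd simulate --out scene.tif --truth truth.json --seed 1 --protocol histamine
mitograd traces   --in scene.tif --out traces.csv
mitograd correlate --traces traces.csv --x atp_proxy --y ibm_index --out corr.json
```

Every subcommand writes a `manifest.json` (version, config hash, input
hashes, seed) beside its outputs; exit codes are 0 / 1 / 2 for success /
computation error / usage error.

## Layout

```
src/mitograd/
  imgio.py            TIFF/CSV/YAML I/O, frame and config types
  preprocess.py       background, overlay, ratio, intensity matching, Beer-Lambert
  gradient_metrics.py masks, IBM association index, profiles, subpixel FWHM
  morphometrics.py    particle analysis (c, a, p, AR, FF)
  synthetic.py        ground-truthed scene generator and protocols
  dynamics.py         traces, normalization, OLS, fission detection
  cli.py              `mitograd` command-line entry point
docs/methods.md       model, parameters, numerical choices, limitations
```
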