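# caflux

Quantification of Ca²⁺ transients in interstitial cells of Cajal of the small
intestinal deep muscular plexus (ICC-DMP), recorded as single-channel confocal
movies of GCaMP3 fluorescence, plus a calibrated synthetic-recording generator
for validating every stage of the analysis against known ground truth.

ICC-DMP are spindle-shaped cells that fire ongoing, stochastic, localized Ca²⁺
transients from a handful of fixed subcellular firing sites.  Stimulating the
intrinsic enteric nerves (electrical field stimulation, EFS) silences this
activity for a couple of seconds; individual sites then *escape* inhibition at
variable times.  Quantifying those dynamics takes a pipeline:

1. **Stabilize** the movie (integer-pixel rigid registration to a reference
   frame by FFT cross-correlation).
2. **Build a spatio-temporal (ST) map**: collapse the cell transversely onto
   its centerline and normalise each position bin to ΔF/F₀ (F₀ = noise-debiased
   10th percentile of the bin's trace, pre-stimulus window when a protocol is
   given), giving a position × time kymograph.
3. **Detect events**: threshold at *k*·σ above the per-bin robust noise floor
   (σ from a bias-corrected trimmed SD), take 8-connected components with a
   2×-threshold seed criterion, and split merged components wherever two peaks
   are separated by a saddle below half the smaller peak (2-D persistence
   flooding).
4. **Measure each event**: peak amplitude (ΔF/F₀ above the local pre-event
   baseline), duration (FDHM, interpolated half-crossings), spatial spread
   (half-maximum extent in µm), and propagation velocity (least-squares slope
   of the leading edge).
5. **Cluster initiation loci into firing sites** (single linkage, 5 µm cut)
   and compute **stimulation-window summaries** (pre / first 2 s of EFS /
   late EFS / post) and **per-site escape latencies** (onset to the site's
   first post-onset event).
6. **Summarise and compare** conditions as mean ± SEM over cells with
   D'Agostino–Pearson screening, Student's *t* / one-way ANOVA, and the usual
   star coding.

The synthetic generator (`caflux.synthetic`) renders movies with the same
statistical structure — per-site homogeneous Poisson trains, lognormal event
kinetics, truncated-normal escape latencies with a shared within-cell
component, photon noise, optional rigid drift — and writes the ground-truth
ledger beside every movie, so recovery can be checked end to end.  Named
presets (`baseline`, `lnna`, `deanonoate`, `odq`, `bay58`, `vip`, `vip6_28`)
carry the published condition kinetics.

## Worked example

```python
import caflux as cf

cfg = cf.preset("baseline")            # pre-EFS kinetics + 10 Hz, 5 s train at t = 10 s
movie, cell, truth = cf.simulate_cell(cfg, seed=42)
result = cf.analyze_movie(movie, cell.roi(), protocol=cfg.efs)

pre = result.window("pre")
print(f"{len(result.events)} events at {len(result.sites)} firing sites "
      f"(ground truth: {truth.n_events} events, {cell.n_sites} sites)")
print(f"pre-EFS: {pre.frequency:.2f} events/s, amplitude {pre.mean_amplitude:.2f} dF/F0, "
      f"FDHM {pre.mean_fdhm:.0f} ms")
```

prints

```
30 events at 8 firing sites (ground truth: 30 events, 8 sites)
pre-EFS: 0.80 events/s, amplitude 0.57 dF/F0, FDHM 224 ms
```

— this cell drew 8 firing sites and fired 0.80 events/s before stimulation
(a single 20 s cell wobbles around the 1.05 events/s population mean); all 30
rendered transients were recovered, and `result.escape.latencies` holds each
site's inhibitory period.  The same pipeline runs from the shell:

```sh
caflux simulate --preset baseline --n-cells 4 --seed 1 --out sim/
caflux analyze --movie sim/cell000.tif --roi sim/cell000.roi.json --out out/
caflux recover --preset baseline --n-cells 48 --seed 1 --out rec/
```

`analyze` accepts any calibrated grayscale TIFF stack with a JSON sidecar
(frame rate, pixel size, optional EFS onset/duration) and a polygon +
centerline ROI JSON; it writes events, sites, window-summary and escape CSVs
plus a machine-readable run log.

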