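# Methods

## The system being modelled

ICC-DMP (interstitial cells of Cajal at the deep muscular plexus of the small
intestine) are thin spindle cells, here idealised as 80 µm × 6 µm, imaged as a
single-channel fluorescence stack at 33 frames/s with 0.5 µm pixels (a 60×
confocal field of view).  Each cell carries a small number of fixed firing
sites along its long axis; each site emits localized Ca²⁺ transients that
propagate a few µm along the cell and decay within a few hundred ms.  Activity
is stochastic and uncoordinated between sites and between cells.  Electrical
field stimulation (EFS) of the intrinsic nerves silences all sites at onset;
each site resumes firing after its own inhibitory period ("escape").

## Synthetic recordings

The generator is the package's test bed: it renders movies with known ground
truth under the statistical assumptions the analysis itself makes.

**Geometry.** An elliptical spindle mask; the centerline is one point per
occupied column; site positions are drawn uniformly along the centerline with
a minimum separation of 10 µm (twice the clustering linkage, so ground-truth
sites are resolvable) and a 4 µm margin from the tapered ends.  When a draw of
*k* sites cannot fit at that separation (possible up to the 13-site maximum),
the separation relaxes to the widest feasible spacing, which stays above the
5 µm linkage.  Site counts follow a clamped Poisson (mean 5.2, range 1–13) —
the observed range and mean; the distributional form itself is a stand-in, as
no distribution is reported.

**Event trains.** Per-site homogeneous Poisson at `cell_rate / n_sites`
(Poisson is the minimal model for "ongoing and stochastic" and keeps recovery
targets analytic).  Event kinetics are drawn per event from lognormals
(CV 0.3) around the preset means — amplitude 0.8 ΔF/F₀, FDHM 189 ms, spread
11.1 µm, velocity 71.4 µm/s for the baseline condition — with floors keeping
every draw renderable; the propagation direction is random but flips inward
when the drawn spread would leave the cell.

**Escape model.** A site's inhibitory period is *defined* by its first
post-onset transient, so the generator emits that event exactly at
`onset + latency` and then resumes Poisson firing at `post_escape_rate_gain`
(default 1.5, configurable) times the basal rate.  Latencies are normal with
mean 3.8 s and SD 1.8 s, clipped to [0.2, 9.9] s, and are *correlated within
a cell*: the variance is split equally between a shared cell-level component
and per-site jitter (intraclass correlation 0.5, configurable via
`escape_icc`).  The split is calibrated analytically: with clamped-Poisson
site counts, E[min over a cell's sites] = 3.8 − 1.101·(1.8/√2) ≈ 2.40 s,
matching the observed mean first-site escape while the pooled per-site
distribution keeps mean 3.8 / SD 1.8.  Fully independent sites (icc = 0)
would drive the expected first-site escape to ≈ 1.7–1.9 s, which is
incompatible with the reported cell-level value.  Clipping (censoring) is
used rather than rejection truncation because it preserves the pooled mean at
≈ 3.8 s.

**Rendering.** Events are separable kernels.  Temporal: linear rise over one
frame, then exponential decay with τ = (FDHM − Δt/2)/ln 2, the unique decay
constant for which the continuous trace's full width at half maximum equals
the drawn FDHM.  Spatial: the event fills the cell transversely and occupies
the centerline interval from its initiation site to `spread` µm along its
direction; the leading edge advances at the drawn velocity, implemented as a
per-bin onset delay of `round(distance/(v·Δt))` frames.  Event onsets snap to
the nearest frame so every bin samples its kernel at the same phase and the
sampled peak equals the drawn amplitude exactly; the longitudinal amplitude
profile ramps from 0.985 at initiation to 1.0 at the terminus so the event's
global maximum is strict and marks full recruitment (needed for a
well-defined peak time under the deterministic tie-breaking rules).
Intensities are `baseline_f0·(1 + ΔF/F₀)` inside the mask (1000 counts; 100
counts outside), plus Gaussian noise of SD `noise_sd·baseline_f0`
(default 0.05), optional integer rigid drift, clipping at 0, and 16-bit
quantisation.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: photophysics (bleaching, indicator kinetics), 3-D
optics, non-rigid tissue deformation, kinetic suppression of the first events
after escape (see *Known limitations*), and any inter-site or inter-cell
coordination beyond the shared escape-latency component.

## Analysis pipeline

**Stabilisation.** Integer-pixel rigid registration of every frame to the
first frame, maximising the mean-subtracted FFT cross-correlation; borders
exposed by a shift are filled with the frame's median.  Frames whose apparent
displacement exceeds 20 % of the frame dimension are flagged unstable, left
untranslated, and excluded from the ST map.  Sub-pixel warping is out of
scope (recordings are made under nicardipine, which minimises contraction).

**ST map.** Every in-polygon pixel is assigned to its nearest centerline
point (KD-tree); the map value is the mean of each bin's pixels (mean rather
than max keeps amplitudes comparable across cell widths).  F₀ per bin is the
10th percentile of the bin's trace — over the pre-stimulus window when a
protocol is supplied — plus 1.28 × a robust per-bin noise SD: a low percentile
resists contamination by frequent events but under-reads a noisy baseline by
exactly that amount, and without the correction quiescent ΔF/F₀ sits ~0.02
above zero and every amplitude is inflated ~2 %.  F₀ is floored at 1 count.
Coordinates: frames and bins are 0-based; times are `frame/frame_rate`;
positions are `bin × bin_size`; intervals are half-open `[start, end)`.

**Noise floor.** σ is estimated per bin as the SD of the bin's values after
excluding the top 25 %, divided by 0.7312 (the SD of a standard normal after
one-sided trimming at the 75th percentile — the analogue of 0.6745 for the
MAD).  Per-bin estimation matters because the transverse collapse averages
many pixels mid-cell but only one or two at the tapered tips, making ST-map
noise strongly heteroscedastic along the cell.

**Detection.** Foreground: ΔF/F₀ exceeding the bin median by k·σ (default
k = 3).  8-connected components must span ≥ 2 frames and ≥ 2 bins and contain
at least one cell above 2k·σ (the two-threshold seed criterion of classic
spark detectors; an event's exponential tail hovers near threshold for ~1 s
over ~20 bins and otherwise sheds spurious near-threshold islands under
noise).  Merged components are decomposed by half-saddle persistence
flooding: visiting cells from brightest to dimmest with union-find, two peaks
remain distinct events iff the saddle connecting them is below half of the
smaller peak and the smaller peak rises at least k·σ above the saddle.  The
2-D formulation is essential: when one site's event propagates over a
neighbouring site, the later site's peak rises on the first event's decaying
tail, and the genuine saddle between them is invisible to 1-D max-projections
along either axis.

**Per-event metrics.** Amplitude: peak ΔF/F₀ above the local pre-event
baseline at the peak bin (median of the 3 frames before the footprint
starts, clipped ≥ 0) — the bare maximum would credit an event with the
residual tail of its predecessor.  Peak ties break to the earliest frame,
then lowest bin.  FDHM: contiguous time around the peak for which the
peak-bin trace stays at or above `local_base + amplitude/2`, with both
crossings linearly interpolated.  Spatial spread: bin extent of footprint
cells at or above the half level, × bin size (interpreted as total half-max
extent; the farthest half-max excursion from the initiation locus is also
reported as `path_length`).  Initiation: the trailing edge of the event's
first appearance — among earliest-frame cells reaching half level, the one
farthest from the peak bin (the first frame holds the origin plus the first
propagation step toward the peak); pieces whose first frame is residual tail
fall back to the strongest cell.  Velocity: least-squares slope of the
signed leading-edge position (farthest half-level bin from initiation)
against time, from initiation to peak; events spanning < 3 frames report 0
by definition.  Window summaries average |velocity| over propagating events
only, since definitional zeros would dilute a propagation-speed average.

**Sites, windows, escape.** Initiation loci are clustered by single linkage
cut at 5 µm (for 1-D data this equals splitting the sorted loci at gaps
larger than the linkage, which the tests verify against a brute-force
pairwise merger).  Protocol windows default to pre = [onset−5, onset),
efs_first2s = [onset, onset+2), efs_late = [onset+2, train end), post =
[train end, +5 s); events are assigned by initiation time; empty windows
report frequency 0 and absent (not zero) means.  A site's escape latency is
its first post-onset event initiation minus onset; sites with no such event
are censored explicitly and excluded from latency means.

**Statistics.** Mean ± SEM over cells (animal identity is carried so
per-animal aggregation is one step away); D'Agostino–Pearson screening at
0.05 (skipped with a flag below 8 observations); Student's *t* (paired or
unpaired) for two groups, one-way ANOVA for more, run parametrically even
when normality fails (flagged); no multiple-testing correction; star code
\*, \*\*, \*\*\*, \*\*\*\* at 0.05/0.01/0.001/0.0001 with strict
inequalities; a paired contrast with all-zero differences reports p = 1 with
a flag.  The pooled escape-latency SE is cluster-robust with cells as
clusters, since latencies share the within-cell component.

## Problem sizes and numerical choices

The recovery experiments are desk-scale by design: 48 cells × 20 s at 33 fps
for the stimulation cohort (the reported cell count for those figures) and
100 cells × 40 s, unstimulated, for site counting (40 s makes the zero-event
probability negligible even for 13-site cells).  Per-cell seeds are spawned
from one seed sequence, so cohorts are bit-reproducible and cells
independent.  Degenerate inputs are contracted rather than crashed: zero
noise floors are floored at 10⁻⁶, all-zero bins floor F₀ at 1 count with a
warning, empty footprints are rejected, events clipped by the recording edge
report their observable width.

## Known limitations

* Coincident events at nearby sites whose footprints deeply overlap (one
  event covering the other's site at full amplitude) are genuinely ambiguous
  under the half-saddle criterion and are counted once; at baseline rates
  this costs ~5–10 % of counts and slightly inflates amplitude and spread.
* The generator renders post-escape events at full kinetics.  Real
  early-escape transients are strongly size-suppressed (tens of ms, ~0.1
  ΔF/F₀ — at or below a 2-frame detection minimum), so the pipeline's
  first-2-s EFS frequency and active-site count on synthetic cohorts
  (~0.45 events/s, ~0.9 sites) sit well above the published in-situ values
  (0.125 events/s, 0.3 sites).  Modelling kinetic recovery after escape is
  deliberately out of scope.
* FDHM carries a small negative bias (~10 ms) from the first-passage
  character of the contiguous half-max rule under noise, and velocity a
  ~5 % negative bias from the fully-spread frames inside the regression
  window; both are inside the stated measurement allowances.
* Integer-pixel registration only; movies with sub-pixel or non-rigid motion
  will blur the ST map.
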