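"""Ca2+ transient detection, per-event metrics, and firing-site clustering.

Operates on an ST map (position x time dF/F0).  Detection thresholds the
map at k robust noise SDs, takes 8-connected components, and splits
components at temporal saddles; measurement reports the standard kymograph
event metrics (peak amplitude, FDHM with interpolated half-crossings,
half-maximum spatial extent, leading-edge velocity); clustering groups
event initiation loci into firing sites by single linkage.

All tie-breaks are deterministic: earliest frame, then lowest bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stmap import STMap

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=int)

# SD of a standard normal sample after one-sided trimming at the 75th
# percentile; dividing the trimmed SD by this makes the estimator consistent
# for the noise SD (same role as 0.6745 for the MAD).
_TRIM_SD_FACTOR = 0.731228


def _trimmed_sigma(values: np.ndarray) -> float:
    """Noise SD estimate: SD after excluding the top 25%, bias-corrected."""
    if values.size < 2:
        return 0.0
    kept = values[values <= np.percentile(values, 75.0)]
    if kept.size < 2:
        return 0.0
    return float(kept.std()) / _TRIM_SD_FACTOR


@dataclass
class Footprint:
    """8-connected set of (bin, frame) ST-map cells belonging to one event."""

    bins: np.ndarray
    frames: np.ndarray

    @property
    def size(self) -> int:
        return self.bins.size

    @property
    def n_frames(self) -> int:
        return np.unique(self.frames).size

    @property
    def n_bins(self) -> int:
        return np.unique(self.bins).size


@dataclass
class CaEvent:
    """A detected Ca2+ transient and its metrics."""

    id: int
    t_init: float            # s
    p_init: float            # um along cell
    t_peak: float            # s
    amplitude: float         # peak dF/F0
    fdhm: float              # ms
    spatial_spread: float    # um, half-max extent
    velocity: float          # um/s, signed leading-edge slope
    path_length: float       # um, farthest half-max excursion from p_init
    footprint: Footprint = field(repr=False, default=None)
    site_id: int | None = None


@dataclass
class FiringSite:
    """Cluster of event initiation loci."""

    id: int
    centroid: float          # um along cell
    event_ids: list[int]

    @property
    def n_events(self) -> int:
        return len(self.event_ids)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def estimate_noise(dff: np.ndarray) -> tuple[float, float]:
    """Robust (center, sigma) of the dF/F0 noise floor of a whole map.

    sigma is the SD of the values that remain after excluding the top 25%
    (event pixels are sparse and bright, so they fall in the excluded
    quartile), rescaled for the truncation bias of the one-sided trim; the
    center is the map median.  sigma is floored at 1e-6 so a noise-free map
    still thresholds sensibly.
    """
    vals = dff[np.isfinite(dff)]
    if vals.size == 0:
        return 0.0, 1e-6
    sigma = _trimmed_sigma(vals)
    if sigma <= 0.0:
        logger.warning("estimate_noise: zero noise estimate, flooring at 1e-6")
        sigma = 1e-6
    return float(np.median(vals)), sigma


def _noise_per_bin(dff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin robust (center, sigma) with the same trimmed-SD estimator.

    ST-map noise is heteroscedastic along the cell: each bin averages a
    different number of transverse pixels (few at the tapered spindle tips),
    so a single map-wide sigma under-thresholds the noisiest bins.  Centers
    are bin medians; sigmas are floored at 1e-6.
    """
    n_bins = dff.shape[0]
    centers = np.zeros(n_bins)
    sigmas = np.full(n_bins, 1e-6)
    for i in range(n_bins):
        row = dff[i]
        row = row[np.isfinite(row)]
        if row.size < 4:
            continue
        centers[i] = np.median(row)
        sigmas[i] = max(_trimmed_sigma(row), 1e-6)
    return centers, sigmas


def _split_at_saddles(
    comp_bins: np.ndarray,
    comp_frames: np.ndarray,
    dff: np.ndarray,
    min_prominence: float = 0.0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Decompose a component into events by half-saddle persistence flooding.

    Two local maxima of the (bin, frame) dF/F0 landscape belong to
    distinct events iff the saddle on the highest path connecting them lies
    below half of the smaller peak — the watershed generalisation of the
    rule "a saddle below half of both flanking peaks splits the component".
    The smaller peak must additionally rise at least ``min_prominence``
    above the saddle, so noise ripples on a decaying tail do not shear off
    spurious fragments.

    Implemented as descending-value union-find flooding: cells are visited
    from brightest to dimmest; a cell joins the basin of its brightest
    already-visited 8-neighbour, and when it bridges two basins they merge
    unless the split criterion holds at the bridge value (values only
    descend, so a qualifying split can never un-split later).  All ties are
    broken deterministically (earliest frame, then lowest bin).
    """
    n = comp_bins.size
    if n <= 1:
        return [(comp_bins, comp_frames)]
    vals = dff[comp_bins, comp_frames]
    order = np.lexsort((comp_bins, comp_frames, -vals))

    index_of = {(b, f): i for i, (b, f) in enumerate(zip(comp_bins, comp_frames))}
    parent = np.full(n, -1, dtype=int)
    peak = np.zeros(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for idx in order:
        b, f, v = int(comp_bins[idx]), int(comp_frames[idx]), vals[idx]
        neigh_roots: list[int] = []
        best = None  # (value, frame, bin, index) of brightest visited neighbour
        for db in (-1, 0, 1):
            for df in (-1, 0, 1):
                if db == 0 and df == 0:
                    continue
                j = index_of.get((b + db, f + df))
                if j is None or parent[j] < 0:
                    continue
                r = find(j)
                if r not in neigh_roots:
                    neigh_roots.append(r)
                key = (-vals[j], comp_frames[j], comp_bins[j])
                if best is None or key < best[0]:
                    best = (key, r)
        if best is None:
            parent[idx] = idx
            peak[idx] = v
            continue
        parent[idx] = best[1]
        for r in neigh_roots:
            r0 = find(best[1])
            if r == r0:
                continue
            lesser = min(peak[r], peak[r0])
            if v < 0.5 * lesser and lesser - v >= min_prominence:
                continue  # genuine saddle: basins stay distinct events
            # merge basins: attach the lesser peak's root under the greater
            hi, lo = (r0, r) if peak[r0] >= peak[r] else (r, r0)
            parent[lo] = hi
            peak[hi] = max(peak[hi], peak[lo])

    roots = np.array([find(i) for i in range(n)])
    out = []
    for r in np.unique(roots):
        sel = roots == r
        out.append((comp_bins[sel], comp_frames[sel]))
    out.sort(key=lambda p: (p[1].min(), p[0].min()))
    return out


_SEED_FACTOR = 2.0  # a component must reach 2x the extension threshold


def detect_events(
    stmap: STMap,
    threshold_k: float = 3.0,
    min_frames: int = 2,
    min_bins: int = 2,
) -> list[Footprint]:
    """Segment supra-threshold 8-connected components into event footprints.

    Two-threshold segmentation in the spark-detection tradition: foreground
    is dF/F0 exceeding the per-bin noise center by ``threshold_k`` robust
    noise SDs, and a connected component is kept only if it contains at
    least one cell above ``2*threshold_k`` SDs (the seed criterion — the
    slowly decaying tail of a genuine event otherwise sheds disconnected
    near-threshold islands under noise).  Components smaller than
    ``min_frames`` distinct frames or ``min_bins`` distinct bins are
    discarded (also after saddle splitting, to drop slivers).
    """
    dff = stmap.dff
    centers, sigmas = _noise_per_bin(dff)
    with np.errstate(invalid="ignore"):
        excess = (dff - centers[:, None]) / sigmas[:, None]
        fg = excess > threshold_k
    fg &= np.isfinite(dff)

    labels, n = ndimage.label(fg, structure=_EIGHT)
    footprints: list[Footprint] = []
    if n == 0:
        return footprints
    all_bins, all_frames = np.nonzero(labels)
    lab_vals = labels[all_bins, all_frames]
    order = np.argsort(lab_vals, kind="stable")
    all_bins, all_frames, lab_vals = all_bins[order], all_frames[order], lab_vals[order]
    starts = np.searchsorted(lab_vals, np.arange(1, n + 2))

    for i in range(n):
        cb = all_bins[starts[i] : starts[i + 1]]
        cf = all_frames[starts[i] : starts[i + 1]]
        if np.unique(cf).size < min_frames or np.unique(cb).size < min_bins:
            continue
        if excess[cb, cf].max() <= _SEED_FACTOR * threshold_k:
            continue
        prominence = threshold_k * float(np.median(sigmas[np.unique(cb)]))
        for sb, sf in _split_at_saddles(cb, cf, dff, prominence):
            if np.unique(sf).size < min_frames or np.unique(sb).size < min_bins:
                continue
            order2 = np.lexsort((sb, sf))
            footprints.append(Footprint(bins=sb[order2], frames=sf[order2]))

    footprints.sort(key=lambda fp: (fp.frames[0], fp.bins[0]))
    return footprints


# ---------------------------------------------------------------------------
# Measurement
# ---------------------------------------------------------------------------

def _interp_crossing(t0, v0, t1, v1, level):
    """Linear interpolation of the time where a trace crosses ``level``."""
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def _fdhm_ms(trace: np.ndarray, peak_frame: int, half: float, frame_rate: float) -> float:
    """Width (ms) of the contiguous region around the peak where trace >= half.

    Half-crossings are linearly interpolated between frames; at recording
    edges the width is clamped to the available extent.
    """
    n = trace.size
    dt = 1.0 / frame_rate
    lo = peak_frame
    while lo > 0 and np.isfinite(trace[lo - 1]) and trace[lo - 1] >= half:
        lo -= 1
    hi = peak_frame
    while hi < n - 1 and np.isfinite(trace[hi + 1]) and trace[hi + 1] >= half:
        hi += 1
    t_left = lo * dt
    if lo > 0 and np.isfinite(trace[lo - 1]):
        t_left = _interp_crossing((lo - 1) * dt, trace[lo - 1], lo * dt, trace[lo], half)
    t_right = hi * dt
    if hi < n - 1 and np.isfinite(trace[hi + 1]):
        t_right = _interp_crossing(hi * dt, trace[hi], (hi + 1) * dt, trace[hi + 1], half)
    return max(t_right - t_left, 0.0) * 1e3


def measure_event(footprint: Footprint, stmap: STMap, event_id: int = 0) -> CaEvent:
    """Measure the standard per-event metrics over a footprint.

    amplitude: peak dF/F0 over the footprint measured above the local
    pre-event baseline at the peak bin (the residual of a preceding event's
    decay tail would otherwise inflate it); the peak is at the earliest
    frame, lowest bin on ties.  FDHM: width of the peak-bin trace at local
    baseline + amplitude/2, with interpolated crossings.  Spatial spread:
    bin extent of footprint cells >= the half level, times bin size.
    Initiation: earliest-frame cell, strongest value first (lowest bin on
    ties).  Velocity: least-squares slope of the signed leading-edge
    position (farthest half-level bin from initiation) against time, from
    initiation to peak; events spanning fewer than 3 frames report 0.
    """
    if footprint.size == 0:
        raise ValueError("empty footprint")
    b, f = footprint.bins, footprint.frames
    vals = stmap.dff[b, f]
    dt = 1.0 / stmap.frame_rate

    raw_max = float(np.nanmax(vals))
    at_max = np.nonzero(vals == raw_max)[0]
    # deterministic peak: earliest frame, then lowest bin
    k = at_max[np.lexsort((b[at_max], f[at_max]))[0]]
    peak_bin, peak_frame = int(b[k]), int(f[k])

    # local baseline: the peak bin's level just before the event starts;
    # clipped to >= 0 so noise dips never inflate the amplitude
    start = int(f.min())
    pre = stmap.dff[peak_bin, max(start - 3, 0) : start]
    pre = pre[np.isfinite(pre)]
    local_base = float(np.clip(np.median(pre), 0.0, None)) if pre.size else 0.0
    if local_base >= raw_max:  # fragment no brighter than its pre-baseline
        local_base = 0.0
    amp = raw_max - local_base

    first_frame = int(f.min())
    # initiation locus: the trailing edge of the event's first appearance —
    # among the earliest-frame cells that already reach half level, the one
    # farthest from the peak bin (lowest bin on ties).  The first frame
    # holds the initiation cell plus the first propagation step toward the
    # peak, so the cell opposite the peak is the origin regardless of
    # propagation direction.  If no earliest-frame cell reaches half level
    # (a saddle-split piece whose first frame is residual tail), fall back
    # to the strongest cell there.
    half_lv = vals.max() / 2.0
    first_sel = f == first_frame
    fb, fv = b[first_sel], vals[first_sel]
    strong = fv >= half_lv
    if np.any(strong):
        cand = fb[strong]
        far = np.abs(cand - peak_bin).max()
        init_bin = int(cand[np.abs(cand - peak_bin) == far].min())
    else:
        init_bin = int(fb[fv == fv.max()].min())
    t_init = first_frame * dt
    p_init = init_bin * stmap.bin_size

    half = local_base + amp / 2.0
    fdhm = _fdhm_ms(stmap.dff[peak_bin], peak_frame, half, stmap.frame_rate)

    half_cells = vals >= half
    hb = b[half_cells]
    spread = float((hb.max() - hb.min() + 1) * stmap.bin_size)

    hf = f[half_cells]
    disp = (hb - init_bin) * stmap.bin_size
    path = float(disp[np.argmax(np.abs(disp))]) if disp.size else 0.0

    velocity = 0.0
    span_frames = peak_frame - first_frame + 1
    if span_frames >= 3:
        ts, ps = [], []
        for fr in range(first_frame, peak_frame + 1):
            m = hf == fr
            if not np.any(m):
                continue
            d = disp[m]
            ts.append(fr * dt)
            ps.append(d[np.argmax(np.abs(d))])
        if len(ts) >= 3:
            velocity = float(np.polyfit(ts, ps, 1)[0])

    return CaEvent(
        id=event_id,
        t_init=t_init,
        p_init=p_init,
        t_peak=peak_frame * dt,
        amplitude=amp,
        fdhm=fdhm,
        spatial_spread=spread,
        velocity=velocity,
        path_length=abs(path),
        footprint=footprint,
    )


def find_events(
    stmap: STMap,
    threshold_k: float = 3.0,
    min_frames: int = 2,
    min_bins: int = 2,
) -> list[CaEvent]:
    """Detect and measure all events on an ST map."""
    fps = detect_events(stmap, threshold_k, min_frames, min_bins)
    return [measure_event(fp, stmap, event_id=i) for i, fp in enumerate(fps)]


# ---------------------------------------------------------------------------
# Firing-site clustering
# ---------------------------------------------------------------------------

def cluster_sites(
    events: list[CaEvent], linkage_um: float = 5.0
) -> tuple[list[FiringSite], list[CaEvent]]:
    """Group event initiation loci into firing sites by single linkage.

    Single-linkage agglomeration of 1-D positions cut at ``linkage_um`` is
    exactly the partition obtained by splitting the sorted initiation loci
    wherever the gap between neighbours exceeds the linkage distance.
    Events are annotated in place with their ``site_id``; sites are ordered
    by centroid.
    """
    if not events:
        return [], events
    p = np.array([ev.p_init for ev in events])
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    breaks = np.nonzero(np.diff(sorted_p) > linkage_um)[0]
    cluster_of_sorted = np.zeros(p.size, dtype=int)
    cluster_of_sorted[breaks + 1] = 1
    cluster_of_sorted = np.cumsum(cluster_of_sorted)
    labels = np.empty(p.size, dtype=int)
    labels[order] = cluster_of_sorted

    sites = []
    for sid in range(cluster_of_sorted[-1] + 1 if p.size else 0):
        members = np.nonzero(labels == sid)[0]
        for m in members:
            events[m].site_id = sid
        sites.append(
            FiringSite(
                id=sid,
                centroid=float(p[members].mean()),
                event_ids=[events[m].id for m in members],
            )
        )
    return sites, events
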