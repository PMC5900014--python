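"""Synthetic ICC-DMP recording generator.

Produces calibrated TIFF-style movies with a ground-truth ledger, emulating
in-situ confocal GCaMP3 recordings of spindle-shaped ICC-DMP: a handful of
fixed firing sites along the cell axis emit stochastic, uncoordinated Ca2+
transients; an optional EFS epoch silences every site until it escapes after
a variable latency.

Three stages, each deterministic under a seeded generator:

    make_cell           geometry: spindle mask, centerline, site positions
    sample_event_trains stochastic ground truth (per-site Poisson + escape)
    render_movie        pixels: separable event kernels + noise + drift
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .config import GeneratorConfig
from .stmap import CellROI, Movie

logger = logging.getLogger(__name__)

# Longitudinal amplitude ramp: initiation pixel renders at RAMP_LO x amplitude,
# rising linearly to the full amplitude at the propagation terminus, so the
# event's global maximum is strict and marks full recruitment.
RAMP_LO = 0.985


@dataclass
class CellGeometry:
    """Spindle cell geometry on a pixel grid.

    The cell lies horizontally: the centerline is one point per occupied
    column at the mid-row, ordered left (bin 0) to right.
    """

    mask: np.ndarray                 # (H, W) bool
    centerline: np.ndarray           # (N, 2) float (row, col), ordered
    positions_um: np.ndarray         # (N,) arc position of each centerline point
    site_positions_um: np.ndarray    # (n_sites,) along the centerline
    polygon: np.ndarray              # (P, 2) outline vertices (row, col)
    pixel_size: float
    col_rows: dict = field(repr=False, default_factory=dict)  # col -> (r0, r1)

    @property
    def n_sites(self) -> int:
        return self.site_positions_um.size

    def roi(self) -> CellROI:
        return CellROI(polygon=self.polygon.copy(), centerline=self.centerline.copy())


@dataclass
class EventSpec:
    """Ground-truth twin of a detected event."""

    site_id: int
    t_init: float        # s
    amplitude: float     # dF/F0
    fdhm: float          # ms
    spread: float        # um
    velocity: float      # um/s
    direction: int       # +1 toward higher bins, -1 toward lower


@dataclass
class GroundTruth:
    """Simulator ledger: sites, events, and (with EFS) per-site escape latencies."""

    site_positions_um: np.ndarray
    events: list[EventSpec]
    escape_latencies: np.ndarray | None = None  # (n_sites,) s; NaN without EFS

    @property
    def n_events(self) -> int:
        return len(self.events)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _draw_site_count(config: GeneratorConfig, rng: np.random.Generator) -> int:
    if isinstance(config.n_sites, int):
        return config.n_sites
    k = int(rng.poisson(config.site_mean))
    return int(np.clip(k, config.site_min, config.site_max))


def _place_sites(
    length: float, k: int, min_sep: float, margin: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform site positions on [margin, length-margin] with min separation.

    If k sites cannot fit at ``min_sep`` the separation is relaxed to the
    widest feasible spacing (logged); sites then remain distinguishable as
    long as the relaxed spacing exceeds the clustering linkage.
    """
    lo, hi = margin, length - margin
    span = hi - lo
    if span <= 0:
        raise ValueError("cell too short for the requested end margin")
    sep = min_sep
    if k > 1 and (k - 1) * sep > span:
        sep = span / (k - 1) * 0.999
        logger.warning(
            "site placement: relaxed min separation to %.2f um to fit %d sites", sep, k
        )
    # exact uniform draw on the min-separation simplex: shrink, sort, re-pad
    slack = span - (k - 1) * sep
    pos = lo + np.sort(rng.uniform(0.0, slack, size=k)) + np.arange(k) * sep
    return pos


def make_cell(config: GeneratorConfig, rng: np.random.Generator) -> CellGeometry:
    """Build the spindle mask, centerline, and firing-site positions.

    The mask is an elliptical spindle of the configured length/width centred
    in the frame; the centerline is one point per occupied column at the
    mid-row.  Site positions are drawn uniformly along the centerline with a
    minimum separation (see :func:`_place_sites`).
    """
    config.validate()
    px = config.pixel_size
    len_px = int(round(config.cell_length / px))
    wid_px = config.cell_width / px

    margin = 8
    auto_shape = (int(math.ceil(wid_px)) + 2 * margin, len_px + 2 * margin)
    shape = config.frame_shape or auto_shape
    if shape[0] < auto_shape[0] - margin or shape[1] < auto_shape[1] - margin:
        raise ValueError(
            f"cell of {config.cell_length}x{config.cell_width} um does not fit "
            f"a {shape} frame at {px} um/px"
        )

    h, w = shape
    row_c = (h - 1) / 2.0
    col0 = (w - len_px) // 2

    cols = np.arange(len_px)
    s = (cols + 0.5) / len_px  # normalised axial position in (0, 1)
    half_w = (wid_px / 2.0) * np.sqrt(np.clip(1.0 - (2 * s - 1) ** 2, 0.0, None))
    half_w = np.maximum(half_w, 0.6)  # keep the tapered tips >= 1 px tall

    mask = np.zeros(shape, dtype=bool)
    col_rows: dict[int, tuple[int, int]] = {}
    for j, hw in zip(cols, half_w):
        r0 = int(math.floor(row_c - hw + 0.5))
        r1 = int(math.ceil(row_c + hw + 0.5))
        r0, r1 = max(r0, 0), min(r1, h)
        mask[r0:r1, col0 + j] = True
        col_rows[col0 + j] = (r0, r1)

    centerline = np.column_stack([np.full(len_px, row_c), col0 + cols]).astype(float)
    positions_um = cols * px

    top = np.column_stack([row_c - half_w, col0 + cols])
    bottom = np.column_stack([row_c + half_w, col0 + cols])[::-1]
    polygon = np.vstack([top, bottom])

    k = _draw_site_count(config, rng)
    sites = _place_sites(
        config.cell_length, k, config.site_min_sep, config.site_end_margin, rng
    )
    return CellGeometry(
        mask=mask,
        centerline=centerline,
        positions_um=positions_um,
        site_positions_um=sites,
        polygon=polygon,
        pixel_size=px,
        col_rows=col_rows,
    )


# ---------------------------------------------------------------------------
# Event trains
# ---------------------------------------------------------------------------

def _lognormal(mean: float, cv: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Lognormal draws parameterised by arithmetic mean and CV."""
    if cv <= 0 or mean <= 0:
        return np.full(size, mean)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


def _poisson_times(rate: float, t0: float, t1: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def _draw_escape_latencies(
    n_sites: int, efs, rng: np.random.Generator
) -> np.ndarray:
    """Per-site inhibitory periods for one cell.

    Latency = shared cell-level normal component + independent per-site
    jitter, with the variance split ``escape_icc`` / (1 - ``escape_icc``),
    clipped to [escape_min, escape_max].  The pooled marginal is
    N(escape_mean, escape_sd^2) censored to the range; the within-cell
    correlation reproduces the observed cell-level first-escape times.
    """
    sd_cell = efs.escape_sd * math.sqrt(efs.escape_icc)
    sd_site = efs.escape_sd * math.sqrt(1.0 - efs.escape_icc)
    shared = rng.normal(0.0, sd_cell)
    lat = efs.escape_mean + shared + rng.normal(0.0, sd_site, size=n_sites)
    return np.clip(lat, efs.escape_min, efs.escape_max)


def sample_event_trains(
    cell: CellGeometry, config: GeneratorConfig, rng: np.random.Generator
) -> GroundTruth:
    """Draw the stochastic ground truth for one cell.

    Each site fires a homogeneous Poisson train at cell_rate/n_sites.  With
    EFS, a site is silent over [onset, onset+latency); its escape is marked
    by an event exactly at onset+latency (the operational definition of the
    inhibitory period), after which it fires at gain x rate.  Kinetic
    parameters are drawn per event (lognormal around the config means); the
    propagation direction points into the cell interior whenever the drawn
    spread would otherwise leave the cell.
    """
    config.validate()
    n_sites = cell.n_sites
    rate = config.cell_rate / n_sites
    efs = config.efs
    dur = config.duration

    times: list[np.ndarray] = []
    site_ids: list[np.ndarray] = []
    latencies = None
    if efs is None:
        for s in range(n_sites):
            t = _poisson_times(rate, 0.0, dur, rng)
            times.append(t)
            site_ids.append(np.full(t.size, s))
    else:
        latencies = _draw_escape_latencies(n_sites, efs, rng)
        gain = efs.post_escape_rate_gain
        for s in range(n_sites):
            pre = _poisson_times(rate, 0.0, efs.onset, rng)
            t_escape = efs.onset + latencies[s]
            post = _poisson_times(gain * rate, t_escape, dur, rng)
            if rate > 0 and t_escape < dur:
                post = np.concatenate([[t_escape], post])
            t = np.concatenate([pre, post])
            times.append(t)
            site_ids.append(np.full(t.size, s))

    t_all = np.concatenate(times) if times else np.empty(0)
    s_all = np.concatenate(site_ids) if site_ids else np.empty(0, dtype=int)
    order = np.argsort(t_all, kind="stable")
    t_all, s_all = t_all[order], s_all[order].astype(int)

    n = t_all.size
    amps = _lognormal(config.amp_mean, config.amp_cv, n, rng)
    fdhms = np.maximum(
        _lognormal(config.fdhm, config.kinetic_cv, n, rng),
        2.2 * config.frame_period * 1e3,
    )
    spreads = np.maximum(
        _lognormal(config.spread, config.kinetic_cv, n, rng), config.pixel_size
    )
    vels = np.maximum(_lognormal(config.velocity, config.kinetic_cv, n, rng), 1.0)
    dirs = rng.choice([-1, 1], size=n)

    cell_len = cell.positions_um[-1] if cell.positions_um.size else 0.0
    events = []
    for i in range(n):
        p0 = cell.site_positions_um[s_all[i]]
        d = int(dirs[i])
        # propagate into the interior if the drawn spread would leave the cell
        if d > 0 and p0 + spreads[i] > cell_len and p0 - spreads[i] >= 0:
            d = -1
        elif d < 0 and p0 - spreads[i] < 0 and p0 + spreads[i] <= cell_len:
            d = 1
        events.append(
            EventSpec(
                site_id=int(s_all[i]),
                t_init=float(t_all[i]),
                amplitude=float(amps[i]),
                fdhm=float(fdhms[i]),
                spread=float(spreads[i]),
                velocity=float(vels[i]),
                direction=d,
            )
        )
    return GroundTruth(
        site_positions_um=cell.site_positions_um.copy(),
        events=events,
        escape_latencies=latencies,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _temporal_kernel(fdhm_ms: float, dt: float) -> np.ndarray:
    """Sampled unit-peak kernel: one-frame linear rise, exponential decay.

    The decay constant is set so the continuous trace's full width at half
    maximum equals ``fdhm_ms`` (rise contributes dt/2, decay tau*ln2).
    Sample 0 falls at onset (value 0), sample 1 at the peak.
    """
    fdhm_s = fdhm_ms / 1e3
    tau = max((fdhm_s - dt / 2.0) / math.log(2.0), dt / 4.0)
    n_decay = int(math.ceil(5.5 * tau / dt))
    k = np.empty(2 + n_decay)
    k[0] = 0.0
    k[1] = 1.0
    k[2:] = np.exp(-np.arange(1, n_decay + 1) * dt / tau)
    return k


def render_movie(
    cell: CellGeometry,
    ground_truth: GroundTruth,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> Movie:
    """Rasterise ground-truth events into a calibrated uint16 stack.

    Each event is a separable kernel.  Temporal: linear rise over one frame
    then exponential decay matched to the event's FDHM; onsets snap to the
    nearest frame.  Spatial: the event occupies the centerline interval from
    its initiation site to ``spread`` um along ``direction``; the leading
    edge advances at the event's velocity (per-bin onset delay of
    round(distance/(v*dt)) frames), the longitudinal amplitude ramps from
    0.985 at initiation to 1.0 at the terminus, and the fluorescence fills
    the cell transversely.  Kernels reaching past the mask are truncated at
    the mask edge (logged).

    Intensities are baseline_f0*(1 + dF/F0) inside the cell (``background``
    counts outside), plus Gaussian noise of SD noise_sd*baseline_f0, optional
    rigid drift, clipping at 0, and 16-bit quantisation.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dt = config.frame_period
    n_frames = config.n_frames
    h, w = cell.mask.shape
    px = config.pixel_size

    dff = np.zeros((n_frames, h, w), dtype=np.float32)
    cl_cols = cell.centerline[:, 1].astype(int)
    pos = cell.positions_um
    cell_len = pos[-1]
    n_truncated = 0

    for ev in ground_truth.events:
        g0 = int(round(ev.t_init / dt))
        if g0 >= n_frames:
            continue
        p0 = ground_truth.site_positions_um[ev.site_id]
        p_end = p0 + ev.direction * ev.spread
        if p_end < 0.0 or p_end > cell_len:
            p_end = float(np.clip(p_end, 0.0, cell_len))
            n_truncated += 1
        lo_um, hi_um = min(p0, p_end), max(p0, p_end)
        sel = np.nonzero((pos >= lo_um - px / 2) & (pos <= hi_um + px / 2))[0]
        if sel.size == 0:
            sel = np.array([int(np.argmin(np.abs(pos - p0)))])
        dists = np.abs(pos[sel] - p0)
        extent = max(abs(p_end - p0), px)
        ramp = RAMP_LO + (1.0 - RAMP_LO) * np.minimum(dists / extent, 1.0)
        delays = np.round(dists / (ev.velocity * dt)).astype(int)
        kern = _temporal_kernel(ev.fdhm, dt) * ev.amplitude

        for i, b in enumerate(sel):
            start = g0 + delays[i]
            if start >= n_frames:
                continue
            stop = min(start + kern.size, n_frames)
            col = cl_cols[b]
            r0, r1 = cell.col_rows[col]
            dff[start:stop, r0:r1, col] += (ramp[i] * kern[: stop - start])[:, None]

    if n_truncated:
        logger.info("render_movie: %d event kernel(s) truncated at the cell edge", n_truncated)

    base = np.full((h, w), config.background, dtype=np.float32)
    base[cell.mask] = config.baseline_f0
    gain = np.zeros((h, w), dtype=np.float32)
    gain[cell.mask] = config.baseline_f0

    stack = base[None, :, :] + gain[None, :, :] * dff
    del dff

    if config.drift is not None:
        ry, rx = config.drift
        out = np.empty_like(stack)
        for f in range(n_frames):
            dy, dx = int(round(ry * f)), int(round(rx * f))
            if dy == 0 and dx == 0:
                out[f] = stack[f]
            else:
                shifted = np.full((h, w), config.background, dtype=np.float32)
                ys0, ys1 = max(0, dy), min(h, h + dy)
                xs0, xs1 = max(0, dx), min(w, w + dx)
                shifted[ys0:ys1, xs0:xs1] = stack[f, ys0 - dy : ys1 - dy, xs0 - dx : xs1 - dx]
                out[f] = shifted
        stack = out

    if config.noise_sd > 0:
        stack = stack + rng.normal(
            0.0, config.noise_sd * config.baseline_f0, size=stack.shape
        ).astype(np.float32)

    np.clip(stack, 0.0, 65535.0, out=stack)
    return Movie(
        intensity=np.round(stack).astype(np.uint16),
        frame_rate=config.frame_rate,
        pixel_size=config.pixel_size,
    )


def simulate_cell(
    config: GeneratorConfig, seed: int | np.random.SeedSequence | None = None
) -> tuple[Movie, CellGeometry, GroundTruth]:
    """Convenience wrapper: geometry + trains + rendering with one seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cell = make_cell(config, rng)
    gt = sample_event_trains(cell, config, rng)
    movie = render_movie(cell, gt, config, rng)
    return movie, cell, gt
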