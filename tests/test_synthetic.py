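"""Generator tests: geometry, event trains, escape model, rendering fidelity."""

import numpy as np
import pytest
from scipy import integrate, stats

import caflux as cf
from caflux.synthetic import (
    EventSpec,
    GroundTruth,
    make_cell,
    render_movie,
    sample_event_trains,
)

from conftest import render_single_event


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def test_single_site_cell_geometry():
    cfg = cf.preset("baseline").replace(n_sites=1, efs=None)
    cell = make_cell(cfg, np.random.default_rng(0))
    assert cell.n_sites == 1
    assert 0.0 <= cell.site_positions_um[0] <= cfg.cell_length
    # centerline lies inside the mask, ordered end to end
    rows = np.round(cell.centerline[:, 0]).astype(int)
    cols = np.round(cell.centerline[:, 1]).astype(int)
    assert cell.mask[rows, cols].all()
    assert (np.diff(cell.centerline[:, 1]) > 0).all()
    assert np.isclose(
        cell.positions_um[-1], cfg.cell_length - cfg.pixel_size, atol=cfg.pixel_size
    )


def test_site_count_sampling_rule():
    """Clamped-Poisson site counts: mean ~5.2, all draws within [1, 13]."""
    cfg = cf.preset("baseline").replace(efs=None)
    rng = np.random.default_rng(7)
    counts = np.array([make_cell(cfg, rng).n_sites for _ in range(500)])
    assert counts.min() >= 1 and counts.max() <= 13
    se = counts.std(ddof=1) / np.sqrt(counts.size)
    assert abs(counts.mean() - 5.2) <= 3 * se


def test_site_min_separation():
    cfg = cf.preset("baseline").replace(n_sites=5, efs=None)
    for s in range(20):
        cell = make_cell(cfg, np.random.default_rng(s))
        assert np.diff(np.sort(cell.site_positions_um)).min() >= cfg.site_min_sep - 1e-9


def test_geometry_deterministic_under_seed():
    cfg = cf.preset("baseline").replace(efs=None)
    a = make_cell(cfg, np.random.default_rng(42))
    b = make_cell(cfg, np.random.default_rng(42))
    assert np.array_equal(a.mask, b.mask)
    assert np.array_equal(a.site_positions_um, b.site_positions_um)


def test_cell_must_fit_frame():
    cfg = cf.preset("baseline").replace(frame_shape=(10, 40), efs=None)
    with pytest.raises(ValueError, match="does not fit"):
        make_cell(cfg, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# Event trains
# ---------------------------------------------------------------------------

def test_zero_rate_gives_no_events():
    cfg = cf.preset("baseline").replace(cell_rate=0.0, efs=None)
    cell = make_cell(cfg, np.random.default_rng(0))
    gt = sample_event_trains(cell, cfg, np.random.default_rng(0))
    assert gt.n_events == 0


def test_poisson_rate_against_count_oracle():
    """Ground-truth event counts match the closed-form Poisson mean."""
    rate, dur, n_cells = 1.0, 60.0, 200
    cfg = cf.preset("baseline").replace(cell_rate=rate, duration=dur, efs=None)
    rng = np.random.default_rng(11)
    counts = []
    for _ in range(n_cells):
        cell = make_cell(cfg, rng)
        counts.append(sample_event_trains(cell, cfg, rng).n_events)
    counts = np.asarray(counts, dtype=float)
    # superposition of per-site Poisson trains is Poisson(rate*dur)
    se_rate = np.sqrt(rate * dur) / dur / np.sqrt(n_cells)
    assert abs(counts.mean() / dur - rate) <= 3 * se_rate


def test_rate_linearity():
    """Doubling cell_rate doubles the expected event count."""
    rng = np.random.default_rng(5)
    means = []
    for rate in (0.6, 1.2):
        cfg = cf.preset("baseline").replace(cell_rate=rate, duration=30.0, efs=None)
        n = [
            sample_event_trains(make_cell(cfg, rng), cfg, rng).n_events
            for _ in range(200)
        ]
        means.append(np.mean(n))
    se = np.sqrt(2 * 0.6 * 30.0) / np.sqrt(200)  # Poisson SD of the doubled count
    assert abs(means[1] - 2 * means[0]) <= 3 * np.sqrt(5) * se


def test_escape_suppression_and_latency_moment():
    """No site fires inside its inhibited window; pooled latencies match the
    censored-normal moment computed by numerical integration."""
    cfg = cf.preset("baseline").replace(duration=20.0)
    efs = cfg.efs
    rng = np.random.default_rng(13)
    latencies = []
    n_sites_total = 0
    while n_sites_total < 1000:
        cell = make_cell(cfg, rng)
        gt = sample_event_trains(cell, cfg, rng)
        n_sites_total += cell.n_sites
        latencies.extend(gt.escape_latencies)
        for ev in gt.events:
            lat = gt.escape_latencies[ev.site_id]
            assert not (efs.onset <= ev.t_init < efs.onset + lat)

    lat = np.asarray(latencies)
    assert lat.min() >= efs.escape_min and lat.max() <= efs.escape_max

    # independent oracle: mean of N(mu, sd) censored to [lo, hi]
    mu, sd, lo, hi = efs.escape_mean, efs.escape_sd, efs.escape_min, efs.escape_max
    mid, _ = integrate.quad(lambda x: x * stats.norm.pdf(x, mu, sd), lo, hi)
    oracle = lo * stats.norm.cdf(lo, mu, sd) + hi * stats.norm.sf(hi, mu, sd) + mid
    # within-cell latency correlation: cluster-robust SE over cells
    se = sd / np.sqrt(lat.size) * np.sqrt(1 + 4.2 * efs.escape_icc)
    assert abs(lat.mean() - oracle) <= 3 * se
    # the pooled mean also sits at the reported 3.8 s (clip vs truncation
    # shifts it by < 0.05 s)
    assert abs(lat.mean() - 3.8) <= 3 * se + 0.05


def test_first_event_after_escape_marks_latency():
    """Each site's first post-onset event initiates exactly at onset+latency."""
    cfg = cf.preset("baseline")
    rng = np.random.default_rng(3)
    cell = make_cell(cfg, rng)
    gt = sample_event_trains(cell, cfg, rng)
    for sid in range(cell.n_sites):
        post = [e.t_init for e in gt.events if e.site_id == sid and e.t_init >= cfg.efs.onset]
        if post:
            assert np.isclose(min(post), cfg.efs.onset + gt.escape_latencies[sid])


def test_event_trains_deterministic_under_seed():
    cfg = cf.preset("baseline")
    outs = []
    for _ in range(2):
        rng = np.random.default_rng(99)
        cell = make_cell(cfg, rng)
        gt = sample_event_trains(cell, cfg, rng)
        outs.append([(e.site_id, e.t_init, e.amplitude) for e in gt.events])
    assert outs[0] == outs[1]


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def test_null_movie_all_frames_identical():
    cfg = cf.preset("baseline").replace(noise_sd=0.0, n_sites=1, duration=2.0, efs=None)
    cell = make_cell(cfg, np.random.default_rng(0))
    gt = GroundTruth(site_positions_um=cell.site_positions_um, events=[])
    movie = render_movie(cell, gt, cfg)
    assert (movie.intensity == movie.intensity[0]).all()
    assert movie.intensity[0][cell.mask].min() == pytest.approx(cfg.baseline_f0, abs=1)


def test_single_event_amplitude_and_fdhm_from_pixels():
    """Recompute dF/F0 at the initiation pixel straight from the stack:
    peak within 2% of the drawn amplitude, half-max width within one frame
    period of the drawn FDHM."""
    movie, cell, ev, cfg = render_single_event()
    p0 = cell.site_positions_um[0]
    b0 = int(np.argmin(np.abs(cell.positions_um - p0)))
    r = int(round(cell.centerline[b0, 0]))
    c = int(round(cell.centerline[b0, 1]))
    trace = movie.intensity[:, r, c].astype(float)
    dff = (trace - cfg.baseline_f0) / cfg.baseline_f0
    assert abs(dff.max() - ev.amplitude) <= 0.02 * ev.amplitude

    half = dff.max() / 2
    above = np.nonzero(dff >= half)[0]
    width_ms = (above[-1] - above[0] + 1) / cfg.frame_rate * 1e3
    assert abs(width_ms - ev.fdhm) <= 1e3 / cfg.frame_rate + 1e-6


def test_single_event_leading_edge_velocity_from_pixels():
    """Leading-edge position vs time, read from the raw stack over the
    advancing phase, has slope within 5% of the drawn velocity."""
    movie, cell, ev, cfg = render_single_event(spread=11.1, velocity=71.4)
    p0 = cell.site_positions_um[0]
    b0 = int(np.argmin(np.abs(cell.positions_um - p0)))
    row = int(round(cell.centerline[b0, 0]))
    cols = cell.centerline[:, 1].astype(int)
    dff = (movie.intensity[:, row, cols].astype(float) - cfg.baseline_f0) / cfg.baseline_f0
    half = dff.max() / 2
    ts, ps = [], []
    for f in range(dff.shape[0]):
        on = np.nonzero(dff[f] >= half)[0]
        if on.size == 0:
            continue
        d = (on - b0) * cfg.pixel_size * ev.direction
        edge = d.max()
        if edge >= ev.spread - cfg.pixel_size:  # fully spread: stop fitting
            break
        ts.append(f / cfg.frame_rate)
        ps.append(edge)
    slope = np.polyfit(ts, ps, 1)[0]
    assert abs(slope - ev.velocity) <= 0.05 * ev.velocity


def test_event_truncated_at_cell_edge_not_error():
    movie, cell, ev, cfg = render_single_event(spread=200.0)
    assert movie.intensity.shape[0] == cfg.n_frames  # rendered fine


def test_movie_deterministic_under_seed(baseline_cfg):
    a = cf.simulate_cell(baseline_cfg, seed=5)[0]
    b = cf.simulate_cell(baseline_cfg, seed=5)[0]
    assert np.array_equal(a.intensity, b.intensity)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "name, rate",
    [("baseline", 1.05), ("lnna", 2.5), ("deanonoate", 0.14), ("vip", 0.08),
     ("odq", 2.1), ("bay58", 0.2), ("vip6_28", 3.3)],
)
def test_preset_rates(name, rate):
    assert cf.preset(name).cell_rate == pytest.approx(rate)


def test_baseline_preset_kinetics():
    cfg = cf.preset("baseline")
    assert cfg.amp_mean == pytest.approx(0.8)
    assert cfg.fdhm == pytest.approx(189.0)
    assert cfg.spread == pytest.approx(11.1)
    assert cfg.velocity == pytest.approx(71.4)
    assert cfg.site_mean == pytest.approx(5.2)
    assert cfg.efs is not None and cfg.efs.escape_mean == pytest.approx(3.8)


def test_unknown_preset_lists_choices():
    with pytest.raises(KeyError, match="baseline"):
        cf.preset("nonesuch")
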