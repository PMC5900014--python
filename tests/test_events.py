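"""Event detection, per-event metrics, and firing-site clustering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import caflux as cf
from caflux.events import Footprint, cluster_sites, detect_events, measure_event
from caflux.stmap import STMap
from caflux.synthetic import EventSpec, GroundTruth, make_cell, render_movie

from conftest import render_single_event


def _stmap(arr, frame_rate=33.0, bin_size=0.5):
    return STMap(dff=np.asarray(arr, dtype=float), bin_size=bin_size, frame_rate=frame_rate)


def _flood_fill_oracle(fg):
    """Brute-force BFS 8-connected labelling of a boolean (bin, frame) mask."""
    seen = np.zeros_like(fg, dtype=bool)
    comps = []
    nb, nf = fg.shape
    for b in range(nb):
        for f in range(nf):
            if not fg[b, f] or seen[b, f]:
                continue
            stack, cells = [(b, f)], []
            seen[b, f] = True
            while stack:
                cb, cfr = stack.pop()
                cells.append((cb, cfr))
                for db in (-1, 0, 1):
                    for df in (-1, 0, 1):
                        xb, xf = cb + db, cfr + df
                        if 0 <= xb < nb and 0 <= xf < nf and fg[xb, xf] and not seen[xb, xf]:
                            seen[xb, xf] = True
                            stack.append((xb, xf))
            comps.append(frozenset(cells))
    return comps


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def test_all_zero_map_detects_nothing():
    assert detect_events(_stmap(np.zeros((30, 60)))) == []


def test_two_rectangles_match_flood_fill_oracle():
    m = np.zeros((40, 60))
    m[5:10, 10:15] = 1.0
    m[20:26, 30:40] = 1.0
    fps = detect_events(_stmap(m))
    got = {frozenset(zip(fp.bins.tolist(), fp.frames.tolist())) for fp in fps}
    want = set(_flood_fill_oracle(m > 0))
    assert got == want and len(got) == 2


@given(st.integers(0, 10_000))
def test_detection_matches_flood_fill_on_random_blocky_maps(seed):
    """Constant-level random rectangles (no internal saddles): components
    must equal the brute-force flood fill, after the size filters."""
    rng = np.random.default_rng(seed)
    m = np.zeros((25, 50))
    for _ in range(rng.integers(1, 5)):
        b0 = rng.integers(0, 20)
        f0 = rng.integers(0, 44)
        m[b0 : b0 + rng.integers(2, 6), f0 : f0 + rng.integers(2, 7)] = 1.0
    fps = detect_events(_stmap(m))
    oracle = [
        c for c in _flood_fill_oracle(m > 0)
        if len({b for b, _ in c}) >= 2 and len({f for _, f in c}) >= 2
    ]
    got = {frozenset(zip(fp.bins.tolist(), fp.frames.tolist())) for fp in fps}
    assert got == set(oracle)


def test_saddle_split_separates_rapid_double_events():
    tr = np.zeros((4, 40))
    tr[1:3, 10:14] = 1.0
    tr[1:3, 14] = 0.3     # saddle below half of both peaks
    tr[1:3, 15:19] = 0.9
    assert len(detect_events(_stmap(tr))) == 2

    tr[1:3, 14] = 0.6     # saddle above half: one event
    assert len(detect_events(_stmap(tr))) == 1


def test_spatial_saddle_separates_simultaneous_neighbours():
    m = np.zeros((40, 30))
    m[5:12, 10:16] = 1.0
    m[12, 10:16] = 0.2    # spatial valley below half
    m[13:20, 10:16] = 0.9
    assert len(detect_events(_stmap(m))) == 2


def test_threshold_monotonicity():
    """Event count is non-increasing in threshold_k."""
    movie, cell, gt = cf.simulate_cell(cf.preset("baseline"), seed=21)
    res = cf.analyze_movie(movie, cell.roi(), protocol=None, params=None)
    smap = res.stmap
    counts = [len(detect_events(smap, threshold_k=k)) for k in (2.0, 2.5, 3.0, 4.0, 5.0, 8.0)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_noise_floor_yields_no_events_on_pure_noise():
    rng = np.random.default_rng(0)
    fps = detect_events(_stmap(rng.normal(0, 0.014, (160, 660))))
    assert len(fps) <= 1


# ---------------------------------------------------------------------------
# Measurement
# ---------------------------------------------------------------------------

def test_point_event_metrics():
    m = np.zeros((5, 8))
    m[2, 3] = 0.7
    ev = measure_event(Footprint(bins=np.array([2]), frames=np.array([3])), _stmap(m))
    assert ev.amplitude == pytest.approx(0.7)
    assert ev.spatial_spread == pytest.approx(0.5)  # one bin
    assert ev.velocity == 0.0
    assert ev.t_init == pytest.approx(3 / 33.0)
    assert ev.p_init == pytest.approx(1.0)


def test_triangular_pulse_fdhm_closed_form():
    """Linear rise/fall pulse: interpolated half-crossings give the exact
    analytic width."""
    fr = 33.0
    n = 200  # long quiescent stretch so the pulse sits in the top quartile
    tri = np.concatenate([np.linspace(0, 1, 11), np.linspace(1, 0, 11)[1:]])
    trace = np.zeros(n)
    trace[50 : 50 + tri.size] = tri
    m = np.vstack([trace, trace])
    fps = detect_events(_stmap(m), threshold_k=3.0)
    assert len(fps) == 1
    ev = measure_event(fps[0], _stmap(m))
    # crossings at half amplitude: 5 frames either side of the peak
    assert ev.fdhm == pytest.approx(10 / fr * 1e3, abs=1e-6)


def test_noise_free_rendered_event_metric_recovery():
    """Amplitude within 5%, FDHM within one frame period, spread within one
    bin, velocity within 10% on a noise-free rendered event."""
    movie, cell, ev, cfg = render_single_event()
    res = cf.analyze_movie(movie, cell.roi())
    assert len(res.events) == 1
    e = res.events[0]
    assert abs(e.amplitude - ev.amplitude) <= 0.05 * ev.amplitude
    assert abs(e.fdhm - ev.fdhm) <= 1e3 / cfg.frame_rate
    assert abs(e.spatial_spread - ev.spread) <= cfg.pixel_size
    assert abs(abs(e.velocity) - ev.velocity) <= 0.10 * ev.velocity


def test_twenty_well_separated_events_all_recovered():
    """Noise-free map with 20 staggered events: exact count, initiation loci
    within one bin / one frame of ground truth."""
    cfg = cf.preset("baseline").replace(noise_sd=0.0, n_sites=4, duration=12.0, efs=None)
    rng = np.random.default_rng(3)
    cell = make_cell(cfg, rng)
    events = []
    for i in range(20):
        site = i % 4
        events.append(
            EventSpec(
                site_id=site, t_init=0.3 + i * 0.55, amplitude=0.8, fdhm=150.0,
                spread=6.0, velocity=71.4, direction=1 if site % 2 else -1,
            )
        )
    gt = GroundTruth(site_positions_um=cell.site_positions_um, events=events)
    movie = render_movie(cell, gt, cfg)
    res = cf.analyze_movie(movie, cell.roi())
    assert len(res.events) == 20
    dt = 1.0 / cfg.frame_rate
    for e, t in zip(sorted(res.events, key=lambda x: x.t_init), events):
        assert abs(e.p_init - cell.site_positions_um[t.site_id]) <= cfg.pixel_size
        assert abs(e.t_init - t.t_init) <= 2 * dt


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _brute_force_single_linkage(positions, linkage):
    """Oracle: iterative pairwise merging of the closest clusters."""
    clusters = [[p] for p in positions]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = min(abs(a - b) for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        if best is None or best[0] > linkage:
            break
        d, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(tuple(sorted(c)) for c in clusters)


def _events_at(positions):
    return [
        cf.CaEvent(
            id=i, t_init=0.0, p_init=float(p), t_peak=0.0, amplitude=1.0,
            fdhm=100.0, spatial_spread=1.0, velocity=0.0, path_length=0.0,
        )
        for i, p in enumerate(positions)
    ]


def test_singleton_cluster():
    sites, evs = cluster_sites(_events_at([12.5]), linkage_um=5.0)
    assert len(sites) == 1 and sites[0].centroid == pytest.approx(12.5)
    assert evs[0].site_id == 0


def test_cluster_example_two_sites():
    sites, _ = cluster_sites(_events_at([10.0, 11.0, 40.0, 41.5]), linkage_um=5.0)
    assert [s.centroid for s in sites] == pytest.approx([10.5, 40.75])
    got = _brute_force_single_linkage([10.0, 11.0, 40.0, 41.5], 5.0)
    assert got == [(10.0, 11.0), (40.0, 41.5)]


@given(st.lists(st.floats(0, 80), min_size=1, max_size=12), st.floats(0.5, 15))
def test_clustering_matches_brute_force(positions, linkage):
    positions = [round(p, 3) for p in positions]
    sites, evs = cluster_sites(_events_at(positions), linkage_um=linkage)
    got = sorted(
        tuple(sorted(positions[i] for i, e in enumerate(evs) if e.site_id == s.id))
        for s in sites
    )
    assert got == _brute_force_single_linkage(positions, linkage)
    # partition property: every event in exactly one site
    assert sorted(i for s in sites for i in s.event_ids) == list(range(len(positions)))


def test_linkage_limits():
    evs = _events_at([1.0, 7.0, 30.0, 30.0, 55.0])
    sites, _ = cluster_sites(evs, linkage_um=1e6)
    assert len(sites) == 1
    sites, _ = cluster_sites(_events_at([1.0, 7.0, 30.0, 30.0, 55.0]), linkage_um=1e-9)
    assert len(sites) == 4  # one per distinct locus


def test_five_true_sites_recovered_noise_free():
    cfg = cf.preset("baseline").replace(
        noise_sd=0.0, n_sites=5, duration=30.0, cell_rate=1.5, efs=None
    )
    movie, cell, gt = cf.simulate_cell(cfg, seed=8)
    res = cf.analyze_movie(movie, cell.roi())
    assert len(res.sites) == 5
    rec = np.sort([s.centroid for s in res.sites])
    true = np.sort(cell.site_positions_um)
    assert np.abs(rec - true).max() <= cfg.pixel_size
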