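"""End-to-end pipelines: analyze one recording, simulate/analyze cohorts, recover.

``analyze_movie`` is the canonical chain stabilize -> ST map -> detect ->
measure -> cluster -> window/escape summaries.  ``run_cohort`` repeats
simulate+analyze over many synthetic cells and ``cohort_metrics`` reduces
the per-cell results to the study's summary quantities (pre-EFS kinetics,
first-2-s EFS activity, sites per cell, escape latencies), which
``recover`` compares against the generator's own ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DetectionParams, EFSProtocol, GeneratorConfig
from .efs import EFS_FIRST2S, PRE, EscapeResult, WindowSummary, escape_latencies, window_metrics
from .events import CaEvent, FiringSite, cluster_sites, find_events
from .stmap import CellROI, Movie, STMap, build_stmap, stabilize
from .synthetic import CellGeometry, GroundTruth, simulate_cell

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    """All pipeline outputs for one recording."""

    stmap: STMap
    events: list[CaEvent]
    sites: list[FiringSite]
    windows: list[WindowSummary] | None = None
    escape: EscapeResult | None = None
    shifts: np.ndarray | None = None
    unstable: np.ndarray | None = None

    @property
    def duration(self) -> float:
        return self.stmap.n_frames / self.stmap.frame_rate

    def window(self, label: str) -> WindowSummary | None:
        if self.windows is None:
            return None
        for w in self.windows:
            if w.label == label:
                return w
        return None

    def events_frame(self) -> pd.DataFrame:
        rows = [
            {
                "event_id": ev.id,
                "site_id": ev.site_id,
                "t_init_s": ev.t_init,
                "p_init_um": ev.p_init,
                "t_peak_s": ev.t_peak,
                "amplitude_dff": ev.amplitude,
                "fdhm_ms": ev.fdhm,
                "spread_um": ev.spatial_spread,
                "velocity_um_s": ev.velocity,
                "path_length_um": ev.path_length,
            }
            for ev in self.events
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "event_id", "site_id", "t_init_s", "p_init_um", "t_peak_s",
                "amplitude_dff", "fdhm_ms", "spread_um", "velocity_um_s",
                "path_length_um",
            ],
        )

    def sites_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"site_id": s.id, "centroid_um": s.centroid, "n_events": s.n_events}
                for s in self.sites
            ],
            columns=["site_id", "centroid_um", "n_events"],
        )


def analyze_movie(
    movie: Movie,
    roi: CellROI,
    protocol: EFSProtocol | None = None,
    params: DetectionParams | None = None,
    stabilize_first: bool = True,
) -> AnalysisResult:
    """Run the full single-cell pipeline on a calibrated movie.

    With a protocol, F0 is estimated from the pre-onset frames and window
    and escape summaries are attached; without one, F0 uses the whole
    recording and only events/sites are returned.
    """
    params = params or DetectionParams()
    params.validate()

    shifts = unstable = None
    if stabilize_first:
        movie, shifts, unstable = stabilize(movie)

    f0_window = None
    if protocol is not None:
        onset_frame = int(protocol.onset * movie.frame_rate)
        if onset_frame >= 33:
            f0_window = (0, onset_frame)
    smap = build_stmap(movie, roi, f0_window=f0_window, exclude_frames=unstable)

    events = find_events(
        smap, params.threshold_k, params.min_frames, params.min_bins
    )
    sites, events = cluster_sites(events, params.linkage_um)

    windows = escape = None
    if protocol is not None:
        duration = movie.n_frames / movie.frame_rate
        windows = window_metrics(events, sites, protocol, duration)
        escape = escape_latencies(events, sites, protocol)
    return AnalysisResult(
        stmap=smap, events=events, sites=sites, windows=windows,
        escape=escape, shifts=shifts, unstable=unstable,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CellResult:
    """One simulated cell with its ground truth and analysis."""

    index: int
    cell: CellGeometry
    ground_truth: GroundTruth
    analysis: AnalysisResult


def run_cohort(
    config: GeneratorConfig,
    n_cells: int,
    seed: int,
    params: DetectionParams | None = None,
) -> list[CellResult]:
    """Simulate and analyze ``n_cells`` independent cells.

    Per-cell randomness is spawned from one seed sequence, so the cohort is
    reproducible as a whole and cells are independent.
    """
    children = np.random.SeedSequence(seed).spawn(n_cells)
    out = []
    for i, ss in enumerate(children):
        movie, cell, gt = simulate_cell(config, seed=ss)
        res = analyze_movie(movie, cell.roi(), protocol=config.efs, params=params)
        out.append(CellResult(index=i, cell=cell, ground_truth=gt, analysis=res))
    return out


@dataclass
class CohortMetric:
    name: str
    estimate: float
    se: float
    n: int
    truth: float | None = None       # same quantity from the ground-truth ledger
    reference: float | None = None   # generator parameterisation (printed value)

    @property
    def within_3se(self) -> bool | None:
        if self.reference is None or not np.isfinite(self.se):
            return None
        return abs(self.estimate - self.reference) <= 3.0 * self.se


def _mean_se(values) -> tuple[float, float, int]:
    v = np.asarray([x for x in values if x is not None and np.isfinite(x)], dtype=float)
    if v.size == 0:
        return float("nan"), float("nan"), 0
    se = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else float("nan")
    return float(v.mean()), float(se), int(v.size)


def cohort_metrics(results: list[CellResult], config: GeneratorConfig) -> dict[str, CohortMetric]:
    """Reduce per-cell analyses to the study's cohort summary quantities.

    Kinetic metrics (amplitude/FDHM/spread/velocity) are cohort means of
    per-cell means over pre-EFS events, matching the cells-as-units
    convention; escape latencies are also pooled over sites.  Without an
    EFS protocol only whole-recording frequency and sites per cell are
    produced.
    """
    efs = config.efs
    metrics: dict[str, CohortMetric] = {}

    def add(name, values, truth=None, reference=None):
        est, se, n = _mean_se(values)
        metrics[name] = CohortMetric(name, est, se, n, truth, reference)

    sites_per_cell = [len(r.analysis.sites) for r in results]
    true_sites = [r.cell.n_sites for r in results]
    add(
        "sites_per_cell",
        sites_per_cell,
        truth=float(np.mean(true_sites)),
        reference=config.site_mean if not isinstance(config.n_sites, int) else float(config.n_sites),
    )

    if efs is None:
        dur = config.duration
        add(
            "frequency_hz",
            [len(r.analysis.events) / dur for r in results],
            truth=float(np.mean([r.ground_truth.n_events / dur for r in results])),
            reference=config.cell_rate,
        )
        return metrics

    def win(r, label):
        return r.analysis.window(label)

    add(
        "pre_frequency_hz",
        [win(r, PRE).frequency for r in results],
        truth=float(np.mean([
            sum(1 for ev in r.ground_truth.events if efs.onset - 5.0 <= ev.t_init < efs.onset) / 5.0
            for r in results
        ])),
        reference=config.cell_rate,
    )
    add(
        "efs2_frequency_hz",
        [win(r, EFS_FIRST2S).frequency for r in results],
        truth=float(np.mean([
            sum(1 for ev in r.ground_truth.events
                if efs.onset <= ev.t_init < efs.onset + 2.0) / 2.0
            for r in results
        ])),
    )
    add(
        "efs2_active_sites",
        [win(r, EFS_FIRST2S).active_sites for r in results],
        truth=float(np.mean([
            len({ev.site_id for ev in r.ground_truth.events
                 if efs.onset <= ev.t_init < efs.onset + 2.0})
            for r in results
        ])),
    )
    add(
        "pre_amplitude_dff",
        [win(r, PRE).mean_amplitude for r in results],
        reference=config.amp_mean,
    )
    add(
        "pre_fdhm_ms",
        [win(r, PRE).mean_fdhm for r in results],
        reference=config.fdhm,
    )
    add(
        "pre_spread_um",
        [win(r, PRE).mean_spread for r in results],
        reference=config.spread,
    )
    add(
        "pre_velocity_um_s",
        [win(r, PRE).mean_velocity for r in results],
        reference=config.velocity,
    )

    first = [r.analysis.escape.first_site_latency for r in results if r.analysis.escape]
    true_first = [
        float(np.nanmin(r.ground_truth.escape_latencies))
        for r in results
        if r.ground_truth.escape_latencies is not None
    ]
    add("first_escape_s", first, truth=float(np.mean(true_first)))

    per_cell = [
        r.analysis.escape.latencies[np.isfinite(r.analysis.escape.latencies)]
        for r in results
        if r.analysis.escape is not None
    ]
    pooled = np.concatenate(per_cell)
    true_pooled = np.concatenate([
        r.ground_truth.escape_latencies
        for r in results
        if r.ground_truth.escape_latencies is not None
    ])
    est = float(pooled.mean()) if pooled.size else float("nan")
    # escape latencies share a within-cell component, so the SE of the
    # pooled mean is computed cluster-robustly (cells as clusters)
    cell_sums = np.array([c.sum() for c in per_cell if c.size])
    cell_ns = np.array([c.size for c in per_cell if c.size])
    if cell_ns.size > 1:
        resid = cell_sums - est * cell_ns
        se = float(np.sqrt(np.sum(resid**2) * cell_ns.size / (cell_ns.size - 1)) / pooled.size)
    else:
        se = float("nan")
    metrics["site_escape_s"] = CohortMetric(
        "site_escape_s", est, se, int(pooled.size),
        truth=float(true_pooled.mean()), reference=efs.escape_mean,
    )
    return metrics


def recovery_report(metrics: dict[str, CohortMetric]) -> pd.DataFrame:
    """Tabulate estimates vs ground truth vs parameterisation, with 3-SE flags."""
    rows = []
    for m in metrics.values():
        rows.append(
            {
                "metric": m.name,
                "estimate": m.estimate,
                "se": m.se,
                "n": m.n,
                "ci95_lo": m.estimate - 1.96 * m.se,
                "ci95_hi": m.estimate + 1.96 * m.se,
                "truth": m.truth,
                "reference": m.reference,
                "within_3se_of_reference": m.within_3se,
            }
        )
    return pd.DataFrame(rows)


def recover(
    config: GeneratorConfig,
    n_cells: int,
    seed: int,
    params: DetectionParams | None = None,
) -> tuple[pd.DataFrame, dict[str, CohortMetric]]:
    """Cohort-level parameter recovery: simulate, analyze, tabulate."""
    results = run_cohort(config, n_cells, seed, params)
    metrics = cohort_metrics(results, config)
    return recovery_report(metrics), metrics
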