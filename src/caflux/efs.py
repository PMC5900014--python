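"""Stimulation-epoch analysis: protocol windows and escape-from-inhibition latencies.

A recording with an EFS train is partitioned into half-open windows —
pre-stimulus, the first 2 s of the train (the inhibitory phase analysed in
the emulated experiments), the remainder of the train, and post-stimulus —
and per-window event summaries are computed.  Escape latency of a firing
site is the time from train onset to the site's first event initiation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import EFSProtocol
from .events import CaEvent, FiringSite

logger = logging.getLogger(__name__)

PRE = "pre"
EFS_FIRST2S = "efs_first2s"
EFS_LATE = "efs_late"
POST = "post"


@dataclass
class WindowSummary:
    """Per-window event summary for one cell.

    Means are None (absent) when the window holds no events — never
    zero-valued.  ``mean_velocity`` averages the magnitude of the signed
    leading-edge velocities over propagating events only (events too brief
    to measure propagation carry a definitional velocity of 0 and would
    dilute a propagation-speed average).
    """

    label: str
    start: float
    end: float
    duration: float
    n_events: int
    frequency: float                 # events/s per cell
    mean_amplitude: float | None     # dF/F0
    mean_fdhm: float | None          # ms
    mean_spread: float | None        # um
    mean_velocity: float | None      # um/s
    active_sites: int


@dataclass
class EscapeResult:
    """Per-site escape latencies for one cell (NaN = censored)."""

    site_ids: np.ndarray
    latencies: np.ndarray            # s; NaN where censored
    onset: float

    @property
    def first_site_latency(self) -> float:
        """Minimum uncensored latency (NaN if every site is censored)."""
        ok = self.latencies[np.isfinite(self.latencies)]
        return float(ok.min()) if ok.size else float("nan")

    @property
    def n_censored(self) -> int:
        return int(np.sum(~np.isfinite(self.latencies)))


def default_windows(
    protocol: EFSProtocol, pre_s: float = 5.0, post_s: float = 5.0
) -> dict[str, tuple[float, float]]:
    """The four standard analysis windows, as half-open [start, end) intervals."""
    on, end = protocol.onset, protocol.train_end
    return {
        PRE: (on - pre_s, on),
        EFS_FIRST2S: (on, min(on + 2.0, end)),
        EFS_LATE: (min(on + 2.0, end), end),
        POST: (end, end + post_s),
    }


def window_metrics(
    events: list[CaEvent],
    sites: list[FiringSite],
    protocol: EFSProtocol,
    recording_duration: float,
    windows: dict[str, tuple[float, float]] | None = None,
) -> list[WindowSummary]:
    """Summarise events per protocol window; assignment is by t_init.

    Windows extending beyond the recording are truncated (with the duration
    adjusted, so frequencies stay correct) and logged.
    """
    if windows is None:
        windows = default_windows(protocol)
    out = []
    for label, (start, end) in windows.items():
        t0, t1 = max(start, 0.0), min(end, recording_duration)
        if (t0, t1) != (start, end):
            logger.warning(
                "window %s truncated from [%.2f, %.2f) to [%.2f, %.2f)",
                label, start, end, t0, t1,
            )
        dur = max(t1 - t0, 0.0)
        inside = [ev for ev in events if t0 <= ev.t_init < t1]
        n = len(inside)
        freq = n / dur if dur > 0 else 0.0
        active = len({ev.site_id for ev in inside if ev.site_id is not None})

        def _mean(attr, transform=lambda x: x):
            return float(np.mean([transform(getattr(ev, attr)) for ev in inside])) if n else None

        moving = [abs(ev.velocity) for ev in inside if abs(ev.velocity) > 1e-9]
        mean_vel = float(np.mean(moving)) if moving else None

        out.append(
            WindowSummary(
                label=label,
                start=t0,
                end=t1,
                duration=dur,
                n_events=n,
                frequency=freq,
                mean_amplitude=_mean("amplitude"),
                mean_fdhm=_mean("fdhm"),
                mean_spread=_mean("spatial_spread"),
                mean_velocity=mean_vel,
                active_sites=active,
            )
        )
    return out


def escape_latencies(
    events: list[CaEvent],
    sites: list[FiringSite],
    protocol: EFSProtocol,
) -> EscapeResult:
    """Per-site latency from EFS onset to the first post-onset event initiation.

    A site with no event at or after onset before the recording ends is
    censored (NaN).  Latency 0 means an event initiated exactly at onset.
    """
    if not sites:
        return EscapeResult(
            site_ids=np.empty(0, dtype=int), latencies=np.empty(0), onset=protocol.onset
        )
    by_id = {ev.id: ev for ev in events}
    lat = np.full(len(sites), np.nan)
    ids = np.array([s.id for s in sites])
    for i, site in enumerate(sites):
        ts = [
            by_id[eid].t_init
            for eid in site.event_ids
            if by_id[eid].t_init >= protocol.onset
        ]
        if ts:
            lat[i] = min(ts) - protocol.onset
    return EscapeResult(site_ids=ids, latencies=lat, onset=protocol.onset)
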