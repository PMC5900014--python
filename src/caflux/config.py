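"""Configuration objects for the synthetic-recording generator and the analysis pipeline.

The generator emulates confocal GCaMP3 recordings of spindle-shaped ICC-DMP
(interstitial cells of Cajal, deep muscular plexus) acquired at 33 frames/s:
localized firing sites distributed along the cell axis emit stochastic,
uncoordinated Ca2+ transients, optionally suppressed by an electrical field
stimulation (EFS) epoch from which individual sites escape after variable
latencies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass
class EFSProtocol:
    """Electrical field stimulation epoch and the per-site escape model.

    EFS of intrinsic enteric nerves silences Ca2+ firing sites; each site
    resumes firing ("escapes") after an inhibitory period.  The inhibitory
    period of a site is defined, as in the experimental analysis, by the
    first Ca2+ transient at that site after stimulus onset.

    Parameters
    ----------
    onset : float
        Stimulus train onset, seconds from recording start.
    train_duration : float
        Train length in seconds (5 s trains in the emulated experiments).
    pulse_freq : float
        Pulse frequency in Hz.  Metadata only; pulses are not rendered.
    escape_mean, escape_sd : float
        Mean and SD (seconds) of the pooled per-site inhibitory period.
    escape_min, escape_max : float
        Range the inhibitory periods are clipped to (seconds).
    escape_icc : float
        Intraclass correlation of latencies among the sites of one cell.
        The latency variance is split into a cell-level shared component
        (``escape_icc`` of the variance) and independent per-site jitter.
        0 makes sites fully independent.
    post_escape_rate_gain : float
        Multiplier applied to a site's firing rate after it escapes,
        emulating the rebound excitation that follows the inhibitory phase.
    """

    onset: float
    train_duration: float = 5.0
    pulse_freq: float = 10.0
    escape_mean: float = 3.8
    escape_sd: float = 1.8
    escape_min: float = 0.2
    escape_max: float = 9.9
    escape_icc: float = 0.5
    post_escape_rate_gain: float = 1.5

    def validate(self) -> None:
        if self.train_duration <= 0:
            raise ValueError("train_duration must be > 0")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.escape_min < 0:
            raise ValueError("escape_min must be >= 0")
        if not (self.escape_min <= self.escape_mean <= self.escape_max):
            raise ValueError("need escape_min <= escape_mean <= escape_max")
        if not 0.0 <= self.escape_icc <= 1.0:
            raise ValueError("escape_icc must be in [0, 1]")
        if self.escape_sd < 0:
            raise ValueError("escape_sd must be >= 0")

    @property
    def train_end(self) -> float:
        return self.onset + self.train_duration


@dataclass
class GeneratorConfig:
    """Parameters of one synthetic ICC-DMP recording.

    Geometry and acquisition
    ------------------------
    pixel_size : um per pixel (0.5 um matches a 60x confocal field of view).
    frame_rate : frames per second.
    duration : recording length, seconds.
    cell_length, cell_width : spindle dimensions, um.
    frame_shape : optional (rows, cols); if omitted, a frame that fits the
        cell plus a margin is chosen.  A frame too small for the cell is an
        error.

    Firing sites
    ------------
    n_sites : fixed integer count, or "poisson" for a clamped-Poisson rule
        (mean ``site_mean``, clamped to [site_min, site_max]).  ICC-DMP carry
        1-13 discrete firing sites, averaging ~5.2 per cell.
    site_min_sep : minimum separation between sites, um.  Chosen as twice the
        default clustering linkage so ground-truth sites are resolvable; when
        a draw of k sites cannot fit at this separation the spacing is relaxed
        to the widest feasible value.
    site_end_margin : keep sites this far (um) from the tapered cell ends.

    Event statistics
    ----------------
    cell_rate : whole-cell event rate, events/s, split evenly across sites.
    amp_mean, amp_cv : lognormal peak-amplitude distribution (dF/F0).
    fdhm : mean full duration at half maximum, ms.
    spread : mean spatial spread (half-maximum extent), um.
    velocity : mean propagation speed of the leading edge, um/s.
    kinetic_cv : lognormal CV shared by the FDHM/spread/velocity draws.

    Imaging model
    -------------
    baseline_f0 : resting in-cell intensity, camera counts.
    background : out-of-cell intensity, counts.
    noise_sd : Gaussian read noise SD in dF/F0 units (sigma = noise_sd * F0).
    drift : optional (rows/frame, cols/frame) rigid drift rate in px/frame.
    """

    pixel_size: float = 0.5
    frame_rate: float = 33.0
    duration: float = 20.0
    cell_length: float = 80.0
    cell_width: float = 6.0
    frame_shape: tuple[int, int] | None = None

    n_sites: int | str = "poisson"
    site_mean: float = 5.2
    site_min: int = 1
    site_max: int = 13
    site_min_sep: float = 10.0
    site_end_margin: float = 4.0

    cell_rate: float = 1.05
    amp_mean: float = 0.8
    amp_cv: float = 0.3
    fdhm: float = 189.0
    spread: float = 11.1
    velocity: float = 71.4
    kinetic_cv: float = 0.3

    baseline_f0: float = 1000.0
    background: float = 100.0
    noise_sd: float = 0.05
    drift: tuple[float, float] | None = None

    efs: EFSProtocol | None = None
    seed: int | None = None

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.cell_length <= 0 or self.cell_width <= 0:
            raise ValueError("cell dimensions must be > 0")
        if isinstance(self.n_sites, str):
            if self.n_sites != "poisson":
                raise ValueError("n_sites must be an int or 'poisson'")
            if self.site_min < 1 or self.site_max < self.site_min:
                raise ValueError("need 1 <= site_min <= site_max")
        elif self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.cell_rate < 0:
            raise ValueError("cell_rate must be >= 0")
        if self.amp_mean <= 0:
            raise ValueError("amp_mean must be > 0")
        if self.fdhm <= 2.0 * self.frame_period * 1e3:
            raise ValueError("fdhm must exceed two frame periods")
        if self.spread < self.pixel_size:
            raise ValueError("spread must be >= pixel_size")
        if self.velocity <= 0:
            raise ValueError("velocity must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline_f0 <= 0:
            raise ValueError("baseline_f0 must be > 0")
        if self.efs is not None:
            self.efs.validate()
            if self.efs.onset + self.efs.train_duration > self.duration:
                raise ValueError("duration must cover the EFS train")

    @property
    def frame_period(self) -> float:
        """Frame period in seconds."""
        return 1.0 / self.frame_rate

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    def replace(self, **kw) -> "GeneratorConfig":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kw)


@dataclass
class DetectionParams:
    """Event-detection and site-clustering knobs (see ``caflux.events``)."""

    threshold_k: float = 3.0
    min_frames: int = 2
    min_bins: int = 2
    linkage_um: float = 5.0

    def validate(self) -> None:
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be > 0")
        if self.min_frames < 1 or self.min_bins < 1:
            raise ValueError("min_frames and min_bins must be >= 1")
        if self.linkage_um <= 0:
            raise ValueError("linkage_um must be > 0")


@dataclass
class AnalysisConfig:
    """End-to-end analysis run description (file-driven entry point)."""

    movie: str
    roi: str
    out_dir: str
    efs_onset: float | None = None
    efs_duration: float = 5.0
    detection: DetectionParams = field(default_factory=DetectionParams)
    pre_window_s: float = 5.0
    post_window_s: float = 5.0
    seed: int = 0
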