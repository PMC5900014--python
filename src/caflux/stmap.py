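"""Movies, cell ROIs, and spatio-temporal (ST) maps.

An ST map is the kymograph of a single cell: fluorescence collapsed across
the cell's short axis and expressed as dF/F0, indexed by position along the
centerline (rows) and frame (columns).  The pipeline is:

    stabilize -> build_stmap (transverse collapse + dF/F0 normalisation)

Coordinates: frames and bins are 0-based; times are frame_index/frame_rate
seconds; positions are bin_index*bin_size um from the ``origin`` cell end;
intervals are half-open [start, end).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage.draw import polygon2mask

logger = logging.getLogger(__name__)


@dataclass
class Movie:
    """Calibrated single-channel image stack (frame, row, column) in counts."""

    intensity: np.ndarray
    frame_rate: float
    pixel_size: float

    def validate(self) -> None:
        if self.intensity.ndim != 3 or self.intensity.shape[0] < 2:
            raise ValueError("movie must be a 3-D stack with >= 2 frames")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("movie intensities must be finite and >= 0")
        if self.frame_rate <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_rate and pixel_size must be > 0")

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.intensity.shape[1:]


@dataclass
class CellROI:
    """Whole-cell region of interest: polygon outline plus ordered centerline.

    ``polygon`` and ``centerline`` are (N, 2) arrays of (row, col) pixel
    coordinates; the centerline runs from one cell end to the other and
    defines the spatial axis of the ST map.
    """

    polygon: np.ndarray
    centerline: np.ndarray

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        self.centerline = np.asarray(self.centerline, dtype=float)

    def validate(self, pixel_size: float | None = None) -> None:
        if self.polygon.ndim != 2 or self.polygon.shape[0] < 3:
            raise ValueError("polygon needs >= 3 vertices")
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2:
            raise ValueError("centerline needs >= 2 points")
        if pixel_size is not None:
            steps = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
            if steps.sum() * pixel_size < 4.0:
                raise ValueError("centerline shorter than 4 um")

    def mask(self, frame_shape: tuple[int, int]) -> np.ndarray:
        """Rasterize the polygon onto a frame of the given shape."""
        if (self.polygon[:, 0].max() >= frame_shape[0] + 0.5) or (
            self.polygon[:, 1].max() >= frame_shape[1] + 0.5
        ) or self.polygon.min() < -0.5:
            raise ValueError("ROI polygon extends outside the frame")
        return polygon2mask(frame_shape, self.polygon)


@dataclass
class STMap:
    """Position-along-cell x time dF/F0 matrix for one cell.

    ``dff`` has shape (n_bins, n_frames); bins with no in-polygon pixels are
    NaN and flagged in ``missing``.  ``bin_size`` equals the movie pixel size
    (one bin per centerline point).
    """

    dff: np.ndarray
    bin_size: float
    frame_rate: float
    origin: str = "centerline start"
    f0: np.ndarray | None = None
    missing: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]


# ---------------------------------------------------------------------------
# Motion stabilisation
# ---------------------------------------------------------------------------

def _integer_shift(frame: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    """Translate by whole pixels, filling exposed borders with ``fill``."""
    out = np.full_like(frame, fill)
    h, w = frame.shape
    ys0, ys1 = max(0, dy), min(h, h + dy)
    xs0, xs1 = max(0, dx), min(w, w + dx)
    out[ys0:ys1, xs0:xs1] = frame[ys0 - dy : ys1 - dy, xs0 - dx : xs1 - dx]
    return out


def stabilize(
    movie: Movie,
    reference_frame_index: int = 0,
    max_shift_frac: float = 0.2,
) -> tuple[Movie, np.ndarray, np.ndarray]:
    """Rigid integer-pixel registration of every frame to a reference frame.

    Each frame is translated by the integer shift that maximises its
    cross-correlation (computed by FFT, mean-subtracted) with the reference
    frame; exposed borders are filled with the frame's median intensity.

    Returns
    -------
    (stabilized_movie, shifts, unstable)
        ``shifts`` is (n_frames, 2) of applied (dy, dx); ``unstable`` flags
        frames whose estimated displacement exceeded ``max_shift_frac`` of
        the frame dimension — these are left untranslated (shift recorded as
        0) and should be excluded from downstream analysis.
    """
    movie.validate()
    stack = movie.intensity.astype(np.float64)
    ref = stack[reference_frame_index]
    h, w = ref.shape

    ref_c = ref - ref.mean()
    frames_c = stack - stack.mean(axis=(1, 2), keepdims=True)
    # circular cross-correlation of every frame with the reference, batched
    corr = np.fft.irfft2(
        np.fft.rfft2(ref_c)[None] * np.conj(np.fft.rfft2(frames_c, axes=(1, 2))),
        s=(h, w),
        axes=(1, 2),
    )
    flat = corr.reshape(corr.shape[0], -1).argmax(axis=1)
    dy = flat // w
    dx = flat % w
    # wrap-around: displacements are signed, in (-dim/2, dim/2]
    dy = np.where(dy > h // 2, dy - h, dy)
    dx = np.where(dx > w // 2, dx - w, dx)

    unstable = (np.abs(dy) > max_shift_frac * h) | (np.abs(dx) > max_shift_frac * w)
    if unstable.any():
        logger.warning(
            "stabilize: %d frame(s) exceeded the %.0f%% shift limit and were "
            "flagged unstable",
            int(unstable.sum()),
            100 * max_shift_frac,
        )

    out = np.empty_like(movie.intensity)
    shifts = np.zeros((movie.n_frames, 2), dtype=int)
    for f in range(movie.n_frames):
        if unstable[f] or (dy[f] == 0 and dx[f] == 0):
            out[f] = movie.intensity[f]
            continue
        fill = float(np.median(movie.intensity[f]))
        out[f] = _integer_shift(movie.intensity[f], int(dy[f]), int(dx[f]), fill)
        shifts[f] = (dy[f], dx[f])
    return Movie(out, movie.frame_rate, movie.pixel_size), shifts, unstable


# ---------------------------------------------------------------------------
# Baseline and ST-map construction
# ---------------------------------------------------------------------------

# SD of a standard normal after one-sided trimming at the 75th percentile
# (trimmed-SD consistency factor).
_TRIM_SD_FACTOR = 0.731228


def compute_f0(
    traces: np.ndarray,
    percentile: float = 10.0,
    window: tuple[int, int] | None = None,
) -> np.ndarray:
    """Per-bin baseline fluorescence F0.

    F0 is the ``percentile`` (default 10th) of each bin's intensity trace,
    over the whole recording or over the frame ``window`` [start, stop)
    (e.g. a pre-stimulus epoch).  A low percentile resists contamination by
    frequent events but under-reads the baseline of a noisy trace by
    z_q * noise SD; that offset is added back using a robust (trimmed-SD)
    per-bin noise estimate, so dF/F0 of quiescent bins is centred on zero.
    F0 is floored at 1 count so dF/F0 is always defined.

    ``traces`` is (n_bins, n_frames); returns (n_bins,) floats.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2:
        raise ValueError("traces must be 2-D (bins x frames)")
    sub = traces if window is None else traces[:, window[0] : window[1]]
    if sub.shape[1] < 33:
        logger.warning("compute_f0: fewer than 33 frames available for baseline")
    with np.errstate(all="ignore"):
        f0 = np.nanpercentile(sub, percentile, axis=1)
        cut = np.nanpercentile(sub, 75.0, axis=1)
    # robust per-bin noise SD: trimmed SD with its truncation-consistency factor
    masked = np.where(sub <= cut[:, None], sub, np.nan)
    with np.errstate(all="ignore"):
        sigma = np.nanstd(masked, axis=1) / _TRIM_SD_FACTOR
    from scipy.stats import norm

    z = float(norm.isf(percentile / 100.0))
    f0 = f0 + z * np.nan_to_num(sigma)
    low = ~(f0 >= 1.0)  # catches NaN too
    if np.any(low):
        logger.warning("compute_f0: %d bin(s) floored at F0 = 1 count", int(np.sum(low)))
        f0 = np.where(low, 1.0, f0)
    return f0


def build_stmap(
    movie: Movie,
    roi: CellROI,
    f0_window: tuple[int, int] | None = None,
    exclude_frames: np.ndarray | None = None,
) -> STMap:
    """Collapse a stabilized movie onto the cell centerline as a dF/F0 map.

    Every in-polygon pixel is assigned to its nearest centerline point; the
    ST-map value of (bin, frame) is the mean intensity of that bin's pixels,
    normalised per bin to dF/F0 = (F - F0)/F0 with F0 from
    :func:`compute_f0`.

    ``exclude_frames`` (boolean, e.g. the unstable flags from
    :func:`stabilize`) marks frames whose values are set to NaN.
    """
    movie.validate()
    roi.validate(pixel_size=movie.pixel_size)
    mask = roi.mask(movie.frame_shape)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("ROI polygon covers no pixels")

    tree = cKDTree(roi.centerline)
    _, bin_idx = tree.query(np.column_stack([rows, cols]).astype(float))
    n_bins = roi.centerline.shape[0]

    order = np.argsort(bin_idx, kind="stable")
    bin_sorted = bin_idx[order]
    present, starts, counts = np.unique(bin_sorted, return_index=True, return_counts=True)

    pix = movie.intensity[:, rows[order], cols[order]].astype(np.float64)
    sums = np.add.reduceat(pix, starts, axis=1)
    traces = np.full((n_bins, movie.n_frames), np.nan)
    traces[present] = (sums / counts).T

    missing = np.ones(n_bins, dtype=bool)
    missing[present] = False
    if missing.any():
        logger.warning("build_stmap: %d empty transverse slice(s)", int(missing.sum()))

    f0 = compute_f0(traces, window=f0_window)
    dff = (traces - f0[:, None]) / f0[:, None]
    if exclude_frames is not None and np.any(exclude_frames):
        dff[:, np.asarray(exclude_frames, dtype=bool)] = np.nan
    return STMap(
        dff=dff,
        bin_size=movie.pixel_size,
        frame_rate=movie.frame_rate,
        f0=f0,
        missing=missing,
    )
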