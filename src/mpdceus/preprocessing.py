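"""Loop containers and preprocessing: log-decompression, smoothing, TIC extraction.

A DCE-US loop is a T x H x W echo-intensity stack with frame-rate and
pixel-spacing metadata.  Scanners export log-compressed grey levels; TIC
analysis needs linear intensities, so `linearize` inverts the compression
with a configurable dynamic range (the exact scanner mapping is generally
proprietary; the default 30 dB mapping is a documented stand-in).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "DceusLoop",
    "TimeIntensityCurve",
    "linearize",
    "compress",
    "smooth",
    "bolus_arrival_index",
    "extract_tic_stack",
    "extract_tics",
]


@dataclass
class DceusLoop:
    """2D+t echo-intensity stack with acquisition metadata.

    ``compression`` is "linear" or "log"; log loops carry grey levels in
    [0, g_max] with a ``dynamic_range`` in dB.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_spacing: float
    compression: str = "linear"
    dynamic_range: float | None = None
    g_max: float = 255.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be a T x H x W stack with T >= 2")
        if self.frame_rate <= 0 or self.pixel_spacing <= 0:
            raise ValueError("frame_rate and pixel_spacing must be positive")
        if self.compression not in ("linear", "log"):
            raise ValueError(f"unknown compression state {self.compression!r}")
        if self.compression == "linear" and np.min(self.frames) < 0:
            raise ValueError("linear-scale intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) / self.frame_rate


@dataclass
class TimeIntensityCurve:
    """One pixel's preprocessed (time, intensity) series."""

    time: np.ndarray
    intensity: np.ndarray
    pixel_coord: tuple[int, int] = field(default=(0, 0))

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must have equal length")


def linearize(loop: DceusLoop) -> DceusLoop:
    """Invert log compression: I = 10**(g * DR / (g_max * 10)).

    Grey level 0 maps to the unit floor, g_max maps to 10**(DR/10).
    Idempotent on linear loops.
    """
    if loop.compression == "linear":
        return loop
    if loop.dynamic_range is None:
        raise ValueError("log-compressed loop without a dynamic_range cannot be linearized")
    lin = 10.0 ** (loop.frames * loop.dynamic_range / (loop.g_max * 10.0))
    return replace(loop, frames=lin, compression="linear", dynamic_range=loop.dynamic_range)


def compress(loop: DceusLoop, dynamic_range: float | None = None, g_max: float | None = None) -> DceusLoop:
    """Log-compress a linear loop (inverse of `linearize`)."""
    if loop.compression == "log":
        return loop
    dr = dynamic_range if dynamic_range is not None else loop.dynamic_range
    if dr is None:
        raise ValueError("dynamic_range required to compress a linear loop")
    gm = g_max if g_max is not None else loop.g_max
    clipped = np.clip(loop.frames, 1.0, 10.0 ** (dr / 10.0))
    g = gm * 10.0 * np.log10(clipped) / dr
    return replace(loop, frames=g, compression="log", dynamic_range=dr, g_max=gm)


def smooth(loop: DceusLoop, spatial_sigma: float = 0.5, temporal_cutoff: float = 0.5) -> DceusLoop:
    """Gaussian spatial smoothing plus zero-phase temporal low-pass.

    ``spatial_sigma`` is in mm (converted through pixel_spacing; 0 disables),
    ``temporal_cutoff`` in Hz (None disables).  The temporal filter is a
    zero-phase second-order Butterworth, which preserves DC (constant pixels
    are unchanged) and timing landmarks.  Output is clipped at zero.
    """
    if loop.compression != "linear":
        raise ValueError("smooth expects a linear-scale loop")
    frames = loop.frames
    if spatial_sigma and spatial_sigma > 0:
        sigma_px = spatial_sigma / loop.pixel_spacing
        frames = gaussian_filter(frames, sigma=(0.0, sigma_px, sigma_px), mode="nearest")
    if temporal_cutoff is not None:
        nyquist = loop.frame_rate / 2.0
        if temporal_cutoff >= nyquist:
            raise ValueError(
                f"temporal_cutoff {temporal_cutoff} Hz must be below Nyquist {nyquist} Hz"
            )
        sos = butter(2, temporal_cutoff, fs=loop.frame_rate, output="sos")
        frames = sosfiltfilt(sos, frames, axis=0)
    return replace(loop, frames=np.clip(frames, 0.0, None))


def bolus_arrival_index(loop: DceusLoop, threshold_fraction: float = 0.05) -> int:
    """First frame where the field-mean intensity exceeds 5% of its own excursion.

    The excursion is measured above the field-mean minimum so that a static
    echogenicity pedestal does not mask the bolus arrival.  Frames before
    this index form the baseline window.
    """
    m = loop.frames.mean(axis=(1, 2))
    m = m - m.min()
    peak = m.max()
    if peak <= 0:
        return 0
    idx = np.nonzero(m >= threshold_fraction * peak)[0]
    return int(idx[0]) if idx.size else 0


def extract_tic_stack(loop: DceusLoop, mask: np.ndarray | None = None):
    """Baseline-subtracted TICs for all (masked) pixels, as arrays.

    Returns ``(time, tics, coords, baseline)`` where ``tics`` is T x N, the
    baseline is the per-pixel median over the pre-arrival window (zero when
    the bolus is already present at frame 0), and negative residuals are
    clipped at zero.  ``coords`` is N x 2 (row, col).
    """
    if loop.compression != "linear":
        raise ValueError("extract_tic_stack expects a linear-scale loop")
    h, w = loop.shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (h, w):
        raise ValueError("mask shape must match the loop frames")
    if not mask.any():
        raise ValueError("mask selects no pixels")
    arrival = bolus_arrival_index(loop)
    coords = np.argwhere(mask)
    pix = loop.frames[:, mask]
    if arrival > 0:
        baseline = np.median(pix[:arrival], axis=0)
    else:
        baseline = np.zeros(pix.shape[1])
    tics = np.clip(pix - baseline, 0.0, None)
    return loop.times, tics, coords, baseline


def extract_tics(loop: DceusLoop, mask: np.ndarray | None = None) -> list[TimeIntensityCurve]:
    """One `TimeIntensityCurve` per pixel inside ``mask`` (or all pixels)."""
    time, tics, coords, _ = extract_tic_stack(loop, mask)
    return [
        TimeIntensityCurve(time, tics[:, i], (int(r), int(c)))
        for i, (r, c) in enumerate(coords)
    ]
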