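"""Dispersion similarity analysis: ring-kernel neighborhood statistics.

Dispersion of the contrast bolus through the microvasculature alters how
similar a pixel's TIC is to the TICs around it.  Two statistics are
computed against a ring-shaped neighborhood of 1.0-2.5 mm radius (the
spatial scale of early angiogenesis):

r    spatiotemporal correlation: mean Pearson correlation between the
     windowed center TIC and each windowed neighbor TIC.
rho  spectral coherence: mean magnitude-squared coherence (Welch estimate)
     between center and neighbor, averaged over a low-frequency band.

Both are computed on an analysis window around bolus arrival of the
field-mean TIC (default [AT - 5 s, AT + 20 s]); r is invariant under
affine intensity rescaling, rho under per-pixel gain and delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .preprocessing import DceusLoop, extract_tic_stack

__all__ = [
    "SimilarityConfig",
    "SimilarityMaps",
    "ring_kernel",
    "analysis_window",
    "spatiotemporal_correlation",
    "spectral_coherence",
    "similarity_maps",
]


@dataclass
class SimilarityConfig:
    ring_inner: float = 1.0        # mm
    ring_outer: float = 2.5        # mm
    window_pre: float = 5.0        # s before field-mean appearance time
    window_post: float = 20.0      # s after
    coherence_band: tuple[float, float] = (0.0, 0.5)   # Hz, DC excluded
    nperseg: int | None = None     # Welch segment length; None = automatic
    min_neighbors: int | None = None  # None = half the full ring count

    def __post_init__(self):
        if not 0 < self.ring_inner < self.ring_outer:
            raise ValueError("require 0 < ring_inner < ring_outer")
        lo, hi = self.coherence_band
        if not 0 <= lo < hi:
            raise ValueError("coherence_band must satisfy 0 <= low < high")


@dataclass
class SimilarityMaps:
    r: np.ndarray
    rho: np.ndarray
    n_neighbors: np.ndarray
    valid: np.ndarray
    window: tuple[int, int]


def ring_kernel(pixel_spacing, ring_inner=1.0, ring_outer=2.5):
    """Integer pixel offsets whose Euclidean distance lies in the ring.

    Offsets (dr, dc) satisfy ring_inner <= pixel_spacing*hypot(dr, dc)
    <= ring_outer.  The set is symmetric under negation and axis swap.
    Raises when the spacing is too coarse for any lattice point to fall
    inside the ring.
    """
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive")
    rmax = int(np.ceil(ring_outer / pixel_spacing))
    offsets = [
        (dr, dc)
        for dr in range(-rmax, rmax + 1)
        for dc in range(-rmax, rmax + 1)
        if (dr, dc) != (0, 0)
        and ring_inner <= pixel_spacing * np.hypot(dr, dc) <= ring_outer
    ]
    if not offsets:
        raise ValueError(
            f"no lattice offsets within ring [{ring_inner}, {ring_outer}] mm "
            f"at {pixel_spacing} mm/pixel"
        )
    return offsets


def analysis_window(time, mean_tic, pre=5.0, post=20.0):
    """(start, stop) frame indices of the window around bolus appearance.

    Appearance is the first sample where the mean TIC (above its minimum)
    reaches 5% of its excursion.
    """
    time = np.asarray(time, dtype=float)
    y = np.asarray(mean_tic, dtype=float)
    y = y - y.min()
    peak_val = y.max()
    idx = np.nonzero(y >= 0.05 * peak_val)[0] if peak_val > 0 else np.array([0])
    at = time[idx[0]] if idx.size else time[0]
    i0 = int(np.searchsorted(time, at - pre))
    i1 = int(np.searchsorted(time, at + post, side="right"))
    i1 = min(max(i1, i0 + 8), time.size)
    return i0, i1


def _auto_nperseg(n, fs, band_high):
    nps = min(64, max(8, (n // 3) // 8 * 8))
    # need at least one FFT bin inside the band
    min_nps = int(np.ceil(fs / band_high)) if band_high > 0 else nps
    return max(nps, min(min_nps, n))


def _segment_fft(x, nperseg, noverlap, axis0_len):
    """Hann-windowed, constant-detrended segment rFFTs along axis 0.

    ``x`` has time on axis 0; returns (n_segments, n_freqs, ...).
    """
    step = nperseg - noverlap
    starts = np.arange(0, axis0_len - nperseg + 1, step)
    win = hann(nperseg, sym=False)
    segs = np.stack([x[s : s + nperseg] for s in starts], axis=0)
    segs = segs - segs.mean(axis=1, keepdims=True)
    shape = [1, nperseg] + [1] * (segs.ndim - 2)
    segs = segs * win.reshape(shape)
    return np.fft.rfft(segs, axis=1)


def _band_indices(nperseg, fs, band):
    f = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    lo, hi = band
    sel = (f > lo) & (f <= hi)
    if not sel.any():
        # fall back to the lowest non-DC bin
        sel = np.zeros_like(f, dtype=bool)
        sel[min(1, f.size - 1)] = True
    return sel


def spatiotemporal_correlation(center, neighbors):
    """Mean Pearson correlation between the center TIC and each neighbor TIC.

    ``neighbors`` is (n, T).  Returns NaN when the center (or every
    neighbor) has zero variance in the window.
    """
    c = np.asarray(center, dtype=float)
    nb = np.atleast_2d(np.asarray(neighbors, dtype=float))
    cs = c.std()
    if cs == 0:
        return float("nan")
    zc = (c - c.mean()) / cs
    stds = nb.std(axis=1)
    ok = stds > 0
    if not ok.any():
        return float("nan")
    zn = (nb[ok] - nb[ok].mean(axis=1, keepdims=True)) / stds[ok, None]
    return float(np.mean(zn @ zc) / c.size)


def spectral_coherence(center, neighbors, fs, band=(0.0, 0.5), nperseg=None):
    """Mean band-averaged magnitude-squared coherence, Welch estimate.

    Matches scipy.signal.coherence (hann window, constant detrend, 50%
    overlap, periodogram averaging); the spectral density scaling cancels
    in the coherence ratio.
    """
    c = np.asarray(center, dtype=float)
    nb = np.atleast_2d(np.asarray(neighbors, dtype=float))
    n = c.size
    if nperseg is None:
        nperseg = _auto_nperseg(n, fs, band[1])
    nperseg = min(nperseg, n)
    noverlap = nperseg // 2
    sel = _band_indices(nperseg, fs, band)
    sc = _segment_fft(c, nperseg, noverlap, n)[:, sel]
    sn = _segment_fft(nb.T, nperseg, noverlap, n)[:, sel]
    pxx = np.mean(np.abs(sc) ** 2, axis=0)
    pyy = np.mean(np.abs(sn) ** 2, axis=0)
    pxy = np.mean(sc[..., None] * np.conj(sn), axis=0)
    denom = pxx[:, None] * pyy
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(pxy) ** 2 / denom
    vals = np.nanmean(coh, axis=0)  # band average per neighbor
    vals = vals[np.isfinite(vals)]
    return float(np.mean(vals)) if vals.size else float("nan")


def similarity_maps(loop: DceusLoop, config: SimilarityConfig | None = None) -> SimilarityMaps:
    """Per-pixel r and rho maps over the whole imaging plane.

    Border pixels use the neighbors whose offsets stay inside the image;
    pixels with fewer than ``min_neighbors`` usable neighbors (or zero
    variance in the window) are flagged invalid.
    """
    cfg = config or SimilarityConfig()
    offsets = ring_kernel(loop.pixel_spacing, cfg.ring_inner, cfg.ring_outer)
    min_nb = cfg.min_neighbors if cfg.min_neighbors is not None else len(offsets) // 2

    time, tics, _, _ = extract_tic_stack(loop)
    t, h, w = loop.frames.shape
    stack = tics.reshape(t, h, w)
    i0, i1 = analysis_window(time, stack.mean(axis=(1, 2)), cfg.window_pre, cfg.window_post)
    x = stack[i0:i1]
    tw = x.shape[0]
    fs = loop.frame_rate

    # --- correlation: z-score in time, average shifted products ---
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    center_ok = std > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / std
    z[:, ~center_ok] = np.nan

    # --- coherence: per-pixel Welch segment spectra in the band ---
    nperseg = cfg.nperseg if cfg.nperseg is not None else _auto_nperseg(tw, fs, cfg.coherence_band[1])
    nperseg = min(nperseg, tw)
    sel = _band_indices(nperseg, fs, cfg.coherence_band)
    spec = _segment_fft(x, nperseg, nperseg // 2, tw)[:, sel]  # (nseg, B, H, W)
    pauto = np.mean(np.abs(spec) ** 2, axis=0)  # (B, H, W)

    r_sum = np.zeros((h, w))
    rho_sum = np.zeros((h, w))
    count = np.zeros((h, w))

    for dr, dc in offsets:
        src_r = slice(max(0, -dr), min(h, h - dr))
        src_c = slice(max(0, -dc), min(w, w - dc))
        dst_r = slice(max(0, dr), min(h, h + dr))
        dst_c = slice(max(0, dc), min(w, w + dc))
        zc = z[:, dst_r, dst_c]
        zn = z[:, src_r, src_c]
        corr = np.mean(zc * zn, axis=0)
        sc = spec[:, :, dst_r, dst_c]
        sn = spec[:, :, src_r, src_c]
        pxy = np.mean(sc * np.conj(sn), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.abs(pxy) ** 2 / (pauto[:, dst_r, dst_c] * pauto[:, src_r, src_c])
        coh_band = np.mean(coh, axis=0)
        ok = np.isfinite(corr) & np.isfinite(coh_band)
        r_sum[dst_r, dst_c] += np.where(ok, corr, 0.0)
        rho_sum[dst_r, dst_c] += np.where(ok, coh_band, 0.0)
        count[dst_r, dst_c] += ok

    with np.errstate(invalid="ignore", divide="ignore"):
        r_map = r_sum / count
        rho_map = rho_sum / count
    valid = center_ok & (count >= min_nb)
    r_map[~valid] = np.nan
    rho_map[~valid] = np.nan
    r_map = np.clip(r_map, -1.0, 1.0)
    rho_map = np.clip(rho_map, 0.0, 1.0)
    return SimilarityMaps(r=r_map, rho=rho_map, n_neighbors=count.astype(int), valid=valid, window=(i0, i1))
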