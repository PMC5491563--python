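"""Model-free perfusion parameters of a time-intensity curve.

PI   peak intensity (a.u.)
PT   peak time (s): time of the first maximal sample
AT   appearance time (s): first up-crossing of 5% of PI
WIT  wash-in time (s): from AT to the first up-crossing of 95% of PI
FWHM full width at half maximum (s)

All threshold crossings are linearly interpolated between samples so the
features are frame-rate independent; thresholds are relative to PI, so all
timing features are invariant under positive intensity scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PerfusionFeatures",
    "peak",
    "appearance_time",
    "wash_in_time",
    "fwhm",
    "compute_perfusion",
]


@dataclass
class PerfusionFeatures:
    PI: float
    PT: float
    AT: float
    WIT: float
    FWHM: float
    valid: bool = True
    fwhm_valid: bool = True
    at_clipped: bool = False

    @classmethod
    def invalid(cls):
        nan = float("nan")
        return cls(nan, nan, nan, nan, nan, valid=False, fwhm_valid=False)


def _first_up_crossing(t, y, level):
    """Linearly interpolated time of the first up-crossing of ``level``."""
    above = y >= level
    if above[0]:
        return float(t[0]), True
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        return float("nan"), False
    i = idx[0]
    frac = (level - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1])), False


def peak(tic_time, tic_intensity):
    """(PI, PT): maximum intensity and the time of its first occurrence."""
    y = np.asarray(tic_intensity, dtype=float)
    t = np.asarray(tic_time, dtype=float)
    i = int(np.argmax(y))
    return float(y[i]), float(t[i])


def appearance_time(tic_time, tic_intensity, pi):
    """First interpolated up-crossing of 0.05*PI; 0 (flagged) if already above."""
    if pi <= 0:
        raise ValueError("appearance_time requires PI > 0")
    t = np.asarray(tic_time, dtype=float)
    y = np.asarray(tic_intensity, dtype=float)
    at, clipped = _first_up_crossing(t, y, 0.05 * pi)
    return at, clipped


def wash_in_time(tic_time, tic_intensity, pi, at):
    """Time from AT to the first interpolated up-crossing of 0.95*PI."""
    t = np.asarray(tic_time, dtype=float)
    y = np.asarray(tic_intensity, dtype=float)
    t95, _ = _first_up_crossing(t, y, 0.95 * pi)
    return max(t95 - at, 0.0)


def fwhm(tic_time, tic_intensity, pi):
    """Width between the interpolated half-max crossings around the peak.

    Up-crossing: first crossing of 0.5*PI before the peak.  Down-crossing:
    last crossing of 0.5*PI after the peak.  When the curve never falls
    below half max after the peak (truncated recording) the FWHM is
    undefined and flagged.
    """
    if pi <= 0:
        raise ValueError("fwhm requires PI > 0")
    t = np.asarray(tic_time, dtype=float)
    y = np.asarray(tic_intensity, dtype=float)
    half = 0.5 * pi
    pk = int(np.argmax(y))
    t_up, _ = _first_up_crossing(t[: pk + 1], y[: pk + 1], half)
    tail_t, tail_y = t[pk:], y[pk:]
    below = np.nonzero(tail_y < half)[0]
    if below.size == 0:
        return float("nan"), False
    # last down-crossing: last transition from >= half to < half
    down = np.nonzero((tail_y[:-1] >= half) & (tail_y[1:] < half))[0]
    i = down[-1]
    frac = (tail_y[i] - half) / (tail_y[i] - tail_y[i + 1])
    t_down = float(tail_t[i] + frac * (tail_t[i + 1] - tail_t[i]))
    return t_down - t_up, True


def compute_perfusion(tic_time, tic_intensity) -> PerfusionFeatures:
    """All perfusion features of one TIC; invalid for a non-positive curve."""
    y = np.asarray(tic_intensity, dtype=float)
    if y.size == 0 or np.max(y) <= 0:
        return PerfusionFeatures.invalid()
    pi, pt = peak(tic_time, y)
    at, clipped = appearance_time(tic_time, y, pi)
    wit = wash_in_time(tic_time, y, pi, at)
    width, fwhm_ok = fwhm(tic_time, y, pi)
    return PerfusionFeatures(
        PI=pi, PT=pt, AT=at, WIT=wit, FWHM=width,
        valid=True, fwhm_valid=fwhm_ok, at_clipped=clipped,
    )
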