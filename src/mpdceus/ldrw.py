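"""Indicator-dilution modelling with the modified local density random walk model.

The modified LDRW model describes the echo-intensity evolution of an
ultrasound-contrast-agent bolus at a pixel as a solution of the
convective-diffusion equation observed at a fixed position:

    C(t) = alpha * sqrt(kappa / (2*pi*(t - t0))) *
           exp(-kappa * (t - t0 - mu)**2 / (2*(t - t0)))      for t > t0

and C(t) = 0 for t <= t0.  Parameters:

``alpha``
    area under the curve (a.u. * s); the curve integrates to alpha exactly.
``mu``
    transit-time parameter (s).  The exact first moment of the normalised
    curve about t0 is mu*(1 + 1/lambda) with lambda = mu*kappa; for the
    large lambda typical of bolus kinetics, mu is the mean transit time.
``kappa``
    skewness parameter (1/s); larger kappa gives a narrower, more
    symmetric curve.  The exact central second moment is
    (mu/kappa)*(1 + 2/lambda).
``t0``
    theoretical injection/arrival time offset (s).

lambda = mu*kappa is the ratio of convective to diffusive time scales and
is reported alongside the fitted parameters, as is var = mu/kappa, the
conventional variance measure derived from the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import least_squares
from scipy.signal import find_peaks

__all__ = [
    "LdrwFit",
    "ldrw_curve",
    "ldrw_moments",
    "ldrw_mode",
    "detect_truncation",
    "fit_ldrw",
    "fit_ldrw_maps",
]

_S_EPS = 1e-12


def ldrw_curve(time, alpha, mu, kappa, t0):
    """Evaluate the modified LDRW curve on a time grid.

    Parameters must satisfy alpha, mu, kappa > 0.  The curve is zero at and
    before ``t0``.
    """
    if alpha <= 0 or mu <= 0 or kappa <= 0:
        raise ValueError(
            f"alpha, mu and kappa must be positive (got alpha={alpha}, mu={mu}, kappa={kappa})"
        )
    t = np.asarray(time, dtype=float)
    s = t - t0
    out = np.zeros_like(s)
    m = s > _S_EPS
    sm = s[m]
    out[m] = alpha * np.sqrt(kappa / (2.0 * np.pi * sm)) * np.exp(
        -kappa * (sm - mu) ** 2 / (2.0 * sm)
    )
    return out


def ldrw_moments(alpha, mu, kappa, t0=0.0):
    """Exact (area, mean, central variance) of the modified LDRW curve.

    Derived from ``int_0^inf s**(nu-1) exp(-a*s - b/s) ds = 2*(b/a)**(nu/2) *
    K_nu(2*sqrt(a*b))`` with half-integer Bessel functions:

    area = alpha, mean = t0 + mu*(1 + 1/lambda),
    variance = (mu/kappa)*(1 + 2/lambda), lambda = mu*kappa.
    """
    lam = mu * kappa
    return alpha, t0 + mu * (1.0 + 1.0 / lam), (mu / kappa) * (1.0 + 2.0 / lam)


def ldrw_mode(mu, kappa):
    """Time (after t0) at which the LDRW curve peaks.

    Setting d/ds [log C] = 0 gives s**2 + s/kappa - mu**2 = 0, hence
    mode = (sqrt(1/kappa**2 + 4*mu**2) - 1/kappa) / 2 ~= mu - 1/(2*kappa).
    """
    return 0.5 * (np.sqrt(1.0 / kappa**2 + 4.0 * mu**2) - 1.0 / kappa)


@dataclass
class LdrwFit:
    """Result of fitting the modified LDRW model to one time-intensity curve.

    ``interval`` is the fitting interval "int": the time between the observed
    peak and the truncation time where recirculation begins.  ``var`` is the
    conventional variance measure mu/kappa derived from the fit and ``lam``
    the convective-to-diffusive ratio mu*kappa (exact identities by
    construction).
    """

    alpha: float
    mu: float
    kappa: float
    lam: float
    t0: float
    var: float
    interval: float
    r_squared: float
    converged: bool
    n_evaluations: int = 0

    @classmethod
    def invalid(cls, interval=0.0):
        nan = float("nan")
        return cls(nan, nan, nan, nan, nan, nan, interval, -np.inf, False)


def detect_truncation(time, intensity, peak_time, *, smooth_sigma=2.0, prominence_fraction=0.05):
    """Find the truncation time where contrast recirculation begins.

    Returns the time of the first prominent local minimum of the (lightly
    smoothed) curve after the peak, or the end of the recording when the
    wash-out is monotone.  ``smooth_sigma`` is in seconds; a minimum must be
    preceded and followed by a rise of at least ``prominence_fraction`` of the
    peak intensity to count, which keeps noise flutter from truncating the
    fitting interval early.
    """
    time = np.asarray(time, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if y.size < 3:
        return float(time[-1])
    fs = 1.0 / (time[1] - time[0])
    if smooth_sigma > 0:
        y = gaussian_filter1d(y, smooth_sigma * fs, mode="nearest")
    peak_idx = int(np.searchsorted(time, peak_time))
    peak_idx = min(max(peak_idx, 0), y.size - 1)
    seg = y[peak_idx:]
    if seg.size < 3:
        return float(time[-1])
    minima, _ = find_peaks(-seg, prominence=prominence_fraction * float(np.max(y)))
    if minima.size == 0:
        return float(time[-1])
    return float(time[peak_idx + minima[0]])


def _model_and_jac(params, t):
    """LDRW model values and analytic Jacobian wrt (alpha, mu, kappa, t0)."""
    alpha, mu, kappa, t0 = params
    s = t - t0
    f = np.zeros_like(s)
    jac = np.zeros((t.size, 4))
    m = s > _S_EPS
    sm = s[m]
    g = np.sqrt(kappa / (2.0 * np.pi * sm)) * np.exp(-kappa * (sm - mu) ** 2 / (2.0 * sm))
    fm = alpha * g
    f[m] = fm
    jac[m, 0] = g
    jac[m, 1] = fm * kappa * (sm - mu) / sm
    jac[m, 2] = fm * (0.5 / kappa - (sm - mu) ** 2 / (2.0 * sm))
    jac[m, 3] = fm * (0.5 / sm + kappa * (sm**2 - mu**2) / (2.0 * sm**2))
    return f, jac


def _initial_guess(t, y):
    """Deterministic starting point from simple curve landmarks."""
    pi = float(np.max(y))
    pt_idx = int(np.argmax(y))
    pt = float(t[pt_idx])
    # crude 5% appearance time on the rising edge
    above = np.nonzero(y[: pt_idx + 1] >= 0.05 * pi)[0]
    at = float(t[above[0]]) if above.size else float(t[0])
    # crude FWHM from half-max crossings around the peak
    half = np.nonzero(y >= 0.5 * pi)[0]
    fwhm = float(t[half[-1]] - t[half[0]]) if half.size >= 2 else max(pt - at, 1.0)
    t0 = max(at - 0.5, 0.0)
    mu = max(pt - t0, 1.0)
    sigma = max(fwhm / 2.355, 0.25)
    kappa = float(np.clip(mu / sigma**2, 1e-3, 50.0))
    alpha = max(float(np.trapezoid(y, t)), 1e-6)
    return np.array([alpha, mu, kappa, t0])


def fit_ldrw(
    time,
    intensity,
    truncation_time=None,
    *,
    peak_time=None,
    r2_floor=0.5,
    weights=None,
    max_nfev=200,
):
    """Fit the modified LDRW model to a time-intensity curve.

    The fit is a bounded nonlinear least squares (analytic Jacobian,
    trust-region reflective) restricted to [first positive sample,
    ``truncation_time``].  A failed or poor first attempt is retried once
    from a perturbed start.  ``converged`` is False when the optimizer fails
    or R**2 falls below ``r2_floor`` — such pixels are the ones that "cannot
    be fitted" and are excluded downstream.
    """
    t_all = np.asarray(time, dtype=float)
    y_all = np.asarray(intensity, dtype=float)
    if truncation_time is None:
        truncation_time = float(t_all[-1])
    i1 = int(np.searchsorted(t_all, truncation_time, side="right"))
    pos = np.nonzero(y_all[:i1] > 0)[0]
    if pos.size == 0:
        return LdrwFit.invalid()
    i0 = int(pos[0])
    t = t_all[i0:i1]
    y = y_all[i0:i1]
    if t.size < 10 or np.max(y) <= 0:
        return LdrwFit.invalid()
    if peak_time is None:
        peak_time = float(t[np.argmax(y)])
    interval = max(truncation_time - peak_time, 0.0)

    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)[i0:i1]

    def residuals(p):
        return w * (_model_and_jac(p, t)[0] - y)

    def jacobian(p):
        return w[:, None] * _model_and_jac(p, t)[1]

    x0 = _initial_guess(t, y)
    duration = float(t_all[-1])
    lower = np.array([1e-10, 1e-2, 1e-4, 0.0])
    upper = np.array([np.inf, 10.0 * duration, 1e3, max(peak_time - 1e-3, 1e-2)])
    x0 = np.clip(x0, lower + 1e-9, np.where(np.isfinite(upper), upper - 1e-9, x0 + 1))

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    best = None
    n_evals = 0
    for attempt, scale in enumerate(([1.0, 1.0, 1.0, 1.0], [1.3, 0.7, 1.5, 0.8])):
        xs = np.clip(x0 * np.asarray(scale), lower + 1e-9, None)
        xs = np.minimum(xs, np.where(np.isfinite(upper), upper - 1e-9, xs))
        try:
            sol = least_squares(
                residuals,
                xs,
                jac=jacobian,
                bounds=(lower, upper),
                method="trf",
                xtol=1e-8,
                ftol=1e-8,
                gtol=1e-8,
                max_nfev=max_nfev,
            )
        except Exception:
            continue
        n_evals += sol.nfev
        ss_res = float(np.sum((_model_and_jac(sol.x, t)[0] - y) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
        if best is None or r2 > best[1]:
            best = (sol, r2)
        if sol.success and r2 >= r2_floor:
            break
    if best is None:
        return LdrwFit.invalid(interval)
    sol, r2 = best
    alpha, mu, kappa, t0 = (float(v) for v in sol.x)
    converged = bool(sol.success) and r2 >= r2_floor
    return LdrwFit(
        alpha=alpha,
        mu=mu,
        kappa=kappa,
        lam=mu * kappa,
        t0=t0,
        var=mu / kappa,
        interval=interval,
        r_squared=float(r2),
        converged=converged,
        n_evaluations=n_evals,
    )


def fit_ldrw_maps(time, stack, mask=None, *, r2_floor=0.5, detect_recirculation=True):
    """Fit every (masked) pixel of a T x H x W stack; return parameter maps.

    Returns a dict of 2-D float maps ``{"alpha", "mu", "kappa", "lam", "t0",
    "var", "int", "r_squared"}`` plus a boolean ``converged`` map.  Unfitted
    pixels hold NaN.
    """
    time = np.asarray(time, dtype=float)
    stack = np.asarray(stack, dtype=float)
    _, h, w = stack.shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    names = ["alpha", "mu", "kappa", "lam", "t0", "var", "int", "r_squared"]
    maps = {n: np.full((h, w), np.nan) for n in names}
    converged = np.zeros((h, w), dtype=bool)
    for r, c in zip(*np.nonzero(mask)):
        y = stack[:, r, c]
        if np.max(y) <= 0:
            continue
        pt = float(time[int(np.argmax(y))])
        trunc = detect_truncation(time, y, pt) if detect_recirculation else float(time[-1])
        fit = fit_ldrw(time, y, trunc, peak_time=pt, r2_floor=r2_floor)
        maps["alpha"][r, c] = fit.alpha
        maps["mu"][r, c] = fit.mu
        maps["kappa"][r, c] = fit.kappa
        maps["lam"][r, c] = fit.lam
        maps["t0"][r, c] = fit.t0
        maps["var"][r, c] = fit.var
        maps["int"][r, c] = fit.interval
        maps["r_squared"][r, c] = fit.r_squared
        converged[r, c] = fit.converged
    maps["converged"] = converged
    return maps
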