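"""Synthetic DCE-US phantom generator with known ground truth.

Emulates two-minute transrectal contrast loops of a prostate cross-section:
each pixel's noiseless TIC is a modified-LDRW bolus passage (plus a delayed,
scaled recirculation pass) on top of a static echogenicity pedestal, with
multiplicative (speckle-like, intensity-proportional) and additive noise.
Malignant lesions are rasterized ellipses (~0.5 cm2, the scale of clinically
relevant foci) whose kinetic parameters are drawn from a separate
distribution: faster, more skewed inflow (lower mu, higher kappa, higher
alpha) and a shorter spatial coherence scale, so that dispersion-similarity
features (r, rho) carry class signal as they do in vivo.

Parameter fields are white Gaussian fields smoothed to a class-specific
correlation length and affinely mapped to the class distribution.  Within a
class, kappa is partially anti-correlated with mu (``kappa_mu_coupling``):
the convective-to-diffusive ratio lambda = mu*kappa varies less across
tissue than either parameter alone, which also makes the wash-in time track
mu, as observed clinically.

No acoustic propagation, beamforming or true speckle statistics are
modelled; the generator's purpose is a controllable, labelled test bed for
the analysis chain, not an ultrasound simulator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from .preprocessing import DceusLoop

__all__ = [
    "ClassKinetics",
    "NoiseModel",
    "Recirculation",
    "BetweenProstateVariance",
    "PhantomConfig",
    "Roi",
    "GroundTruth",
    "CohortPlane",
    "generate_phantom",
    "generate_cohort",
]


@dataclass
class ClassKinetics:
    """Per-class (mean, sd) of the LDRW parameters and tissue properties.

    ``coherence_scale`` (mm) is the correlation length of the smooth random
    fields the per-pixel parameters are drawn from; ``echogenicity`` is the
    static B-mode pedestal (a.u.) that provides the greylevel feature.
    """

    alpha: tuple[float, float] = (15.0, 2.5)
    mu: tuple[float, float] = (25.0, 3.0)
    kappa: tuple[float, float] = (0.6, 0.12)
    t0: tuple[float, float] = (8.0, 0.8)
    echogenicity: tuple[float, float] = (0.30, 0.05)
    coherence_scale: float = 1.3


def _malignant_defaults() -> ClassKinetics:
    # rapid, enhanced, more dispersed inflow; rougher microvascular texture
    return ClassKinetics(
        alpha=(20.0, 4.0),
        mu=(19.0, 3.0),
        kappa=(0.9, 0.18),
        t0=(6.8, 0.8),
        echogenicity=(0.22, 0.05),
        coherence_scale=1.1,
    )


@dataclass
class NoiseModel:
    multiplicative_sd: float = 0.10
    additive_sd: float = 0.02


@dataclass
class Recirculation:
    delay: float = 45.0            # s after the first-pass t0
    amplitude_fraction: float = 0.25


@dataclass
class BetweenProstateVariance:
    """SD of prostate-level effects applied to both classes in a cohort.

    Mean shifts on mu and t0 (circulation time, injection timing), a
    log-normal gain on alpha (dose, attenuation), a log-normal factor on
    the spatial coherence scales (tissue texture) and on the noise level
    (recording quality) — the patient-to-patient variability that grouped
    cross-validation has to generalize across.
    """

    mu_sd: float = 2.0
    t0_sd: float = 1.0
    alpha_log_sd: float = 0.10
    coherence_log_sd: float = 0.25
    noise_log_sd: float = 0.30


@dataclass
class PhantomConfig:
    grid_height: int = 64
    grid_width: int = 64
    pixel_spacing: float = 0.5     # mm / pixel
    frame_rate: float = 10.0       # Hz
    duration: float = 120.0        # s (two-minute recordings)
    n_lesions: int = 2
    lesion_area: float = 0.5       # cm2, per lesion / ROI
    benign: ClassKinetics = field(default_factory=ClassKinetics)
    malignant: ClassKinetics = field(default_factory=_malignant_defaults)
    noise: NoiseModel = field(default_factory=NoiseModel)
    recirculation: Recirculation = field(default_factory=Recirculation)
    kappa_mu_coupling: float = 0.8
    between_prostate: BetweenProstateVariance = field(default_factory=BetweenProstateVariance)
    n_benign_rois: int | None = None   # None -> n_lesions
    seed: int = 0

    def __post_init__(self):
        if min(self.duration, self.frame_rate, self.pixel_spacing) <= 0:
            raise ValueError("duration, frame_rate and pixel_spacing must be positive")
        if not 0 <= self.recirculation.amplitude_fraction < 1:
            raise ValueError("recirculation amplitude_fraction must be in [0, 1)")
        if not 0 <= self.kappa_mu_coupling <= 1:
            raise ValueError("kappa_mu_coupling must be in [0, 1]")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be non-negative")
        if self.n_lesions and self.lesion_pixels * self.n_lesions > 0.5 * self.grid_height * self.grid_width:
            raise ValueError(
                f"{self.n_lesions} lesions of {self.lesion_area} cm2 exceed half the "
                f"{self.grid_height}x{self.grid_width} field at {self.pixel_spacing} mm/pixel"
            )

    @property
    def lesion_pixels(self) -> float:
        """Lesion area in pixels: cm2 -> mm2 / (mm/px)^2."""
        return self.lesion_area * 100.0 / self.pixel_spacing**2

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class Roi:
    roi_id: int
    label: int                      # 0 benign, 1 malignant
    mask: np.ndarray
    polygon: np.ndarray             # M x 2 (row, col) vertices
    prostate_id: int = 0
    plane_id: int = 0


@dataclass
class GroundTruth:
    label_map: np.ndarray
    parameter_maps: dict[str, np.ndarray]
    rois: list[Roi]


@dataclass
class CohortPlane:
    prostate_id: int
    plane_id: int
    loop: DceusLoop
    truth: GroundTruth


def _ellipse_mask(shape, center, a, b, theta):
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _ellipse_polygon(center, a, b, theta, n=24):
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    u = a * np.cos(phi)
    v = b * np.sin(phi)
    rr = center[0] + u * np.cos(theta) - v * np.sin(theta)
    cc = center[1] + u * np.sin(theta) + v * np.cos(theta)
    return np.column_stack([rr, cc])


def _place_ellipses(shape, n, area_px, rng, forbidden=None, what="lesion", max_tries=300):
    """Place n non-overlapping ellipses of given pixel area; axis ratio U[1, 2]."""
    h, w = shape
    occupied = np.zeros(shape, dtype=bool) if forbidden is None else forbidden.copy()
    out = []
    for k in range(n):
        for _ in range(max_tries):
            q = rng.uniform(1.0, 2.0)
            a = np.sqrt(area_px * q / np.pi)
            b = a / q
            if 2 * a + 2 >= min(h, w):
                raise ValueError(
                    f"{what} of {area_px:.0f} px cannot fit inside a {h}x{w} grid"
                )
            theta = rng.uniform(0, np.pi)
            center = (rng.uniform(a + 1, h - a - 1), rng.uniform(a + 1, w - a - 1))
            mask = _ellipse_mask(shape, center, a, b, theta)
            if not (mask & occupied).any():
                occupied |= mask
                out.append((mask, _ellipse_polygon(center, a, b, theta)))
                break
        else:
            raise RuntimeError(
                f"could not place {what} {k + 1}/{n} of {area_px:.0f} px after "
                f"{max_tries} tries: field too crowded for the requested "
                f"n_lesions x lesion_area"
            )
    return out, occupied


def _smooth_field(shape, scale_px, rng):
    f = rng.standard_normal(shape)
    if scale_px > 0:
        f = gaussian_filter(f, scale_px, mode="reflect")
        s = f.std()
        if s > 0:
            f = f / s
    return f


_PARAM_FLOORS = {"alpha": 0.05, "mu": 2.0, "kappa": 0.05, "t0": 0.5, "echogenicity": 0.0}


def _class_parameter_maps(cfg: PhantomConfig, kinetics: ClassKinetics, rng):
    """Smooth per-class fields affinely mapped to the class distribution."""
    shape = (cfg.grid_height, cfg.grid_width)
    scale_px = kinetics.coherence_scale / cfg.pixel_spacing
    u_mu = _smooth_field(shape, scale_px, rng)
    u_kres = _smooth_field(shape, scale_px, rng)
    u_t0 = _smooth_field(shape, scale_px, rng)
    u_alpha = _smooth_field(shape, scale_px, rng)
    u_echo = _smooth_field(shape, scale_px, rng)
    c = cfg.kappa_mu_coupling
    u_kappa = -c * u_mu + np.sqrt(1.0 - c**2) * u_kres
    raw = {
        "mu": kinetics.mu[0] + kinetics.mu[1] * u_mu,
        "kappa": kinetics.kappa[0] + kinetics.kappa[1] * u_kappa,
        "t0": kinetics.t0[0] + kinetics.t0[1] * u_t0,
        "alpha": kinetics.alpha[0] + kinetics.alpha[1] * u_alpha,
        "echogenicity": kinetics.echogenicity[0] + kinetics.echogenicity[1] * u_echo,
    }
    return {k: np.clip(v, _PARAM_FLOORS[k], None) for k, v in raw.items()}


def _ldrw_grid(t, alpha, mu, kappa, t0):
    """Vectorized LDRW evaluation: t (T,), parameters (N,) -> (T, N)."""
    s = t[:, None] - t0[None, :]
    out = np.zeros_like(s)
    m = s > 1e-12
    sm = s[m]
    kk = np.broadcast_to(kappa, s.shape)[m]
    mm = np.broadcast_to(mu, s.shape)[m]
    aa = np.broadcast_to(alpha, s.shape)[m]
    out[m] = aa * np.sqrt(kk / (2.0 * np.pi * sm)) * np.exp(-kk * (sm - mm) ** 2 / (2.0 * sm))
    return out


def generate_phantom(config: PhantomConfig, rng=None, prostate_id=0, plane_id=0):
    """Generate one labelled DCE-US loop; deterministic given config.seed.

    Returns ``(DceusLoop, GroundTruth)``.  The loop is linear-scale; the
    ground truth carries the label map, the true per-pixel parameter maps
    and the generated ROI set (malignant lesions plus equal-sized benign
    reference regions).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    shape = (config.grid_height, config.grid_width)

    lesions, occupied = _place_ellipses(
        shape, config.n_lesions, config.lesion_pixels, rng, what="lesion"
    )
    label_map = np.zeros(shape, dtype=np.uint8)
    for mask, _ in lesions:
        label_map[mask] = 1

    n_ben = config.n_benign_rois if config.n_benign_rois is not None else config.n_lesions
    # keep benign ROIs off the lesion rims, where classes mix
    buffer = binary_dilation(occupied, iterations=2) if occupied.any() else occupied
    benign_rois, _ = _place_ellipses(
        shape, n_ben, config.lesion_pixels, rng, forbidden=buffer, what="benign ROI"
    )

    rois = []
    for mask, poly in lesions:
        rois.append(Roi(len(rois), 1, mask, poly, prostate_id, plane_id))
    for mask, poly in benign_rois:
        rois.append(Roi(len(rois), 0, mask, poly, prostate_id, plane_id))

    ben = _class_parameter_maps(config, config.benign, rng)
    mal = _class_parameter_maps(config, config.malignant, rng)
    mal_mask = label_map == 1
    params = {k: np.where(mal_mask, mal[k], ben[k]) for k in ben}

    t = np.arange(config.n_frames) / config.frame_rate
    flat = {k: v.ravel() for k, v in params.items()}
    signal = _ldrw_grid(t, flat["alpha"], flat["mu"], flat["kappa"], flat["t0"])
    rc = config.recirculation
    if rc.amplitude_fraction > 0:
        signal += _ldrw_grid(
            t,
            rc.amplitude_fraction * flat["alpha"],
            flat["mu"],
            flat["kappa"],
            flat["t0"] + rc.delay,
        )
    frames = flat["echogenicity"][None, :] + signal
    nz = config.noise
    if nz.multiplicative_sd > 0:
        frames = frames * (1.0 + nz.multiplicative_sd * rng.standard_normal(frames.shape))
    if nz.additive_sd > 0:
        frames = frames + nz.additive_sd * rng.standard_normal(frames.shape)
    frames = np.clip(frames, 0.0, None).reshape(config.n_frames, *shape)

    loop = DceusLoop(
        frames=frames,
        frame_rate=config.frame_rate,
        pixel_spacing=config.pixel_spacing,
        compression="linear",
    )
    truth = GroundTruth(label_map=label_map, parameter_maps=params, rois=rois)
    return loop, truth


def generate_cohort(config: PhantomConfig, n_prostates, planes_per_prostate=(1, 4), seed=None):
    """Generate a multi-prostate cohort of labelled planes.

    Prostate-level mean shifts (mu, t0, log-alpha) are drawn once per
    prostate and applied to both classes, introducing the between-patient
    variance that leave-one-prostate-out validation has to cope with.
    ``planes_per_prostate`` is an int or an inclusive (low, high) range.
    Every loop gets its own RNG stream derived from (seed, prostate, plane),
    so the cohort is reproducible plane-by-plane.
    """
    if n_prostates < 2:
        raise ValueError("a cohort needs n_prostates >= 2 for leave-one-out validation")
    seed = config.seed if seed is None else seed
    bp = config.between_prostate
    planes = []
    for pid in range(n_prostates):
        prng = np.random.default_rng([seed, 1 + pid])
        d_mu = prng.normal(0.0, bp.mu_sd)
        d_t0 = prng.normal(0.0, bp.t0_sd)
        alpha_scale = float(np.exp(prng.normal(0.0, bp.alpha_log_sd)))
        coherence_scale = float(np.exp(prng.normal(0.0, bp.coherence_log_sd)))
        noise_scale = float(np.exp(prng.normal(0.0, bp.noise_log_sd)))
        if isinstance(planes_per_prostate, int):
            n_planes = planes_per_prostate
        else:
            lo, hi = planes_per_prostate
            n_planes = int(prng.integers(lo, hi + 1))

        def shifted(k: ClassKinetics) -> ClassKinetics:
            return dataclasses.replace(
                k,
                mu=(max(k.mu[0] + d_mu, 3.0), k.mu[1]),
                t0=(max(k.t0[0] + d_t0, 1.0), k.t0[1]),
                alpha=(k.alpha[0] * alpha_scale, k.alpha[1]),
                coherence_scale=k.coherence_scale * coherence_scale,
            )

        pcfg = dataclasses.replace(
            config,
            benign=shifted(config.benign),
            malignant=shifted(config.malignant),
            noise=NoiseModel(
                config.noise.multiplicative_sd * noise_scale,
                config.noise.additive_sd * noise_scale,
            ),
        )
        for plid in range(n_planes):
            lrng = np.random.default_rng([seed, 1 + pid, plid])
            loop, truth = generate_phantom(pcfg, rng=lrng, prostate_id=pid, plane_id=plid)
            planes.append(CohortPlane(pid, plid, loop, truth))
    return planes
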