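"""Per-plane feature extraction: from a raw loop to the per-pixel feature table.

Chains preprocessing (linearization, smoothing, baseline subtraction),
similarity maps over the full plane, and per-ROI-pixel perfusion and LDRW
fitting into the 14-column feature panel used by the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import FEATURE_NAMES, PixelDataset
from .ldrw import detect_truncation, fit_ldrw
from .perfusion import compute_perfusion
from .preprocessing import DceusLoop, bolus_arrival_index, extract_tic_stack, linearize, smooth
from .similarity import SimilarityConfig, similarity_maps
from .synthetic import CohortPlane, GroundTruth

__all__ = ["FeatureConfig", "compute_plane_table", "cohort_dataset"]


@dataclass
class FeatureConfig:
    """Settings of the per-plane extraction chain.

    Curve fitting and similarity analysis use separately preprocessed
    copies of the loop: the fitting chain is spatially smoothed to tame
    speckle-like noise, while the similarity chain applies no spatial
    smoothing — mixing neighboring TICs before comparing them would erase
    exactly the neighborhood (dis)similarity that r and rho measure.
    """

    fit_spatial_sigma: float = 1.0    # mm; fitting/perfusion chain
    similarity_spatial_sigma: float = 0.0   # mm; similarity chain
    temporal_cutoff: float | None = 0.5     # Hz; both chains
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    r2_floor: float = 0.5             # below this a pixel counts as unfittable
    max_pixels_per_roi: int | None = None   # deterministic subsample for speed
    subsample_seed: int = 0


def _greylevel_map(loop: DceusLoop) -> np.ndarray:
    """Pre-contrast echogenicity: per-pixel median over the baseline window."""
    arrival = bolus_arrival_index(loop)
    if arrival > 0:
        return np.median(loop.frames[:arrival], axis=0)
    return loop.frames[0].copy()


def compute_plane_table(
    loop: DceusLoop,
    truth_or_rois,
    config: FeatureConfig | None = None,
    prostate_id: int = 0,
    plane_id: int = 0,
) -> pd.DataFrame:
    """Extract the full feature panel for every ROI pixel of one plane.

    ``truth_or_rois`` is a GroundTruth or a list of Roi objects.  Returns a
    flat table with one row per ROI pixel: the 14 features, label, group
    IDs, pixel coordinates, and the aux columns (peak_time, r_squared,
    fittable) used for pixel exclusion.
    """
    cfg = config or FeatureConfig()
    rois = truth_or_rois.rois if isinstance(truth_or_rois, GroundTruth) else truth_or_rois

    lin = linearize(loop)
    grey = _greylevel_map(lin)
    sm = smooth(lin, cfg.fit_spatial_sigma, cfg.temporal_cutoff)
    time, tics, _, _ = extract_tic_stack(sm)
    stack = tics.reshape(sm.frames.shape)
    sim_loop = smooth(lin, cfg.similarity_spatial_sigma, cfg.temporal_cutoff)
    simmaps = similarity_maps(sim_loop, cfg.similarity)

    rng = np.random.default_rng([cfg.subsample_seed, prostate_id, plane_id])
    rows = []
    for roi in rois:
        rr, cc = np.nonzero(roi.mask)
        if cfg.max_pixels_per_roi is not None and rr.size > cfg.max_pixels_per_roi:
            pick = rng.choice(rr.size, cfg.max_pixels_per_roi, replace=False)
            pick.sort()
            rr, cc = rr[pick], cc[pick]
        for r, c in zip(rr, cc):
            y = stack[:, r, c]
            perf = compute_perfusion(time, y)
            if not perf.valid:
                fit_vals = dict.fromkeys(("alpha", "mu", "kappa", "lam", "var", "int"), np.nan)
                r2, fittable, pt = np.nan, False, np.nan
            else:
                trunc = detect_truncation(time, y, perf.PT)
                fit = fit_ldrw(time, y, trunc, peak_time=perf.PT, r2_floor=cfg.r2_floor)
                fit_vals = {
                    "alpha": fit.alpha,
                    "mu": fit.mu,
                    "kappa": fit.kappa,
                    "lam": fit.lam,
                    "var": fit.var,
                    "int": fit.interval,
                }
                r2, fittable, pt = fit.r_squared, fit.converged, perf.PT
            rows.append(
                {
                    "greylevel": grey[r, c],
                    "WIT": perf.WIT,
                    "AT": perf.AT,
                    "PT": perf.PT,
                    "PI": perf.PI,
                    "FWHM": perf.FWHM,
                    **fit_vals,
                    "rho": simmaps.rho[r, c],
                    "r": simmaps.r[r, c],
                    "label": roi.label,
                    "prostate_id": prostate_id,
                    "plane_id": plane_id,
                    "roi_id": roi.roi_id,
                    "row": r,
                    "col": c,
                    "peak_time": pt,
                    "r_squared": r2,
                    "fittable": fittable,
                }
            )
    return pd.DataFrame(rows, columns=FEATURE_NAMES + [
        "label", "prostate_id", "plane_id", "roi_id", "row", "col",
        "peak_time", "r_squared", "fittable",
    ])


def cohort_dataset(planes: list[CohortPlane], config: FeatureConfig | None = None) -> PixelDataset:
    """Feature tables for every plane of a cohort, stacked into a PixelDataset."""
    tables = [
        compute_plane_table(p.loop, p.truth, config, p.prostate_id, p.plane_id)
        for p in planes
    ]
    return PixelDataset.from_frame(pd.concat(tables, ignore_index=True))
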