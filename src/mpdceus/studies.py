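"""Reusable study drivers: round-trip recovery, mechanism studies, oracles.

These functions bundle the multi-stage computations that the analysis
scripts and the acceptance checks both run: noiseless kinetics round-trips,
numerical moment verification of the bolus model, and multi-seed cohort
studies of classifier fusion, confidence-based exclusion and the WIT-mu
relationship.

Problem sizes are deliberately desk-scale (64 x 64 planes, 4-8 prostates,
4 Hz cohort loops); see the methods note for the reasoning.
"""

from __future__ import annotations

import dataclasses
import time

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .dataset import FEATURE_NAMES
from .evaluation import evaluate_loo, exclusion_sweep, permutation_null_accuracy
from .features import FeatureConfig, cohort_dataset
from .ldrw import fit_ldrw_maps, ldrw_curve
from .preprocessing import extract_tic_stack
from .synthetic import NoiseModel, PhantomConfig, Recirculation, generate_cohort, generate_phantom

__all__ = [
    "kinetics_roundtrip",
    "ldrw_moment_errors",
    "mechanism_study",
    "MULTI_SUBSET",
]

MULTI_SUBSET = ("r", "mu", "kappa", "PT")


def kinetics_roundtrip(seed: int = 0, grid: int = 64, frame_rate: float = 10.0) -> dict:
    """Noiseless phantom -> extract -> fit, per-pixel recovery statistics.

    Returns the fraction of pixels whose (alpha, mu, kappa, t0) are all
    recovered within 1% with R**2 > 0.999, plus timing.
    """
    cfg = PhantomConfig(
        grid_height=grid,
        grid_width=grid,
        frame_rate=frame_rate,
        noise=NoiseModel(0.0, 0.0),
        recirculation=Recirculation(45.0, 0.0),
        seed=seed,
    )
    start = time.perf_counter()
    loop, truth = generate_phantom(cfg)
    t, tics, _, _ = extract_tic_stack(loop)
    maps = fit_ldrw_maps(t, tics.reshape(loop.frames.shape), detect_recirculation=False)
    elapsed = time.perf_counter() - start
    ok = np.ones((grid, grid), dtype=bool)
    for k in ("alpha", "mu", "kappa", "t0"):
        rel = np.abs(maps[k] - truth.parameter_maps[k]) / truth.parameter_maps[k]
        ok &= rel < 0.01
    ok &= maps["r_squared"] > 0.999
    return {
        "recovery_fraction": float(ok.mean()),
        "median_r_squared": float(np.nanmedian(maps["r_squared"])),
        "converged_fraction": float(maps["converged"].mean()),
        "n_pixels": grid * grid,
        "elapsed_s": elapsed,
    }


def ldrw_moment_errors(mu_values=(17.0, 25.0, 33.0), kappa_values=(0.5, 0.8, 1.1),
                       t0_values=(3.0, 6.0, 9.0)) -> pd.DataFrame:
    """Numerically integrate the bolus model over a parameter grid.

    For each (mu, kappa, t0) the area, first moment and central second
    moment are computed by adaptive quadrature and compared with alpha,
    t0 + mu, and mu/kappa — the conventional large-lambda interpretations
    of the parameters — as well as with the exact values
    t0 + mu*(1 + 1/lambda) and (mu/kappa)*(1 + 2/lambda).
    """
    rows = []
    for mu in mu_values:
        for kappa in kappa_values:
            for t0 in t0_values:
                alpha = 1.0
                lam = mu * kappa
                f = lambda t: ldrw_curve(np.array([t]), alpha, mu, kappa, t0)[0]
                area = quad(f, t0, np.inf, limit=300)[0]
                m1 = quad(lambda t: (t - t0) * f(t), t0, np.inf, limit=300)[0] / area
                m2 = quad(lambda t: ((t - t0) - m1) ** 2 * f(t), t0, np.inf, limit=300)[0] / area
                rows.append(
                    {
                        "mu": mu,
                        "kappa": kappa,
                        "t0": t0,
                        "lambda": lam,
                        "area_rel_err": abs(area - alpha) / alpha,
                        "mean_rel_err_vs_mu": abs(m1 - mu) / mu,
                        "var_rel_err_vs_mu_over_kappa": abs(m2 - mu / kappa) / (mu / kappa),
                        "mean_rel_err_exact": abs(m1 - mu * (1 + 1 / lam)) / (mu * (1 + 1 / lam)),
                        "var_rel_err_exact": abs(m2 - (mu / kappa) * (1 + 2 / lam))
                        / ((mu / kappa) * (1 + 2 / lam)),
                    }
                )
    return pd.DataFrame(rows)


def _cohort_config(frame_rate: float, seed: int) -> PhantomConfig:
    return PhantomConfig(frame_rate=frame_rate, seed=seed)


def mechanism_study(
    seeds,
    *,
    n_prostates: int = 8,
    planes_per_prostate=1,
    frame_rate: float = 4.0,
    max_pixels_per_roi: int = 80,
    exclusion_quantiles=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    progress: bool = False,
) -> pd.DataFrame:
    """One row per seed: fusion vs single features, exclusion, WIT-mu, null.

    Per seed a fresh labelled cohort is generated and the full chain is
    run: feature extraction, leave-one-prostate-out evaluation of the
    fused parameter set {r, mu, kappa, PT} and of every single feature, a
    label-permutation chance baseline, and a confidence-ordered exclusion
    sweep on quantile thresholds of the out-of-fold confidence P.
    """
    rows = []
    for seed in seeds:
        cfg = _cohort_config(frame_rate, int(seed))
        planes = generate_cohort(cfg, n_prostates, planes_per_prostate, seed=int(seed))
        ds = cohort_dataset(planes, FeatureConfig(max_pixels_per_roi=max_pixels_per_roi))
        inc = ds.included

        multi = evaluate_loo(ds, MULTI_SUBSET, seed=int(seed))
        singles = {
            name: evaluate_loo(ds, (name,), seed=int(seed)).mean["accuracy"]
            for name in FEATURE_NAMES
        }
        best_single = max(singles, key=lambda k: singles[k])
        null_acc = permutation_null_accuracy(ds, MULTI_SUBSET, seed=int(seed))

        p = multi.pixel_confidence
        qs = np.nanquantile(p[inc], exclusion_quantiles)
        curve = exclusion_sweep(multi, ds, "confidence", qs)
        acc_curve = curve.metrics["accuracy"].to_numpy()

        # per-prostate excluded fraction at the P > 0.5 operating point
        excl_05 = []
        for pid in np.unique(ds.prostate_id):
            sel = inc & (ds.prostate_id == pid)
            if sel.any():
                excl_05.append(float(np.mean(p[sel] < 0.5)))
        wit_mu = float(
            np.corrcoef(ds.features["WIT"][inc], ds.features["mu"][inc])[0, 1]
        )

        row = {
            "seed": int(seed),
            "n_pixels": int(len(ds)),
            "included_fraction": float(inc.mean()),
            "multi_accuracy": multi.mean["accuracy"],
            "multi_npv": multi.mean["npv"],
            "multi_sensitivity": multi.mean["sensitivity"],
            "multi_specificity": multi.mean["specificity"],
            "multi_ppv": multi.mean["ppv"],
            "best_single": best_single,
            "best_single_accuracy": singles[best_single],
            "null_accuracy": null_acc,
            "wit_mu_pearson": wit_mu,
            "excluded_fraction_at_P05": float(np.mean(excl_05)),
            "accuracy_full": float(acc_curve[0]),
            "accuracy_at_half_retained": float(acc_curve[-1]),
        }
        for i, q in enumerate(exclusion_quantiles):
            row[f"accuracy_excl_q{int(q * 100):02d}"] = float(acc_curve[i])
        for name, acc in singles.items():
            row[f"single_{name}"] = acc
        rows.append(row)
        if progress:
            print(
                f"seed {seed}: multi {row['multi_accuracy']:.1f} "
                f"best single {best_single} {row['best_single_accuracy']:.1f} "
                f"null {null_acc:.1f}"
            )
    return pd.DataFrame(rows)
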