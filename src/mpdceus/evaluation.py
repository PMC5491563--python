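"""Grouped cross-validation, exhaustive subset search, and pixel exclusion.

Validation is leave-one-prostate-out: every fold holds out all pixels of
one prostate, the normalization scales and mixtures are fitted on the
remaining prostates only, and metrics are averaged (unweighted) across
prostates.  Undefined metrics (zero denominators, e.g. a held-out prostate
with one class) propagate as NaN and are skipped in the averages, never
counted as zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classification import classify, confusion_metrics, fit_gmm
from .dataset import PixelDataset

__all__ = [
    "LooResult",
    "evaluate_loo",
    "subset_search",
    "ExclusionCurve",
    "exclusion_sweep",
    "permutation_null_accuracy",
]

_METRICS = ["accuracy", "sensitivity", "specificity", "ppv", "npv"]


@dataclass
class LooResult:
    """Per-prostate performance plus pooled per-pixel out-of-fold outputs."""

    subset: tuple[str, ...]
    per_prostate: pd.DataFrame
    mean: dict[str, float]
    sd: dict[str, float]
    # aligned with the dataset rows; NaN / -1 where not included
    pixel_pred: np.ndarray = field(repr=False, default=None)
    pixel_confidence: np.ndarray = field(repr=False, default=None)
    pixel_density: np.ndarray = field(repr=False, default=None)
    included: np.ndarray = field(repr=False, default=None)

    @property
    def pooled(self):
        inc = self.included
        return confusion_metrics(self.pixel_pred[inc], self._truth[inc])


def evaluate_loo(
    dataset: PixelDataset,
    feature_subset,
    *,
    n_components: int = 1,
    priors: str = "equal",
    seed: int = 0,
) -> LooResult:
    """Leave-one-prostate-out evaluation of one feature subset.

    Per fold, the 90th-percentile scales and the per-class mixtures are
    computed on the training prostates and applied to the held-out one;
    no test pixel influences training.  Returns per-prostate metric rows,
    their unweighted mean and sd, and the pooled out-of-fold per-pixel
    predictions, confidences and winning-class densities (for exclusion
    sweeps).
    """
    subset = tuple(feature_subset)
    inc = dataset.included
    x = dataset.features[list(subset)].to_numpy()
    y = dataset.labels
    pids = np.unique(dataset.prostate_id)
    if pids.size < 2:
        raise ValueError("leave-one-prostate-out needs at least 2 prostates")

    n = len(dataset)
    pred = np.full(n, -1, dtype=int)
    conf = np.full(n, np.nan)
    dens = np.full(n, np.nan)
    rows = []
    for pid in pids:
        test = inc & (dataset.prostate_id == pid)
        train = inc & (dataset.prostate_id != pid)
        if not test.any():
            continue
        model = fit_gmm(
            x[train], y[train], n_components, feature_names=list(subset),
            priors=priors, seed=seed,
        )
        res = classify(model, x[test])
        pred[test] = res.labels
        conf[test] = res.confidence
        dens[test] = res.density
        row = confusion_metrics(res.labels, y[test]).as_dict()
        row["prostate_id"] = pid
        rows.append(row)

    per = pd.DataFrame(rows).set_index("prostate_id")
    mean = {m: float(np.nanmean(per[m])) for m in _METRICS}
    sd = {m: float(np.nanstd(per[m], ddof=1)) if per[m].notna().sum() > 1 else 0.0 for m in _METRICS}
    out = LooResult(subset, per, mean, sd, pred, conf, dens, inc)
    out._truth = y
    return out


def _all_subsets(names, max_size):
    names = sorted(names)
    for size in range(1, max_size + 1):
        yield from itertools.combinations(names, size)


def subset_search(
    dataset: PixelDataset,
    max_size: int = 4,
    *,
    feature_names=None,
    n_components: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate every feature subset of size 1..max_size by LOO.

    Returns one row per subset with the mean/sd of each metric, ranked by
    mean accuracy (``rank_accuracy``) and separately by mean NPV
    (``rank_npv``); ties break toward fewer parameters, then lexicographic
    feature names.  Deterministic.
    """
    names = feature_names if feature_names is not None else dataset.feature_names
    rows = []
    for subset in _all_subsets(names, max_size):
        res = evaluate_loo(dataset, subset, n_components=n_components, seed=seed)
        row = {"subset": ",".join(subset), "size": len(subset)}
        for m in _METRICS:
            row[m] = res.mean[m]
            row[m + "_sd"] = res.sd[m]
        rows.append(row)
    table = pd.DataFrame(rows)

    def rank_by(metric):
        order = sorted(
            range(len(table)),
            key=lambda i: (-table[metric][i] if np.isfinite(table[metric][i]) else np.inf,
                           table["size"][i], table["subset"][i]),
        )
        ranks = np.empty(len(table), dtype=int)
        ranks[order] = np.arange(1, len(table) + 1)
        return ranks

    table["rank_accuracy"] = rank_by("accuracy")
    table["rank_npv"] = rank_by("npv")
    return table.sort_values("rank_accuracy").reset_index(drop=True)


@dataclass
class ExclusionCurve:
    measure: str
    thresholds: np.ndarray
    retained_fraction: np.ndarray
    retained_benign: np.ndarray
    retained_malignant: np.ndarray
    metrics: pd.DataFrame           # pooled metrics per threshold (NaN when undefined)
    n_retained: np.ndarray


def exclusion_sweep(
    loo: LooResult,
    dataset: PixelDataset,
    measure: str = "confidence",
    thresholds=None,
) -> ExclusionCurve:
    """Recompute pooled metrics after excluding low-quality pixels.

    ``measure`` is one of ``confidence`` (P), ``r_squared``,
    ``absolute_probability`` (winning class density), or ``peak_time``
    (exclude the lowest-PT fraction per plane; thresholds are fractions).
    Unfittable pixels are excluded at every threshold, so retained
    fractions are reported against the full ROI pixel count.
    """
    inc = loo.included
    y = dataset.labels
    n_total = len(dataset)
    n_ben = int(np.sum(y == 0))
    n_mal = int(np.sum(y == 1))

    if measure == "confidence":
        values = loo.pixel_confidence
        if thresholds is None:
            thresholds = np.arange(0.0, 1.0, 0.05)
        retain_fn = lambda thr: inc & (values >= thr)
    elif measure == "r_squared":
        values = dataset.aux["r_squared"].to_numpy(dtype=float)
        if thresholds is None:
            thresholds = np.arange(0.0, 1.0, 0.05)
        retain_fn = lambda thr: inc & (values >= thr)
    elif measure == "absolute_probability":
        values = loo.pixel_density
        if thresholds is None:
            finite = values[inc & np.isfinite(values)]
            thresholds = np.quantile(finite, np.arange(0.0, 0.96, 0.05)) if finite.size else np.array([0.0])
        retain_fn = lambda thr: inc & (values >= thr)
    elif measure == "peak_time":
        pt = dataset.aux["peak_time"].to_numpy(dtype=float)
        if thresholds is None:
            thresholds = np.arange(0.0, 0.96, 0.05)  # excluded fraction per plane

        def retain_fn(frac):
            keep = inc.copy()
            for pid, plid in set(zip(dataset.prostate_id, dataset.plane_id)):
                sel = inc & (dataset.prostate_id == pid) & (dataset.plane_id == plid)
                if not sel.any():
                    continue
                cut = np.quantile(pt[sel], frac)
                keep &= ~sel | (pt >= cut)
            return keep
    else:
        raise ValueError(f"unknown exclusion measure {measure!r}")

    thresholds = np.asarray(thresholds, dtype=float)
    rows, kept_frac, kept_ben, kept_mal, n_kept = [], [], [], [], []
    for thr in thresholds:
        keep = retain_fn(thr)
        nk = int(keep.sum())
        n_kept.append(nk)
        kept_frac.append(nk / n_total if n_total else np.nan)
        kept_ben.append(np.sum(keep & (y == 0)) / n_ben if n_ben else np.nan)
        kept_mal.append(np.sum(keep & (y == 1)) / n_mal if n_mal else np.nan)
        if nk == 0:
            rows.append(dict.fromkeys(_METRICS, np.nan))
        else:
            rows.append({m: v for m, v in confusion_metrics(loo.pixel_pred[keep], y[keep]).as_dict().items() if m in _METRICS})
    return ExclusionCurve(
        measure=measure,
        thresholds=thresholds,
        retained_fraction=np.asarray(kept_frac),
        retained_benign=np.asarray(kept_ben),
        retained_malignant=np.asarray(kept_mal),
        metrics=pd.DataFrame(rows),
        n_retained=np.asarray(n_kept),
    )


def permutation_null_accuracy(
    dataset: PixelDataset, feature_subset, *, seed: int = 0, n_components: int = 1
) -> float:
    """Mean LOO accuracy after randomly permuting the pixel labels.

    The same grouped pipeline run on label-shuffled data gives the
    chance-level baseline against which the real accuracy is compared.
    """
    rng = np.random.default_rng(seed)
    shuffled = dataset.labels.copy()
    rng.shuffle(shuffled)
    permuted = PixelDataset(
        features=dataset.features,
        labels=shuffled,
        prostate_id=dataset.prostate_id,
        plane_id=dataset.plane_id,
        roi_id=dataset.roi_id,
        aux=dataset.aux,
    )
    res = evaluate_loo(permuted, feature_subset, n_components=n_components, seed=seed)
    return res.mean["accuracy"]
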