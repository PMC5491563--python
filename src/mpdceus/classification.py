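"""Two-class Gaussian-mixture pixel classification with confidence.

Each class (benign, malignant) is described by a mixture of normal
distributions over the selected, 90th-percentile-normalized features;
pixels are assigned to the class with the larger posterior.  The default of
one component per class reduces to a closed-form Gaussian discriminant;
more components are fitted by expectation-maximization.

The classification confidence is

    P = 2 * p_A / (p_A + p_B) - 1,

with A the more probable class: P = 0 means indifference, P = 1 certainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture

__all__ = [
    "ClassifierModel",
    "ClassificationResult",
    "PerformanceRow",
    "normalize",
    "confidence",
    "fit_gmm",
    "classify",
    "confusion_metrics",
]

BENIGN, MALIGNANT = 0, 1


def normalize(features, scales=None, feature_names=None):
    """Divide each feature column by its training 90th percentile.

    On a training call (``scales=None``) the per-column 90th percentiles
    (linear interpolation between order statistics) are computed and
    returned for reuse; on a test call the supplied training scales are
    applied unchanged, so test data never influence the normalization.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if scales is None:
        scales = np.percentile(x, 90.0, axis=0)
        bad = np.nonzero(scales <= 0)[0]
        if bad.size:
            names = (
                [feature_names[i] for i in bad]
                if feature_names is not None
                else list(bad)
            )
            raise ValueError(f"non-positive 90th percentile for feature(s) {names}")
    else:
        scales = np.asarray(scales, dtype=float)
    return x / scales, scales


def confidence(p_a, p_b):
    """Classification confidence P = 2*max(p)/(p_a + p_b) - 1, in [0, 1]."""
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    hi = np.maximum(p_a, p_b)
    tot = p_a + p_b
    out = np.where(tot > 0, 2.0 * hi / np.where(tot > 0, tot, 1.0) - 1.0, 0.0)
    return out if out.ndim else float(out)


@dataclass
class ClassifierModel:
    """Per-class Gaussian mixtures plus the training normalization scales."""

    mixtures: dict[int, GaussianMixture]
    scales: np.ndarray
    feature_names: list[str]
    class_priors: dict[int, float]
    n_components: int = 1


@dataclass
class ClassificationResult:
    labels: np.ndarray
    p_benign: np.ndarray           # posterior, sums to 1 with p_malignant
    p_malignant: np.ndarray
    confidence: np.ndarray         # P in [0, 1]
    density: np.ndarray            # winning class-conditional density (abs. probability)


def fit_gmm(
    features,
    labels,
    n_components: int = 1,
    *,
    feature_names=None,
    scales=None,
    priors="equal",
    reg_covar: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
) -> ClassifierModel:
    """Fit one Gaussian mixture per class on normalized training features.

    ``features`` are raw (unnormalized); the 90th-percentile scales are
    computed here from the training data unless supplied.  With a single
    component EM reduces to the exact per-class mean/covariance estimate
    (plus ``reg_covar`` on the diagonal).  Deterministic given ``seed``.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels)
    classes = np.unique(y)
    if not (len(classes) == 2 and set(classes) <= {BENIGN, MALIGNANT}):
        raise ValueError("training data must contain both classes (0=benign, 1=malignant)")
    xn, scales = normalize(x, scales, feature_names)
    mixtures = {}
    for cls in (BENIGN, MALIGNANT):
        xc = xn[y == cls]
        gm = GaussianMixture(
            n_components=n_components,
            covariance_type="full",
            reg_covar=reg_covar,
            tol=tol,
            max_iter=max_iter,
            random_state=seed,
            init_params="kmeans",
        )
        gm.fit(xc)
        mixtures[cls] = gm
    if priors == "equal":
        class_priors = {BENIGN: 0.5, MALIGNANT: 0.5}
    elif priors == "empirical":
        class_priors = {c: float(np.mean(y == c)) for c in (BENIGN, MALIGNANT)}
    else:
        class_priors = dict(priors)
    names = list(feature_names) if feature_names is not None else [f"f{i}" for i in range(x.shape[1])]
    return ClassifierModel(mixtures, scales, names, class_priors, n_components)


def classify(model: ClassifierModel, features, *, normalized: bool = False) -> ClassificationResult:
    """Classify pixels with the trained model.

    Raw features are normalized with the model's training scales.  Posterior
    probabilities are prior-weighted mixture densities normalized to sum to
    one; ties are broken toward benign with P = 0.  ``density`` holds the
    winning class-conditional density ("absolute probability").
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    xn = x if normalized else x / model.scales
    log_d = np.column_stack(
        [model.mixtures[BENIGN].score_samples(xn), model.mixtures[MALIGNANT].score_samples(xn)]
    )
    log_p = log_d + np.log(
        [model.class_priors[BENIGN], model.class_priors[MALIGNANT]]
    )
    log_post = log_p - logsumexp(log_p, axis=1, keepdims=True)
    post = np.exp(log_post)
    p_ben, p_mal = post[:, 0], post[:, 1]
    labels = (p_mal > p_ben).astype(int)  # tie -> benign
    conf = confidence(p_ben, p_mal)
    density = np.exp(np.where(labels == MALIGNANT, log_d[:, 1], log_d[:, 0]))
    return ClassificationResult(labels, p_ben, p_mal, conf, density)


@dataclass
class PerformanceRow:
    """Confusion counts and the derived metrics (percent; NaN when undefined).

    Malignant is the positive class: sensitivity is the fraction of
    malignant pixels called malignant, specificity the fraction of benign
    pixels called benign, PPV/NPV the fraction of malignant/benign calls
    that are correct.
    """

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @staticmethod
    def _ratio(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.n)

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
        }


def confusion_metrics(predicted, truth) -> PerformanceRow:
    """Confusion counts of a prediction against ground truth labels."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have the same length")
    if truth.size and not set(np.unique(truth)) <= {BENIGN, MALIGNANT}:
        raise ValueError("truth labels must be 0 (benign) or 1 (malignant)")
    tp = int(np.sum((predicted == MALIGNANT) & (truth == MALIGNANT)))
    fn = int(np.sum((predicted == BENIGN) & (truth == MALIGNANT)))
    tn = int(np.sum((predicted == BENIGN) & (truth == BENIGN)))
    fp = int(np.sum((predicted == MALIGNANT) & (truth == BENIGN)))
    return PerformanceRow(tp=tp, fn=fn, tn=tn, fp=fp)
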