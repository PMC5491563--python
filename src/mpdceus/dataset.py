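"""Per-pixel feature dataset with class labels and grouping identifiers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FEATURE_NAMES", "PixelDataset"]

# Table-style feature panel: B-mode greylevel, perfusion, LDRW fit, similarity.
FEATURE_NAMES = [
    "greylevel",
    "WIT",
    "AT",
    "PT",
    "PI",
    "FWHM",
    "kappa",
    "mu",
    "lam",
    "alpha",
    "var",
    "int",
    "rho",
    "r",
]


@dataclass
class PixelDataset:
    """N pixels x D features with labels and prostate/plane/ROI group IDs.

    ``aux`` carries per-pixel quantities used for exclusion variants
    (peak_time, r_squared, fittable).  Rows that are unfittable or carry
    non-finite features are never included in classification but stay in
    the dataset so exclusion fractions are reported against the full ROI
    pixel count.
    """

    features: pd.DataFrame
    labels: np.ndarray
    prostate_id: np.ndarray
    plane_id: np.ndarray
    roi_id: np.ndarray
    aux: pd.DataFrame

    def __post_init__(self):
        n = len(self.features)
        for name in ("labels", "prostate_id", "plane_id", "roi_id"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != {n} feature rows")
            setattr(self, name, arr)
        if len(self.aux) != n:
            raise ValueError("aux length must match feature rows")
        if self.features.shape[1] > len(FEATURE_NAMES):
            raise ValueError(f"at most {len(FEATURE_NAMES)} features supported")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def included(self) -> np.ndarray:
        """Fittable rows with fully finite feature values."""
        finite = np.isfinite(self.features.to_numpy()).all(axis=1)
        fittable = self.aux["fittable"].to_numpy(dtype=bool)
        return finite & fittable

    @classmethod
    def from_frame(cls, df: pd.DataFrame, feature_names=None) -> "PixelDataset":
        """Build from a flat per-pixel table (as written by feature extraction)."""
        names = feature_names or [c for c in FEATURE_NAMES if c in df.columns]
        aux_cols = [c for c in ("peak_time", "r_squared", "fittable") if c in df.columns]
        return cls(
            features=df[names].reset_index(drop=True),
            labels=df["label"].to_numpy(),
            prostate_id=df["prostate_id"].to_numpy(),
            plane_id=df["plane_id"].to_numpy(),
            roi_id=df["roi_id"].to_numpy(),
            aux=df[aux_cols].reset_index(drop=True),
        )
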