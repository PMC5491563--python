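"""Shared fixtures: small phantoms and synthetic Gaussian pixel datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mpdceus import PhantomConfig, generate_phantom
from mpdceus.dataset import PixelDataset
from mpdceus.synthetic import NoiseModel, Recirculation


@pytest.fixture(scope="session")
def noiseless_phantom():
    """32x32 noiseless, recirculation-free phantom with one lesion."""
    cfg = PhantomConfig(
        grid_height=32,
        grid_width=32,
        n_lesions=1,
        lesion_area=0.2,
        frame_rate=10.0,
        noise=NoiseModel(0.0, 0.0),
        recirculation=Recirculation(45.0, 0.0),
        seed=11,
    )
    return cfg, *generate_phantom(cfg)


def make_gaussian_dataset(
    n_prostates=4,
    n_per_class=60,
    n_features=3,
    separation=2.5,
    prostate_sd=0.3,
    seed=0,
    feature_names=None,
):
    """Synthetic PixelDataset drawn directly from class Gaussians.

    Fast stand-in for an extracted cohort: positive-valued features with a
    mean shift of ``separation`` (in within-class sd) between classes and a
    random prostate-level offset shared by both classes.
    """
    rng = np.random.default_rng(seed)
    names = feature_names or [f"f{i}" for i in range(n_features)]
    frames = []
    for pid in range(n_prostates):
        offset = rng.normal(0, prostate_sd, n_features)
        for label in (0, 1):
            x = rng.normal(5.0 + offset + label * separation, 1.0, (n_per_class, n_features))
            df = pd.DataFrame(np.abs(x), columns=names)
            df["label"] = label
            df["prostate_id"] = pid
            df["plane_id"] = 0
            df["roi_id"] = label
            frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    n = len(table)
    aux = pd.DataFrame(
        {
            "peak_time": rng.uniform(10, 30, n),
            "r_squared": rng.uniform(0.6, 1.0, n),
            "fittable": np.ones(n, dtype=bool),
        }
    )
    return PixelDataset(
        features=table[names],
        labels=table["label"].to_numpy(),
        prostate_id=table["prostate_id"].to_numpy(),
        plane_id=table["plane_id"].to_numpy(),
        roi_id=table["roi_id"].to_numpy(),
        aux=aux,
    )


@pytest.fixture()
def gaussian_dataset():
    return make_gaussian_dataset()
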