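"""Reading and writing loops, label maps, ROI tables and feature maps.

Loops are stored as multi-page float32 TIFF stacks with a plain-text
``key: value`` sidecar carrying the acquisition metadata (frame rate, pixel
spacing, compression state); NIfTI stacks are accepted on read.  Label maps
are single-page integer TIFFs, ROI tables CSV with polygon vertices.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .preprocessing import DceusLoop
from .synthetic import GroundTruth, Roi

__all__ = [
    "write_loop",
    "read_loop",
    "write_label_map",
    "read_label_map",
    "write_rois",
    "read_rois",
    "write_feature_maps",
    "read_feature_maps",
    "write_classification_overlay",
]

_SIDECAR_SUFFIX = ".meta.txt"


def _sidecar_path(stack_path: Path) -> Path:
    return stack_path.with_name(stack_path.stem + _SIDECAR_SUFFIX)


def write_loop(path, loop: DceusLoop) -> Path:
    """Write a loop as a multi-page TIFF plus metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, loop.frames.astype(np.float32))
    meta = {
        "frame_rate": loop.frame_rate,
        "pixel_spacing": loop.pixel_spacing,
        "compression": loop.compression,
        "dynamic_range": "" if loop.dynamic_range is None else loop.dynamic_range,
        "g_max": loop.g_max,
    }
    _sidecar_path(path).write_text(
        "".join(f"{k}: {v}\n" for k, v in meta.items()), encoding="utf-8"
    )
    return path


def read_loop(path) -> DceusLoop:
    """Read a loop written by `write_loop` (TIFF, or NIfTI via nibabel)."""
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        import nibabel as nib

        data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
        frames = np.transpose(data, (2, 0, 1))
    else:
        frames = tifffile.imread(path).astype(float)
    meta = {}
    for line in _sidecar_path(path).read_text(encoding="utf-8").splitlines():
        if ":" in line:
            k, v = line.split(":", 1)
            meta[k.strip()] = v.strip()
    dr = meta.get("dynamic_range", "")
    return DceusLoop(
        frames=frames,
        frame_rate=float(meta["frame_rate"]),
        pixel_spacing=float(meta["pixel_spacing"]),
        compression=meta.get("compression", "linear"),
        dynamic_range=float(dr) if dr else None,
        g_max=float(meta.get("g_max", 255)),
    )


def write_label_map(path, label_map: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(label_map, dtype=np.uint8))
    return path


def read_label_map(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.uint8)


def write_rois(path, rois: list[Roi]) -> Path:
    """ROI table as CSV: ids, class, and the polygon as 'r,c;r,c;...'."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "prostate_id": roi.prostate_id,
            "plane_id": roi.plane_id,
            "roi_id": roi.roi_id,
            "class": "malignant" if roi.label == 1 else "benign",
            "polygon": ";".join(f"{r:.2f},{c:.2f}" for r, c in roi.polygon),
        }
        for roi in rois
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_rois(path, shape) -> list[Roi]:
    """Rebuild Roi objects (rasterizing the polygons) from a CSV table."""
    from matplotlib.path import Path as MplPath  # lazy; only needed for reads

    df = pd.read_csv(path)
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    rois = []
    for _, row in df.iterrows():
        poly = np.array(
            [[float(a) for a in v.split(",")] for v in str(row["polygon"]).split(";")]
        )
        mask = MplPath(poly).contains_points(pts).reshape(h, w)
        rois.append(
            Roi(
                roi_id=int(row["roi_id"]),
                label=1 if row["class"] == "malignant" else 0,
                mask=mask,
                polygon=poly,
                prostate_id=int(row["prostate_id"]),
                plane_id=int(row["plane_id"]),
            )
        )
    return rois


def write_feature_maps(directory, maps: dict[str, np.ndarray]) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, arr in maps.items():
        tifffile.imwrite(directory / f"{name}.tif", np.asarray(arr, dtype=np.float32))
    return directory


def read_feature_maps(directory) -> dict[str, np.ndarray]:
    directory = Path(directory)
    return {
        p.stem: tifffile.imread(p).astype(float) for p in sorted(directory.glob("*.tif"))
    }


def write_classification_overlay(path, label_map, confidence_map) -> Path:
    """RGBA PNG: red = malignant, green = benign, alpha scaled by confidence."""
    import imageio.v3 as iio

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = np.asarray(label_map)
    conf = np.nan_to_num(np.asarray(confidence_map, dtype=float), nan=0.0)
    h, w = labels.shape
    rgba = np.zeros((h, w, 4), dtype=np.uint8)
    rgba[..., 0] = np.where(labels == 1, 255, 0)
    rgba[..., 1] = np.where(labels == 0, 255, 0)
    rgba[..., 3] = np.clip(conf * 255, 0, 255).astype(np.uint8)
    iio.imwrite(path, rgba)
    return path
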