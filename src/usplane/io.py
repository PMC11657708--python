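"""Image and dataset-manifest I/O (PNG/TIFF/JPEG, 8-bit grayscale).

Color inputs are converted to grayscale by the luminance average of the
channels.  A dataset manifest is a CSV with header ``path,label``;
paths are resolved relative to the manifest's directory.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .imgproc import GrayImage, LabeledDataset

__all__ = ["read_image", "write_image", "load_manifest", "save_dataset"]


def read_image(path) -> GrayImage:
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    arr = np.clip(np.rint(arr.astype(np.float64)), 0, 255).astype(np.uint8)
    return GrayImage(arr)


def write_image(image: GrayImage, path) -> None:
    px = image.pixels
    if image.normalized:
        px = np.clip(np.rint(px * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(px, mode="L").save(path)


def load_manifest(path) -> LabeledDataset:
    path = Path(path)
    df = pd.read_csv(path)
    if not {"path", "label"} <= set(df.columns):
        raise ValueError("manifest CSV requires 'path' and 'label' columns")
    images = [read_image(path.parent / p) for p in df["path"]]
    return LabeledDataset(images, df["label"].to_numpy(np.int64))


def save_dataset(data: LabeledDataset, outdir, prefix: str = "img") -> Path:
    """Write PNGs plus a ``manifest.csv``; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, (im, lab) in enumerate(zip(data.images, data.labels)):
        name = f"{prefix}_{k:05d}.png"
        write_image(im, outdir / name)
        rows.append({"path": name, "label": int(lab)})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
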