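"""TIFF and table I/O for the screening pipeline.

Field-of-view images follow the ``<plate>_<well>_f<k>.tif`` naming
convention, which is the single source of the image-to-well mapping.
Images are stored as 16-bit grayscale TIFF at unit gain (1 ADU per count),
rounded to the nearest integer and clipped to the uint16 range.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .granulometry import Image, as_image
from .synthetic import GROUND_TRUTH_COLUMNS, PlateData

__all__ = [
    "parse_fov_filename",
    "fov_filename",
    "read_fov_image",
    "write_fov_image",
    "write_plate",
]

_FOV_RE = re.compile(r"^(?P<plate>.+)_(?P<well>[A-P](?:[1-9]|1[0-9]|2[0-4]))_f(?P<fov>\d+)\.tiff?$")
FILENAME_PATTERN = "<plate>_<well>_f<k>.tif  (well = A1..P24)"


def fov_filename(plate: str, well: str, fov: int) -> str:
    return f"{plate}_{well}_f{fov}.tif"


def parse_fov_filename(name: str) -> tuple[str, str, int]:
    """Extract (plate, well, fov) from a FOV filename."""
    m = _FOV_RE.match(Path(name).name)
    if not m:
        raise ValueError(f"cannot parse FOV filename {name!r}; expected {FILENAME_PATTERN}")
    return m["plate"], m["well"], int(m["fov"])


def read_fov_image(path: str | Path) -> tuple[Image, str, str, int]:
    """Read one grayscale TIFF field of view.

    Returns the image plus the (plate, well, fov) parsed from the filename.
    Multi-channel / RGB files are rejected with the offending axis named.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single grayscale plane, got shape {arr.shape} "
            f"(extra axis of length {arr.shape[0] if arr.ndim > 2 else arr.shape[-1]})"
        )
    plate, well, fov = parse_fov_filename(path.name)
    return Image(arr.astype(float), channel_label=plate), plate, well, fov


def write_fov_image(image: Image | np.ndarray, path: str | Path) -> np.ndarray:
    """Write an image as 16-bit TIFF (unit gain, rounded, clipped at 65535).

    Returns the array as stored, so callers can assert exact round-trips.
    """
    image = as_image(image)
    stored = np.clip(np.round(image.pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, stored)
    return stored


def write_plate(plate: PlateData, out_dir: str | Path, plate_name: str = "plate") -> dict:
    """Write a simulated plate to disk: TIFF per FOV + platemap + ground truth.

    Returns the paths written: ``{"images_dir", "platemap", "ground_truth"}``.
    """
    out = Path(out_dir)
    images_dir = out / "images"
    images_dir.mkdir(parents=True, exist_ok=True)
    for (well, fov), img in plate.images.items():
        write_fov_image(img, images_dir / fov_filename(plate_name, well, fov))
    platemap_path = out / "platemap.csv"
    plate.platemap.to_csv(platemap_path, index=False)
    truth_path = out / "ground_truth.csv"
    plate.ground_truth.to_csv(truth_path, index=False, columns=["well", "fov"] + GROUND_TRUTH_COLUMNS)
    return {"images_dir": str(images_dir), "platemap": str(platemap_path), "ground_truth": str(truth_path)}
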