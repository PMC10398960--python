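"""Text and TIFF interchange formats.

* per-curve TSV: two columns ``height_um``, ``deflection_um``;
* map manifest CSV: ``curve_file, x_um, y_um, animal, cohort`` plus the
  shared spring constant stored in a sidecar key-value config;
* region masks and fluorescence images as TIFF;
* configs as flat YAML key-value files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .elastmap import RegionMask
from .forcecurve import ForceCurve
from .gfapquant import FluorescenceImage

__all__ = [
    "write_curve_tsv",
    "read_curve_tsv",
    "write_manifest",
    "read_manifest",
    "write_mask_tiff",
    "read_mask_tiff",
    "write_image_tiff",
    "read_image_tiff",
    "save_config",
    "load_config",
]


def write_curve_tsv(curve: ForceCurve, path) -> None:
    pd.DataFrame(
        {"height_um": curve.heights, "deflection_um": curve.deflections}
    ).to_csv(path, sep="\t", index=False)


def read_curve_tsv(
    path,
    spring_constant: float,
    position: tuple[float, float] = (0.0, 0.0),
    curve_id: str = "",
) -> ForceCurve:
    df = pd.read_csv(path, sep="\t")
    return ForceCurve(
        heights=df["height_um"].to_numpy(),
        deflections=df["deflection_um"].to_numpy(),
        spring_constant=spring_constant,
        position=position,
        id=curve_id or Path(path).stem,
    )


def write_manifest(manifest: pd.DataFrame, path) -> None:
    cols = ["curve_file", "x_um", "y_um", "animal", "cohort"]
    manifest[cols].to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_mask_tiff(mask: RegionMask, path) -> None:
    tifffile.imwrite(path, mask.labels.astype(np.uint8))


def read_mask_tiff(path) -> RegionMask:
    return RegionMask(labels=tifffile.imread(path).astype(int))


def write_image_tiff(image: FluorescenceImage, path) -> None:
    tifffile.imwrite(path, image.pixels)


def read_image_tiff(
    path, pixel_size: float, animal: str = "", cohort: str = "", slice_id: str = ""
) -> FluorescenceImage:
    return FluorescenceImage(
        pixels=tifffile.imread(path),
        pixel_size=pixel_size,
        animal=animal,
        cohort=cohort,
        slice_id=slice_id,
    )


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
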