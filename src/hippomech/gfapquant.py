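"""GFAP immunofluorescence quantification over hippocampal subregions.

Astrocyte reactivity is scored as the mean 8-bit GFAP fluorescence
inside fixed-size square regions of interest (ROIs), five per
subregion per slice, each approximately 150 × 150 μm (22,500 μm²).
ROI placement is seeded-random within the subregion mask — a
reproducible stand-in for the manual selection used at the bench —
and measurements aggregate to per-animal means and cohort summaries.

Intensities are raw detector counts under fixed acquisition settings;
no background subtraction or normalisation is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .elastmap import LABEL_TO_GROUP, RegionMask
from .errors import AggregationError, DomainError, ParameterError

__all__ = [
    "FluorescenceImage",
    "RoiMeasurement",
    "measure_roi",
    "sample_rois",
    "aggregate_gfap",
]

ROI_SIZE_UM = 150.0
ROIS_PER_REGION = 5
MIN_INSIDE_FRACTION = 0.8


@dataclass(frozen=True)
class FluorescenceImage:
    """8-bit grayscale fluorescence image with physical pixel size."""

    pixels: np.ndarray
    pixel_size: float  # μm per pixel
    animal: str = ""
    cohort: str = ""
    slice_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ParameterError("image must be 2-D grayscale")
        if px.dtype != np.uint8:
            if px.min(initial=0) < 0 or px.max(initial=0) > 255:
                raise ParameterError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RoiMeasurement:
    """Mean intensity of one square ROI within one subregion."""

    region: int
    bounds_um: tuple[float, float, float, float]  # x, y, w, h
    mean_intensity: float
    animal: str = ""
    cohort: str = ""
    slice_id: str = ""


def measure_roi(
    image: FluorescenceImage, bounds_um: tuple[float, float, float, float], region: int = 0
) -> RoiMeasurement:
    """Mean pixel value inside a rectangular ROI given in μm coordinates."""
    x, y, w, h = bounds_um
    ps = image.pixel_size
    c0, r0 = int(round(x / ps)), int(round(y / ps))
    c1, r1 = int(round((x + w) / ps)), int(round((y + h) / ps))
    nr, nc = image.shape
    if not (0 <= r0 < r1 <= nr and 0 <= c0 < c1 <= nc):
        raise DomainError(f"ROI {bounds_um} exceeds image bounds {nr}x{nc}px")
    mean = float(image.pixels[r0:r1, c0:c1].mean())
    return RoiMeasurement(
        region=region,
        bounds_um=bounds_um,
        mean_intensity=mean,
        animal=image.animal,
        cohort=image.cohort,
        slice_id=image.slice_id,
    )


def sample_rois(
    image: FluorescenceImage,
    mask: RegionMask,
    n: int = ROIS_PER_REGION,
    size_um: float = ROI_SIZE_UM,
    seed: int | None = None,
    exclude_plaque_mask: np.ndarray | None = None,
    max_attempts: int = 4000,
) -> list[RoiMeasurement]:
    """Place ``n`` non-overlapping square ROIs per subregion and measure them.

    Each ROI must have at least 80% of its pixels inside its region's
    mask.  Placement is rejection sampling with a seeded generator.
    Regions that cannot host ``n`` ROIs are skipped with a warning.
    When ``exclude_plaque_mask`` is given (boolean array, True at
    plaque pixels), candidate ROIs overlapping any plaque pixel are
    rejected — the sensitivity-analysis mode.
    """
    if mask.shape != image.shape:
        raise ParameterError(
            f"mask shape {mask.shape} does not match image shape {image.shape}"
        )
    side = int(round(size_um / image.pixel_size))
    if side < 1:
        raise ParameterError("ROI smaller than one pixel")
    rng = np.random.default_rng(seed)
    nr, nc = image.shape
    results: list[RoiMeasurement] = []
    labels = [int(l) for l in np.unique(mask.labels) if l > 0]
    for label in labels:
        inside = (mask.labels == label).astype(np.int64)
        integral = inside.cumsum(0).cumsum(1)

        def frac_inside(r0: int, c0: int) -> float:
            r1, c1 = r0 + side, c0 + side
            s = integral[r1 - 1, c1 - 1]
            if r0 > 0:
                s -= integral[r0 - 1, c1 - 1]
            if c0 > 0:
                s -= integral[r1 - 1, c0 - 1]
            if r0 > 0 and c0 > 0:
                s += integral[r0 - 1, c0 - 1]
            return s / side**2

        placed: list[tuple[int, int]] = []
        attempts = 0
        while len(placed) < n and attempts < max_attempts:
            attempts += 1
            r0 = int(rng.integers(0, max(nr - side, 1)))
            c0 = int(rng.integers(0, max(nc - side, 1)))
            if r0 + side > nr or c0 + side > nc:
                continue
            if frac_inside(r0, c0) < MIN_INSIDE_FRACTION:
                continue
            if any(abs(r0 - r) < side and abs(c0 - c) < side for r, c in placed):
                continue
            if exclude_plaque_mask is not None and exclude_plaque_mask[
                r0 : r0 + side, c0 : c0 + side
            ].any():
                continue
            placed.append((r0, c0))
        if len(placed) < n:
            warnings.warn(
                f"region {label}: placed only {len(placed)}/{n} ROIs; region skipped",
                stacklevel=2,
            )
            continue
        ps = image.pixel_size
        for r0, c0 in placed:
            results.append(
                measure_roi(
                    image,
                    (c0 * ps, r0 * ps, side * ps, side * ps),
                    region=label,
                )
            )
    return results


def aggregate_gfap(measurements) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate ROI measurements to per-animal and per-cohort summaries.

    Returns ``(per_animal, cohort_summary)``:

    * ``per_animal`` — mean ROI intensity per (cohort, animal,
      analysis_group), the black-dot level of regional plots;
    * ``cohort_summary`` — mean, median and SD across all ROI points
      per (cohort, analysis_group), the bar/line/whisker level.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements.copy()
    else:
        df = pd.DataFrame(
            {
                "animal": [m.animal for m in measurements],
                "cohort": [m.cohort for m in measurements],
                "region": [m.region for m in measurements],
                "mean_intensity": [m.mean_intensity for m in measurements],
            }
        )
    if df.empty:
        raise AggregationError("no ROI measurements to aggregate")
    if "analysis_group" not in df.columns:
        df["analysis_group"] = [LABEL_TO_GROUP[int(r)].value for r in df["region"]]
    per_animal = (
        df.groupby(["cohort", "animal", "analysis_group"], as_index=False)[
            "mean_intensity"
        ]
        .mean()
        .rename(columns={"mean_intensity": "animal_mean"})
    )
    cohort = (
        df.groupby(["cohort", "analysis_group"])["mean_intensity"]
        .agg(mean="mean", median="median", sd="std", n="count")
        .reset_index()
    )
    return per_animal, cohort
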