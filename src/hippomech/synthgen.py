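"""Synthetic inputs for every stage of the hippocampal stiffness pipeline.

Three generators mirror the three experimental data streams:

* :func:`simulate_force_curve` — forward Hertz model for one AFM
  approach curve: flat (optionally tilted, noisy) pre-contact baseline,
  then a self-consistent sphere-indentation segment where the force
  depends on the indentation, which itself depends on the cantilever's
  own deflection (δ = (z − z_c) − d, d = F/k), solved by fixed-point
  iteration.  The ramp stops at the force setpoint (default 15 nN).

* :func:`simulate_cohort` — per-animal, per-region modulus samples for
  the three cohorts (3-month wild type n = 12, 18-month wild type
  n = 11, 17-month APP knock-in n = 4).  Each animal carries an
  additive normal random intercept; within an animal and region,
  moduli are log-normal (positive, right-skewed) with mean equal to
  the region × cohort calibration mean plus the intercept.

* :func:`simulate_gfap_image` — 8-bit GFAP-like immunofluorescence:
  per-region base intensity, Gaussian detector noise, and Poisson-
  placed bright disks emulating plaque-associated reactive astrocytes
  in the APP cohort.

The region × cohort calibration means in :data:`REGION_MEANS_PA` are
the package's reference description of regional mouse hippocampal
stiffness and of its changes with age and amyloid pathology; they are
what parameter-recovery tests try to get back out of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .elastmap import AnalysisGroup, GROUP_TO_LABELS, RegionMask
from .errors import ConfigurationError, ParameterError
from .forcecurve import ForceCurve
from .gfapquant import FluorescenceImage
from .units import NN_PER_NPM_UM, NN_PER_PA_UM2

__all__ = [
    "COHORT_WT_3M",
    "COHORT_WT_18M",
    "COHORT_APP_17M",
    "DEFAULT_COHORTS",
    "REGION_MEANS_PA",
    "GFAP_INTENSITY_8BIT",
    "CurveGenParams",
    "CohortDesign",
    "CohortDataset",
    "GfapImageParams",
    "simulate_force_curve",
    "simulate_cohort",
    "simulate_gfap_image",
    "band_region_mask",
    "gfap_intensity_by_label",
]

COHORT_WT_3M = "3mo-WT"
COHORT_WT_18M = "18mo-WT"
COHORT_APP_17M = "17mo-APP"

#: cohort sizes of the AFM arm of the study design being emulated
DEFAULT_COHORTS: tuple[tuple[str, int], ...] = (
    (COHORT_WT_3M, 12),
    (COHORT_WT_18M, 11),
    (COHORT_APP_17M, 4),
)

# Calibration means (Pa) per (analysis group, cohort). Anchored cells
# reproduce reported regional stiffness of the mouse hippocampus: CA1
# pyramidal 546/491/251, CA1 SO/SR 396/409/275, DG granule layer
# 180/311/139 across the three cohorts, CA3 pyramidal 168 and
# Hilus/CA3 196 in young wild types. Remaining cells are package
# choices consistent with the qualitative pattern (stable SLM/ML,
# slight non-significant CA3/Hilus softening under amyloid pathology).
REGION_MEANS_PA: Mapping[tuple[str, str], float] = {
    ("CA1_SO_SR", COHORT_WT_3M): 396.0,
    ("CA1_SO_SR", COHORT_WT_18M): 409.0,
    ("CA1_SO_SR", COHORT_APP_17M): 275.0,
    ("CA1_PYR", COHORT_WT_3M): 546.0,
    ("CA1_PYR", COHORT_WT_18M): 491.0,
    ("CA1_PYR", COHORT_APP_17M): 251.0,
    ("SLM", COHORT_WT_3M): 320.0,
    ("SLM", COHORT_WT_18M): 330.0,
    ("SLM", COHORT_APP_17M): 300.0,
    ("ML", COHORT_WT_3M): 240.0,
    ("ML", COHORT_WT_18M): 250.0,
    ("ML", COHORT_APP_17M): 230.0,
    ("DG_GCL", COHORT_WT_3M): 180.0,
    ("DG_GCL", COHORT_WT_18M): 311.0,
    ("DG_GCL", COHORT_APP_17M): 139.0,
    ("HILUS_CA3_SO_SR", COHORT_WT_3M): 196.0,
    ("HILUS_CA3_SO_SR", COHORT_WT_18M): 205.0,
    ("HILUS_CA3_SO_SR", COHORT_APP_17M): 185.0,
    ("CA3_PYR", COHORT_WT_3M): 168.0,
    ("CA3_PYR", COHORT_WT_18M): 175.0,
    ("CA3_PYR", COHORT_APP_17M): 160.0,
}

# Synthetic 8-bit GFAP intensity levels per (cohort → analysis group).
# Chosen to emulate the qualitative immunofluorescence pattern: broadly
# stable reactivity with healthy aging except a drop in the dentate
# granule layer, and elevated reactivity across CA1/CA3/Hilus/DG under
# amyloid pathology.
GFAP_INTENSITY_8BIT: Mapping[str, Mapping[str, float]] = {
    COHORT_WT_3M: {
        "CA1_SO_SR": 70.0,
        "CA1_PYR": 75.0,
        "SLM": 65.0,
        "ML": 68.0,
        "DG_GCL": 90.0,
        "HILUS_CA3_SO_SR": 72.0,
        "CA3_PYR": 74.0,
    },
    COHORT_WT_18M: {
        "CA1_SO_SR": 72.0,
        "CA1_PYR": 76.0,
        "SLM": 66.0,
        "ML": 70.0,
        "DG_GCL": 68.0,
        "HILUS_CA3_SO_SR": 74.0,
        "CA3_PYR": 75.0,
    },
    COHORT_APP_17M: {
        "CA1_SO_SR": 100.0,
        "CA1_PYR": 108.0,
        "SLM": 80.0,
        "ML": 85.0,
        "DG_GCL": 95.0,
        "HILUS_CA3_SO_SR": 105.0,
        "CA3_PYR": 106.0,
    },
}


@dataclass
class CurveGenParams:
    """Parameters of one simulated force-distance curve.

    ``baseline_slope`` is expressed in nN per μm of piezo travel and
    ``noise_sd`` in nN; both are converted to deflection units through
    the spring constant.
    """

    elastic_modulus: float  # Pa
    contact_point: float = 20.0  # μm
    poisson_ratio: float = 0.5
    bead_radius: float = 12.5  # μm
    spring_constant: float = 0.07  # N/m
    max_force: float = 15.0  # nN
    sample_spacing: float = 0.05  # μm
    noise_sd: float = 0.0  # nN
    baseline_slope: float = 0.0  # nN/μm
    pre_contact_travel: float = 6.0  # μm
    seed: int | None = None

    def __post_init__(self):
        if self.elastic_modulus <= 0:
            raise ParameterError("elastic_modulus must be positive")
        if not (0 <= self.poisson_ratio <= 0.5 + 1e-12):
            raise ParameterError("poisson_ratio must lie in [0, 0.5]")
        if self.bead_radius <= 0:
            raise ParameterError("bead_radius must be positive")
        if self.spring_constant <= 0:
            raise ParameterError("spring_constant must be positive")
        if self.max_force <= 0:
            raise ParameterError("max_force must be positive")
        if self.sample_spacing <= 0:
            raise ParameterError("sample_spacing must be positive")
        if self.noise_sd < 0 or self.pre_contact_travel <= 0:
            raise ParameterError("noise_sd must be >= 0 and pre_contact_travel > 0")


def _hertz_prefactor_nn(params: CurveGenParams) -> float:
    """prefactor a such that F[nN] = a · δ[μm]^{3/2}."""
    return (
        (4.0 / 3.0)
        * params.elastic_modulus
        / (1.0 - params.poisson_ratio**2)
        * np.sqrt(params.bead_radius)
        * NN_PER_PA_UM2
    )


def simulate_force_curve(
    params: CurveGenParams,
    position: tuple[float, float] = (0.0, 0.0),
    curve_id: str = "",
) -> ForceCurve:
    """Generate one approach force-distance curve from the forward model.

    Past contact the cantilever and tissue are in equilibrium:
    F = a·δ^{3/2} with δ = (z − z_c) − d and d = F/k.  The coupled pair
    is solved per sample by fixed-point iteration to a relative
    tolerance of 1e-12, so noiseless curves are exact equilibria and
    round-trip fits recover the generating modulus to machine
    precision.  The ramp ends once the equilibrium force reaches the
    setpoint ``max_force``.
    """
    a = _hertz_prefactor_nn(params)
    k_nn_um = params.spring_constant * NN_PER_NPM_UM  # nN per μm of deflection
    delta_end = (params.max_force / a) ** (2.0 / 3.0)
    post_travel = delta_end + params.max_force / k_nn_um
    pre_travel = max(params.pre_contact_travel, 0.55 * post_travel)

    z0 = params.contact_point - pre_travel
    z = np.arange(z0, params.contact_point + post_travel + params.sample_spacing, params.sample_spacing)

    force = np.zeros_like(z)
    post = z > params.contact_point
    travel = z[post] - params.contact_point
    f = a * travel**1.5  # start from the rigid-cantilever bound
    for _ in range(500):
        f_new = a * np.clip(travel - f / k_nn_um, 0.0, None) ** 1.5
        if np.all(np.abs(f_new - f) <= 1e-12 * (f_new + 1e-30)):
            f = f_new
            break
        f = f_new
    force[post] = f

    # truncate at the setpoint, keeping the first sample that reaches it
    reached = np.flatnonzero(force >= params.max_force * (1 - 1e-12))
    if reached.size:
        z = z[: reached[0] + 1]
        force = force[: reached[0] + 1]

    deflection = force / k_nn_um
    deflection = deflection + params.baseline_slope * (z - z[0]) / k_nn_um
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        deflection = deflection + rng.normal(0.0, params.noise_sd, z.size) / k_nn_um

    return ForceCurve(
        heights=z,
        deflections=deflection,
        spring_constant=params.spring_constant,
        position=position,
        id=curve_id,
    )


@dataclass
class CohortDesign:
    """Design of a synthetic multi-cohort stiffness dataset.

    ``animal_sd`` defaults to 15% of the grand mean of the calibration
    table; ``within_sd_fraction`` is the coefficient of variation of
    the log-normal within-animal spread.
    """

    cohorts: Sequence[tuple[str, int]] = DEFAULT_COHORTS
    region_means: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(REGION_MEANS_PA)
    )
    animal_sd: float | None = None
    within_sd_fraction: float = 0.35
    points_per_region: int = 200
    seed: int | None = None

    def __post_init__(self):
        valid_groups = {g.value for g in AnalysisGroup}
        cohort_labels = {label for label, _ in self.cohorts}
        for (group, cohort), mean in self.region_means.items():
            if group not in valid_groups:
                raise ConfigurationError(f"unknown analysis group {group!r}")
            if cohort not in cohort_labels:
                raise ConfigurationError(f"unknown cohort {cohort!r} in region_means")
            if mean <= 0:
                raise ParameterError(f"mean for {(group, cohort)} must be positive")
        for label, n in self.cohorts:
            if n < 1:
                raise ParameterError(f"cohort {label!r} needs at least 1 animal")
            if not any(c == label for _, c in self.region_means):
                raise ConfigurationError(f"no region means supplied for cohort {label!r}")
        if self.within_sd_fraction < 0:
            raise ParameterError("within_sd_fraction must be >= 0")
        if self.points_per_region < 1:
            raise ParameterError("points_per_region must be >= 1")

    @property
    def grand_mean(self) -> float:
        return float(np.mean(list(self.region_means.values())))

    @property
    def effective_animal_sd(self) -> float:
        return self.animal_sd if self.animal_sd is not None else 0.15 * self.grand_mean


@dataclass
class CohortDataset:
    """Per-point stiffness records plus optional raw curves.

    ``points`` columns: animal, cohort, analysis_group, modulus_Pa.
    ``curves`` maps a row index of ``points`` to the ForceCurve whose
    fit would yield that row's modulus.
    """

    points: pd.DataFrame
    design: CohortDesign
    curves: dict[int, ForceCurve] = field(default_factory=dict)


def simulate_cohort(design: CohortDesign, curves_per_group: int = 0) -> CohortDataset:
    """Draw the full multi-animal stiffness dataset.

    Per animal: intercept b ~ N(0, animal_sd), additive on the Pa
    scale.  Per analysis group: ``points_per_region`` draws from a
    log-normal with mean (region mean + b) and CV
    ``within_sd_fraction``; the cell mean is floored at 1% of the
    configured mean so moduli stay positive even for extreme
    intercepts.  Optionally emits full force curves for the first
    ``curves_per_group`` points of each animal × group cell.
    """
    rng = np.random.default_rng(design.seed)
    cv = design.within_sd_fraction
    sigma = float(np.sqrt(np.log1p(cv**2))) if cv > 0 else 0.0
    animal_sd = design.effective_animal_sd

    records: list[dict] = []
    curves: dict[int, ForceCurve] = {}
    for cohort, n_animals in design.cohorts:
        groups = sorted({g for g, c in design.region_means if c == cohort})
        for a in range(n_animals):
            animal = f"{cohort}-a{a + 1:02d}"
            intercept = rng.normal(0.0, animal_sd) if animal_sd > 0 else 0.0
            for group in groups:
                mean = design.region_means[(group, cohort)]
                m = max(mean + intercept, 0.01 * mean)
                if sigma > 0:
                    mu = np.log(m) - sigma**2 / 2.0
                    draws = rng.lognormal(mu, sigma, design.points_per_region)
                else:
                    draws = np.full(design.points_per_region, m)
                for i, e_pa in enumerate(draws):
                    idx = len(records)
                    records.append(
                        {
                            "animal": animal,
                            "cohort": cohort,
                            "analysis_group": group,
                            "modulus_Pa": float(e_pa),
                        }
                    )
                    if i < curves_per_group:
                        params = CurveGenParams(
                            elastic_modulus=float(e_pa),
                            seed=int(rng.integers(0, 2**31 - 1)),
                            noise_sd=0.05,
                        )
                        curves[idx] = simulate_force_curve(
                            params, curve_id=f"{animal}-{group}-{i}"
                        )
    return CohortDataset(points=pd.DataFrame(records), design=design, curves=curves)


@dataclass
class GfapImageParams:
    """Parameters of one synthetic GFAP immunofluorescence image."""

    image_size: tuple[int, int] = (600, 750)  # rows, cols (px)
    pixel_size: float = 2.0  # μm/px
    region_intensity: Mapping[int, float] = field(default_factory=dict)  # label → level
    background_intensity: float = 8.0
    noise_sd: float = 6.0  # 8-bit levels
    plaque_density: float = 0.0  # per mm²
    plaque_radius: float = 15.0  # μm
    plaque_intensity: float = 60.0  # added level inside a plaque
    seed: int | None = None

    def __post_init__(self):
        for label, level in self.region_intensity.items():
            if not (0 <= level <= 255):
                raise ParameterError(f"intensity for label {label} outside [0, 255]")
        if not (0 <= self.background_intensity <= 255):
            raise ParameterError("background_intensity outside [0, 255]")
        if self.plaque_density < 0:
            raise ParameterError("plaque_density must be >= 0")
        if self.noise_sd < 0 or self.plaque_radius <= 0:
            raise ParameterError("noise_sd must be >= 0 and plaque_radius > 0")


def gfap_intensity_by_label(cohort: str) -> dict[int, float]:
    """Expand the per-group GFAP calibration to subregion labels 1-10."""
    if cohort not in GFAP_INTENSITY_8BIT:
        raise ConfigurationError(f"unknown cohort {cohort!r}")
    by_group = GFAP_INTENSITY_8BIT[cohort]
    out: dict[int, float] = {}
    for group, labels in GROUP_TO_LABELS.items():
        for label in labels:
            out[label] = by_group[group.value]
    return out


def simulate_gfap_image(
    params: GfapImageParams,
    mask: RegionMask,
    animal: str = "",
    cohort: str = "",
    slice_id: str = "",
    return_plaque_mask: bool = False,
):
    """Render an 8-bit GFAP-like image over a subregion mask.

    Per-region base intensity + Gaussian noise + Poisson-placed bright
    disks (plaque-associated gliosis); output clamped to [0, 255].
    """
    from skimage.draw import disk

    if mask.shape != tuple(params.image_size):
        raise ParameterError(
            f"mask shape {mask.shape} does not match image_size {params.image_size}"
        )
    rng = np.random.default_rng(params.seed)
    img = np.full(mask.shape, params.background_intensity, dtype=float)
    for label, level in params.region_intensity.items():
        img[mask.labels == label] = level
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, mask.shape)

    plaque_mask = np.zeros(mask.shape, dtype=bool)
    if params.plaque_density > 0:
        nr, nc = mask.shape
        area_mm2 = nr * nc * params.pixel_size**2 / 1e6
        n_plaques = rng.poisson(params.plaque_density * area_mm2)
        radius_px = max(params.plaque_radius / params.pixel_size, 1.0)
        for _ in range(n_plaques):
            r = float(rng.uniform(0, nr))
            c = float(rng.uniform(0, nc))
            rr, cc = disk((r, c), radius_px, shape=mask.shape)
            img[rr, cc] += params.plaque_intensity
            plaque_mask[rr, cc] = True

    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    image = FluorescenceImage(
        pixels=pixels,
        pixel_size=params.pixel_size,
        animal=animal,
        cohort=cohort,
        slice_id=slice_id,
    )
    if return_plaque_mask:
        return image, plaque_mask
    return image


def band_region_mask(shape: tuple[int, int], n_regions: int = 10) -> RegionMask:
    """Simple synthetic anatomy: ``n_regions`` vertical bands labelled 1..n.

    A stand-in for a hand-drawn subregion mask, giving every label a
    contiguous territory on the grid or image.
    """
    if not (1 <= n_regions <= 10):
        raise ParameterError("n_regions must lie in 1..10")
    nr, nc = shape
    cols = np.arange(nc)
    band = 1 + (cols * n_regions) // nc
    labels = np.tile(band, (nr, 1)).astype(int)
    return RegionMask(labels=labels)
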