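"""Force-distance curve processing and Hertz sphere-indentation fitting.

A raw AFM approach record — piezo height ``z`` versus cantilever
deflection ``d`` — is turned into an apparent elastic modulus in four
steps:

1. :func:`baseline_correct` removes the linear pre-contact trend
   (optical interference / drift) fitted on the early part of the curve.
2. :func:`detect_contact_point` locates the piezo height ``z_c`` at
   which the probe first touches the tissue, via a two-segment
   piecewise fit (flat baseline + Hertz-shaped contact segment).
3. :func:`to_indentation` converts post-contact samples to
   force-indentation pairs using F = k·d and δ = (z − z_c) − d.
4. :func:`fit_hertz` fits the sphere-on-half-space Hertz model

       F = (4/3) · E/(1 − ν²) · √R_c · δ^{3/2}

   by nonlinear least squares over (E, contact-point offset),
   restricted to indentations of at most 7 μm so that the contact
   radius α = √(R_c·δ) stays below the bead radius.

Units follow :mod:`hippomech.units`: μm, nN, Pa, N/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    DomainError,
    FitError,
    InsufficientBaselineError,
    NoContactError,
    ParameterError,
)
from .units import NN_PER_NPM_UM, NN_PER_PA_UM2

__all__ = [
    "ForceCurve",
    "IndentationCurve",
    "HertzFitResult",
    "hertz_force",
    "baseline_correct",
    "detect_contact_point",
    "to_indentation",
    "fit_hertz",
    "analyze_curve",
    "fit_curves",
]

#: default bead radius (μm) of the glass sphere glued to the cantilever
DEFAULT_BEAD_RADIUS_UM = 12.5
#: Poisson's ratio for incompressible, hydrated brain tissue
DEFAULT_POISSON_RATIO = 0.5
#: maximum indentation depth (μm) admitted into the Hertz fit
DEFAULT_MAX_FIT_DEPTH_UM = 7.0


@dataclass(frozen=True)
class ForceCurve:
    """One raw approach record at a single grid position.

    ``heights`` increase toward the sample: larger z means the piezo
    has extended further and (past contact) the bead indents deeper.
    """

    heights: np.ndarray
    deflections: np.ndarray
    spring_constant: float
    position: tuple[float, float] = (0.0, 0.0)
    id: str = ""

    def __post_init__(self):
        h = np.asarray(self.heights, dtype=float)
        d = np.asarray(self.deflections, dtype=float)
        object.__setattr__(self, "heights", h)
        object.__setattr__(self, "deflections", d)
        if h.ndim != 1 or d.ndim != 1 or h.shape != d.shape:
            raise ParameterError("heights and deflections must be equal-length 1-D arrays")
        if h.size < 20:
            raise ParameterError(f"need at least 20 samples, got {h.size}")
        dh = np.diff(h)
        if not (np.all(dh > 0) or np.all(dh < 0)):
            raise ParameterError("heights must be strictly monotonic")
        if self.spring_constant <= 0:
            raise ParameterError("spring_constant must be positive")

    @property
    def n_samples(self) -> int:
        return self.heights.size


@dataclass(frozen=True)
class IndentationCurve:
    """Post-contact force-indentation samples for one curve."""

    indentations: np.ndarray
    forces: np.ndarray
    contact_point: float
    spring_constant: float = 0.07

    def __post_init__(self):
        delta = np.asarray(self.indentations, dtype=float)
        f = np.asarray(self.forces, dtype=float)
        object.__setattr__(self, "indentations", delta)
        object.__setattr__(self, "forces", f)
        if delta.shape != f.shape:
            raise ParameterError("indentations and forces must have equal shapes")
        if np.any(delta < 0):
            raise ParameterError("indentations must be non-negative")
        if not np.all(np.isfinite(f)):
            raise ParameterError("forces must be finite")


@dataclass(frozen=True)
class HertzFitResult:
    """Elastic modulus estimate plus diagnostics for one indentation."""

    elastic_modulus: float
    contact_point: float
    contact_radius: float
    fit_max_indentation: float
    rms_residual: float
    n_points_fitted: int
    quality_flag: str = "ok"  # ok | low_depth | poor_fit | no_contact
    position: tuple[float, float] = (0.0, 0.0)
    id: str = ""


def hertz_force(
    elastic_modulus: float,
    poisson_ratio: float,
    bead_radius: float,
    delta,
):
    """Hertz force (nN) of a rigid sphere indenting an elastic half-space.

    F = (4/3) · E/(1 − ν²) · √R · δ^{3/2}, with E in Pa and R, δ in μm.

    Parameters
    ----------
    elastic_modulus : Pa, > 0
    poisson_ratio : dimensionless, in [0, 1)
    bead_radius : μm, > 0
    delta : μm, scalar or array, ≥ 0
    """
    if elastic_modulus <= 0:
        raise ParameterError("elastic_modulus must be positive")
    if bead_radius <= 0:
        raise ParameterError("bead_radius must be positive")
    if not (0 <= poisson_ratio < 1):
        raise ParameterError("poisson_ratio must lie in [0, 1)")
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise DomainError("indentation depth must be non-negative")
    prefactor = (4.0 / 3.0) * elastic_modulus / (1.0 - poisson_ratio**2)
    out = prefactor * np.sqrt(bead_radius) * delta**1.5 * NN_PER_PA_UM2
    return out if out.ndim else float(out)


def baseline_correct(curve: ForceCurve, fraction: float = 0.3) -> ForceCurve:
    """Subtract a linear baseline fitted on the first ``fraction`` of samples.

    The fitted window is assumed to precede contact; the line (deflection
    vs height) absorbs photodiode offset and optical-interference tilt.
    """
    if not (0 < fraction <= 0.9):
        raise ParameterError("fraction must lie in (0, 0.9]")
    n_base = int(round(curve.n_samples * fraction))
    if n_base < 5:
        raise InsufficientBaselineError(
            f"baseline window has {n_base} samples; need at least 5"
        )
    z = curve.heights[:n_base]
    d = curve.deflections[:n_base]
    slope, intercept = np.polyfit(z, d, 1)
    corrected = curve.deflections - (slope * curve.heights + intercept)
    return ForceCurve(
        heights=curve.heights.copy(),
        deflections=corrected,
        spring_constant=curve.spring_constant,
        position=curve.position,
        id=curve.id,
    )


def _piecewise_sse(z: np.ndarray, d: np.ndarray, i: int) -> float:
    """SSE of flat-zero (before index i) + Hertz-shaped (after) model."""
    z_c = z[i]
    sse_pre = float(np.dot(d[:i], d[:i]))
    delta = np.clip((z[i:] - z_c) - d[i:], 0.0, None)
    phi = delta**1.5
    denom = float(np.dot(phi, phi))
    a = max(float(np.dot(d[i:], phi)) / denom, 0.0) if denom > 0 else 0.0
    resid = d[i:] - a * phi
    return sse_pre + float(np.dot(resid, resid))


def detect_contact_point(curve: ForceCurve, baseline_fraction: float = 0.3) -> float:
    """Estimate the piezo height at which tip-sample contact begins.

    Scans candidate break points and minimises the total squared
    residual of a two-segment model: zero deflection before the break,
    a Hertz-shaped (δ^{3/2}) segment after it.  The curve must already
    be baseline corrected.  Raises :class:`NoContactError` when the
    post-contact deflection never exceeds 5× the baseline noise SD.
    """
    z = curve.heights
    d = curve.deflections
    if z[0] > z[-1]:  # normalise to increasing-height order
        z, d = z[::-1], d[::-1]
    n = z.size
    n_base = max(int(round(n * baseline_fraction)), 5)
    noise_sd = float(np.std(d[:n_base]))

    lo, hi = 5, n - 10
    if hi <= lo:
        raise NoContactError("curve too short to bracket a contact point")
    candidates = range(lo, hi)
    sse = [_piecewise_sse(z, d, i) for i in candidates]
    best = lo + int(np.argmin(sse))
    z_c = float(z[best])

    post_max = float(np.max(d[best:], initial=0.0))
    if post_max <= 5.0 * noise_sd + 1e-12:
        raise NoContactError(
            f"max post-contact deflection {post_max:.3g} μm does not exceed "
            f"5× baseline noise SD ({noise_sd:.3g} μm)"
        )
    return z_c


def to_indentation(curve: ForceCurve, contact_point: float) -> IndentationCurve:
    """Convert a baseline-corrected curve to force-indentation samples.

    For samples at or past contact, F = k·d and δ = (z − z_c) − d
    (the piezo travel past contact minus the cantilever's own bending).
    Pre-contact samples are dropped; δ is clipped at zero.
    """
    z = curve.heights
    d = curve.deflections
    if z[0] > z[-1]:
        z, d = z[::-1], d[::-1]
    if not (z[0] <= contact_point <= z[-1]):
        raise DomainError(
            f"contact point {contact_point} outside height range [{z[0]}, {z[-1]}]"
        )
    post = z >= contact_point
    zp, dp = z[post], d[post]
    delta = np.clip((zp - contact_point) - dp, 0.0, None)
    forces = curve.spring_constant * dp * NN_PER_NPM_UM
    return IndentationCurve(
        indentations=delta,
        forces=forces,
        contact_point=contact_point,
        spring_constant=curve.spring_constant,
    )


def fit_hertz(
    ind: IndentationCurve,
    bead_radius: float = DEFAULT_BEAD_RADIUS_UM,
    poisson_ratio: float = DEFAULT_POISSON_RATIO,
    max_depth: float = DEFAULT_MAX_FIT_DEPTH_UM,
) -> HertzFitResult:
    """Fit the Hertz model to an indentation curve.

    Nonlinear least squares over (E, contact-point offset dz_c) on
    samples whose adjusted indentation is at most ``max_depth`` μm.
    The contact offset is a free nuisance parameter that refines the
    initial contact-point estimate.

    Quality flags: ``low_depth`` when the fitted segment never exceeds
    0.5 μm indentation; ``poor_fit`` when the RMS residual exceeds 10%
    of the maximum fitted force or the optimiser fails to converge.
    """
    delta_all = ind.indentations
    f_all = ind.forces
    prefac = (4.0 / 3.0) / (1.0 - poisson_ratio**2) * np.sqrt(bead_radius) * NN_PER_PA_UM2

    def model(e_mod: float, dzc: float, delta: np.ndarray) -> np.ndarray:
        return prefac * e_mod * np.clip(delta - dzc, 0.0, None) ** 1.5

    def window(dzc: float) -> np.ndarray:
        adj = delta_all - dzc
        return (adj > 0) & (adj <= max_depth)

    mask = window(0.0)
    if int(mask.sum()) < 10:
        raise FitError(
            f"only {int(mask.sum())} post-contact samples within {max_depth} μm; need 10"
        )

    # initial E from the deepest in-window sample
    i_deep = np.flatnonzero(mask)[-1]
    e0 = max(f_all[i_deep] / (prefac * max(delta_all[i_deep], 1e-6) ** 1.5), 1.0)

    x = np.array([e0, 0.0])
    converged = True
    for _ in range(3):  # re-select the fit window as the contact offset moves
        delta_w, f_w = delta_all[mask], f_all[mask]

        def resid(p):
            return model(p[0], p[1], delta_w) - f_w

        sol = least_squares(
            resid,
            x,
            bounds=([1e-6, -2.0], [np.inf, 2.0]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        converged = bool(sol.success)
        x = sol.x
        new_mask = window(x[1])
        if int(new_mask.sum()) < 10 or np.array_equal(new_mask, mask):
            break
        mask = new_mask

    e_fit, dzc = float(x[0]), float(x[1])
    delta_w = np.clip(delta_all[mask] - dzc, 0.0, None)
    f_w = f_all[mask]
    resid_final = prefac * e_fit * delta_w**1.5 - f_w
    rms = float(np.sqrt(np.mean(resid_final**2)))
    delta_max = float(np.max(delta_w, initial=0.0))
    f_max = float(np.max(np.abs(f_w), initial=0.0))

    if not converged or (f_max > 0 and rms > 0.10 * f_max):
        flag = "poor_fit"
    elif delta_max < 0.5:
        flag = "low_depth"
    else:
        flag = "ok"

    return HertzFitResult(
        elastic_modulus=e_fit,
        contact_point=ind.contact_point + dzc,
        contact_radius=float(np.sqrt(bead_radius * delta_max)),
        fit_max_indentation=delta_max,
        rms_residual=rms,
        n_points_fitted=int(mask.sum()),
        quality_flag=flag,
    )


def analyze_curve(
    curve: ForceCurve,
    bead_radius: float = DEFAULT_BEAD_RADIUS_UM,
    poisson_ratio: float = DEFAULT_POISSON_RATIO,
    max_depth: float = DEFAULT_MAX_FIT_DEPTH_UM,
    baseline_fraction: float = 0.3,
) -> HertzFitResult:
    """Full single-curve chain: baseline → contact point → Hertz fit.

    Curves in which no contact is detectable come back flagged
    ``no_contact`` (modulus NaN) instead of raising, so that batch
    runs degrade gracefully into missing map cells.
    """
    corrected = baseline_correct(curve, baseline_fraction)
    try:
        z_c = detect_contact_point(corrected, baseline_fraction)
        ind = to_indentation(corrected, z_c)
        result = fit_hertz(ind, bead_radius, poisson_ratio, max_depth)
    except (NoContactError, FitError):
        return HertzFitResult(
            elastic_modulus=float("nan"),
            contact_point=float("nan"),
            contact_radius=0.0,
            fit_max_indentation=0.0,
            rms_residual=float("nan"),
            n_points_fitted=0,
            quality_flag="no_contact",
            position=curve.position,
            id=curve.id,
        )
    return HertzFitResult(
        elastic_modulus=result.elastic_modulus,
        contact_point=result.contact_point,
        contact_radius=result.contact_radius,
        fit_max_indentation=result.fit_max_indentation,
        rms_residual=result.rms_residual,
        n_points_fitted=result.n_points_fitted,
        quality_flag=result.quality_flag,
        position=curve.position,
        id=curve.id,
    )


def fit_curves(curves: Iterable[ForceCurve], **kwargs) -> pd.DataFrame:
    """Batch-fit curves; one row per curve, ready for map assembly.

    Columns: id, x_um, y_um, E_Pa, quality_flag, rms_residual.
    """
    rows = []
    for curve in curves:
        res = analyze_curve(curve, **kwargs)
        rows.append(
            {
                "id": res.id,
                "x_um": res.position[0],
                "y_um": res.position[1],
                "E_Pa": res.elastic_modulus,
                "quality_flag": res.quality_flag,
                "rms_residual": res.rms_residual,
            }
        )
    return pd.DataFrame(rows)
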