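"""Percent-change summaries, paired stiffness/GFAP heatmaps, pipeline driver.

The headline readout of the analysis is a pair of 7 × 2 matrices: the
percent change of each analysis group's stiffness (EMM scale) and of
its GFAP fluorescence (cohort mean of ROI intensities) for the two
cohort comparisons — healthy aging (18-month vs 3-month wild type) and
amyloid pathology (17-month APP knock-in vs 18-month wild type).
Cells whose mixed-model Tukey contrast clears the significance
threshold carry a directional flag.

:func:`run_pipeline` chains every stage on synthetic inputs:
simulate → fit curves → assemble/label a map → outlier cleansing +
mixed model + contrasts → GFAP quantification → heatmaps, writing
CSV/PNG/TXT artifacts and a run log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import elastmap, forcecurve, gfapquant, groupstats, synthgen
from .errors import ConfigurationError, DomainError, StageError

__all__ = [
    "GROUP_ORDER",
    "DEFAULT_COMPARISONS",
    "percent_change",
    "ChangeHeatmap",
    "build_heatmaps",
    "render_heatmaps",
    "default_config",
    "run_pipeline",
]

#: anatomical display order of the seven analysis groups
GROUP_ORDER = (
    "CA1_SO_SR",
    "CA1_PYR",
    "SLM",
    "ML",
    "DG_GCL",
    "HILUS_CA3_SO_SR",
    "CA3_PYR",
)

#: (new cohort, reference cohort) pairs: aging, then amyloid pathology
DEFAULT_COMPARISONS = (
    (synthgen.COHORT_WT_18M, synthgen.COHORT_WT_3M),
    (synthgen.COHORT_APP_17M, synthgen.COHORT_WT_18M),
)


def percent_change(m_ref: float, m_new: float) -> float:
    """100 × (m_new − m_ref) / m_ref.

    Example: 180 → 311 Pa gives +72.8% (a 73% stiffening); 491 → 251 Pa
    gives −48.9% (a 49% softening).
    """
    if m_ref <= 0:
        raise DomainError("reference value must be positive")
    return 100.0 * (m_new - m_ref) / m_ref


@dataclass
class ChangeHeatmap:
    """Paired Δ% matrices over analysis groups × cohort comparisons."""

    comparisons: list[str]
    stiffness_pct: pd.DataFrame
    stiffness_sig: pd.DataFrame
    gfap_pct: pd.DataFrame | None = None
    gfap_sig: pd.DataFrame | None = None


def _pct_matrix(
    means: pd.DataFrame,
    value_col: str,
    comparisons,
    labels: list[str],
) -> pd.DataFrame:
    lookup = {
        (r.analysis_group, r.cohort): getattr(r, value_col)
        for r in means.itertuples(index=False)
    }
    data = {}
    for (new, ref), label in zip(comparisons, labels):
        col = []
        for g in GROUP_ORDER:
            for cohort in (new, ref):
                if (g, cohort) not in lookup:
                    raise ConfigurationError(
                        f"missing mean for group {g!r}, cohort {cohort!r}"
                    )
            col.append(percent_change(lookup[(g, ref)], lookup[(g, new)]))
        data[label] = col
    return pd.DataFrame(data, index=list(GROUP_ORDER))


def _sig_matrix(
    contrasts: pd.DataFrame | None,
    comparisons,
    labels: list[str],
    threshold: float,
) -> pd.DataFrame:
    flags = pd.DataFrame(False, index=list(GROUP_ORDER), columns=labels)
    if contrasts is None:
        return flags
    for row in contrasts.itertuples(index=False):
        if row.group_1 != row.group_2:
            continue
        pair = {row.cohort_1, row.cohort_2}
        for (new, ref), label in zip(comparisons, labels):
            if pair == {new, ref} and row.group_1 in flags.index:
                flags.loc[row.group_1, label] = bool(row.p_adjusted < threshold)
    return flags


def build_heatmaps(
    stiffness_emm: pd.DataFrame,
    gfap_means: pd.DataFrame | None = None,
    stiffness_contrasts: pd.DataFrame | None = None,
    gfap_contrasts: pd.DataFrame | None = None,
    comparisons=DEFAULT_COMPARISONS,
    sig_threshold: float = 0.001,
) -> ChangeHeatmap:
    """Fill the paired Δ% matrices and attach significance flags.

    ``stiffness_emm`` needs columns analysis_group, cohort, emm;
    ``gfap_means`` (optional) analysis_group, cohort, mean.  Missing
    group × cohort cells raise a completeness error.
    """
    labels = [f"{new} vs {ref}" for new, ref in comparisons]
    stiff = _pct_matrix(stiffness_emm, "emm", comparisons, labels)
    stiff_sig = _sig_matrix(stiffness_contrasts, comparisons, labels, sig_threshold)
    gfap = gfap_sig = None
    if gfap_means is not None:
        gfap = _pct_matrix(gfap_means, "mean", comparisons, labels)
        gfap_sig = _sig_matrix(gfap_contrasts, comparisons, labels, sig_threshold)
    return ChangeHeatmap(
        comparisons=labels,
        stiffness_pct=stiff,
        stiffness_sig=stiff_sig,
        gfap_pct=gfap,
        gfap_sig=gfap_sig,
    )


def render_heatmaps(hm: ChangeHeatmap, path: str | None = None):
    """Two-panel diverging heatmap with arrows on significant cells."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    panels = [("Δ% elastic modulus", hm.stiffness_pct, hm.stiffness_sig)]
    if hm.gfap_pct is not None:
        panels.append(("Δ% GFAP intensity", hm.gfap_pct, hm.gfap_sig))
    fig, axes = plt.subplots(1, len(panels), figsize=(5.2 * len(panels), 4.2))
    axes = np.atleast_1d(axes)
    for ax, (title, mat, sig) in zip(axes, panels):
        vmax = max(float(np.nanmax(np.abs(mat.to_numpy()))), 1.0)
        im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        for i, g in enumerate(mat.index):
            for j, c in enumerate(mat.columns):
                val = mat.iloc[i, j]
                arrow = ""
                if sig is not None and bool(sig.iloc[i, j]):
                    arrow = " ↑" if val > 0 else " ↓"
                ax.text(
                    j, i, f"{val:+.0f}%{arrow}", ha="center", va="center", fontsize=8
                )
        ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=20, fontsize=7)
        ax.set_yticks(range(len(mat.index)), mat.index, fontsize=7)
        ax.set_title(title)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def default_config() -> dict:
    """Demo pipeline configuration (desk-scale problem sizes)."""
    return {
        "seed": 0,
        "outdir": "pipeline_out",
        "points_per_region": 40,
        "curves_per_group": 1,
        "within_sd_fraction": 0.35,
        "animal_sd": None,
        "simulate_gfap": True,
        "gfap_animals": 3,
        "gfap_slices": 3,
        "gfap_image_rows": 600,
        "gfap_image_cols": 750,
        "gfap_pixel_size": 2.0,
        "plaque_density_app": 20.0,
        "color_range_max": 800.0,
        "sig_threshold": 0.001,
    }


def _stage_simulate(cfg: dict, log: list[str]) -> synthgen.CohortDataset:
    design = synthgen.CohortDesign(
        points_per_region=int(cfg["points_per_region"]),
        within_sd_fraction=float(cfg["within_sd_fraction"]),
        animal_sd=cfg["animal_sd"],
        seed=int(cfg["seed"]),
    )
    data = synthgen.simulate_cohort(
        design, curves_per_group=int(cfg["curves_per_group"])
    )
    log.append(
        f"simulate: {len(data.points)} stiffness points, "
        f"{len(data.curves)} raw curves, seed={cfg['seed']}"
    )
    return data


def _stage_fit_curves(data: synthgen.CohortDataset, log: list[str]) -> pd.DataFrame:
    rows = []
    for idx, curve in data.curves.items():
        res = forcecurve.analyze_curve(curve)
        truth = data.points.loc[idx, "modulus_Pa"]
        rows.append(
            {
                "id": curve.id,
                "E_generated_Pa": truth,
                "E_fitted_Pa": res.elastic_modulus,
                "rel_error": abs(res.elastic_modulus - truth) / truth,
                "quality_flag": res.quality_flag,
            }
        )
    fits = pd.DataFrame(rows)
    if len(fits):
        ok = fits[fits.quality_flag == "ok"]
        log.append(
            f"fit-curves: {len(fits)} curves, median |rel err| "
            f"{ok.rel_error.median():.3%} on {len(ok)} ok fits"
        )
    return fits


def _stage_map(
    data: synthgen.CohortDataset, cfg: dict, outdir: Path, log: list[str]
) -> pd.DataFrame:
    """One demonstration elasticity map from the first animal's points."""
    ny, nx = elastmap.grid_shape()
    mask = synthgen.band_region_mask((ny, nx))
    animal = data.points["animal"].iloc[0]
    sub = data.points[data.points["animal"] == animal]
    rng = np.random.default_rng(int(cfg["seed"]) + 1)
    rows = []
    for j in range(ny):
        for i in range(nx):
            label = int(mask.labels[j, i])
            group = elastmap.LABEL_TO_GROUP[label].value
            pool = sub[sub["analysis_group"] == group]["modulus_Pa"].to_numpy()
            rows.append(
                {
                    "id": f"{animal}-{i}-{j}",
                    "x_um": i * elastmap.DEFAULT_STEP_UM,
                    "y_um": j * elastmap.DEFAULT_STEP_UM,
                    "E_Pa": float(rng.choice(pool)),
                    "quality_flag": "ok",
                    "rms_residual": 0.0,
                }
            )
    fits = pd.DataFrame(rows)
    emap = elastmap.assemble_map(fits)
    elastmap.render_map(
        emap, color_range=(0.0, float(cfg["color_range_max"])), path=outdir / "map.png"
    )
    points = elastmap.group_regions(elastmap.assign_regions(emap, mask))
    points.to_csv(outdir / "map_points.csv", index=False)
    log.append(
        f"map: {animal}, {np.isfinite(emap.grid).sum()} of {emap.grid.size} cells "
        f"populated, {len(points)} labelled points"
    )
    return points


def _stage_stats(
    data: synthgen.CohortDataset, cfg: dict, outdir: Path, log: list[str]
):
    cleaned, removal = groupstats.remove_outliers(data.points)
    model = groupstats.fit_mixed_model(cleaned)
    contrasts = groupstats.tukey_contrasts(
        model, mvt_seed=int(cfg["seed"]), alpha_star=float(cfg["sig_threshold"])
    )
    qq = groupstats.qq_diagnostics(model)
    removal.to_csv(outdir / "outlier_report.csv", index=False)
    model.emm.to_csv(outdir / "emm.csv", index=False)
    contrasts.to_csv(outdir / "contrasts.csv", index=False)
    qq.to_csv(outdir / "qq.csv", index=False)
    log.append(
        f"stats: removed {len(data.points) - len(cleaned)} of {len(data.points)} "
        f"points ({(len(data.points) - len(cleaned)) / len(data.points):.2%}); "
        f"animal SD {np.sqrt(model.random_intercept_var):.1f} Pa"
        + (" [singular]" if model.singular else "")
    )
    return cleaned, removal, model, contrasts


def _stage_gfap(cfg: dict, outdir: Path, log: list[str]):
    shape = (int(cfg["gfap_image_rows"]), int(cfg["gfap_image_cols"]))
    mask = synthgen.band_region_mask(shape)
    seed = int(cfg["seed"])
    measurements: list[gfapquant.RoiMeasurement] = []
    for ci, (cohort, _) in enumerate(synthgen.DEFAULT_COHORTS):
        density = (
            float(cfg["plaque_density_app"])
            if cohort == synthgen.COHORT_APP_17M
            else 0.0
        )
        for a in range(int(cfg["gfap_animals"])):
            animal = f"{cohort}-if{a + 1}"
            for s in range(int(cfg["gfap_slices"])):
                params = synthgen.GfapImageParams(
                    image_size=shape,
                    pixel_size=float(cfg["gfap_pixel_size"]),
                    region_intensity=synthgen.gfap_intensity_by_label(cohort),
                    plaque_density=density,
                    seed=seed + 1000 * ci + 100 * a + s,
                )
                image = synthgen.simulate_gfap_image(
                    params, mask, animal=animal, cohort=cohort, slice_id=f"s{s + 1}"
                )
                measurements.extend(
                    gfapquant.sample_rois(
                        image, mask, seed=seed + 7919 * ci + 97 * a + s
                    )
                )
    per_animal, cohort_summary = gfapquant.aggregate_gfap(measurements)
    per_animal.to_csv(outdir / "gfap_per_animal.csv", index=False)
    cohort_summary.to_csv(outdir / "gfap_cohort.csv", index=False)

    roi_table = pd.DataFrame(
        {
            "animal": [m.animal for m in measurements],
            "cohort": [m.cohort for m in measurements],
            "analysis_group": [
                elastmap.LABEL_TO_GROUP[m.region].value for m in measurements
            ],
            "intensity": [m.mean_intensity for m in measurements],
        }
    )
    roi_table.to_csv(outdir / "gfap_measurements.csv", index=False)
    gfap_model = groupstats.fit_mixed_model(roi_table, value_col="intensity")
    gfap_contrasts = groupstats.tukey_contrasts(gfap_model, mvt_seed=seed)
    gfap_contrasts.to_csv(outdir / "gfap_contrasts.csv", index=False)
    log.append(
        f"gfap: {len(measurements)} ROI measurements across "
        f"{roi_table['animal'].nunique()} animals"
    )
    return cohort_summary, gfap_contrasts


def run_pipeline(config: dict | str | Path | None = None, **overrides) -> dict:
    """Execute the full synthetic pipeline and write the report bundle.

    ``config`` may be a dict or a YAML path; keyword overrides win.
    Returns a dict with the key dataframes and the output directory.
    Stage failures raise :class:`StageError` tagged with the stage
    name; artifacts written before the failure are retained.
    """
    from .io import load_config, save_config

    cfg = default_config()
    if config is not None:
        cfg.update(config if isinstance(config, dict) else load_config(config))
    cfg.update(overrides)

    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    cfg["outdir"] = str(outdir)
    save_config(cfg, outdir / "run_config.yaml")
    log: list[str] = []

    def run_stage(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:  # noqa: BLE001 - re-tagged with stage name
            (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
            raise StageError(name, str(exc)) from exc

    data = run_stage("simulate", _stage_simulate, cfg, log)
    data.points.to_csv(outdir / "points.csv", index=False)
    curve_fits = run_stage("fit-curves", _stage_fit_curves, data, log)
    curve_fits.to_csv(outdir / "curve_fits.csv", index=False)
    map_points = run_stage("build-map", _stage_map, data, cfg, outdir, log)
    cleaned, removal, model, contrasts = run_stage(
        "stats", _stage_stats, data, cfg, outdir, log
    )

    gfap_summary = gfap_contrasts = None
    if cfg["simulate_gfap"]:
        gfap_summary, gfap_contrasts = run_stage("gfap", _stage_gfap, cfg, outdir, log)
    else:
        log.append("gfap: disabled in config; GFAP panel omitted")

    def heatmap_stage():
        hm = build_heatmaps(
            model.emm,
            gfap_means=gfap_summary,
            stiffness_contrasts=contrasts,
            gfap_contrasts=gfap_contrasts,
            sig_threshold=float(cfg["sig_threshold"]),
        )
        hm.stiffness_pct.to_csv(outdir / "heatmap_stiffness_pct.csv")
        if hm.gfap_pct is not None:
            hm.gfap_pct.to_csv(outdir / "heatmap_gfap_pct.csv")
        render_heatmaps(hm, path=outdir / "heatmaps.png")
        return hm

    hm = run_stage("report", heatmap_stage)

    summary_lines = ["Percent change in stiffness (EMM scale):"]
    for label in hm.comparisons:
        for g in GROUP_ORDER:
            mark = " *" if bool(hm.stiffness_sig.loc[g, label]) else ""
            summary_lines.append(
                f"  {label:24s} {g:16s} {hm.stiffness_pct.loc[g, label]:+.0f}%{mark}"
            )
    if hm.gfap_pct is not None:
        summary_lines.append("Percent change in GFAP intensity (cohort means):")
        for label in hm.comparisons:
            for g in GROUP_ORDER:
                mark = " *" if bool(hm.gfap_sig.loc[g, label]) else ""
                summary_lines.append(
                    f"  {label:24s} {g:16s} {hm.gfap_pct.loc[g, label]:+.0f}%{mark}"
                )
    (outdir / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    log.append("report: heatmaps and summary written")
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")

    return {
        "config": cfg,
        "outdir": outdir,
        "points": data.points,
        "curve_fits": curve_fits,
        "map_points": map_points,
        "cleaned": cleaned,
        "outlier_report": removal,
        "model": model,
        "contrasts": contrasts,
        "gfap_summary": gfap_summary,
        "gfap_contrasts": gfap_contrasts,
        "heatmap": hm,
        "log": log,
    }
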