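"""Group statistics: outlier cleansing, mixed model, Tukey contrasts.

The modelling chain mirrors the standard analysis of grouped
indentation data:

1. :func:`remove_outliers` — one cleansing pass per
   (cohort, analysis group) stratum dropping points beyond ±2 sample
   standard deviations of the stratum mean.
2. :func:`fit_mixed_model` — linear mixed model of modulus on
   analysis group × cohort (full factorial fixed effects) with a
   random intercept per animal, fitted by REML.  The fixed part uses
   cell-means coding, so each fixed-effect coefficient *is* the
   estimated marginal mean (EMM) of one group × cohort cell and the
   fixed-effect covariance directly provides EMM and contrast SEs.
3. :func:`tukey_contrasts` — pairwise EMM differences with family-wise
   adjustment via the multivariate-t distribution of the joint
   t-statistics (the exact generalisation of Tukey's method to an
   arbitrary comparison family).
4. :func:`qq_diagnostics` — normal Q-Q data for residual checking.

Degrees of freedom use a containment-style split: contrasts that
compare cohorts (between-animal information) get
``n_animals − n_cohorts`` df; contrasts within a cohort (within-animal
information) get the residual within-animal df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, FitError, ParameterError

__all__ = [
    "MixedModelResult",
    "remove_outliers",
    "fit_mixed_model",
    "tukey_contrasts",
    "cross_cohort_family",
    "qq_diagnostics",
]

Cell = tuple[str, str]  # (analysis_group, cohort)


def remove_outliers(
    table: pd.DataFrame,
    value_col: str = "modulus_Pa",
    by: tuple[str, str] = ("cohort", "analysis_group"),
    n_sd: float = 2.0,
    min_stratum: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass ±2 SD outlier removal per stratum.

    For each stratum the mean and sample (n−1) SD are computed once and
    points strictly outside mean ± ``n_sd``·SD are dropped.  Strata
    smaller than ``min_stratum`` are left untouched with a warning.

    Returns ``(cleaned, report)``; the report has one row per stratum
    with counts, the removed fraction and the bounds used, so that any
    mismatch between the nominal rule and the achieved removal rate is
    visible rather than silent.
    """
    for col in (*by, value_col):
        if col not in table.columns:
            raise ParameterError(f"missing column {col!r}")
    keep = np.ones(len(table), dtype=bool)
    rows = []
    grouped = table.groupby(list(by), sort=True, observed=True)
    for key, idx in grouped.groups.items():
        vals = table.loc[idx, value_col].to_numpy(dtype=float)
        if vals.size < min_stratum:
            warnings.warn(
                f"stratum {key}: only {vals.size} points, outlier rule skipped",
                stacklevel=2,
            )
            rows.append(
                dict(zip(by, key))
                | {
                    "n_in": vals.size,
                    "n_removed": 0,
                    "fraction_removed": 0.0,
                    "mean": float(vals.mean()) if vals.size else np.nan,
                    "sd": np.nan,
                    "lower": np.nan,
                    "upper": np.nan,
                    "skipped": True,
                }
            )
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        lower, upper = mean - n_sd * sd, mean + n_sd * sd
        out = (vals < lower) | (vals > upper)
        positions = table.index.get_indexer(idx)
        keep[positions[out]] = False
        rows.append(
            dict(zip(by, key))
            | {
                "n_in": int(vals.size),
                "n_removed": int(out.sum()),
                "fraction_removed": float(out.mean()),
                "mean": mean,
                "sd": sd,
                "lower": lower,
                "upper": upper,
                "skipped": False,
            }
        )
    cleaned = table.loc[keep].copy()
    report = pd.DataFrame(rows)
    return cleaned, report


@dataclass
class MixedModelResult:
    """Fitted mixed model with EMMs on the group × cohort grid."""

    cells: list[Cell]
    emm: pd.DataFrame  # analysis_group, cohort, emm, se, ci_low, ci_high
    beta: np.ndarray
    cov_beta: np.ndarray
    random_intercept_var: float
    residual_var: float
    residuals: np.ndarray
    n_obs: int
    n_animals: int
    n_cohorts: int
    df_between: float
    df_within: float
    singular: bool = False

    def cell_index(self, cell: Cell) -> int:
        try:
            return self.cells.index(cell)
        except ValueError:
            raise ConfigurationError(f"cell {cell} not on the EMM grid") from None


def fit_mixed_model(
    table: pd.DataFrame, value_col: str = "modulus_Pa"
) -> MixedModelResult:
    """REML linear mixed model: modulus ~ group × cohort + (1 | animal).

    The fixed design is one indicator per observed (analysis group,
    cohort) cell, hence β̂ are the EMMs computed with equal weight for
    every cell of the factorial grid.  A fit that drives the animal
    variance to the boundary is kept and flagged ``singular``.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    required = {"animal", "cohort", "analysis_group", value_col}
    missing = required - set(table.columns)
    if missing:
        raise ParameterError(f"missing columns {sorted(missing)}")
    a2c = table.groupby("animal", observed=True)["cohort"].nunique()
    if (a2c > 1).any():
        raise ParameterError("each animal must belong to exactly one cohort")
    per_cohort = table.groupby("cohort", observed=True)["animal"].nunique()
    if (per_cohort < 2).any():
        raise ParameterError("need at least 2 animals per cohort")

    df = table.sort_values(["cohort", "analysis_group", "animal"], kind="stable")
    y = df[value_col].to_numpy(dtype=float)
    cell_of_row = list(zip(df["analysis_group"], df["cohort"]))
    cells = sorted(set(cell_of_row))
    col = {c: j for j, c in enumerate(cells)}
    x = np.zeros((len(df), len(cells)))
    for i, c in enumerate(cell_of_row):
        x[i, col[c]] = 1.0

    # sanity bounds: with cell-means coding every coefficient is a
    # weighted mean of its own stratum, so it must lie inside that
    # stratum's data range
    lo = np.array([y[x[:, j] == 1].min() for j in range(x.shape[1])])
    hi = np.array([y[x[:, j] == 1].max() for j in range(x.shape[1])])

    def acceptable(candidate) -> bool:
        b = np.asarray(candidate.fe_params, dtype=float)
        if not (np.isfinite(candidate.llf) and np.all(np.isfinite(b))):
            return False
        span = np.maximum(hi - lo, 1e-12)
        return bool(np.all(b >= lo - 0.01 * span) and np.all(b <= hi + 0.01 * span))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, x, groups=df["animal"].to_numpy())
        fit = best = None
        last_err: Exception | None = None
        # the default lbfgs path can fail (singular GLS system) or return
        # corrupt fixed effects when the animal variance hits the boundary;
        # fall through to derivative-free optimisers and keep the first
        # sane fit (best remaining REML likelihood otherwise)
        for method in (None, "powell", "nm"):
            try:
                kwargs = {} if method is None else {"method": method}
                candidate = model.fit(reml=True, **kwargs)
            except np.linalg.LinAlgError as err:
                last_err = err
                continue
            if acceptable(candidate):
                fit = candidate
                break
            if best is None or (
                np.isfinite(candidate.llf) and candidate.llf > best.llf
            ):
                best = candidate
        if fit is None:
            fit = best
        if fit is None:
            raise FitError(f"mixed model did not fit: {last_err}")

    beta = np.asarray(fit.fe_params, dtype=float)
    cov_beta = np.asarray(fit.cov_params())[: len(cells), : len(cells)]
    resid_var = float(fit.scale)
    re_var = float(np.asarray(fit.cov_re).ravel()[0])
    singular = re_var < 1e-8 * max(float(np.var(y)), 1e-30)

    n_animals = int(df["animal"].nunique())
    n_cohorts = int(df["cohort"].nunique())
    p = len(cells)
    df_between = max(n_animals - n_cohorts, 1)
    df_within = max(len(df) - n_animals - (p - n_cohorts), 1)

    t_crit = stats.t.ppf(0.975, df_between)
    se = np.sqrt(np.diag(cov_beta))
    emm = pd.DataFrame(
        {
            "analysis_group": [g for g, _ in cells],
            "cohort": [c for _, c in cells],
            "emm": beta,
            "se": se,
            "ci_low": beta - t_crit * se,
            "ci_high": beta + t_crit * se,
        }
    )
    residuals = y - x @ beta

    return MixedModelResult(
        cells=cells,
        emm=emm,
        beta=beta,
        cov_beta=cov_beta,
        random_intercept_var=re_var,
        residual_var=resid_var,
        residuals=residuals,
        n_obs=len(df),
        n_animals=n_animals,
        n_cohorts=n_cohorts,
        df_between=float(df_between),
        df_within=float(df_within),
        singular=singular,
    )


#: canonical cohort ordering (young → aged → pathology); unknown labels sort last
_COHORT_RANK = {"3mo-WT": 0, "18mo-WT": 1, "17mo-APP": 2}


def cross_cohort_family(
    model: MixedModelResult, cohort_order: list[str] | None = None
) -> list[tuple[Cell, Cell]]:
    """All cross-cohort pairs within each analysis group on the grid.

    Each pair is oriented (later cohort, earlier cohort) so the
    estimate reads as the change relative to the younger/reference
    cohort.
    """

    def rank(c: str):
        if cohort_order is not None:
            return (cohort_order.index(c) if c in cohort_order else len(cohort_order), c)
        return (_COHORT_RANK.get(c, len(_COHORT_RANK)), c)

    pairs: list[tuple[Cell, Cell]] = []
    groups = sorted({g for g, _ in model.cells})
    for g in groups:
        cohorts = sorted((c for gg, c in model.cells if gg == g), key=rank)
        for i in range(len(cohorts)):
            for j in range(i + 1, len(cohorts)):
                pairs.append(((g, cohorts[j]), (g, cohorts[i])))
    return pairs


def tukey_contrasts(
    model: MixedModelResult,
    comparisons: list[tuple[Cell, Cell]] | None = None,
    alpha_star: float = 0.001,
    mvt_seed: int = 0,
) -> pd.DataFrame:
    """Pairwise EMM contrasts with multivariate-t family-wise adjustment.

    Each comparison ``((g1, c1), (g2, c2))`` is estimated as
    EMM(g1, c1) − EMM(g2, c2) with its SE from the fixed-effect
    covariance.  The adjusted p-value of contrast i is
    P(max_j |T_j| ≥ |t_i|) where T follows a multivariate t with the
    correlation of the contrast estimates — Tukey's method over an
    arbitrary family.  The rectangle probabilities are evaluated by
    seeded quasi-Monte-Carlo, so output is reproducible.
    """
    if comparisons is None:
        comparisons = cross_cohort_family(model)
    m = len(comparisons)
    if m == 0:
        raise ParameterError("empty comparison family")

    lmat = np.zeros((m, len(model.cells)))
    dfs = np.empty(m)
    for i, (cell_a, cell_b) in enumerate(comparisons):
        ja, jb = model.cell_index(cell_a), model.cell_index(cell_b)
        lmat[i, ja] = 1.0
        lmat[i, jb] = -1.0
        cross_cohort = cell_a[1] != cell_b[1]
        dfs[i] = model.df_between if cross_cohort else model.df_within

    est = lmat @ model.beta
    cov = lmat @ model.cov_beta @ lmat.T
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, est / se, np.where(est == 0, 0.0, np.inf))
    p_unadj = 2.0 * stats.t.sf(np.abs(tstat), dfs)

    d = np.where(se > 0, se, 1.0)
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)

    p_adj = np.empty(m)
    for i in range(m):
        t_abs = abs(float(tstat[i]))
        if not np.isfinite(t_abs):
            p_adj[i] = 0.0
            continue
        if m == 1:
            p_adj[i] = p_unadj[i]
            continue
        mvt = stats.multivariate_t(shape=corr, df=max(dfs[i], 1.0), allow_singular=True)
        inside = float(
            mvt.cdf(
                np.full(m, t_abs),
                lower_limit=np.full(m, -t_abs),
                random_state=np.random.default_rng(mvt_seed),
            )
        )
        p_adj[i] = min(max(1.0 - inside, p_unadj[i]), 1.0)

    return pd.DataFrame(
        {
            "group_1": [a[0] for a, _ in comparisons],
            "cohort_1": [a[1] for a, _ in comparisons],
            "group_2": [b[0] for _, b in comparisons],
            "cohort_2": [b[1] for _, b in comparisons],
            "estimate": est,
            "se": se,
            "df": dfs,
            "t": tstat,
            "p_unadjusted": p_unadj,
            "p_adjusted": p_adj,
            "stars": ["***" if p < alpha_star else "" for p in p_adj],
        }
    )


def qq_diagnostics(model: MixedModelResult) -> pd.DataFrame:
    """Normal Q-Q data of the (marginal) residuals.

    Returns ordered residuals against normal quantiles computed with
    the Blom plotting position; ``attrs['qq_correlation']`` carries the
    Q-Q correlation (NaN when the residuals are constant).
    """
    r = np.sort(np.asarray(model.residuals, dtype=float))
    n = r.size
    probs = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    theo = stats.norm.ppf(probs)
    out = pd.DataFrame({"theoretical_quantile": theo, "residual_quantile": r})
    sd = r.std()
    out.attrs["qq_correlation"] = (
        float(np.corrcoef(theo, r)[0, 1]) if sd > 0 else float("nan")
    )
    return out
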