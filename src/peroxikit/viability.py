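"""Plate-viability analysis for the two-stage drug-challenge assay.

Fits a Gaussian linear model of well fluorescence with the full
genotype x primary-dose x secondary-treatment interaction expansion plus
categorical row, column and timepoint main effects::

    fluorescence ~ genotype * dose * secondary + row + column + timepoint

Dose enters as a continuous covariate (single slope; a log1p option exists
because doses follow a 1:2 serial dilution).  The three-way interaction
coefficient measures genotype-dependent adaptation: how the primary dose
changes the response to the secondary challenge differently between
genotypes.  Its significance comes from a likelihood-ratio test against a
reduced model that drops only the three-way term (all two-way terms
retained).  The fitted row/column effects are used to correct raw
fluorescence for spatial plate artifacts before dose-response summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .hurdle import DesignError, LRTResult, _check_full_rank, _ordered_levels

__all__ = [
    "ViabilityFit",
    "build_viability_design",
    "fit_viability",
    "lrt_interaction",
    "correct_spatial",
    "dose_response_summary",
]

REQUIRED_PLATE_COLUMNS = (
    "row",
    "column",
    "genotype",
    "primary_dose",
    "secondary_treatment",
    "timepoint",
    "fluorescence",
)


def _dose_values(table: pd.DataFrame, transform: str) -> np.ndarray:
    dose = table["primary_dose"].to_numpy(dtype=float)
    if np.any(dose < 0):
        raise ValueError("doses must be non-negative")
    if transform == "linear":
        return dose
    if transform == "log1p":
        return np.log1p(dose)
    raise ValueError(f"unknown dose transform {transform!r}")


def build_viability_design(
    table: pd.DataFrame,
    include_three_way: bool = True,
    dose_transform: str = "linear",
    plate_term: bool = False,
):
    """Hand-coded treatment-coded design matrix; returns (X, column names)."""
    missing = [c for c in REQUIRED_PLATE_COLUMNS if c not in table.columns]
    if missing:
        raise DesignError(f"plate table lacks required columns: {missing}")
    genotypes = _ordered_levels(table["genotype"])
    secondaries = _ordered_levels(
        table["secondary_treatment"],
        "DMSO" if "DMSO" in set(table["secondary_treatment"]) else None,
    )
    rows = sorted(pd.unique(table["row"]))
    columns_lv = sorted(pd.unique(table["column"]))
    timepoints = _ordered_levels(table["timepoint"])

    n = len(table)
    dose = _dose_values(table, dose_transform)
    g = table["genotype"].to_numpy()
    s = table["secondary_treatment"].to_numpy()

    cols = [np.ones(n)]
    names = ["Intercept"]
    for lev in genotypes[1:]:
        cols.append((g == lev).astype(float))
        names.append(f"genotype[{lev}]")
    cols.append(dose)
    names.append("dose")
    for lev in secondaries[1:]:
        cols.append((s == lev).astype(float))
        names.append(f"secondary[{lev}]")
    for lev in genotypes[1:]:
        cols.append((g == lev) * dose)
        names.append(f"genotype[{lev}]:dose")
    for gl in genotypes[1:]:
        for sl in secondaries[1:]:
            cols.append(((g == gl) & (s == sl)).astype(float))
            names.append(f"genotype[{gl}]:secondary[{sl}]")
    for sl in secondaries[1:]:
        cols.append((s == sl) * dose)
        names.append(f"dose:secondary[{sl}]")
    if include_three_way:
        for gl in genotypes[1:]:
            for sl in secondaries[1:]:
                cols.append(((g == gl) & (s == sl)) * dose)
                names.append(f"genotype[{gl}]:dose:secondary[{sl}]")
    r = table["row"].to_numpy()
    for lev in rows[1:]:
        cols.append((r == lev).astype(float))
        names.append(f"row[{lev}]")
    c = table["column"].to_numpy()
    for lev in columns_lv[1:]:
        cols.append((c == lev).astype(float))
        names.append(f"column[{lev}]")
    t = table["timepoint"].to_numpy()
    for lev in timepoints[1:]:
        cols.append((t == lev).astype(float))
        names.append(f"timepoint[{lev}]")
    if plate_term and "plate_id" in table.columns:
        plates = sorted(pd.unique(table["plate_id"]))
        p = table["plate_id"].to_numpy()
        for lev in plates[1:]:
            cols.append((p == lev).astype(float))
            names.append(f"plate[{lev}]")
    X = np.column_stack(cols)
    _check_full_rank(X, names)
    return X, names


@dataclass
class ViabilityFit:
    """Ordinary-least-squares fit with Gaussian log-likelihood for LRT use."""

    coefficients: pd.Series
    loglik: float
    n_params: int  # coefficients + 1 for the residual variance
    residual_sd: float
    fitted: np.ndarray
    residuals: np.ndarray
    columns: tuple[str, ...]
    row_levels: tuple
    col_levels: tuple
    options: dict

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    def effect_vector(self, kind: str) -> pd.Series:
        """Fitted row or column effects, centered to mean zero."""
        levels = self.row_levels if kind == "row" else self.col_levels
        prefix = "row[" if kind == "row" else "column["
        if not any(name.startswith(prefix) for name in self.columns):
            raise ValueError(f"fit has no {kind} effects")
        eff = pd.Series(0.0, index=list(levels))
        for lev in levels[1:]:
            eff.loc[lev] = self.coefficients.get(f"{prefix}{lev}]", 0.0)
        return eff - eff.mean()


def fit_viability(
    table: pd.DataFrame,
    include_three_way: bool = True,
    dose_transform: str = "linear",
    plate_term: bool = False,
) -> ViabilityFit:
    """Least-squares fit of the viability model.

    The log-likelihood is the Gaussian profile likelihood (variance at its
    MLE), the quantity needed by the likelihood-ratio test.
    """
    X, names = build_viability_design(table, include_three_way, dose_transform, plate_term)
    y = table["fluorescence"].to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted
    n, p = X.shape
    rss = float(resid @ resid)
    sigma2 = rss / n
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return ViabilityFit(
        coefficients=pd.Series(coef, index=names),
        loglik=float(loglik),
        n_params=p + 1,
        residual_sd=float(np.sqrt(rss / max(n - p, 1))),
        fitted=fitted,
        residuals=resid,
        columns=tuple(names),
        row_levels=tuple(sorted(pd.unique(table["row"]))),
        col_levels=tuple(sorted(pd.unique(table["column"]))),
        options={
            "include_three_way": include_three_way,
            "dose_transform": dose_transform,
            "plate_term": plate_term,
        },
    )


def lrt_interaction(
    table: pd.DataFrame, dose_transform: str = "linear", plate_term: bool = False
) -> LRTResult:
    """Likelihood-ratio test for the three-way genotype:dose:secondary term.

    The reduced model drops only the three-way columns; every two-way
    interaction is retained.  The statistic is ``2 * (ll_full - ll_reduced)``
    under the Gaussian profile likelihood; because that statistic is a
    monotone function of the F statistic for the same nested comparison,
    the p-value uses the exact F reference (numerator df = dropped columns,
    denominator df = residual df of the full model).  The chi-square
    approximation is anti-conservative here — it ignores that the error
    variance is estimated — by about one percentage point at a two-plate
    design's size.
    """
    if table["genotype"].nunique() < 2:
        raise ValueError("interaction test needs at least two genotypes")
    if table["secondary_treatment"].nunique() < 2:
        raise ValueError("interaction test needs both secondary treatments")
    full = fit_viability(table, True, dose_transform, plate_term)
    reduced = fit_viability(table, False, dose_transform, plate_term)
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = full.n_params - reduced.n_params
    n = len(table)
    rss_full = float(full.residuals @ full.residuals)
    rss_red = float(reduced.residuals @ reduced.residuals)
    df_resid = n - (full.n_params - 1)
    if df <= 0 or rss_full <= 0:
        return LRTResult(statistic=stat, df=max(df, 0), p_value=1.0)
    f_stat = ((rss_red - rss_full) / df) / (rss_full / df_resid)
    return LRTResult(statistic=stat, df=df, p_value=float(sps.f.sf(f_stat, df, df_resid)))


def correct_spatial(table: pd.DataFrame, fit: ViabilityFit) -> pd.DataFrame:
    """Subtract fitted (mean-centered) row and column effects from each well.

    All other variation is untouched; correcting an already corrected table
    is a no-op up to numerical tolerance.
    """
    row_eff = fit.effect_vector("row")
    col_eff = fit.effect_vector("column")
    out = table.copy()
    out["fluorescence"] = (
        table["fluorescence"].to_numpy(dtype=float)
        - row_eff.reindex(table["row"]).to_numpy()
        - col_eff.reindex(table["column"]).to_numpy()
    )
    return out


def dose_response_summary(corrected: pd.DataFrame, timepoint=None):
    """Replicate means, dose-zero normalization and linear trendlines.

    Per (genotype, secondary treatment): the replicate mean at each dose,
    the mean minus the dose-zero mean (so every normalized curve is zero at
    dose 0), and a least-squares line of normalized mean versus dose.
    Returns ``(curves, trends)`` data frames.
    """
    tab = corrected if timepoint is None else corrected[corrected["timepoint"] == timepoint]
    if len(tab) == 0:
        raise ValueError("no rows after timepoint filtering")
    curves = []
    trends = []
    for (g, s), grp in tab.groupby(["genotype", "secondary_treatment"], sort=True):
        means = grp.groupby("primary_dose")["fluorescence"].mean().sort_index()
        if 0.0 not in means.index:
            raise ValueError(f"missing dose-0 wells for genotype={g}, secondary={s}")
        normalized = means - means.loc[0.0]
        slope, intercept = np.polyfit(means.index.to_numpy(), normalized.to_numpy(), 1)
        for dose in means.index:
            curves.append((g, s, float(dose), float(means.loc[dose]), float(normalized.loc[dose])))
        trends.append((g, s, float(slope), float(intercept)))
    curves_df = pd.DataFrame(
        curves, columns=["genotype", "secondary_treatment", "dose", "mean", "normalized_mean"]
    )
    trends_df = pd.DataFrame(
        trends, columns=["genotype", "secondary_treatment", "slope", "intercept"]
    )
    return curves_df, trends_df
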