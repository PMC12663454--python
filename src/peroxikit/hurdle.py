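"""Hurdle-model regression for per-cell organelle counts.

A hurdle model describes per-cell peroxisome counts with two separate
components:

* a *zero component*: a logistic regression for whether a cell has any
  peroxisomes at all, parameterized as ``P(count > 0) = logistic(x @ gamma)``
  so that a larger coefficient always means *more* peroxisomes;
* a *positive component*: a zero-truncated negative-binomial regression with
  log link for the counts of cells that cleared the hurdle,
  ``mu = exp(x @ beta)`` with a single shared dispersion ``theta``
  (variance of the untruncated NB is ``mu + mu**2 / theta``).

Both components share the same design: treatment-coded ``strain``,
``treatment`` and ``batch`` main effects, plus an optional
``strain:treatment`` interaction.  The interaction term is the quantity of
scientific interest: it measures whether a mutant strain's response to a
treatment (e.g. tunicamycin) differs from the wild-type response, pooling the
wild-type data across all experimental batches.  Significance comes from a
likelihood-ratio test against the reduced (no-interaction) model, and
direction calls are based on the positive-component interaction coefficient
only, because excess zeros can be dominated by dead cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from scipy.special import digamma, expit, gammaln

__all__ = [
    "DesignError",
    "FitError",
    "DesignMatrices",
    "HurdleFit",
    "LRTResult",
    "StrainComparison",
    "build_design",
    "trunc_nb_logpmf",
    "fit_hurdle",
    "compare_models",
    "lrt",
    "compare_strain_to_wt",
    "compare_all_strains",
    "comparisons_frame",
    "heatmap_matrix",
]

REQUIRED_COUNT_COLUMNS = ("cell_id", "strain", "treatment", "batch", "count")


class DesignError(ValueError):
    """Invalid or rank-deficient design specification."""


class FitError(RuntimeError):
    """Maximum-likelihood fit failed to converge."""


# --------------------------------------------------------------------------
# Design construction
# --------------------------------------------------------------------------


def _ordered_levels(values, reference=None):
    levels = list(pd.unique(np.asarray(values)))
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise DesignError(f"reference level {reference!r} absent from data")
    levels.remove(reference)
    return [reference] + levels


@dataclass(frozen=True)
class DesignMatrices:
    """Shared design for both hurdle components (identical formula)."""

    X: np.ndarray
    columns: tuple[str, ...]
    references: dict[str, str]
    include_interaction: bool

    @property
    def X_zero(self) -> np.ndarray:
        return self.X

    @property
    def X_pos(self) -> np.ndarray:
        return self.X

    @property
    def n_columns(self) -> int:
        return len(self.columns)


def _check_full_rank(X: np.ndarray, columns) -> None:
    # QR with pivoting identifies which columns are aliased
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        aliased = [columns[i] for i in piv[rank:]]
        raise DesignError(f"design is rank deficient; aliased columns: {aliased}")


def build_design(
    table: pd.DataFrame,
    include_interaction: bool = True,
    strain_ref: str | None = None,
    treatment_ref: str | None = None,
    batch_ref: str | None = None,
) -> DesignMatrices:
    """Build the treatment-coded design matrix for a count table.

    References default to ``"WT"`` / ``"DMSO"`` when present (first observed
    level otherwise) and the first observed batch.  Interaction columns for
    strain/treatment combinations never observed are dropped, then the design
    is checked for full column rank.
    """
    missing = [c for c in ("strain", "treatment", "batch") if c not in table.columns]
    if missing:
        raise DesignError(f"count table lacks required columns: {missing}")
    if strain_ref is None:
        strain_ref = "WT" if "WT" in set(table["strain"]) else None
    if treatment_ref is None:
        treatment_ref = "DMSO" if "DMSO" in set(table["treatment"]) else None

    strains = _ordered_levels(table["strain"], strain_ref)
    treatments = _ordered_levels(table["treatment"], treatment_ref)
    batches = _ordered_levels(table["batch"], batch_ref)

    n = len(table)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]
    s = table["strain"].to_numpy()
    t = table["treatment"].to_numpy()
    b = table["batch"].to_numpy()
    for lev in strains[1:]:
        cols.append((s == lev).astype(float))
        names.append(f"strain[{lev}]")
    for lev in treatments[1:]:
        cols.append((t == lev).astype(float))
        names.append(f"treatment[{lev}]")
    for lev in batches[1:]:
        cols.append((b == lev).astype(float))
        names.append(f"batch[{lev}]")
    if include_interaction:
        for sl in strains[1:]:
            for tl in treatments[1:]:
                col = ((s == sl) & (t == tl)).astype(float)
                if col.any():  # drop never-observed combinations
                    cols.append(col)
                    names.append(f"strain[{sl}]:treatment[{tl}]")
    X = np.column_stack(cols)
    _check_full_rank(X, names)
    return DesignMatrices(
        X=X,
        columns=tuple(names),
        references={
            "strain": strains[0],
            "treatment": treatments[0],
            "batch": batches[0],
        },
        include_interaction=include_interaction,
    )


# --------------------------------------------------------------------------
# Zero-truncated negative binomial
# --------------------------------------------------------------------------


def _log1mexp(log_p: np.ndarray) -> np.ndarray:
    """log(1 - exp(log_p)) for log_p < 0, numerically stable near both ends."""
    log_p = np.asarray(log_p, dtype=float)
    out = np.where(
        log_p > -np.log(2.0),
        np.log(-np.expm1(log_p)),
        np.log1p(-np.exp(log_p)),
    )
    return out


def trunc_nb_logpmf(k, mu, theta):
    """Log-pmf of the zero-truncated negative binomial.

    ``NB(k; mu, theta) / (1 - NB(0; mu, theta))`` with
    ``NB(0; mu, theta) = (theta / (theta + mu))**theta``.  Stable for large
    ``theta`` (Poisson limit) and large ``k``.  ``k`` must be >= 1.
    """
    k = np.asarray(k, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = float(theta)
    if np.any(k < 1):
        raise ValueError("truncated pmf undefined for k = 0 (zero component's job)")
    if theta <= 0 or np.any(mu <= 0):
        raise ValueError("mu and theta must be positive")
    log_ratio = np.log1p(mu / theta)  # log((theta + mu) / theta)
    log_unnorm = (
        gammaln(k + theta)
        - gammaln(theta)
        - gammaln(k + 1)
        - theta * log_ratio
        + k * (np.log(mu) - np.log(theta + mu))
    )
    log_p0 = -theta * log_ratio
    return log_unnorm - _log1mexp(log_p0)


def _truncnb_nll_grad(params, X, k):
    """Negative loglik and gradient for the positive component.

    ``params = (beta, log_theta)``; gradient is analytic (chain rule through
    the log link and the truncation normalizer).
    """
    p = X.shape[1]
    beta = params[:p]
    theta = np.exp(np.clip(params[p], -20.0, 20.0))
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = np.exp(eta)

    log_ratio = np.log1p(mu / theta)
    log_p0 = -theta * log_ratio
    p0 = np.exp(log_p0)
    one_m_p0 = -np.expm1(log_p0)

    ll = (
        gammaln(k + theta)
        - gammaln(theta)
        - gammaln(k + 1)
        - theta * log_ratio
        + k * (np.log(mu) - np.log(theta + mu))
        - np.log(one_m_p0)
    )
    nll = -ll.sum()

    # d ll / d eta  (eta = log mu)
    dmu = k / mu - (k + theta) / (theta + mu) - theta * p0 / ((theta + mu) * one_m_p0)
    g_beta = -(X.T @ (dmu * mu))
    # d ll / d theta
    A = -log_ratio + mu / (theta + mu)  # d log p0 / d theta
    dtheta = (
        digamma(k + theta)
        - digamma(theta)
        + A
        - k / (theta + mu)
        + p0 * A / one_m_p0
    )
    g_ltheta = -dtheta.sum() * theta
    return nll, np.append(g_beta, g_ltheta)


def _fit_truncnb(X, k, tol=1e-8):
    """Maximum-likelihood fit of the zero-truncated NB regression."""
    p = X.shape[1]
    # init: least squares on log counts, moment estimate of theta
    beta0, *_ = np.linalg.lstsq(X, np.log(k + 0.5), rcond=None)
    m, v = k.mean(), k.var()
    theta0 = m**2 / (v - m) if v > m * 1.05 else 10.0
    theta0 = float(np.clip(theta0, 0.05, 1e4))
    x0 = np.append(beta0, np.log(theta0))
    res = optimize.minimize(
        _truncnb_nll_grad,
        x0,
        args=(X, k),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-6, "maxiter": 500},
    )
    if not res.success and np.linalg.norm(res.jac) > 1e-3 * (1 + abs(res.fun)):
        # one retry from a flatter start before declaring failure
        res2 = optimize.minimize(
            _truncnb_nll_grad,
            np.append(np.zeros(p), 0.0),
            args=(X, k),
            jac=True,
            method="BFGS",
            options={"gtol": 1e-6, "maxiter": 1000},
        )
        if res2.fun < res.fun:
            res = res2
    return res


def _hessian_from_grad(fun_grad, x, args, step=1e-5):
    """Central-difference Hessian using the analytic gradient."""
    d = len(x)
    H = np.empty((d, d))
    for i in range(d):
        h = step * max(1.0, abs(x[i]))
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        _, gp = fun_grad(xp, *args)
        _, gm = fun_grad(xm, *args)
        H[i] = (gp - gm) / (2 * h)
    return (H + H.T) / 2


# --------------------------------------------------------------------------
# Logistic (zero-component) IRLS
# --------------------------------------------------------------------------


def _logistic_irls(X, z, max_iter=100, tol=1e-10):
    n, p = X.shape
    coef = np.zeros(p)
    pbar = np.clip(z.mean(), 1e-6, 1 - 1e-6)
    coef[0] = np.log(pbar / (1 - pbar))  # column 0 is the intercept

    def loglik(c):
        eta = X @ c
        return -np.logaddexp(0.0, -np.where(z > 0, eta, -eta)).sum()

    ll = loglik(coef)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ coef, -30, 30)
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        g = X.T @ (z - mu)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p), g)
        except np.linalg.LinAlgError:
            break
        new = coef + step
        ll_new = loglik(new)
        halvings = 0
        while ll_new < ll - 1e-12 and halvings < 30:
            step /= 2
            new = coef + step
            ll_new = loglik(new)
            halvings += 1
        coef, ll_prev, ll = new, ll, ll_new
        if abs(ll - ll_prev) < tol * (abs(ll) + 1):
            converged = True
            break

    eta = np.clip(X @ coef, -30, 30)
    mu = expit(eta)
    separated = bool(
        z.all()
        or (~z.astype(bool)).all()
        or (ll > -1e-6)
        or np.all((mu > 1 - 1e-6) == z.astype(bool))
    )
    w = np.clip(mu * (1 - mu), 1e-10, None)
    try:
        cov = np.linalg.inv(X.T @ (X * w[:, None]))
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return coef, ll, se, converged, separated


# --------------------------------------------------------------------------
# Hurdle fit
# --------------------------------------------------------------------------


@dataclass
class HurdleFit:
    """Fitted hurdle model.

    ``gamma`` are the zero-component coefficients (logit of P(count > 0)),
    ``beta`` the positive-component coefficients (log of the untruncated NB
    mean), ``theta`` the shared NB dispersion.  The total log-likelihood is
    exactly the binomial log-likelihood of the zero indicators plus the
    truncated-NB log-likelihood of the positive counts.
    """

    gamma: pd.Series
    beta: pd.Series
    theta: float
    loglik: float
    loglik_zero: float
    loglik_pos: float
    n_params: int
    converged: bool
    separation: bool
    se_gamma: pd.Series
    se_beta: pd.Series
    se_log_theta: float
    columns: tuple[str, ...]

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    def to_dict(self) -> dict:
        return {
            "gamma": self.gamma.to_dict(),
            "beta": self.beta.to_dict(),
            "se_gamma": self.se_gamma.to_dict(),
            "se_beta": self.se_beta.to_dict(),
            "theta": self.theta,
            "se_log_theta": self.se_log_theta,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "aic": self.aic,
            "converged": self.converged,
            "separation": self.separation,
        }


def fit_hurdle(y, design: DesignMatrices, compute_se: bool = True) -> HurdleFit:
    """Fit the hurdle model by maximum likelihood.

    The likelihood separates: the zero component is a logistic regression of
    ``count > 0`` fit by IRLS; the positive component is a truncated-NB
    regression fit by BFGS on ``(beta, log theta)``.  Complete separation in
    the zero component is flagged (not fatal).  Standard errors come from the
    observed information of each component.
    """
    y = np.asarray(y)
    if y.ndim != 1 or len(y) != design.X.shape[0]:
        raise ValueError("response length does not match design")
    if np.any(y < 0) or not np.issubdtype(np.asarray(y).dtype, np.number):
        raise ValueError("counts must be non-negative")
    z = (y > 0).astype(float)
    pos = y[y > 0].astype(float)
    if pos.size == 0:
        raise FitError("no positive counts: positive component cannot be fit")

    gamma, ll_zero, se_gamma, conv_zero, separated = _logistic_irls(design.X_zero, z)
    if separated:
        warnings.warn(
            "complete separation detected in the zero component; "
            "its coefficients are unreliable",
            stacklevel=2,
        )

    Xp = design.X_pos[y > 0]
    res = _fit_truncnb(Xp, pos)
    p = Xp.shape[1]
    beta = res.x[:p]
    log_theta = res.x[p]
    ll_pos = -res.fun
    conv_pos = bool(res.success or np.linalg.norm(res.jac) < 1e-3 * (1 + abs(res.fun)))
    if not conv_pos:
        warnings.warn("positive-component optimizer did not fully converge", stacklevel=2)

    if compute_se:
        H = _hessian_from_grad(_truncnb_nll_grad, res.x, (Xp, pos))
        try:
            cov = np.linalg.inv(H)
            se_pos = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se_pos = np.full(p + 1, np.nan)
    else:
        se_pos = np.full(p + 1, np.nan)

    cols = list(design.columns)
    return HurdleFit(
        gamma=pd.Series(gamma, index=cols),
        beta=pd.Series(beta, index=cols),
        theta=float(np.exp(log_theta)),
        loglik=float(ll_zero + ll_pos),
        loglik_zero=float(ll_zero),
        loglik_pos=float(ll_pos),
        n_params=2 * len(cols) + 1,
        converged=bool(conv_zero and conv_pos),
        separation=separated,
        se_gamma=pd.Series(se_gamma, index=cols),
        se_beta=pd.Series(se_pos[:p], index=cols),
        se_log_theta=float(se_pos[p]),
        columns=design.columns,
    )


# --------------------------------------------------------------------------
# Model family comparison (AIC)
# --------------------------------------------------------------------------


def compare_models(y, design: DesignMatrices) -> pd.DataFrame:
    """Fit hurdle, zero-inflated NB and plain NB; report k, loglik and AIC.

    The hurdle fit is this module's own; the zero-inflated and plain NB
    baselines are standard count regressions fit with statsmodels.  Rows for
    families that fail to converge are still returned, flagged.
    """
    import statsmodels.api as sm

    y = np.asarray(y)
    X = design.X
    rows = []

    hf = fit_hurdle(y, design)
    rows.append(("hurdle", hf.n_params, hf.loglik, hf.aic, hf.converged))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            nb = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
            k_nb = X.shape[1] + 1
            rows.append(
                ("negbin", k_nb, nb.llf, 2 * k_nb - 2 * nb.llf, bool(nb.mle_retvals["converged"]))
            )
            nb_params = nb.params
        except Exception:
            rows.append(("negbin", X.shape[1] + 1, np.nan, np.nan, False))
            nb_params = np.append(np.zeros(X.shape[1]), 1.0)

        try:
            start = np.concatenate([-hf.gamma.to_numpy(), nb_params[:-1], [1.0 / hf.theta]])
            zinb = sm.ZeroInflatedNegativeBinomialP(y, X, exog_infl=X, p=2).fit(
                start_params=start, method="bfgs", maxiter=500, disp=0
            )
            k_z = 2 * X.shape[1] + 1
            rows.append(
                ("zinb", k_z, zinb.llf, 2 * k_z - 2 * zinb.llf, bool(zinb.mle_retvals["converged"]))
            )
        except Exception:
            rows.append(("zinb", 2 * X.shape[1] + 1, np.nan, np.nan, False))

    out = pd.DataFrame(rows, columns=["family", "k", "loglik", "aic", "converged"])
    out = out.set_index("family")
    out.attrs["best"] = out["aic"].idxmin()
    return out


# --------------------------------------------------------------------------
# Likelihood-ratio test
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float


def lrt(full: HurdleFit, reduced: HurdleFit) -> LRTResult:
    """Likelihood-ratio test of a reduced (nested) hurdle fit against the full.

    The statistic ``2 * (ll_full - ll_reduced)`` is clamped at zero to absorb
    optimizer tolerance; df is the parameter-count difference (the interaction
    enters both components, so 2 per strain:treatment pair).
    """
    if not set(reduced.columns) <= set(full.columns) or reduced.n_params > full.n_params:
        raise ValueError("reduced model is not nested in the full model")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = full.n_params - reduced.n_params
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return LRTResult(statistic=stat, df=df, p_value=p)


# --------------------------------------------------------------------------
# Strain-vs-WT comparisons
# --------------------------------------------------------------------------


@dataclass
class StrainComparison:
    strain: str
    interaction_zero: float
    interaction_pos: float
    p_raw: float
    p_adj: float = np.nan
    direction: str = ""
    lrt_result: LRTResult | None = field(default=None, repr=False)
    full_fit: HurdleFit | None = field(default=None, repr=False)


def compare_strain_to_wt(
    mutant: pd.DataFrame,
    wt_pool: pd.DataFrame,
    wt_label: str = "WT",
    treatment_ref: str = "DMSO",
) -> StrainComparison:
    """Compare one mutant strain's treatment response against pooled WT data.

    The mutant's rows (both treatments) are concatenated with the full WT
    pool across batches; full (with strain:treatment interaction) and reduced
    hurdle models are fit and compared by LRT.  The direction call
    ("stronger"/"weaker" response than WT) uses the sign of the
    positive-component interaction coefficient only.
    """
    strains = [s for s in pd.unique(mutant["strain"]) if s != wt_label]
    if len(strains) != 1:
        raise ValueError(f"mutant table must contain exactly one non-{wt_label} strain, got {strains}")
    mutant_label = strains[0]
    if wt_label not in set(wt_pool["strain"]):
        raise ValueError(f"WT pool contains no {wt_label!r} rows")
    for name, tab in (("mutant", mutant), ("WT pool", wt_pool)):
        levels = set(tab.loc[tab["strain"].isin([mutant_label, wt_label]), "treatment"])
        if len(levels) < 2:
            raise ValueError(f"{name} table lacks a treatment level (has {sorted(levels)})")

    data = pd.concat(
        [wt_pool[wt_pool["strain"] == wt_label], mutant], ignore_index=True
    )
    treatments = _ordered_levels(data["treatment"], treatment_ref if treatment_ref in set(data["treatment"]) else None)
    if len(treatments) != 2:
        raise ValueError("strain comparison expects exactly two treatment levels")
    alt = treatments[1]

    full_d = build_design(data, include_interaction=True, strain_ref=wt_label)
    red_d = build_design(data, include_interaction=False, strain_ref=wt_label)
    y = data["count"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = fit_hurdle(y, full_d)
        red = fit_hurdle(y, red_d, compute_se=False)
    res = lrt(full, red)
    term = f"strain[{mutant_label}]:treatment[{alt}]"
    ipos = float(full.beta[term])
    return StrainComparison(
        strain=mutant_label,
        interaction_zero=float(full.gamma[term]),
        interaction_pos=ipos,
        p_raw=res.p_value,
        direction="stronger" if ipos > 0 else "weaker",
        lrt_result=res,
        full_fit=full,
    )


def compare_all_strains(
    table: pd.DataFrame, wt_label: str = "WT", treatment_ref: str = "DMSO"
) -> list[StrainComparison]:
    """Run every mutant-vs-WT comparison and BH-adjust the p-values jointly."""
    from .stats import adjust_bh

    wt_pool = table[table["strain"] == wt_label]
    mutants = [s for s in pd.unique(table["strain"]) if s != wt_label]
    if not mutants:
        raise ValueError("no mutant strains in table")
    comps = [
        compare_strain_to_wt(
            table[table["strain"] == m], wt_pool, wt_label=wt_label, treatment_ref=treatment_ref
        )
        for m in mutants
    ]
    adj = adjust_bh([c.p_raw for c in comps])
    for c, a in zip(comps, adj):
        c.p_adj = float(a)
    return comps


def comparisons_frame(comparisons: list[StrainComparison]) -> pd.DataFrame:
    """Tidy one-row-per-strain summary of the comparisons."""
    return pd.DataFrame(
        {
            "strain": [c.strain for c in comparisons],
            "interaction_zero": [c.interaction_zero for c in comparisons],
            "interaction_pos": [c.interaction_pos for c in comparisons],
            "p_raw": [c.p_raw for c in comparisons],
            "p_adj": [c.p_adj for c in comparisons],
            "direction": [c.direction for c in comparisons],
        }
    )


def heatmap_matrix(comparisons: list[StrainComparison]) -> pd.DataFrame:
    """Z-scored interaction-coefficient matrix for heatmap display.

    One row per strain, columns ``zero_count`` and ``positive_count``,
    z-scored within each column (sample s.d.).  Both components are oriented
    so that a positive value predicts a stronger treatment response (higher
    counts): the zero component already models P(count > 0), so no sign flip
    is needed before z-scoring.
    """
    if len(comparisons) < 2:
        raise ValueError("z-scoring needs at least two strains")
    raw = pd.DataFrame(
        {
            "zero_count": [c.interaction_zero for c in comparisons],
            "positive_count": [c.interaction_pos for c in comparisons],
        },
        index=[c.strain for c in comparisons],
    )
    return (raw - raw.mean()) / raw.std(ddof=1)
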