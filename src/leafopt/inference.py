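"""Statistical layer: climate regressions of ln Vcmax25, model bias,
partial residuals and leaf-soil regressions.

Two parallel analyses mirror the two ways of slicing a multi-species
leaf-trait dataset:

* **site-mean** — one data point per site (community mean); ordinary
  least squares of ln Vcmax25 on ln PPFD, Tg and ln D.
* **all-species** — one data point per species-at-site; a linear mixed
  model with the same fixed effects and *crossed* random intercepts for
  site and species (crossed, not nested, because a species can occur at
  several sites).  Estimated by REML through a variance-components
  formulation; the share of each random term in the model's unexplained
  variance (site + species + residual) is reported.

Model bias of a prediction is B = 100 (pred - obs) / obs (%), and bias
regressions ask whether B trends with climate or with leaf nutrients.
Partial residual plots show the response adjusted to hold all other
predictors at their median values; the slope of the partial residuals
against a predictor equals that predictor's fitted coefficient exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .theory import BERNACCHI, EnvConditions, KineticParams, vcmax_opt

__all__ = [
    "CLIMATE_PREDICTORS",
    "SOIL_PREDICTORS",
    "RegressionSpec",
    "FitResult",
    "CollinearityError",
    "fit_site_mean",
    "fit_all_species",
    "theoretical_prediction",
    "bias",
    "bias_regression",
    "partial_residuals",
    "leaf_soil_regressions",
    "cooks_distance",
    "refit_without_influential",
]

#: (column, log-transform?) pairs for the standard climate model.
CLIMATE_PREDICTORS = (("ppfd", True), ("tg_c", False), ("d_kpa", True))
#: Soil predictors for the leaf-nutrient regressions.
SOIL_PREDICTORS = (("c_to_n", False), ("total_p", True), ("ph", False))


class CollinearityError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


@dataclass(frozen=True)
class RegressionSpec:
    """A response plus ordered predictors with log-transform flags."""

    response: str
    log_response: bool
    predictors: tuple  # of (name, log?) pairs
    random_intercepts: tuple = ()  # e.g. ("site_id", "species")

    def __post_init__(self):
        if not self.predictors:
            raise ValueError("predictors must be non-empty")


@dataclass
class FitResult:
    """Coefficients, uncertainty and variance decomposition of one fit."""

    model: str                      # 'ols' or 'mixed'
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    n: int
    r2: float | None = None         # OLS R^2
    r2_marginal: float | None = None
    r2_conditional: float | None = None
    varfrac: dict = field(default_factory=dict)  # site/species/residual shares
    fallback_ols: bool = False
    design: pd.DataFrame | None = None  # transformed predictors (+ response)
    result: object = None           # underlying statsmodels results

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.bse,
                             "p": self.pvalues})


def _transform(df: pd.DataFrame, spec: RegressionSpec) -> pd.DataFrame:
    """Build the transformed analysis frame: ln-prefixed columns where asked."""
    out = pd.DataFrame(index=df.index)
    y = df[spec.response].astype(float)
    if spec.log_response:
        if (y <= 0).any():
            raise ValueError(f"log response {spec.response} requires positive values")
        out["_y"] = np.log(y)
    else:
        out["_y"] = y
    for name, use_log in spec.predictors:
        x = df[name].astype(float)
        if use_log:
            if (x <= 0).any():
                raise ValueError(f"log predictor {name} requires positive values")
            out[f"ln_{name}"] = np.log(x)
        else:
            out[name] = x
    for g in spec.random_intercepts:
        out[g] = df[g].values
    return out.dropna()


def _check_rank(X: pd.DataFrame) -> None:
    arr = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        rdiag = np.abs(np.diag(np.linalg.qr(arr)[1]))
        bad = [c for c, d in zip(X.columns, rdiag) if d < 1e-8 * rdiag.max()]
        raise CollinearityError(f"rank-deficient design; offending columns: {bad}")


def _xnames(spec: RegressionSpec) -> list:
    return [f"ln_{n}" if lg else n for n, lg in spec.predictors]


def fit_site_mean(site_means: pd.DataFrame,
                  spec: RegressionSpec | None = None) -> FitResult:
    """OLS regression on site-mean data (default: ln Vcmax25 on climate)."""
    spec = spec or RegressionSpec("vcmax25", True, CLIMATE_PREDICTORS)
    data = _transform(site_means, spec)
    names = _xnames(spec)
    if len(data) <= len(names) + 1:
        raise ValueError(f"need n > {len(names) + 1} rows, got {len(data)}")
    X = sm.add_constant(data[names], has_constant='add')
    _check_rank(X)
    res = sm.OLS(data["_y"], X).fit()
    return FitResult(model="ols", params=res.params, bse=res.bse,
                     pvalues=res.pvalues, n=int(res.nobs),
                     r2=float(res.rsquared), design=data, result=res)


def fit_all_species(records: pd.DataFrame,
                    spec: RegressionSpec | None = None,
                    reml: bool = True) -> FitResult:
    """Crossed mixed model on species-at-site records.

    ``records`` needs the response and predictor columns plus the random
    grouping columns (default site_id and species).  Falls back to OLS
    with ``fallback_ols=True`` if the random-effects fit is singular or
    fails to converge.  Fixed-effect p-values use the large-sample
    normal approximation.
    """
    spec = spec or RegressionSpec("vcmax25", True, CLIMATE_PREDICTORS,
                                  random_intercepts=("site_id", "species"))
    if not spec.random_intercepts:
        raise ValueError("fit_all_species needs random_intercepts in the spec")
    data = _transform(records, spec)
    for g in spec.random_intercepts:
        if data[g].nunique() < 2:
            raise ValueError(f"need >= 2 levels of {g}")
    names = _xnames(spec)
    X = sm.add_constant(data[names], has_constant='add')
    _check_rank(X)

    data = data.copy()
    data["_one"] = 1
    vc = {g: f"0 + C({g})" for g in spec.random_intercepts}
    formula = "_y ~ " + " + ".join(names)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM.from_formula(formula, groups="_one", vc_formula=vc,
                                         re_formula="0", data=data)
            res = md.fit(reml=reml, method="lbfgs", maxiter=200)
        if not res.converged or not np.all(np.isfinite(res.bse_fe.iloc[:len(names) + 1])):
            raise RuntimeError("mixed fit did not converge")
    except (RuntimeError, np.linalg.LinAlgError, ValueError) as exc:
        warnings.warn(f"mixed model failed ({exc}); falling back to OLS")
        ols = sm.OLS(data["_y"], X).fit()
        return FitResult(model="mixed", params=ols.params, bse=ols.bse,
                         pvalues=ols.pvalues, n=int(ols.nobs),
                         r2=float(ols.rsquared), fallback_ols=True,
                         design=data, result=ols)

    k = len(names) + 1
    params = res.params.iloc[:k]
    bse = res.bse.iloc[:k]
    pvalues = res.pvalues.iloc[:k]

    vcomp = dict(zip(md.exog_vc.names, res.vcomp))
    resid_var = float(res.scale)
    total_re = sum(vcomp.values()) + resid_var
    varfrac = {g: float(vcomp[g] / total_re) for g in vcomp}
    varfrac["residual"] = resid_var / total_re

    fitted_fixed = np.asarray(X) @ np.asarray(params)
    var_f = float(np.var(fitted_fixed))
    total = var_f + total_re
    return FitResult(model="mixed", params=params, bse=bse, pvalues=pvalues,
                     n=len(data),
                     r2_marginal=var_f / total,
                     r2_conditional=(var_f + sum(vcomp.values())) / total,
                     varfrac=varfrac, design=data, result=res)


def theoretical_prediction(env_table: pd.DataFrame,
                           params: KineticParams = BERNACCHI) -> pd.Series:
    """Optimality-predicted Vcmax25 for each row of a climate table.

    Expects columns ``tg_c, d_kpa, ppfd`` and optionally ``elevation_m``
    and ``ca_ppm``.
    """
    out = np.empty(len(env_table))
    for i, row in enumerate(env_table.itertuples(index=False)):
        env = EnvConditions.from_climate(
            tg_c=row.tg_c, d_kpa=row.d_kpa, ppfd=row.ppfd,
            elevation_m=getattr(row, "elevation_m", 0.0),
            ca_ppm=getattr(row, "ca_ppm", 400.0))
        out[i] = vcmax_opt(env, params).vcmax25
    return pd.Series(out, index=env_table.index, name="vcmax25_pred")


def bias(pred, obs):
    """Model bias B = 100 (pred - obs) / obs, %.  Scale invariant."""
    obs = np.asarray(obs, dtype=float)
    if np.any(obs <= 0):
        raise ValueError("observed values must be positive")
    out = 100.0 * (np.asarray(pred, dtype=float) - obs) / obs
    return float(out) if out.ndim == 0 else out


def bias_regression(table: pd.DataFrame, covariates,
                    mixed: bool = False) -> FitResult:
    """Regress bias B (%) on covariates (OLS, or mixed for all-species data).

    ``table`` needs a ``bias`` column plus the covariate columns;
    ``covariates`` is a sequence of (name, log?) pairs.
    """
    ri = ("site_id", "species") if mixed else ()
    spec = RegressionSpec("bias", False, tuple(covariates), random_intercepts=ri)
    return fit_all_species(table, spec) if mixed else fit_site_mean(table, spec)


def partial_residuals(fit: FitResult, predictor: str) -> pd.DataFrame:
    """Median-anchored partial residuals for one predictor.

    Each observation's response is adjusted to hold every *other*
    predictor at its median:  pr_i = b0 + b_j x_ij + sum_k b_k med_k +
    e_i.  Regressing ``partial_residual`` on ``x`` reproduces the
    fitted coefficient b_j exactly.
    """
    if fit.design is None or fit.result is None:
        raise ValueError("fit does not carry its design; refit with this package")
    names = [c for c in fit.params.index if c != "const"]
    if predictor not in names:
        raise KeyError(f"unknown predictor {predictor!r}; have {names}")
    data = fit.design
    X = sm.add_constant(data[names], has_constant='add')
    resid = data["_y"].to_numpy() - (np.asarray(X) @ fit.params.to_numpy())
    anchor = float(fit.params.get("const", 0.0))
    for k in names:
        if k != predictor:
            anchor += fit.params[k] * float(data[k].median())
    x = data[predictor].to_numpy()
    pr = anchor + fit.params[predictor] * x + resid
    return pd.DataFrame({"x": x, "partial_residual": pr}, index=data.index)


def leaf_soil_regressions(site_means: pd.DataFrame,
                          traits=("narea", "parea"),
                          soil_predictors=SOIL_PREDICTORS) -> dict:
    """OLS of each (log) leaf nutrient on soil C:N, ln total P and pH jointly.

    Returns {trait: FitResult}; traits whose soil columns are entirely
    missing are skipped with an entry of None.
    """
    out = {}
    soil_cols = [n for n, _ in soil_predictors]
    for trait in traits:
        cols = [trait] + soil_cols
        sub = site_means.dropna(subset=[c for c in cols if c in site_means])
        if any(c not in site_means for c in cols) or len(sub) == 0:
            out[trait] = None
            continue
        spec = RegressionSpec(trait, True, tuple(soil_predictors))
        out[trait] = fit_site_mean(sub, spec)
    return out


def cooks_distance(fit: FitResult) -> pd.Series:
    """Cook's distances of an OLS fit (diagnostic; nothing is auto-dropped)."""
    if fit.model != "ols":
        raise ValueError("Cook's distance is defined here for OLS fits")
    d = fit.result.get_influence().cooks_distance[0]
    return pd.Series(d, index=fit.design.index, name="cooks_d")


def refit_without_influential(site_means: pd.DataFrame, spec: RegressionSpec,
                              k: int = 3) -> tuple:
    """Refit after removing the k most influential points (by Cook's distance).

    Returns (refit, dropped_index).  A sensitivity utility — the full-data
    fit remains the primary result.
    """
    full = fit_site_mean(site_means, spec)
    drop = cooks_distance(full).nlargest(k).index
    refit = fit_site_mean(site_means.drop(index=drop), spec)
    return refit, list(drop)
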