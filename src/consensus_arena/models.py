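"""Inference layer: mixed models, Type II Wald ANOVA, EMM contrasts, FDR.

Models are described by a :class:`ModelSpec` (response, fixed-effect terms,
random-intercept grouping columns, family).  Reported coefficients use
treatment coding with the first factor level as reference; the Type II Wald
chi-square ANOVA refits each tested term under sum-to-zero coding in a
model that contains all other terms except interactions involving the
tested term.  Post-hoc pairwise comparisons use estimated marginal means
(equal weights over the levels of the other factors, covariates at their
means) on the linear-predictor scale, with Benjamini-Hochberg adjustment
within the contrast family.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from scipy.special import expit
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .glmm import BinomialMixedFit, fit_binomial_mixed

logger = logging.getLogger(__name__)

FAMILIES = ("binomial_logit", "gaussian_identity")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed model."""

    response: str
    fixed_terms: tuple[str, ...]
    random_intercepts: tuple[str, ...] = ()
    family: str = "binomial_logit"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))
        object.__setattr__(self, "random_intercepts",
                           tuple(self.random_intercepts))

    def formula(self, coding: str = "treatment",
                categoricals: Sequence[str] = (),
                terms: Sequence[str] | None = None) -> str:
        terms = list(self.fixed_terms if terms is None else terms)
        if coding == "sum":
            terms = [_sum_code_term(t, categoricals) for t in terms]
        rhs = " + ".join(terms) if terms else "1"
        return f"{self.response} ~ {rhs}"


def _sum_code_term(term: str, categoricals: Sequence[str]) -> str:
    out = term
    for col in categoricals:
        out = re.sub(rf"(?<![\w.(]){re.escape(col)}(?![\w.(])",
                     f"C({col}, Sum)", out)
    return out


def _components(term: str) -> frozenset[str]:
    return frozenset(p.strip() for p in term.split(":"))


@dataclass
class FitResult:
    """Fitted coefficients, covariance and bookkeeping for one model."""

    params: pd.Series
    cov_params: pd.DataFrame
    vc: dict[str, float]
    loglike: float
    converged: bool
    fallback: bool
    spec: ModelSpec
    design_info: patsy.DesignInfo
    data: pd.DataFrame = field(repr=False)
    n_dropped: int = 0
    scale: float = np.nan

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)),
                         index=self.params.index)

    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    def summary_frame(self) -> pd.DataFrame:
        z = self.tvalues()
        return pd.DataFrame({
            "coef": self.params, "se": self.bse, "z": z,
            "p": 2 * stats.norm.sf(np.abs(z)),
        })


def _required_columns(spec: ModelSpec) -> list[str]:
    cols = {spec.response, *spec.random_intercepts}
    for term in spec.fixed_terms:
        for tok in re.findall(r"[A-Za-z_][A-Za-z0-9_]*", term):
            if tok not in {"I", "C", "np", "Sum", "Treatment", "center",
                           "standardize", "log", "exp"}:
                cols.add(tok)
    return sorted(cols)


def _complete_cases(table: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, int]:
    cols = [c for c in _required_columns(spec) if c in table.columns]
    missing = [c for c in _required_columns(spec) if c not in table.columns]
    if missing:
        raise ValueError(f"columns missing from table: {missing}")
    sub = table.dropna(subset=cols).reset_index(drop=True)
    return sub, len(table) - len(sub)


def _categorical_columns(df: pd.DataFrame, spec: ModelSpec) -> list[str]:
    cats = []
    for c in _required_columns(spec):
        if c in df.columns and (df[c].dtype == object or df[c].dtype == bool
                                or isinstance(df[c].dtype, pd.CategoricalDtype)):
            cats.append(c)
    return cats


def fit_model(table: pd.DataFrame, spec: ModelSpec,
              coding: str = "treatment",
              terms: Sequence[str] | None = None) -> FitResult:
    """Fit the mixed model described by ``spec`` on ``table``.

    Gaussian responses use statsmodels (OLS without random terms, MixedLM
    variance components for crossed random intercepts).  Binomial responses
    use the package's Laplace random-intercept logistic model, falling back
    to a fixed-effects GLM with cluster-robust covariance (by the first
    grouping column) if the mixed fit does not converge.
    """
    data, n_dropped = _complete_cases(table, spec)
    if n_dropped:
        logger.info("dropped %d incomplete rows", n_dropped)
    cats = _categorical_columns(data, spec)
    for c in spec.random_intercepts:
        if data[c].nunique() < 1:
            raise ValueError(f"random intercept column {c} has no levels")
    formula = spec.formula(coding=coding, categoricals=cats, terms=terms)
    y, X = patsy.dmatrices(formula, data, return_type="dataframe")
    if X.shape[1] > np.linalg.matrix_rank(X.to_numpy()):
        raise ValueError("singular fixed-effect design")
    yv = y.to_numpy().ravel()
    names = list(X.columns)

    if spec.family == "gaussian_identity":
        return _fit_gaussian(data, spec, formula, X, yv, names, n_dropped)
    if not np.isin(yv, (0.0, 1.0)).all():
        raise ValueError("binomial response must be coded 0/1")
    return _fit_binomial(data, spec, X, yv, names, n_dropped)


def _fit_gaussian(data, spec, formula, X, yv, names, n_dropped) -> FitResult:
    if not spec.random_intercepts:
        res = sm.OLS(yv, X.to_numpy()).fit()
        return FitResult(
            params=pd.Series(res.params, index=names),
            cov_params=pd.DataFrame(res.cov_params(), index=names, columns=names),
            vc={}, loglike=float(res.llf), converged=True, fallback=False,
            spec=spec, design_info=X.design_info, data=data,
            n_dropped=n_dropped, scale=float(res.scale))
    vc_formula = {g: f"0 + C({g})" for g in spec.random_intercepts}
    groups = np.ones(len(data))
    try:
        model = sm.MixedLM.from_formula(
            formula, data, groups=groups, vc_formula=vc_formula,
            re_formula="0")
        with np.errstate(all="ignore"):
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
        conv = bool(res.converged)
    except Exception:
        conv = False
        res = None
    if not conv:
        first = spec.random_intercepts[0]
        ols = sm.OLS(yv, X.to_numpy()).fit(
            cov_type="cluster", cov_kwds={"groups": data[first]})
        return FitResult(
            params=pd.Series(ols.params, index=names),
            cov_params=pd.DataFrame(ols.cov_params(), index=names,
                                    columns=names),
            vc={}, loglike=float(ols.llf), converged=False, fallback=True,
            spec=spec, design_info=X.design_info, data=data,
            n_dropped=n_dropped, scale=float(ols.scale))
    fe = res.fe_params
    k = len(fe)
    cov = np.asarray(res.cov_params())[:k, :k]
    vc = {g: float(v) for g, v in zip(spec.random_intercepts,
                                      np.atleast_1d(res.vcomp))}
    return FitResult(
        params=pd.Series(np.asarray(fe), index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        vc=vc, loglike=float(res.llf), converged=True, fallback=False,
        spec=spec, design_info=X.design_info, data=data,
        n_dropped=n_dropped, scale=float(res.scale))


def _fit_binomial(data, spec, X, yv, names, n_dropped) -> FitResult:
    if not spec.random_intercepts:
        res = sm.GLM(yv, X.to_numpy(), family=sm.families.Binomial()).fit()
        return FitResult(
            params=pd.Series(res.params, index=names),
            cov_params=pd.DataFrame(np.asarray(res.cov_params()),
                                    index=names, columns=names),
            vc={}, loglike=float(res.llf), converged=True, fallback=False,
            spec=spec, design_info=X.design_info, data=data,
            n_dropped=n_dropped)
    factors = {g: data[g].to_numpy() for g in spec.random_intercepts}
    try:
        fit = fit_binomial_mixed(X.to_numpy(), yv, factors)
    except Exception:
        fit = None
    if fit is None or not np.all(np.isfinite(fit.beta)):
        return _binomial_fallback(data, spec, X, yv, names, n_dropped)
    return FitResult(
        params=pd.Series(fit.beta, index=names),
        cov_params=pd.DataFrame(fit.cov_beta, index=names, columns=names),
        vc=fit.vc, loglike=fit.loglike, converged=fit.converged,
        fallback=False, spec=spec, design_info=X.design_info, data=data,
        n_dropped=n_dropped)


def _binomial_fallback(data, spec, X, yv, names, n_dropped) -> FitResult:
    first = spec.random_intercepts[0]
    res = sm.GLM(yv, X.to_numpy(), family=sm.families.Binomial()).fit(
        cov_type="cluster", cov_kwds={"groups": data[first]})
    return FitResult(
        params=pd.Series(res.params, index=names),
        cov_params=pd.DataFrame(np.asarray(res.cov_params()),
                                index=names, columns=names),
        vc={}, loglike=float(res.llf), converged=False, fallback=True,
        spec=spec, design_info=X.design_info, data=data, n_dropped=n_dropped)


def _term_slice(design_info: patsy.DesignInfo, raw_term: str,
                categoricals: Sequence[str], coding: str) -> slice:
    wrapped = (_sum_code_term(raw_term, categoricals)
               if coding == "sum" else raw_term)
    norm = lambda s: s.replace(" ", "")
    for name, sl in design_info.term_name_slices.items():
        if norm(name) == norm(wrapped):
            return sl
    # patsy may reorder interaction components; match on component sets
    want = frozenset(map(norm, _components(wrapped)))
    for name, sl in design_info.term_name_slices.items():
        if frozenset(map(norm, _components(name))) == want:
            return sl
    raise KeyError(f"term {raw_term!r} not found in design")


def anova_type2(fit: FitResult) -> pd.DataFrame:
    """Type II Wald chi-square test for every fixed term.

    Each term is tested in a sum-to-zero-coded refit containing all other
    terms except interactions that involve the tested term; the Wald
    statistic is ``b' V^-1 b`` over the term's coefficients.
    """
    spec = fit.spec
    cats = _categorical_columns(fit.data, spec)
    rows = []
    for term in spec.fixed_terms:
        comp = _components(term)
        kept = [t for t in spec.fixed_terms
                if t == term or not (_components(t) > comp)]
        sub = fit_model(fit.data, spec, coding="sum", terms=kept)
        sl = _term_slice(sub.design_info, term, cats, "sum")
        b = sub.params.to_numpy()[sl]
        V = sub.cov_params.to_numpy()[sl, sl]
        try:
            chi2 = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"rank-deficient covariance for term {term!r}")
        df = len(b)
        rows.append({"term": term, "chi2": chi2, "df": df,
                     "p": float(stats.chi2.sf(chi2, df))})
    return pd.DataFrame(rows)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def emm_pairwise(fit: FitResult, factor: str) -> pd.DataFrame:
    """All pairwise EMM contrasts of one factor (linear-predictor scale).

    EMMs average model predictions over the levels of the other factors
    with equal weights, holding numeric covariates at their observed means;
    contrasts are two-sided Wald z tests with BH adjustment across the
    family of pairs.
    """
    data = fit.data
    cats = _categorical_columns(data, fit.spec)
    if factor not in cats:
        raise ValueError(f"{factor!r} is not a factor in the model")
    levels = {c: sorted(data[c].dropna().unique()) for c in cats}
    if len(levels[factor]) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    num_cols = [c for c in _required_columns(fit.spec)
                if c in data.columns and c not in cats
                and c != fit.spec.response
                and c not in fit.spec.random_intercepts]
    grid = pd.DataFrame(
        list(itertools.product(*[levels[c] for c in cats])), columns=cats)
    for c in num_cols:
        grid[c] = float(data[c].mean())
    (Xg,) = patsy.build_design_matrices([fit.design_info], grid,
                                        return_type="dataframe")
    Xg = Xg.to_numpy()
    beta = fit.params.to_numpy()
    V = fit.cov_params.to_numpy()
    emm_rows = {lv: Xg[(grid[factor] == lv).to_numpy()].mean(axis=0)
                for lv in levels[factor]}
    rows = []
    for a, b in itertools.combinations(levels[factor], 2):
        c = emm_rows[a] - emm_rows[b]
        est = float(c @ beta)
        se = float(np.sqrt(c @ V @ c))
        z = est / se if se > 0 else np.nan
        rows.append({"contrast": f"{a} - {b}", "estimate": est, "se": se,
                     "z": z, "p": 2 * float(stats.norm.sf(abs(z)))})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"])
    return out


def predicted_switch_curve(fit: FitResult, grid: Sequence[float],
                           at: Mapping[str, object] | None = None,
                           var: str = "delta_social") -> pd.DataFrame:
    """Fixed-effect switch probabilities over a covariate grid.

    Random effects are set to zero; factors default to their first level
    and numeric covariates to their means unless overridden via ``at``.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty prediction grid")
    data = fit.data
    cats = _categorical_columns(data, fit.spec)
    at = dict(at or {})
    df = pd.DataFrame({var: grid})
    for c in _required_columns(fit.spec):
        if c == var or c not in data.columns or c == fit.spec.response \
                or c in fit.spec.random_intercepts:
            continue
        if c in at:
            df[c] = at[c]
        elif c in cats:
            df[c] = sorted(data[c].dropna().unique())[0]
        else:
            df[c] = float(data[c].mean())
    (Xg,) = patsy.build_design_matrices([fit.design_info], df,
                                        return_type="dataframe")
    eta = Xg.to_numpy() @ fit.params.to_numpy()
    prob = expit(eta) if fit.spec.family == "binomial_logit" else eta
    return pd.DataFrame({var: grid, "eta": eta, "probability": prob})
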