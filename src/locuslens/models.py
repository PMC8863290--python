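"""Nested generalized linear models for expression and disease.

Expression responses use a Gaussian GLM (ordinary least squares under
maximum likelihood), binary disease responses an additive logistic GLM.
Markers enter as additive minor-allele dosages (0/1/2); nested models are
compared with a likelihood-ratio test (2·ΔlogLik ~ chi-square on the
parameter difference), with Bonferroni adjustment over the emitted family
of comparisons and AIC = 2k − 2·logLik reported per model. A marker that
is perfectly collinear with terms already in the model is dropped as
aliased and the comparison is reported as uninformative (df = 0, p = 1) —
the behaviour expected when adding a perfect LD proxy of an included
variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError as _SmPerfectSeparationError,
    PerfectSeparationWarning as _SmPerfectSeparationWarning,
)

__all__ = [
    "ModelSpec",
    "FitResult",
    "ComparisonResult",
    "PerfectSeparationError",
    "fit_glm",
    "compare_nested",
    "sequential_marker_analysis",
    "genotype_stratified_test",
]


class PerfectSeparationError(RuntimeError):
    """Logistic fit abandoned: outcome perfectly separated by the design."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model: response column, marker dosage columns, covariates.

    response_kind is "expression" (Gaussian, identity link) or "disease"
    (binomial, logit link, additive dosage coding).
    """

    response: str
    response_kind: str
    markers: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.response_kind not in {"expression", "disease"}:
            raise ValueError("response_kind must be 'expression' or 'disease'")
        overlap = set(self.markers) & set(self.covariates)
        if overlap:
            raise ValueError(f"terms are both marker and covariate: {sorted(overlap)}")

    @property
    def terms(self) -> tuple[str, ...]:
        return self.markers + self.covariates

    def formula(self) -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"{self.response} ~ {rhs}"


@dataclass
class FitResult:
    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    loglik: float
    n_obs: int
    df_resid: int
    n_params: int
    converged: bool
    aliased: tuple[str, ...] = ()
    rows_used: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik


@dataclass
class ComparisonResult:
    statistic: float
    df: int
    pvalue: float
    pvalue_bonferroni: float
    aic_reduced: float
    aic_full: float
    informative: bool


def _design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.Series, pd.DataFrame, np.ndarray, list[str]]:
    cols = [spec.response, *spec.terms]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns not in data: {missing}")
    sub = data[cols].dropna()  # listwise deletion
    n_dropped = len(data) - len(sub)
    if n_dropped:
        warnings.warn(f"listwise deletion dropped {n_dropped} rows", stacklevel=3)
    y = sub[spec.response]
    if spec.terms:
        x = pd.get_dummies(sub[list(spec.terms)], drop_first=True, dtype=float)
        x = sm.add_constant(x, has_constant="add")
    else:
        x = pd.DataFrame({"const": np.ones(len(sub))}, index=sub.index)
    # Drop aliased (perfectly collinear) columns, keeping earlier ones.
    aliased = []
    keep = ["const"]
    mat = x[["const"]].to_numpy()
    for c in [c for c in x.columns if c != "const"]:
        cand = np.column_stack([mat, x[c].to_numpy()])
        if np.linalg.matrix_rank(cand) > mat.shape[1]:
            keep.append(c)
            mat = cand
        else:
            aliased.append(c)
    if aliased:
        warnings.warn(
            f"dropping aliased term(s): {aliased}", stacklevel=3
        )
    return y, x[keep], sub.index.to_numpy(), aliased


def fit_glm(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Maximum-likelihood GLM fit with listwise deletion and aliased-term
    dropping. Raises PerfectSeparationError for separated logistic fits
    and ValueError when complete cases < parameters + 5."""
    y, x, rows, aliased = _design(data, spec)
    if len(y) < x.shape[1] + 5:
        raise ValueError(
            f"{len(y)} complete cases for {x.shape[1]} parameters; need at least "
            f"{x.shape[1] + 5}"
        )
    if spec.response_kind == "expression":
        family = sm.families.Gaussian()
    else:
        vals = set(pd.unique(y))
        if not vals <= {0, 1}:
            raise ValueError(f"disease response must be 0/1, got values {sorted(vals)}")
        family = sm.families.Binomial()
    model = sm.GLM(y.to_numpy(dtype=float), x.to_numpy(), family=family)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=_SmPerfectSeparationWarning)
        try:
            res = model.fit(maxiter=200)
        except (_SmPerfectSeparationError, _SmPerfectSeparationWarning) as exc:
            raise PerfectSeparationError(str(exc)) from exc
    if spec.response_kind == "disease":
        fitted = res.fittedvalues
        if np.min(fitted) < 1e-10 or np.max(fitted) > 1 - 1e-10:
            # quasi-separation that statsmodels let converge to the boundary
            if (np.abs(res.params) > 1e2).any():
                raise PerfectSeparationError("coefficients diverged to boundary")
    names = list(x.columns)
    # Gaussian GLM: statsmodels' llf uses the MLE of the dispersion; count
    # the variance as an estimated parameter in k for AIC, matching the
    # usual linear-model AIC.
    k = x.shape[1] + (1 if spec.response_kind == "expression" else 0)
    return FitResult(
        spec=spec,
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        loglik=float(res.llf),
        n_obs=int(res.nobs),
        df_resid=int(res.df_resid),
        n_params=k,
        converged=bool(getattr(res, "converged", True)),
        aliased=tuple(aliased),
        rows_used=rows,
    )


def compare_nested(
    reduced: FitResult, full: FitResult, family_size: int = 1
) -> ComparisonResult:
    """Likelihood-ratio test of nested GLMs (ANOVA-style).

    The reduced model's terms must be a subset of the full model's; both
    fits must use the same rows. When the full model adds only aliased
    (perfectly collinear) terms the comparison has df = 0 and is reported
    uninformative with p = 1. Bonferroni p = min(1, family_size x p).
    """
    r_terms = set(reduced.spec.terms)
    f_terms = set(full.spec.terms)
    if not r_terms <= f_terms:
        raise ValueError("models are not nested: reduced terms not a subset of full")
    if reduced.spec.response != full.spec.response:
        raise ValueError("models have different responses")
    if len(reduced.rows_used) != len(full.rows_used) or not np.array_equal(
        reduced.rows_used, full.rows_used
    ):
        raise ValueError("models were fit on different sample rows")
    df = full.n_params - reduced.n_params
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if df <= 0:
        return ComparisonResult(
            statistic=stat,
            df=0,
            pvalue=1.0,
            pvalue_bonferroni=1.0,
            aic_reduced=reduced.aic,
            aic_full=full.aic,
            informative=False,
        )
    p = float(stats.chi2.sf(stat, df))
    return ComparisonResult(
        statistic=stat,
        df=df,
        pvalue=p,
        pvalue_bonferroni=min(1.0, family_size * p),
        aic_reduced=reduced.aic,
        aic_full=full.aic,
        informative=True,
    )


def sequential_marker_analysis(
    data: pd.DataFrame,
    response: str,
    response_kind: str,
    markers: list[str],
    covariates: list[str],
    bonferroni_family: int | None = None,
) -> pd.DataFrame:
    """Sequential "in context of" model comparison table.

    Emits (a) each marker alone against the covariate-only base model and
    (b) each marker added in context of the previously accepted marker
    set, accumulating markers in the given order. Each row reports the
    LRT p (raw and Bonferroni over the emitted family) and both AICs.
    """
    if response_kind not in {"expression", "disease"}:
        raise ValueError("response_kind must be 'expression' or 'disease'")
    rows = []
    plans: list[tuple[str, tuple[str, ...], tuple[str, ...]]] = []
    for m in markers:
        plans.append((m, (), (m,)))
    accepted: list[str] = []
    for m in markers:
        if accepted:
            plans.append(
                (
                    " & ".join(accepted) + f" + {m}",
                    tuple(accepted),
                    tuple(accepted) + (m,),
                )
            )
        accepted.append(m)
    family = bonferroni_family if bonferroni_family is not None else len(plans)
    covs = tuple(covariates)
    # complete cases over every column any plan uses, so all fits share rows
    all_cols = [response, *covs, *markers]
    shared = data[all_cols].dropna()
    cache: dict[tuple[str, ...], FitResult] = {}

    def _fit(marker_terms: tuple[str, ...]) -> FitResult:
        if marker_terms not in cache:
            spec = ModelSpec(
                response=response,
                response_kind=response_kind,
                markers=marker_terms,
                covariates=covs,
            )
            cache[marker_terms] = fit_glm(spec, shared)
        return cache[marker_terms]

    for label, red_markers, full_markers in plans:
        reduced = _fit(red_markers)
        full = _fit(full_markers)
        cmp = compare_nested(reduced, full, family_size=family)
        added = [t for t in full_markers if t not in red_markers]
        in_context = (
            " & ".join(red_markers) + " in context of " + " & ".join(added)
            if red_markers
            else added[0]
        )
        rows.append(
            {
                "variable_of_interest": in_context,
                "anova_p": cmp.pvalue,
                "anova_p_bonferroni": cmp.pvalue_bonferroni,
                "model1": reduced.spec.formula(),
                "aic1": reduced.aic,
                "model2": full.spec.formula(),
                "aic2": full.aic,
                "informative": cmp.informative,
            }
        )
    return pd.DataFrame(rows)


def genotype_stratified_test(
    expression: np.ndarray,
    disease: np.ndarray,
    dosage: np.ndarray,
    min_per_class: int = 2,
) -> pd.DataFrame:
    """Within each genotype group (dosage 0/1/2), a two-sided Wilcoxon
    rank-sum test of expression between disease classes.

    Uses the exact null distribution for small groups (automatic in
    scipy's mannwhitneyu without ties). Groups with an empty disease
    class, or fewer than ``min_per_class`` observations in either class,
    are reported untestable (p = NaN).
    """
    expression = np.asarray(expression, dtype=float)
    disease = np.asarray(disease)
    dosage = np.asarray(dosage)
    rows = []
    for g in (0, 1, 2):
        mask = dosage == g
        x = expression[mask & (disease == 1)]
        y = expression[mask & (disease == 0)]
        if len(x) < min_per_class or len(y) < min_per_class:
            rows.append(
                {"dosage": g, "n_disease": len(x), "n_control": len(y),
                 "pvalue": np.nan, "testable": False}
            )
            continue
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        rows.append(
            {"dosage": g, "n_disease": len(x), "n_control": len(y),
             "pvalue": p, "testable": True}
        )
    return pd.DataFrame(rows)
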