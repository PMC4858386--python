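"""Adjusted birth-weight models with trend and interaction tests.

The outcome is continuous term birth weight (g).  Exposures enter as
categorical tertile factors (reference = lowest tertile), singly or as a
pair in the joint ingestion + shower/bath/swim-uptake model.  Every model
adjusts a priori for ten maternal factors (caffeine intake, education,
fasting and post-load glucose, ethnicity, smoking, parity, age, BMI
quartile, IMD quintile) and two infant factors (gestational age as linear
and quadratic terms, sex).  Stratified models drop the ethnicity covariate.

Three p-values accompany each exposure: an overall F-test on the factor,
a linear-trend test obtained by refitting with the tertiles coded 0/1/2 as
a continuous term, and (in total-population models) an F-test on the
exposure-by-ethnicity interaction terms jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import linalg

#: a-priori adjustment set: 10 maternal + 2 infant factors; gestational age
#: always enters as linear + quadratic
MATERNAL_COVARIATES = (
    "caffeine_ge200", "education", "fasting_glucose", "postload_glucose",
    "ethnicity", "smoking", "parity_cat", "age", "bmi_quartile",
    "imd_quintile",
)
INFANT_COVARIATES = ("gestational_age_wk", "sex")
CATEGORICAL_COVARIATES = {
    "caffeine_ge200", "education", "ethnicity", "smoking", "parity_cat",
    "bmi_quartile", "imd_quintile", "sex",
}
STRATA = ("total", "white_British", "Pakistani_origin")


@dataclass
class ModelSpec:
    """Specification of one adjusted birth-weight model."""

    exposures: Sequence[str]                 # 1 or 2 tertile-coded columns
    outcome: str = "birth_weight_g"
    stratum: str = "total"
    extra_covariates: Sequence[str] = ()     # e.g. sensitivity additions
    min_per_level: int = 20

    def __post_init__(self):
        if not 1 <= len(self.exposures) <= 2:
            raise ValueError("specify one or two exposure terms")
        if self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}")

    @property
    def covariates(self) -> list[str]:
        cov = [c for c in MATERNAL_COVARIATES
               if not (self.stratum != "total" and c == "ethnicity")]
        cov += list(INFANT_COVARIATES) + list(self.extra_covariates)
        return cov

    def covariate_terms(self) -> list[str]:
        terms = []
        for c in self.covariates:
            if c in CATEGORICAL_COVARIATES or c in self.extra_covariates:
                terms.append(f"C({c})")
            elif c == "gestational_age_wk":
                terms.append("gestational_age_wk + I(gestational_age_wk**2)")
            else:
                terms.append(c)
        return terms

    def formula(self, categorical_exposure: bool = True) -> str:
        expo = [f"C({e})" if categorical_exposure else e for e in self.exposures]
        rhs = " + ".join(expo + self.covariate_terms())
        return f"{self.outcome} ~ {rhs}"


@dataclass
class EffectEstimate:
    """Adjusted (and crude) effect of exposure tertiles on birth weight."""

    exposure: str
    stratum: str
    levels: pd.DataFrame         # level, n, diff, lcl, ucl (adjusted scale)
    crude_levels: pd.DataFrame | None
    p_overall: float
    p_trend: float | None = None
    p_interaction: float | None = None
    n_used: int = 0
    fit: object = field(default=None, repr=False)


def _check_rank(res, formula: str) -> None:
    X = res.model.exog
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, pivots = linalg.qr(X, pivoting=True, mode="economic")
        names = np.array(res.model.exog_names)
        aliased = sorted(names[pivots[rank:]])
        raise ValueError(
            f"rank-deficient design for {formula!r}; aliased terms: {aliased}"
        )


def _term_f_test(res, term: str) -> float:
    """F-test that all coefficients of a factor term are jointly zero."""
    slices = res.model.data.design_info.term_name_slices
    if term not in slices:
        raise KeyError(f"term {term!r} not in model "
                       f"({list(slices)})")
    sl = slices[term]
    k = res.params.shape[0]
    idx = range(*sl.indices(k))
    R = np.zeros((len(list(idx)), k))
    for row, j in enumerate(range(*sl.indices(k))):
        R[row, j] = 1.0
    return float(res.f_test(R).pvalue)


def _level_table(res, data: pd.DataFrame, exposure: str) -> pd.DataFrame:
    ci = res.conf_int()
    rows = []
    levels = sorted(data[exposure].dropna().unique())
    counts = data[exposure].value_counts()
    for lev in levels:
        name = f"C({exposure})[T.{lev}]" if lev != levels[0] else None
        if name is None:
            rows.append({"level": lev, "n": int(counts[lev]), "diff": 0.0,
                         "lcl": 0.0, "ucl": 0.0, "reference": True})
        else:
            if name not in res.params.index:
                # integers may render without decimal point differences
                matches = [p for p in res.params.index
                           if p.startswith(f"C({exposure})[T.")
                           and p.endswith(f"{lev}]")]
                name = matches[0]
            rows.append({
                "level": lev, "n": int(counts[lev]),
                "diff": float(res.params[name]),
                "lcl": float(ci.loc[name, 0]), "ucl": float(ci.loc[name, 1]),
                "reference": False,
            })
    return pd.DataFrame(rows)


def _prepare(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    cols = [spec.outcome, *spec.exposures, *spec.covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data is missing columns: {missing}")
    df = data
    if spec.stratum != "total":
        df = df[df["ethnicity"] == spec.stratum]
    df = df.dropna(subset=cols)
    for e in spec.exposures:
        counts = df[e].value_counts()
        if len(counts) < 2:
            raise ValueError(f"exposure {e!r} has a single level after filtering")
        if (counts < spec.min_per_level).any():
            small = counts[counts < spec.min_per_level].to_dict()
            raise ValueError(
                f"exposure {e!r} has levels below the observation floor "
                f"({spec.min_per_level}): {small}"
            )
        df = df.copy()
        df[e] = df[e].astype(int)
    return df


def fit_model(data: pd.DataFrame, spec: ModelSpec, *,
              crude: bool = True, trend: bool = True
              ) -> dict[str, EffectEstimate]:
    """Fit the adjusted model; returns one EffectEstimate per exposure.

    ``crude`` and ``trend`` control whether the bivariate comparison fit
    and the linear-trend refit are also run.
    """
    df = _prepare(data, spec)
    res = smf.ols(spec.formula(), data=df).fit()
    _check_rank(res, spec.formula())
    crude_res = None
    if crude:
        crude_formula = (f"{spec.outcome} ~ "
                         + " + ".join(f"C({e})" for e in spec.exposures))
        crude_res = smf.ols(crude_formula, data=df).fit()
    out = {}
    for e in spec.exposures:
        out[e] = EffectEstimate(
            exposure=e, stratum=spec.stratum,
            levels=_level_table(res, df, e),
            crude_levels=_level_table(crude_res, df, e) if crude_res is not None
            else None,
            p_overall=_term_f_test(res, f"C({e})"),
            p_trend=test_trend(df, spec, e) if trend else None,
            n_used=int(res.nobs),
            fit=res,
        )
    return out


def test_trend(data: pd.DataFrame, spec: ModelSpec, exposure: str) -> float:
    """Linear-trend p-value: refit with the tertiles coded 0/1/2 as a
    continuous covariate and read the slope's two-sided p."""
    df = _prepare(data, spec)
    if df[exposure].nunique() < 3:
        raise ValueError("trend test needs at least 3 exposure levels")
    other = [e for e in spec.exposures if e != exposure]
    terms = [exposure] + [f"C({e})" for e in other] + spec.covariate_terms()
    formula = f"{spec.outcome} ~ " + " + ".join(terms)
    res = smf.ols(formula, data=df).fit()
    return float(res.pvalues[exposure])


def test_interaction(data: pd.DataFrame, spec: ModelSpec,
                     exposure: str) -> float:
    """Joint F-test of the exposure-by-ethnicity interaction terms.

    Defined only for total-population models; a stratified model has a
    single ethnicity and the interaction is not estimable.
    """
    if spec.stratum != "total":
        raise ValueError("interaction test requires the total-population model")
    df = _prepare(data, spec)
    if df["ethnicity"].nunique() < 2:
        raise ValueError("interaction test needs at least two ethnicity levels")
    formula = spec.formula() + f" + C({exposure}):C(ethnicity)"
    res = smf.ols(formula, data=df).fit()
    return _term_f_test(res, f"C({exposure}):C(ethnicity)")


def run_analysis_suite(data: pd.DataFrame,
                       metrics: Sequence[Sequence[str] | str],
                       windows: Sequence[str] = ("whole",),
                       strata: Sequence[str] = STRATA,
                       extra_covariates: Sequence[str] = (),
                       min_per_level: int = 20) -> pd.DataFrame:
    """Fit the full grid of models and emit a long results table.

    ``data`` is the merged analysis dataset with one row per pregnancy and
    exposure-tertile columns named ``<metric>_<window>_tert``.  ``metrics``
    entries are either a single metric name or a pair for the joint
    two-exposure model.  Output columns mirror the published table layout:
    per metric x window x stratum x tertile level, the n, crude and
    adjusted mean differences with CIs, and trend/overall/interaction
    p-values.
    """
    rows = []
    for metric in metrics:
        pair = (metric,) if isinstance(metric, str) else tuple(metric)
        for window in windows:
            expo_cols = [f"{m}_{window}_tert" for m in pair]
            missing = [c for c in expo_cols if c not in data.columns]
            if missing:
                available = sorted(c for c in data.columns if c.endswith("_tert"))
                raise ValueError(
                    f"exposure column(s) {missing} absent; available tertile "
                    f"columns: {available}"
                )
            for stratum in strata:
                spec = ModelSpec(exposures=expo_cols, stratum=stratum,
                                 extra_covariates=extra_covariates,
                                 min_per_level=min_per_level)
                estimates = fit_model(data, spec)
                for m, col in zip(pair, expo_cols):
                    est = estimates[col]
                    p_int = None
                    if stratum == "total":
                        p_int = test_interaction(data, spec, col)
                    for _, lev in est.levels.iterrows():
                        crude = None
                        if est.crude_levels is not None:
                            crude = est.crude_levels.set_index("level").loc[
                                lev["level"]]
                        rows.append({
                            "metric": m, "window": window, "stratum": stratum,
                            "level": int(lev["level"]), "n": int(lev["n"]),
                            "crude_diff": None if crude is None
                            else float(crude["diff"]),
                            "crude_lcl": None if crude is None
                            else float(crude["lcl"]),
                            "crude_ucl": None if crude is None
                            else float(crude["ucl"]),
                            "adj_diff": float(lev["diff"]),
                            "adj_lcl": float(lev["lcl"]),
                            "adj_ucl": float(lev["ucl"]),
                            "p_overall": est.p_overall,
                            "p_trend": est.p_trend,
                            "p_interaction": p_int,
                            "n_model": est.n_used,
                        })
    return pd.DataFrame(rows)
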