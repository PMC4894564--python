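"""Cohort-level statistics: age x genotype models, correlations, summaries.

The statistical stage mirrors the study design: ordinary least squares with
main effects of age and genotype (optionally their interaction) for each
mechanical property at the DMA reference condition (1 Hz, 0.04 N); a
two-covariate model of normalized ocular rigidity on age and last IOP in
the affected group; Pearson correlations between outcomes of different
testing methods; and paired t-tests for anterior vs posterior sclera.
p-values are two-sided throughout and no multiple-testing correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "Term",
    "LineFit",
    "ModelFit",
    "fit_age_genotype",
    "fit_rigidity_model",
    "pearson",
    "paired_ttest",
    "group_summary",
    "mean_iop",
    "interval_weighted_iop",
]


@dataclass(frozen=True)
class Term:
    name: str
    coef: float
    se: float
    p: float


@dataclass(frozen=True)
class LineFit:
    """Per-group regression line derived from the fitted model."""

    intercept: float
    slope: float
    slope_se: float


@dataclass(frozen=True)
class ModelFit:
    response: str
    n: int
    terms: tuple[Term, ...]
    r: float | None = None                      # Pearson R of response with age
    group_lines: dict | None = None             # group -> LineFit
    group_p: float | None = None                # genotype main-effect p (age-adjusted)

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"no term named {name!r} in model for {self.response}")


def _check_finite(**arrays: np.ndarray) -> None:
    for name, arr in arrays.items():
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} contains missing or non-finite values")


def fit_age_genotype(
    y: np.ndarray,
    age: np.ndarray,
    group: np.ndarray,
    interaction: bool = True,
    response: str = "y",
    site: np.ndarray | None = None,
) -> ModelFit:
    """OLS of a property on age and genotype, optionally with interaction.

    With the interaction term the model is y ~ age * group, from which the
    per-group intercept/slope lines are derived (these equal separate
    per-group OLS fits exactly).  The genotype main-effect p-value with age
    as a covariate (the group-contrast layout of the summary table) comes
    from the additive model y ~ age + group.  An optional housing-site
    covariate is supported but off by default.
    """
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    group = np.asarray(group)
    _check_finite(y=y, age=age)
    groups = sorted(set(group))
    if len(groups) != 2:
        raise ValueError("exactly two genotype groups are required")
    if interaction:
        for g in groups:
            if (group == g).sum() < 3:
                raise ValueError("need at least 3 eyes per group for the interaction model")
    # "affected" is the reference level when present.
    ref = "affected" if "affected" in groups else groups[0]
    other = [g for g in groups if g != ref][0]
    ind = (group == other).astype(float)

    cols = {"age": age, f"group[{other}]": ind}
    if interaction:
        cols[f"age:group[{other}]"] = age * ind
    if site is not None:
        for s in sorted(set(site))[1:]:
            cols[f"site[{s}]"] = (np.asarray(site) == s).astype(float)
    X = sm.add_constant(pd.DataFrame(cols))
    try:
        fit = sm.OLS(y, X).fit()
    except np.linalg.LinAlgError as err:
        raise ValueError(f"rank-deficient design for response {response!r}") from err
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"rank-deficient design for response {response!r}")

    terms = tuple(
        Term(name="intercept" if n == "const" else n, coef=float(fit.params[n]),
             se=float(fit.bse[n]), p=float(fit.pvalues[n]))
        for n in X.columns
    )

    lines: dict[str, LineFit] = {}
    b0 = float(fit.params["const"])
    b_age = float(fit.params["age"])
    se_age = float(fit.bse["age"])
    lines[ref] = LineFit(intercept=b0, slope=b_age, slope_se=se_age)
    b_grp = float(fit.params[f"group[{other}]"])
    if interaction:
        b_int = float(fit.params[f"age:group[{other}]"])
        cov = fit.cov_params()
        var = (cov.loc["age", "age"] + cov.loc[f"age:group[{other}]", f"age:group[{other}]"]
               + 2 * cov.loc["age", f"age:group[{other}]"])
        lines[other] = LineFit(intercept=b0 + b_grp, slope=b_age + b_int,
                               slope_se=float(np.sqrt(max(var, 0.0))))
    else:
        lines[other] = LineFit(intercept=b0 + b_grp, slope=b_age, slope_se=se_age)

    # Age-adjusted group contrast from the additive model.
    X_add = sm.add_constant(pd.DataFrame({"age": age, "grp": ind}))
    group_p = float(sm.OLS(y, X_add).fit().pvalues["grp"])

    r = float(np.corrcoef(y, age)[0, 1]) if np.std(y) > 0 and np.std(age) > 0 else None
    return ModelFit(response=response, n=len(y), terms=terms, r=r,
                    group_lines=lines, group_p=group_p)


def fit_rigidity_model(
    k_norm: np.ndarray, age: np.ndarray, last_iop: np.ndarray,
    response: str = "k_norm",
) -> ModelFit:
    """Two-covariate OLS of normalized rigidity on age and last IOP.

    Intended for affected-group rows, mirroring the study's model
    k = β0 + β1·age + β2·lastIOP (the fitted β2 is negative: eyes exposed
    to higher chronic IOP have lower normalized rigidity at a given age).
    """
    k_norm = np.asarray(k_norm, dtype=float)
    age = np.asarray(age, dtype=float)
    last_iop = np.asarray(last_iop, dtype=float)
    _check_finite(k_norm=k_norm, age=age, last_iop=last_iop)
    X = sm.add_constant(pd.DataFrame({"age": age, "last_iop": last_iop}))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design: age and last IOP are collinear")
    fit = sm.OLS(k_norm, X).fit()
    terms = tuple(
        Term(name="intercept" if n == "const" else n, coef=float(fit.params[n]),
             se=float(fit.bse[n]), p=float(fit.pvalues[n]))
        for n in X.columns
    )
    return ModelFit(response=response, n=len(k_norm), terms=terms)


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Sample Pearson correlation with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_finite(x=x, y=y)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), int(x.size)


def paired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Paired two-sided t-test; returns (t, p, mean difference a-b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need paired vectors of length >= 2")
    _check_finite(a=a, b=b)
    diff = a - b
    if np.all(diff == diff[0]) and diff[0] == 0:
        return 0.0, 1.0, 0.0  # identical pairs: no evidence of a difference
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), float(np.mean(a - b))


def group_summary(
    data: pd.DataFrame,
    properties: list[str] | None = None,
    group_col: str = "group",
    age_col: str = "age_months",
) -> pd.DataFrame:
    """Per-group mean ± SD of each property, with age-adjusted group p-values.

    Lays out the posterior-sclera summary table: one row per group with
    ``mean`` and ``sd`` per property, plus a ``p`` row from the additive
    age + genotype model.  Raw (unadjusted) means are reported.
    """
    if group_col not in data:
        raise ValueError(f"missing group column {group_col!r}")
    if properties is None:
        properties = [c for c in data.columns
                      if c not in (group_col, age_col) and
                      pd.api.types.is_numeric_dtype(data[c])]
    groups = sorted(data[group_col].unique())
    if any((data[group_col] == g).sum() == 0 for g in groups) or not groups:
        raise ValueError("every group must contain at least one eye")
    out: dict[str, dict[str, float]] = {}
    for prop in properties:
        col: dict[str, float] = {}
        for g in groups:
            vals = data.loc[data[group_col] == g, prop].dropna()
            if vals.empty:
                raise ValueError(f"group {g!r} has no data for {prop!r}")
            col[f"{g}_mean"] = float(vals.mean())
            col[f"{g}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        sub = data[[prop, group_col, age_col]].dropna()
        if len(groups) == 2 and sub[group_col].nunique() == 2 and len(sub) >= 4:
            fit = fit_age_genotype(sub[prop].to_numpy(), sub[age_col].to_numpy(),
                                   sub[group_col].to_numpy(), interaction=False,
                                   response=prop)
            col["p"] = fit.group_p if fit.group_p is not None else np.nan
        else:
            col["p"] = np.nan
        out[prop] = col
    return pd.DataFrame(out).T


def mean_iop(iops: np.ndarray) -> float:
    """Arithmetic mean of all IOP readings over the animal's life."""
    iops = np.asarray(iops, dtype=float)
    if iops.size == 0:
        raise ValueError("need at least one IOP reading")
    return float(iops.mean())


def interval_weighted_iop(ages: np.ndarray, iops: np.ndarray,
                          window_months: float = 24.0) -> float:
    """Interval-weighted mean IOP over the last ``window_months`` of life.

    Each reading is weighted by the time interval it covers (trapezoidal
    weighting over reading times restricted to the window).  Falls back to
    the plain mean when fewer than two readings fall inside the window.
    """
    ages = np.asarray(ages, dtype=float)
    iops = np.asarray(iops, dtype=float)
    if ages.size != iops.size or ages.size == 0:
        raise ValueError("ages and iops must be equal-length and non-empty")
    order = np.argsort(ages)
    ages, iops = ages[order], iops[order]
    mask = ages >= ages[-1] - window_months
    if mask.sum() < 2:
        return float(iops[mask].mean()) if mask.any() else float(iops[-1])
    a, v = ages[mask], iops[mask]
    return float(np.trapezoid(v, a) / (a[-1] - a[0]))
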