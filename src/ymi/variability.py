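"""Group-level variability analyses.

Variability of a behavioral measure within a group of flies (usually a
genotype) is quantified by the coefficient of variation, CV = σ/μ.
Variance heterogeneity across predictors is modeled by ordinary least
squares on Levene-transformed data — each observation replaced by its
absolute deviation from its group mean — the regression analogue of the
classical Levene variance-homogeneity test.  Treatment/control and
temperature contrasts are aggregated as the mean over genotypes of the
relative change in genotype CV, tested by a paired t-test; all p-values
are nominal (no multiple-testing correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "RankDeficiencyError",
    "PairingError",
    "LinearModelResult",
    "EffectSizeResult",
    "EnrichmentResult",
    "SexEffectResult",
    "levene_transform",
    "add_levene_columns",
    "group_cv",
    "fit_metadata_model",
    "genotype_pvalues",
    "genotype_enrichment",
    "measure_correlation",
    "paired_effect",
    "absolute_bias",
    "merge_temperature_labels",
    "sex_variability_effect",
]


class RankDeficiencyError(ValueError):
    """The design matrix is rank deficient; offending columns are named."""

    def __init__(self, aliased: list[str]):
        self.aliased = list(aliased)
        super().__init__(f"design matrix is rank deficient; aliased columns: {self.aliased}")


class PairingError(ValueError):
    """No (or too few) groups are present in both conditions."""


@dataclass
class LinearModelResult:
    response: str
    predictors: tuple[str, ...]
    intercept: float
    coefficients: pd.Series
    standard_errors: pd.Series
    p_values: pd.Series
    n_obs: int
    r_squared: float

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictors": list(self.predictors),
            "intercept": self.intercept,
            "coefficients": self.coefficients.to_dict(),
            "standard_errors": self.standard_errors.to_dict(),
            "p_values": self.p_values.to_dict(),
            "n_obs": self.n_obs,
            "r_squared": self.r_squared,
        }


@dataclass
class EffectSizeResult:
    control: str
    treatment: str
    measure: str
    genotypes: tuple[str, ...]
    cv_control: np.ndarray
    cv_treatment: np.ndarray
    effect_pct: float
    t_statistic: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "control": self.control,
            "treatment": self.treatment,
            "measure": self.measure,
            "n_genotypes": len(self.genotypes),
            "effect_pct": self.effect_pct,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
        }


@dataclass
class EnrichmentResult:
    n_below: int
    n_total: int
    expected: float
    p_value: float


@dataclass
class SexEffectResult:
    measure: str
    effect_pct: float
    coefficient: float
    standard_error: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "effect_pct": self.effect_pct,
            "coefficient": self.coefficient,
            "standard_error": self.standard_error,
            "p_value": self.p_value,
        }


def levene_transform(values, groups) -> pd.DataFrame:
    """Absolute deviations from group means, d_ij = |y_ij − ȳ_j|.

    Returns a DataFrame with columns ``group``, ``value`` and
    ``abs_dev``.  Singleton groups carry no information about spread and
    are excluded with a warning; missing values are dropped.
    """
    df = pd.DataFrame({"group": np.asarray(groups), "value": np.asarray(values, dtype=float)})
    df = df.dropna(subset=["value"])
    sizes = df.groupby("group")["value"].transform("size")
    singles = sizes < 2
    if singles.any():
        dropped = df.loc[singles, "group"].unique().tolist()
        logger.warning("levene_transform: excluding singleton group(s): %s", dropped)
        df = df[~singles]
    means = df.groupby("group")["value"].transform("mean")
    df = df.assign(abs_dev=(df["value"] - means).abs())
    return df.reset_index(drop=True)


def add_levene_columns(
    df: pd.DataFrame,
    measures=(("handedness", "lev_handedness"), ("numTurns", "lev_numTurns"),
              ("switchiness", "lev_switchiness")),
    by=("genotype", "expCond"),
) -> pd.DataFrame:
    """Attach lev_* columns: |y − ȳ| within genotype × condition groups."""
    df = df.copy()
    keys = [df[k] for k in by]
    for source, target in measures:
        if source not in df:
            continue
        y = pd.to_numeric(df[source], errors="coerce")
        grp_mean = y.groupby(keys).transform("mean")
        df[target] = (y - grp_mean).abs()
    return df


def group_cv(values, groups, min_n: int = 2) -> pd.DataFrame:
    """Per-group coefficient of variation (sample SD / sample mean).

    Groups with fewer than ``min_n`` flies are excluded; groups with a
    non-positive mean get NaN CV and a warning (CV is meaningless on a
    non-positive scale).
    """
    df = pd.DataFrame({"group": np.asarray(groups), "value": np.asarray(values, dtype=float)})
    df = df.dropna(subset=["value"])
    agg = df.groupby("group")["value"].agg(n_flies="size", mean="mean", sd=lambda v: v.std(ddof=1))
    agg = agg[agg["n_flies"] >= max(min_n, 2)]
    with np.errstate(divide="ignore", invalid="ignore"):
        agg["cv"] = np.where(agg["mean"] > 0, agg["sd"] / agg["mean"], np.nan)
    bad = agg.index[agg["mean"] <= 0].tolist()
    if bad:
        logger.warning("group_cv: non-positive mean, CV undefined for group(s): %s", bad)
    return agg.reset_index()


def _build_design(df: pd.DataFrame, predictors) -> pd.DataFrame:
    """Design matrix with intercept; categoricals get treatment coding."""
    parts = [pd.Series(1.0, index=df.index, name="Intercept")]
    for col in predictors:
        s = df[col]
        if pd.api.types.is_numeric_dtype(s) and s.nunique() > 2:
            parts.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s.astype("string"), prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
    return pd.concat(parts, axis=1)


def _aliased_columns(X: np.ndarray, names) -> list[str]:
    """Columns pivoted out by rank-revealing QR (linearly dependent)."""
    from scipy.linalg import qr as scipy_qr

    _, r, piv = scipy_qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [names[i] for i in sorted(piv[rank:])]


def fit_metadata_model(table, response: str, predictors) -> LinearModelResult:
    """OLS of a measure on metadata predictors (treatment coding).

    Raises :class:`RankDeficiencyError` naming the aliased columns when
    the design is singular — e.g. when ``date`` is included alongside
    the other metadata, which jointly determine it.
    """
    df = table.df if hasattr(table, "df") else table
    predictors = tuple(predictors)
    missing = [p for p in predictors if p not in df.columns]
    if missing:
        raise KeyError(f"unknown predictor column(s): {missing}")
    sub = df[[response, *predictors]].dropna(subset=[response])
    y = pd.to_numeric(sub[response], errors="coerce")
    keep = y.notna()
    sub, y = sub[keep], y[keep]
    X = _build_design(sub, predictors)
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise RankDeficiencyError(_aliased_columns(Xv, list(X.columns)))
    fit = sm.OLS(y.to_numpy(), Xv).fit()
    names = list(X.columns)
    params = pd.Series(fit.params, index=names)
    return LinearModelResult(
        response=response,
        predictors=predictors,
        intercept=float(params["Intercept"]),
        coefficients=params.drop("Intercept"),
        standard_errors=pd.Series(fit.bse, index=names).drop("Intercept"),
        p_values=pd.Series(fit.pvalues, index=names).drop("Intercept"),
        n_obs=int(fit.nobs),
        r_squared=float(fit.rsquared),
    )


def genotype_pvalues(values, genotypes, min_n: int = 2) -> pd.Series:
    """One p-value per genotype for a mean effect on the measure.

    Each genotype's mean is tested against the grand mean by a
    two-sided one-sample t-test, giving one nominal p-value per
    genotype; under a null in which all genotype means are equal the
    p-values are approximately uniform.
    """
    df = pd.DataFrame({"g": np.asarray(genotypes), "y": np.asarray(values, dtype=float)})
    df = df.dropna(subset=["y"])
    grand = df["y"].mean()
    out = {}
    for g, grp in df.groupby("g"):
        if len(grp) < min_n or grp["y"].std(ddof=1) == 0:
            continue
        res = stats.ttest_1samp(grp["y"], popmean=grand)
        out[g] = float(res.pvalue)
    return pd.Series(out, name="p_value")


def genotype_enrichment(p_values, alpha: float = 0.05) -> EnrichmentResult:
    """Are more p-values below alpha than chance (α·N) predicts?

    One-sided binomial test of the count below ``alpha`` against a
    Binomial(N, alpha) null.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n_below = int((p < alpha).sum())
    test = stats.binomtest(n_below, p.size, alpha, alternative="greater")
    return EnrichmentResult(
        n_below=n_below, n_total=p.size, expected=alpha * p.size, p_value=float(test.pvalue)
    )


def measure_correlation(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def paired_effect(
    table,
    measure: str,
    control_cond: str,
    treatment_cond: str,
    pair_key: str = "genotype",
    cond_col: str = "expCond",
    min_n: int = 2,
    aggregation: str = "mean_relative",
) -> EffectSizeResult:
    """Treatment effect on group variability, paired across genotypes.

    For every genotype present in both conditions, the genotype CV of
    ``measure`` is computed in each condition.  ``effect_pct`` is 100 ×
    the mean over genotypes of (cv_treatment − cv_control)/cv_control
    (``aggregation="pooled"`` instead contrasts the across-genotype mean
    CVs), and significance is a two-sided paired t-test on the CV pairs.
    """
    df = table.df if hasattr(table, "df") else table
    cvs = {}
    for label in (control_cond, treatment_cond):
        sub = df[df[cond_col] == label]
        g = group_cv(sub[measure], sub[pair_key], min_n=min_n)
        cvs[label] = g.dropna(subset=["cv"]).set_index("group")["cv"]
    common = cvs[control_cond].index.intersection(cvs[treatment_cond].index)
    if len(common) < 2:
        raise PairingError(
            f"only {len(common)} genotype(s) present in both "
            f"{control_cond!r} and {treatment_cond!r}"
        )
    cv_c = cvs[control_cond].loc[common].to_numpy()
    cv_t = cvs[treatment_cond].loc[common].to_numpy()
    if aggregation == "mean_relative":
        effect = 100.0 * float(np.mean((cv_t - cv_c) / cv_c))
    elif aggregation == "pooled":
        effect = 100.0 * float((cv_t.mean() - cv_c.mean()) / cv_c.mean())
    else:
        raise ValueError("aggregation must be 'mean_relative' or 'pooled'")
    diffs = cv_t - cv_c
    if np.allclose(diffs, 0):
        # identical conditions: no evidence of any effect
        t_stat, p_val = 0.0, 1.0
    else:
        t_res = stats.ttest_rel(cv_t, cv_c)
        t_stat, p_val = float(t_res.statistic), float(t_res.pvalue)
    return EffectSizeResult(
        control=control_cond,
        treatment=treatment_cond,
        measure=measure,
        genotypes=tuple(common),
        cv_control=cv_c,
        cv_treatment=cv_t,
        effect_pct=effect,
        t_statistic=t_stat,
        p_value=p_val,
    )


def absolute_bias(p_hat):
    """Folded turn bias |p̂ − 0.5|: direction-free bias strength."""
    p = np.asarray(p_hat, dtype=float)
    if np.any((p[np.isfinite(p)] < 0) | (p[np.isfinite(p)] > 1)):
        raise ValueError("turn bias must lie in [0, 1]")
    out = np.abs(p - 0.5)
    return float(out) if np.isscalar(p_hat) else out


def merge_temperature_labels(temps):
    """Fold 22→23 °C and 32→33 °C (experiments run at either label)."""
    t = np.asarray(temps, dtype=float)
    merged = t.copy()
    merged[np.isclose(t, 22.0)] = 23.0
    merged[np.isclose(t, 32.0)] = 33.0
    return merged


def sex_variability_effect(
    table, measure: str, lev_col: str | None = None, group_key: str = "genotype"
) -> SexEffectResult:
    """Male-vs-female variability contrast via a Levene-transform model.

    Fits OLS of the absolute group-mean deviations on genotype + sex and
    expresses the male coefficient as a percent of the female baseline
    (the mean deviation among females), so +7.5% means males are 7.5%
    more variable than females on this measure.
    """
    df = table.df if hasattr(table, "df") else table
    df = df[df["sex"].isin(["male", "female"])].copy()
    if lev_col is not None and lev_col in df:
        df["_lev"] = pd.to_numeric(df[lev_col], errors="coerce")
    else:
        # deviations from the genotype × sex cell mean, kept row-aligned
        y = pd.to_numeric(df[measure], errors="coerce")
        grp_mean = y.groupby([df[group_key], df["sex"]]).transform("mean")
        df["_lev"] = (y - grp_mean).abs()
    df = df.dropna(subset=["_lev"])
    model = fit_metadata_model(df, "_lev", (group_key, "sex"))
    male_name = "sex_male"
    if male_name not in model.coefficients.index:
        # female was the dropped reference is the usual case; otherwise flip
        female_name = "sex_female"
        coef = -model.coefficients[female_name]
        se = model.standard_errors[female_name]
        p = model.p_values[female_name]
        female_base = float(df.loc[df["sex"] == "female", "_lev"].mean())
    else:
        coef = model.coefficients[male_name]
        se = model.standard_errors[male_name]
        p = model.p_values[male_name]
        female_base = float(df.loc[df["sex"] == "female", "_lev"].mean())
    return SexEffectResult(
        measure=measure,
        effect_pct=100.0 * float(coef) / female_base,
        coefficient=float(coef),
        standard_error=float(se),
        p_value=float(p),
    )
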