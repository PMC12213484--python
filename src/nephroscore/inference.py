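"""Statistical battery for score validation.

Two-group comparisons (t / Mann-Whitney / chi-squared / Fisher by a fixed
per-variable policy), univariate and covariate-adjusted logistic regression
of binary outcomes (stone-free status, high blood loss) on a score, and the
analogous ordinary-least-squares panel for continuous outcomes (haemoglobin
change, operative time, postoperative stay).

Conventions: scores enter the models as continuous integer covariates;
inference is Wald-based and two-sided with no multiple-testing correction;
chi-squared statistics are uncorrected (no Yates continuity correction) by
default; Fisher's exact test replaces chi-squared on a 2x2 table whenever
any expected cell count falls below 5.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "GroupComparison",
    "RegressionResult",
    "SeparationError",
    "RankDeficiencyError",
    "compare_groups",
    "univariate_logistic",
    "multivariate_logistic",
    "linear_panel",
    "or_from_coefficient",
    "chi2_2x2_closed_form",
    "DEFAULT_COVARIATES",
]

#: The ten-covariate adjustment set used by the multivariate models:
#: demographic factors (age, sex, BMI); stone characteristics (size = total
#: burden in mm^2, density = mean HU, number of stones, side); operative
#: parameters (anatomic class, tract length, hydronephrosis grade).
DEFAULT_COVARIATES: tuple[str, ...] = (
    "age_years",
    "C(sex)",
    "bmi",
    "stone_burden_mm2",
    "mean_hu",
    "stone_count",
    "C(side)",
    "C(anatomic_class)",
    "tract_length_mm",
    "C(hydronephrosis)",
)

Z95 = float(stats.norm.ppf(0.975))


class SeparationError(RuntimeError):
    """Logistic fit failed to converge because a predictor separates the outcome."""


class RankDeficiencyError(ValueError):
    """The design matrix is rank-deficient; carries the aliased columns."""

    def __init__(self, aliased: list[str]):
        super().__init__(f"rank-deficient design; aliased column(s): {', '.join(aliased)}")
        self.aliased = aliased


@dataclass
class GroupComparison:
    variable: str
    test: str  # t | mann_whitney | chi_squared | fisher
    statistic: float
    p_value: float
    descriptives: dict
    warning: str | None = None


@dataclass
class RegressionResult:
    """One fitted model: per-term coefficients with Wald 95% CIs and p-values.

    ``table`` is indexed by term name with columns ``B``, ``odds_ratio``
    (logistic only), ``ci_low``, ``ci_high``, ``p_value``.  CI bounds are on
    the odds-ratio scale for logistic models and the coefficient scale for
    linear models, matching how such panels are conventionally printed.
    """

    model_kind: str  # logistic | linear
    outcome: str
    table: pd.DataFrame
    n_used: int
    adjusted: bool
    covariates: tuple[str, ...] = ()
    warnings: list = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _as_df(table) -> pd.DataFrame:
    return getattr(table, "df", table)


def chi2_2x2_closed_form(a: float, b: float, c: float, d: float) -> float:
    """Uncorrected chi-squared for a 2x2 table [[a,b],[c,d]]: N(ad-bc)^2 / (r1 r2 c1 c2)."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return float("nan")
    return n * (a * d - b * c) ** 2 / denom


def compare_groups(table, variable: str, group_label: str, kind: str | None = None,
                   continuity_correction: bool = False) -> GroupComparison:
    """Compare a variable between the two levels of a binary group label.

    ``kind`` picks the test family: ``"normal"`` (t-test), ``"skewed"``
    (Mann-Whitney U, tie-corrected, two-sided) or ``"categorical"``
    (chi-squared, switching to Fisher's exact when any expected cell count
    of a 2x2 table is below 5).  When omitted it is inferred from the dtype
    (numeric -> skewed, else categorical).
    """
    df = _as_df(table)
    groups = df[group_label]
    levels = sorted(pd.unique(groups.dropna()), key=str)
    if len(levels) != 2:
        raise ValueError(f"group label {group_label!r} must be binary, found {levels}")
    mask1, mask2 = groups == levels[0], groups == levels[1]
    if mask1.sum() == 0 or mask2.sum() == 0:
        raise ValueError(f"empty group under {group_label!r}")
    if kind is None:
        kind = "skewed" if pd.api.types.is_numeric_dtype(df[variable]) and df[variable].dtype != bool else "categorical"

    warning = None
    if kind in ("normal", "skewed"):
        x = df.loc[mask1, variable].astype(float).dropna()
        y = df.loc[mask2, variable].astype(float).dropna()
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"need >=2 observations per group for {variable!r}")
        desc = {
            str(levels[0]): {"n": len(x), "mean": x.mean(), "median": x.median()},
            str(levels[1]): {"n": len(y), "mean": y.mean(), "median": y.median()},
        }
        if kind == "normal":
            stat, p = stats.ttest_ind(x, y, equal_var=True)
            test = "t"
        else:
            if x.nunique() == 1 and y.nunique() == 1 and x.iloc[0] == y.iloc[0]:
                # degenerate: every observation identical; U is defined but the
                # tie-corrected normal approximation divides by zero
                return GroupComparison(variable, "mann_whitney", len(x) * len(y) / 2.0, 1.0,
                                       desc, warning="degenerate: all values identical")
            stat, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            test = "mann_whitney"
        return GroupComparison(variable, test, float(stat), float(p), desc, warning)

    # categorical
    contingency = pd.crosstab(df[variable].astype(str), groups)
    if contingency.shape[0] < 2:
        return GroupComparison(variable, "chi_squared", 0.0, 1.0,
                               {"table": contingency.to_dict()},
                               warning="degenerate: single observed category")
    expected = stats.contingency.expected_freq(contingency.to_numpy())
    desc = {"table": contingency.to_dict()}
    if contingency.shape == (2, 2) and (expected < 5).any():
        _, p = stats.fisher_exact(contingency.to_numpy())
        return GroupComparison(variable, "fisher", float("nan"), float(p), desc)
    if (expected < 5).any():
        warning = "expected cell count < 5 in an r x c table; chi-squared approximation weak"
    stat, p, _, _ = stats.chi2_contingency(contingency.to_numpy(), correction=continuity_correction)
    return GroupComparison(variable, "chi_squared", float(stat), float(p), desc, warning)


def _check_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify aliased columns via pivoted QR: small diagonal of R
        _, r, piv = _qr_pivot(x)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        aliased = [design.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        aliased += [design.columns[j] for j in piv[len(diag):]]
        raise RankDeficiencyError(sorted(set(map(str, aliased))))


def _qr_pivot(x: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(x, mode="economic", pivoting=True)
    return q, r, piv


def _logistic_result(fit, outcome: str, adjusted: bool, covariates: tuple[str, ...],
                     n_used: int, warn: list) -> RegressionResult:
    params = fit.params
    conf = fit.conf_int(alpha=0.05)
    tab = pd.DataFrame({
        "B": params,
        "odds_ratio": np.exp(params),
        "ci_low": np.exp(conf[0]),
        "ci_high": np.exp(conf[1]),
        "p_value": fit.pvalues,
    })
    return RegressionResult("logistic", outcome, tab, n_used, adjusted, covariates, warn)


def _fit_logit(model, predictor_hint: str):
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = model.fit(disp=0, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(
                f"perfect separation while fitting outcome on {predictor_hint!r}"
            ) from exc
    if not fit.mle_retvals.get("converged", True):
        raise SeparationError(f"logistic fit did not converge for {predictor_hint!r}")
    return fit


def univariate_logistic(table, score_name: str, outcome: str) -> RegressionResult:
    """Logistic regression of a binary outcome on one score (continuous covariate).

    Reports the maximum-likelihood B, odds ratio exp(B), Wald 95% CI and
    Wald p-value for the score term.
    """
    df = _as_df(table)[[score_name, outcome]].dropna()
    y = df[outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError(f"outcome {outcome!r} is constant; cannot fit")
    x = sm.add_constant(df[[score_name]].astype(float))
    fit = _fit_logit(sm.Logit(y, x), score_name)
    return _logistic_result(fit, outcome, False, (), len(df), [])


def _design_matrices(df: pd.DataFrame, outcome: str, terms: list[str]):
    import patsy

    formula = f"{outcome} ~ " + " + ".join(terms)
    y, x = patsy.dmatrices(formula, df, return_type="dataframe")
    return y, x


def _adjusted_frame(table, score_name: str, outcome: str,
                    covariates: tuple[str, ...]) -> tuple[pd.DataFrame, list[str]]:
    df = _as_df(table).copy()
    if df[outcome].dtype == bool or df[outcome].dtype == object:
        df[outcome] = df[outcome].astype(float)
    terms = [score_name, *covariates]
    bare = [t[2:-1] if t.startswith("C(") else t for t in terms]
    used = df[[outcome, *bare]].dropna()
    return used, terms


def multivariate_logistic(table, score_name: str, outcome: str,
                          covariates: tuple[str, ...] = DEFAULT_COVARIATES) -> RegressionResult:
    """Covariate-adjusted logistic regression of a binary outcome on a score.

    Categorical covariates are dummy-coded against their first level.  A
    rank-deficient design raises :class:`RankDeficiencyError` naming the
    aliased columns; an ill-conditioned design (e.g. covariates that overlap
    the score's own components) attaches a condition-number warning.
    """
    df, terms = _adjusted_frame(table, score_name, outcome, covariates)
    if df[outcome].nunique() < 2:
        raise ValueError(f"outcome {outcome!r} is constant; cannot fit")
    y, x = _design_matrices(df, outcome, terms)
    _check_rank(x)
    warn = []
    cond = np.linalg.cond(x.to_numpy(dtype=float))
    if cond > 1e8:
        warn.append(f"ill-conditioned design (condition number {cond:.2e}); "
                    "covariates may overlap score components")
    fit = _fit_logit(sm.Logit(y.iloc[:, 0], x), score_name)
    return _logistic_result(fit, outcome, True, tuple(terms[1:]), len(df), warn)


def linear_panel(table, score_name: str, outcome: str, adjusted: bool = False,
                 covariates: tuple[str, ...] = DEFAULT_COVARIATES) -> RegressionResult:
    """OLS regression of a continuous outcome (Hb change, OT, PLOS) on a score.

    The adjusted variant uses the same ten-covariate set as the logistic
    models.  CI bounds are on the coefficient scale.
    """
    terms = [score_name, *(covariates if adjusted else ())]
    df, terms = _adjusted_frame(table, score_name, outcome, tuple(terms[1:])) if adjusted else (
        _as_df(table)[[outcome, score_name]].dropna(), [score_name])
    if len(df) <= len(terms) + 1:
        raise ValueError("not enough observations for the requested model")
    y, x = _design_matrices(df, outcome, terms)
    _check_rank(x)
    fit = sm.OLS(y.iloc[:, 0].astype(float), x).fit()
    conf = fit.conf_int(alpha=0.05)
    tab = pd.DataFrame({
        "B": fit.params,
        "odds_ratio": np.nan,
        "ci_low": conf[0],
        "ci_high": conf[1],
        "p_value": fit.pvalues,
    })
    return RegressionResult("linear", outcome, tab, len(df), adjusted,
                            tuple(terms[1:]), [])


def or_from_coefficient(b: float) -> float:
    """Odds ratio from a logistic coefficient: exp(B)."""
    if not math.isfinite(b):
        raise ValueError("coefficient must be finite")
    return math.exp(b)
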