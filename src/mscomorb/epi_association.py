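"""Prevalence, baseline comparisons and odds-ratio models.

Reproduces the structure of a population-based comorbidity comparison:
per-disease prevalence per 1000 in the MS and MS-free groups, chi-square /
one-way-ANOVA baseline contrasts, and logistic regression of each AID
flag on MS status adjusted for age (continuous), sex and the 5-year
all-cause hospitalization count (continuous).  Odds ratios carry Wald
95% confidence intervals, matching conventional epidemiological output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

__all__ = [
    "ContingencyTable2x2",
    "prevalence_per_1000",
    "crude_or",
    "fit_adjusted_logistic",
    "AdjustedModelResult",
    "baseline_tests",
    "association_analysis",
]

_Z975 = st.norm.ppf(0.975)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d) = (exposed-case, exposed-noncase, unexposed-case, unexposed-noncase)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} must be non-negative")

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, disease: str) -> "ContingencyTable2x2":
        """Exposure = MS flag, outcome = AID flag."""
        ms = cohort["ms_flag"].to_numpy(dtype=bool)
        aid = cohort[f"aid_{disease}"].to_numpy(dtype=bool)
        return cls(
            a=int((ms & aid).sum()),
            b=int((ms & ~aid).sum()),
            c=int((~ms & aid).sum()),
            d=int((~ms & ~aid).sum()),
        )


def prevalence_per_1000(case_count: int, population_count: int) -> float:
    """Cases per 1000 population; exact value (callers round for display)."""
    if population_count <= 0:
        raise ValueError("population_count must be positive")
    if not 0 <= case_count <= population_count:
        raise ValueError("case_count must lie in [0, population_count]")
    return 1000.0 * case_count / population_count


def crude_or(table: ContingencyTable2x2) -> dict:
    """Unadjusted odds ratio ad/bc with a Wald 95% CI on the log scale.

    When any cell is zero, the Haldane-Anscombe 0.5 continuity correction
    is applied to every cell and the result is flagged
    (``corrected=True``).  Two zero cells sharing a margin leave the OR
    undefined and raise.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    zero_margins = (
        (a == 0 and b == 0)
        or (c == 0 and d == 0)
        or (a == 0 and c == 0)
        or (b == 0 and d == 0)
    )
    if zero_margins:
        raise ValueError("odds ratio undefined: a full margin of the 2x2 table is zero")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return {
        "or": float(np.exp(log_or)),
        "ci_low": float(np.exp(log_or - _Z975 * se)),
        "ci_high": float(np.exp(log_or + _Z975 * se)),
        "log_or": float(log_or),
        "se_log_or": float(se),
        "corrected": corrected,
    }


@dataclass
class AdjustedModelResult:
    """Logistic-model summary for one disease.

    ``params`` holds per-covariate coefficient, standard error, OR and
    Wald 95% CI; ``or_ms`` is the exposure (MS) odds ratio.
    """

    params: pd.DataFrame
    converged: bool
    separation: bool
    n_obs: int

    @property
    def or_ms(self) -> float:
        return float(self.params.loc["ms", "or"])

    @property
    def ci_ms(self) -> tuple:
        row = self.params.loc["ms"]
        return float(row["ci_low"]), float(row["ci_high"])


def _design(cohort: pd.DataFrame, covariates: tuple) -> pd.DataFrame:
    X = pd.DataFrame(index=cohort.index)
    X["const"] = 1.0
    X["ms"] = cohort["ms_flag"].astype(float)
    if "age" in covariates:
        X["age"] = cohort["age_years"].astype(float)
    if "sex" in covariates:
        X["sex_female"] = (cohort["sex"] == "female").astype(float)
    if "hosp" in covariates:
        X["hosp"] = cohort["hosp_count_5y"].astype(float)
    return X


def fit_adjusted_logistic(
    cohort: pd.DataFrame,
    disease: str,
    covariates: tuple = ("age", "sex", "hosp"),
) -> AdjustedModelResult:
    """Logistic regression of one AID flag on MS status plus covariates.

    Fitted by Newton/IRLS; convergence tolerance 1e-10 on the objective,
    100 iterations.  Perfect separation and non-convergence are flagged
    on the result rather than silently reported.  With
    ``covariates=()`` the model is exposure-only and its MS odds ratio
    equals the crude 2x2 odds ratio exactly (closed-form equivalence).
    """
    y = cohort[f"aid_{disease}"].astype(float).to_numpy()
    X = _design(cohort, covariates)
    if len(y) <= X.shape[1]:
        raise ValueError("n_obs must exceed the number of parameters")

    separation = False
    converged = False
    params = None
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        warnings.simplefilter("ignore", sm.tools.sm_exceptions.ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            fit = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-10, disp=False)
            converged = bool(fit.mle_retvals.get("converged", False))
            coef = fit.params
            se = fit.bse
            params = pd.DataFrame(
                {
                    "coef": coef,
                    "se": se,
                    "or": np.exp(coef),
                    "ci_low": np.exp(coef - _Z975 * se),
                    "ci_high": np.exp(coef + _Z975 * se),
                }
            )
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning):
            separation = True
        except np.linalg.LinAlgError:
            # singular Hessian: quasi-separation / empty cells
            separation = True

    if params is None:
        params = pd.DataFrame(
            columns=["coef", "se", "or", "ci_low", "ci_high"],
            index=pd.Index(X.columns),
            dtype=float,
        )
    return AdjustedModelResult(
        params=params, converged=converged, separation=separation, n_obs=len(y)
    )


def baseline_tests(cohort: pd.DataFrame, disease: str) -> dict:
    """Baseline contrasts between MS and non-MS cases of one disease.

    Pearson chi-square (1 df, no continuity correction) for the sex
    split, and one-way ANOVA F tests for age and hospitalization counts.
    Degenerate inputs (an empty group, or zero variance in both groups)
    raise instead of returning NaN.
    """
    cases = cohort.loc[cohort[f"aid_{disease}"].astype(bool)]
    g_ms = cases.loc[cases["ms_flag"]]
    g_no = cases.loc[~cases["ms_flag"]]
    if len(g_ms) == 0 or len(g_no) == 0:
        raise ValueError(f"both MS and non-MS case groups required for {disease!r}")

    tab = np.array(
        [
            [(g_ms["sex"] == "female").sum(), (g_ms["sex"] == "male").sum()],
            [(g_no["sex"] == "female").sum(), (g_no["sex"] == "male").sum()],
        ]
    )
    if (tab.sum(axis=0) == 0).any():
        raise ValueError("degenerate sex table: one sex absent from both groups")
    chi2, p_sex, _, _ = st.chi2_contingency(tab, correction=False)

    out = {"chi2_p_sex": float(p_sex)}
    for label, col in (("anova_p_age", "age_years"), ("anova_p_discharges", "hosp_count_5y")):
        x, z = g_ms[col].to_numpy(float), g_no[col].to_numpy(float)
        if np.var(np.concatenate([x, z])) == 0:
            raise ValueError(f"zero variance in {col}; ANOVA undefined")
        _, p = st.f_oneway(x, z)
        out[label] = float(p)
    return out


def chi2_proportions(k1: int, n1: int, k2: int, n2: int) -> float:
    """Pearson chi-square p-value (no continuity correction) for two proportions."""
    tab = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    _, p, _, _ = st.chi2_contingency(tab, correction=False)
    return float(p)


def association_analysis(cohort: pd.DataFrame, diseases=None) -> pd.DataFrame:
    """Per-disease association table: prevalences, crude and adjusted ORs.

    Columns mirror a published comorbidity table: prevalence per 1000 in
    each group, the crude OR, the age/sex-adjusted OR and the fully
    (age/sex/hospitalizations) adjusted OR, each with a Wald 95% CI.
    """
    if diseases is None:
        diseases = [c[len("aid_"):] for c in cohort.columns if c.startswith("aid_")]
    n_ms = int(cohort["ms_flag"].sum())
    n_non = int((~cohort["ms_flag"].astype(bool)).sum())
    rows = []
    for d in diseases:
        tab = ContingencyTable2x2.from_cohort(cohort, d)
        row = {
            "disease": d,
            "n_ms_cases": tab.a,
            "n_non_ms_cases": tab.c,
            "prevalence_ms_per_1000": prevalence_per_1000(tab.a, n_ms),
            "prevalence_non_ms_per_1000": prevalence_per_1000(tab.c, n_non),
        }
        try:
            cr = crude_or(tab)
            row.update(crude_or_=cr["or"], crude_ci_low=cr["ci_low"], crude_ci_high=cr["ci_high"])
        except ValueError:
            row.update(crude_or_=np.nan, crude_ci_low=np.nan, crude_ci_high=np.nan)
        for label, covs in (
            ("age_sex", ("age", "sex")),
            ("age_sex_hosp", ("age", "sex", "hosp")),
        ):
            res = fit_adjusted_logistic(cohort, d, covariates=covs)
            if (
                res.separation
                or not res.converged
                or res.params.empty
                or np.isnan(res.params["coef"]).all()
                or not np.isfinite(res.params["se"]).all()
                or res.params.loc["ms", "se"] > 50  # quasi-separation
            ):
                row.update({f"or_{label}": np.nan, f"or_{label}_ci_low": np.nan, f"or_{label}_ci_high": np.nan})
            else:
                lo, hi = res.ci_ms
                row.update({f"or_{label}": res.or_ms, f"or_{label}_ci_low": lo, f"or_{label}_ci_high": hi})
        rows.append(row)
    out = pd.DataFrame(rows).set_index("disease")
    return out.rename(columns={"crude_or_": "crude_or"})
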