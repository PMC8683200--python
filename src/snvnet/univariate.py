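"""Univariate smoker vs ex-smoker association statistics.

Categorical exposures are summarized by 2x2 contingency tables oriented so
that an odds ratio above 1 means the exposure is associated with current
smoking: ``a`` = exposed smokers, ``b`` = unexposed smokers, ``c`` = exposed
ex-smokers, ``d`` = unexposed ex-smokers. Point odds ratios are the
cross-product ``ad/bc`` with a Woolf (log-OR) confidence interval,
``exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))``, with no continuity
correction by default (a Haldane-Anscombe 0.5 correction is available behind
a flag). Tests are Pearson chi-square (1 df, no Yates correction) or the
Fisher exact test when any expected cell count is below 5; continuous
covariates use the pooled-variance t-test when both groups look roughly
symmetric (|skew| < 1) and the Mann-Whitney U test otherwise.

Participants missing a given exposure are dropped from that exposure's table
only, so denominators differ across rows of the report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import OUTCOME_EX_SMOKER, OUTCOME_SMOKER, PhenotypeTable

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "build_contingency",
    "odds_ratio_ci",
    "chi_square_test",
    "fisher_exact_test",
    "two_group_continuous",
    "table1_report",
    "AUDIT_HAZARDOUS_CUTOFF",
]

#: AUDIT score at or above which alcohol use is classified hazardous.
AUDIT_HAZARDOUS_CUTOFF = 8


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure x outcome counts. a,b = smokers exposed/unexposed; c,d = ex-smokers."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError(f"cell counts must be non-negative integers, got {cell}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def swap_outcome(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)


@dataclass
class AssociationResult:
    """One row of the univariate report."""

    variable: str
    or_point: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    p_value: float = math.nan
    test_used: str = "not_applicable"
    n_smokers: int = 0
    n_exsmokers: int = 0
    #: (mean, sd) summaries for continuous variables, exposed/total counts for booleans
    smoker_summary: tuple = field(default=())
    exsmoker_summary: tuple = field(default=())
    flag: str = ""

    def to_record(self) -> dict:
        return {
            "variable": self.variable,
            "or": self.or_point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p_value,
            "test": self.test_used,
            "n_smokers": self.n_smokers,
            "n_exsmokers": self.n_exsmokers,
            "flag": self.flag,
        }


_DERIVED_EXPOSURES = {
    "hazardous_alcohol": lambda p: p.hazardous_alcohol(AUDIT_HAZARDOUS_CUTOFF),
    "male": lambda p: p.df["gender"].map({"male": True, "female": False}).astype("boolean"),
    "white": lambda p: p.df["race"].map({"white": True, "black": False}).astype("boolean"),
}


def _exposure_series(pheno: PhenotypeTable, exposure: str) -> pd.Series:
    if exposure in _DERIVED_EXPOSURES:
        return _DERIVED_EXPOSURES[exposure](pheno)
    if exposure not in pheno.df.columns:
        raise ValueError(f"unknown exposure {exposure!r}")
    col = pheno.df[exposure]
    if str(col.dtype) != "boolean":
        raise ValueError(
            f"exposure {exposure!r} is not boolean and has no derivation rule"
        )
    return col


def build_contingency(pheno: PhenotypeTable, exposure: str) -> ContingencyTable2x2:
    """2x2 table for a boolean (or derivable-boolean) exposure vs smoking status.

    Rows with a missing exposure are dropped from this table only.
    """
    exp = _exposure_series(pheno, exposure)
    smoker = pheno.df["outcome"] == OUTCOME_SMOKER
    keep = exp.notna()
    if not keep.any():
        raise ValueError(f"empty contingency table: all {exposure!r} values missing")
    exp_b = exp[keep].astype(bool).to_numpy()
    smoker_b = smoker[keep].to_numpy()
    return ContingencyTable2x2(
        a=int((exp_b & smoker_b).sum()),
        b=int((~exp_b & smoker_b).sum()),
        c=int((exp_b & ~smoker_b).sum()),
        d=int((~exp_b & ~smoker_b).sum()),
    )


def odds_ratio_ci(
    table: ContingencyTable2x2,
    level: float = 0.95,
    continuity: bool = False,
) -> AssociationResult:
    """Cross-product odds ratio with a Woolf confidence interval.

    Zero cells yield an infinite or undefined OR with an explanatory flag —
    never a silent correction. ``continuity=True`` applies the
    Haldane-Anscombe +0.5 to every cell.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if continuity:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    res = AssociationResult(
        variable="", n_smokers=table.a + table.b, n_exsmokers=table.c + table.d
    )
    if b == 0 and c == 0:
        res.or_point = math.nan
        res.flag = "undefined_or"
        return res
    if b == 0 or c == 0:
        res.or_point = math.inf
        res.flag = "infinite_or"
        return res
    res.or_point = (a * d) / (b * c)
    if a == 0 or d == 0:
        res.ci_low, res.ci_high = (0.0, math.inf)
        res.flag = "degenerate_ci"
        return res
    z = stats.norm.ppf(0.5 + level / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(res.or_point)
    res.ci_low = math.exp(log_or - z * se)
    res.ci_high = math.exp(log_or + z * se)
    return res


def chi_square_test(table: ContingencyTable2x2, correction: bool = False) -> float:
    """Pearson chi-square p-value (1 df); Yates correction off by default."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero marginal total")
    _, p, _, _ = stats.chi2_contingency(arr, correction=correction)
    return float(p)


def fisher_exact_test(table: ContingencyTable2x2, alternative: str = "two-sided") -> float:
    """Fisher exact p-value: sum of hypergeometric probabilities of tables
    (fixed margins) no more probable than the observed one."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0
    _, p = stats.fisher_exact(arr, alternative=alternative)
    return float(p)


def _expected_counts(table: ContingencyTable2x2) -> np.ndarray:
    arr = table.as_array()
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()


def choose_categorical_test(table: ContingencyTable2x2) -> str:
    """Fisher exact when any expected cell count is < 5, else chi-square."""
    if table.n == 0:
        return "fisher_exact"
    return "fisher_exact" if (_expected_counts(table) < 5).any() else "chi_square"


def two_group_continuous(
    values, groups, method: str | None = None
) -> tuple[float, tuple[float, float], tuple[float, float], str]:
    """Two-sided comparison of a continuous covariate between outcome groups.

    Returns ``(p, (mean1, sd1), (mean0, sd0), test_used)`` where group 1 is
    the smokers. ``method`` of None picks the t-test when |skew| < 1 in both
    groups and Mann-Whitney otherwise. The t-test pools variances; the
    Mann-Whitney test uses mid-ranks for ties and the normal approximation
    (no continuity correction) for n > 20, exact otherwise.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    x = values[groups == OUTCOME_SMOKER]
    y = values[groups == OUTCOME_EX_SMOKER]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 non-missing values per group")
    if method is None:
        method = (
            "t_test"
            if abs(stats.skew(x)) < 1 and abs(stats.skew(y)) < 1
            else "mann_whitney"
        )
    if method == "t_test":
        _, p = stats.ttest_ind(x, y, equal_var=True)
    elif method == "mann_whitney":
        mw_method = "asymptotic" if len(x) + len(y) > 20 else "exact"
        _, p = stats.mannwhitneyu(
            x, y, alternative="two-sided", method=mw_method, use_continuity=False
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    summ = lambda v: (float(np.mean(v)), float(np.std(v, ddof=1)))
    return float(p), summ(x), summ(y), method


def _categorical_row(pheno: PhenotypeTable, name: str, exposure: str) -> AssociationResult:
    table = build_contingency(pheno, exposure)
    res = odds_ratio_ci(table)
    res.variable = name
    res.test_used = choose_categorical_test(table)
    res.p_value = (
        fisher_exact_test(table)
        if res.test_used == "fisher_exact"
        else chi_square_test(table)
    )
    res.smoker_summary = (table.a, table.a + table.b)
    res.exsmoker_summary = (table.c, table.c + table.d)
    return res


def _continuous_row(pheno: PhenotypeTable, name: str, column: str) -> AssociationResult:
    p, s1, s0, test = two_group_continuous(
        pheno.df[column].to_numpy(float), pheno.df["outcome"].to_numpy()
    )
    vals = pheno.df[column]
    smoker = pheno.df["outcome"] == OUTCOME_SMOKER
    return AssociationResult(
        variable=name,
        p_value=p,
        test_used=test,
        n_smokers=int((vals.notna() & smoker).sum()),
        n_exsmokers=int((vals.notna() & ~smoker).sum()),
        smoker_summary=s1,
        exsmoker_summary=s0,
    )


def _education_row(pheno: PhenotypeTable) -> AssociationResult:
    df = pheno.df
    keep = df["education"].notna()
    if not keep.any():
        raise ValueError("empty contingency table: all education values missing")
    sub = df[keep]
    counts = pd.crosstab(sub["education"], sub["outcome"] == OUTCOME_SMOKER)
    arr = counts.to_numpy(dtype=float)
    _, p, _, _ = stats.chi2_contingency(arr, correction=False)
    smoker = sub["outcome"] == OUTCOME_SMOKER
    return AssociationResult(
        variable="education",
        p_value=float(p),
        test_used="chi_square",
        n_smokers=int(smoker.sum()),
        n_exsmokers=int((~smoker).sum()),
    )


def table1_report(pheno: PhenotypeTable) -> list[AssociationResult]:
    """Full univariate report: one association per behavioral characteristic.

    Rows: age, male gender, race (White vs Black among the two declared
    categories), Latino/a ethnicity, education (4 ordered levels), hazardous
    alcohol use (AUDIT >= 8), past-30-day marijuana use, past-30-day cocaine
    use, depression score (CESD-20), anxiety score (GAD-7).
    """
    if len(pheno) == 0:
        raise ValueError("empty phenotype table")
    if pheno.n_smokers == 0 or pheno.n_ex_smokers == 0:
        raise ValueError("both outcome groups must be present")
    rows = [
        _continuous_row(pheno, "age", "age"),
        _categorical_row(pheno, "male_gender", "male"),
        _categorical_row(pheno, "race_white", "white"),
        _categorical_row(pheno, "latino", "latino"),
        _education_row(pheno),
        _categorical_row(pheno, "hazardous_alcohol", "hazardous_alcohol"),
        _categorical_row(pheno, "marijuana_30d", "marijuana_30d"),
        _categorical_row(pheno, "cocaine_30d", "cocaine_30d"),
        _continuous_row(pheno, "depression_cesd", "cesd"),
        _continuous_row(pheno, "anxiety_gad7", "gad7"),
    ]
    return rows
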