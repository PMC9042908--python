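"""Two-group cohort statistics for the anti-VEGF visual-outcome analysis.

Implements the outcome grouping (>= 15 ETDRS-letter gain at 12 months), the
per-variable group comparison (chi-square for categorical, Mann-Whitney for
continuous), univariable and screened multivariable logistic regression with
Wald intervals, the baseline-SFCT linear regression on BCVA change, and the
ellipsoid-zone subgroup comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .morphometry import BiomarkerSet

__all__ = [
    "EyeRecord",
    "TwoByTwoTable",
    "LogisticResult",
    "ComparisonRow",
    "ComparisonReport",
    "CohortError",
    "IMPROVED",
    "NOT_IMPROVED",
    "CONTINUOUS_VARIABLES",
    "CATEGORICAL_VARIABLES",
    "classify_outcome",
    "chi_square_2x2",
    "mann_whitney",
    "cohort_to_frame",
    "compare_groups",
    "univariable_logistic",
    "logistic_from_table",
    "screen_and_fit_multivariable",
    "linear_regression_change",
    "ez_subgroup_change",
]

logger = logging.getLogger(__name__)

IMPROVED = "improved"
NOT_IMPROVED = "maintained_worse"

#: Letters gained at 12 months that count as clinically significant.
IMPROVEMENT_THRESHOLD_LETTERS = 15.0


class CohortError(ValueError):
    """Raised when a cohort analysis precondition is violated."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class EyeRecord:
    """One eye of the cohort: clinical fields, grades, flags, biomarkers.

    Missing values are ``None`` and are handled complete-case per analysis.
    Grades follow the study convention: 0 = intact or mild disruption,
    1 = severe disruption.
    """

    eye_id: str = ""
    age: float | None = None
    age_ge_55: bool | None = None
    sex: str | None = None  # "M" / "F"
    axial_length: float | None = None
    spherical_equivalent: float | None = None
    bcva_baseline: float | None = None
    bcva_12m: float | None = None
    sfct: float | None = None
    cft: float | None = None
    ez_grade: int | None = None
    elm_grade: int | None = None
    srf_present: bool | None = None
    morphology: str | None = None  # "medusa_seafan" / "tangled"
    branching: bool | None = None
    loops: bool | None = None
    dark_halo: bool | None = None
    n_injections: float | None = None
    biomarkers: BiomarkerSet | None = None
    outcome: str | None = None  # IMPROVED / NOT_IMPROVED

    def __post_init__(self) -> None:
        for name in ("bcva_baseline", "bcva_12m"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise CohortError(f"{name} must lie in [0, 100] letters, got {v}")
        for name in ("ez_grade", "elm_grade"):
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                raise CohortError(f"{name} must be 0 or 1, got {v}")
        for name in ("sfct", "cft"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise CohortError(f"{name} must be > 0, got {v}")
        if self.age is not None and self.age_ge_55 is None:
            self.age_ge_55 = self.age >= 55


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts (a, b; c, d): rows = outcome groups, columns = predictor levels."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise CohortError(f"cell {name} must be a non-negative integer")
        if self.total == 0:
            raise CohortError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return math.inf
        return self.a * self.d / (self.b * self.c)


@dataclass(frozen=True)
class LogisticResult:
    """Odds ratio with Wald 95% interval for one model term."""

    variable: str
    odds_ratio: float
    ci_low: float | None
    ci_high: float | None
    p_value: float
    coef: float
    se: float | None
    predictor_coding: str = ""
    separation: bool = False
    n: int = 0

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.odds_ratio <= self.ci_high):
                raise CohortError("CI must bracket the odds ratio")


@dataclass
class ComparisonRow:
    variable: str
    test: str  # "chi-square" / "mann-whitney" / "none"
    summary_improved: str
    summary_not_improved: str
    statistic: float | None
    p_value: float | None
    n_excluded: int = 0
    flag: str | None = None


@dataclass
class ComparisonReport:
    rows: list[ComparisonRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    def __getitem__(self, variable: str) -> ComparisonRow:
        for r in self.rows:
            if r.variable == variable:
                return r
        raise KeyError(variable)


# ---------------------------------------------------------------------------
# variable registry (the cohort column dictionary)
# ---------------------------------------------------------------------------

CONTINUOUS_VARIABLES: tuple[str, ...] = (
    "age",
    "axial_length",
    "spherical_equivalent",
    "bcva_baseline",
    "bcva_12m",
    "sfct",
    "cft",
    "cnv_size",
    "vessel_density",
    "vessel_length_density",
    "vessel_diameter_index",
    "vessel_tortuosity",
    "fractal_dimension",
    "lacunarity",
    "n_injections",
)

CATEGORICAL_VARIABLES: tuple[str, ...] = (
    "age_ge_55",
    "sex",
    "ez_grade",
    "elm_grade",
    "srf_present",
    "morphology",
    "branching",
    "loops",
    "dark_halo",
)

#: Coding that makes each binary predictor's OR match the study's direction:
#: the listed level is coded 1.
PREDICTOR_CODING: dict[str, tuple[str, object]] = {
    "age_lt_55": ("age < 55 years = 1", None),
    "ez_grade": ("EZ grade 0 = 1", 0),
    "elm_grade": ("ELM grade 0 = 1", 0),
    "srf_present": ("subretinal fluid absent = 1", False),
    "morphology": ("medusa/sea-fan = 1", "medusa_seafan"),
    "branching": ("branching vessels present = 1", True),
    "loops": ("anastomotic loops present = 1", True),
    "dark_halo": ("dark halo present = 1", True),
    "sex": ("male = 1", "M"),
}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def classify_outcome(bcva_baseline: float, bcva_12m: float) -> str:
    """Group an eye by 12-month letter gain (boundary 15 letters inclusive)."""
    for name, v in (("bcva_baseline", bcva_baseline), ("bcva_12m", bcva_12m)):
        if v is None:
            raise CohortError(f"{name} is missing")
        if not (0.0 <= v <= 100.0):
            raise CohortError(f"{name} must lie in [0, 100] letters, got {v}")
    gain = bcva_12m - bcva_baseline
    return IMPROVED if gain >= IMPROVEMENT_THRESHOLD_LETTERS else NOT_IMPROVED


def chi_square_2x2(table: TwoByTwoTable) -> tuple[float, float]:
    """Pearson chi-square without continuity correction, 1 df, two-sided."""
    r1, r2, c1, c2 = table.margins
    for name, m in zip(("row1", "row2", "col1", "col2"), (r1, r2, c1, c2)):
        if m == 0:
            raise CohortError(f"margin {name} is zero; chi-square undefined")
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_n: int = 12,
    use_continuity: bool = False,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when n1 + n2 <= ``exact_max_n`` and there are no ties;
    otherwise the tie-corrected normal approximation (no continuity
    correction by default).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise CohortError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        # fully tied: tie-corrected variance is zero; no evidence either way
        return float(x.size * y.size / 2), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=use_continuity
    )
    return float(res.statistic), float(res.pvalue)


def cohort_to_frame(cohort: Iterable[EyeRecord]) -> pd.DataFrame:
    """Flatten records (including nested biomarkers) into one DataFrame."""
    rows = []
    for rec in cohort:
        row = {k: v for k, v in rec.__dict__.items() if k != "biomarkers"}
        if rec.biomarkers is not None:
            row.update(rec.biomarkers.to_dict())
        if row.get("outcome") is None and (
            rec.bcva_baseline is not None and rec.bcva_12m is not None
        ):
            row["outcome"] = classify_outcome(rec.bcva_baseline, rec.bcva_12m)
        rows.append(row)
    return pd.DataFrame(rows)


def _split_groups(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    if "outcome" not in frame.columns:
        raise CohortError("cohort has no outcome column")
    g1 = frame[frame["outcome"] == IMPROVED]
    g2 = frame[frame["outcome"] == NOT_IMPROVED]
    if len(g1) == 0 or len(g2) == 0:
        raise CohortError("both outcome groups must be non-empty")
    return g1, g2


def _binary_series(values: pd.Series, variable: str) -> pd.Series:
    """Map a categorical column onto {0, 1} using the registry coding."""
    if variable in PREDICTOR_CODING:
        _, level1 = PREDICTOR_CODING[variable]
        return (values == level1).astype(int)
    uniq = sorted(values.dropna().unique(), key=str)
    if len(uniq) > 2:
        raise CohortError(f"{variable} has more than two levels")
    return (values == uniq[-1]).astype(int)


def compare_groups(cohort: Sequence[EyeRecord] | pd.DataFrame) -> ComparisonReport:
    """Per-variable comparison of the two outcome groups.

    Continuous variables are summarized mean +/- SD and tested by
    Mann-Whitney; categorical variables are counted and tested by Pearson
    chi-square.  Variables constant across both groups are flagged and left
    untested; missing values are dropped per variable with the exclusion
    count recorded.
    """
    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    g1, g2 = _split_groups(frame)
    report = ComparisonReport()

    for var in CONTINUOUS_VARIABLES:
        if var not in frame.columns:
            continue
        x = pd.to_numeric(g1[var], errors="coerce").dropna()
        y = pd.to_numeric(g2[var], errors="coerce").dropna()
        n_excl = (len(g1) - len(x)) + (len(g2) - len(y))
        s1 = f"{x.mean():.2f} ± {x.std(ddof=1):.2f}" if len(x) else "n/a"
        s2 = f"{y.mean():.2f} ± {y.std(ddof=1):.2f}" if len(y) else "n/a"
        row = ComparisonRow(var, "mann-whitney", s1, s2, None, None, n_excl)
        if len(x) == 0 or len(y) == 0:
            row.test, row.flag = "none", "empty group after exclusions"
        elif pd.concat([x, y]).nunique() == 1:
            row.test, row.flag = "none", "constant in both groups"
        else:
            row.statistic, row.p_value = mann_whitney(x.to_numpy(), y.to_numpy())
        report.rows.append(row)

    for var in CATEGORICAL_VARIABLES:
        if var not in frame.columns:
            continue
        x = g1[var].dropna()
        y = g2[var].dropna()
        n_excl = (len(g1) - len(x)) + (len(g2) - len(y))
        if len(x) == 0 or len(y) == 0:
            report.rows.append(
                ComparisonRow(var, "none", "n/a", "n/a", None, None, n_excl,
                              "empty group after exclusions")
            )
            continue
        bx = _binary_series(x, var)
        by = _binary_series(y, var)
        s1 = f"{int(bx.sum())}/{len(bx)}"
        s2 = f"{int(by.sum())}/{len(by)}"
        row = ComparisonRow(var, "chi-square", s1, s2, None, None, n_excl)
        table_counts = (
            int(bx.sum()), int((1 - bx).sum()), int(by.sum()), int((1 - by).sum())
        )
        t = TwoByTwoTable(*table_counts)
        if min(t.margins) == 0:
            row.test, row.flag = "none", "constant in both groups"
        else:
            row.statistic, row.p_value = chi_square_2x2(t)
        report.rows.append(row)

    for row in report.rows:
        if row.n_excluded:
            logger.info("compare_groups: %s excluded %d record(s) with missing data",
                        row.variable, row.n_excluded)
    return report


def _fit_logit(y: np.ndarray, X: np.ndarray) -> sm.Logit:
    model = sm.Logit(y, X)
    return model.fit(disp=0, method="newton", tol=1e-8, maxiter=100)


def _predictor_column(frame: pd.DataFrame, variable: str) -> tuple[pd.Series, str]:
    """Numeric predictor column plus a human-readable coding description."""
    if variable == "age_lt_55":
        col = (~frame["age_ge_55"].astype("boolean")).astype("Int64")
        return col.astype(float), PREDICTOR_CODING["age_lt_55"][0]
    values = frame[variable]
    if variable in CONTINUOUS_VARIABLES:
        return pd.to_numeric(values, errors="coerce"), f"{variable} per unit"
    coding = PREDICTOR_CODING.get(variable, (f"{variable} coded by level", None))[0]
    _, level1 = PREDICTOR_CODING.get(variable, (None, None))
    if level1 is not None:
        return (values == level1).astype(float).where(values.notna()), coding
    return _binary_series(values, variable).astype(float).where(values.notna()), coding


def univariable_logistic(
    cohort: Sequence[EyeRecord] | pd.DataFrame,
    variable: str,
) -> LogisticResult:
    """Single-predictor logistic regression of improved-vs-not.

    For a binary predictor with all four 2x2 cells positive the ML odds
    ratio equals the cross-product ratio ad/bc and the Wald standard error
    equals sqrt(sum of reciprocal cells).  Separation (a zero cell) is
    flagged and no Wald interval is reported.
    """
    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    if "outcome" not in frame.columns:
        raise CohortError("cohort has no outcome column")
    x, coding = _predictor_column(frame, variable)
    y = (frame["outcome"] == IMPROVED).astype(float)
    keep = x.notna() & frame["outcome"].notna()
    x, y = x[keep].to_numpy(dtype=float), y[keep].to_numpy()
    if np.unique(y).size < 2:
        raise CohortError("outcome is constant; logistic model undefined")
    if np.unique(x).size < 2:
        raise CohortError(f"predictor {variable} is constant")

    is_binary = set(np.unique(x)) <= {0.0, 1.0}
    if is_binary:
        a = int(((y == 1) & (x == 1)).sum())
        b = int(((y == 1) & (x == 0)).sum())
        c = int(((y == 0) & (x == 1)).sum())
        d = int(((y == 0) & (x == 0)).sum())
        if min(a, b, c, d) == 0:
            logger.warning("separation for %s: cells (%d,%d,%d,%d)", variable, a, b, c, d)
            coef = math.inf if (b == 0 or c == 0) else -math.inf
            return LogisticResult(
                variable=variable, odds_ratio=math.exp(coef) if math.isfinite(coef) else math.inf,
                ci_low=None, ci_high=None, p_value=1.0, coef=coef, se=None,
                predictor_coding=coding, separation=True, n=int(len(y)),
            )

    X = sm.add_constant(x)
    fit = _fit_logit(y, X)
    coef = float(fit.params[1])
    se = float(fit.bse[1])
    return LogisticResult(
        variable=variable,
        odds_ratio=math.exp(coef),
        ci_low=math.exp(coef - 1.96 * se),
        ci_high=math.exp(coef + 1.96 * se),
        p_value=float(fit.pvalues[1]),
        coef=coef,
        se=se,
        predictor_coding=coding,
        n=int(len(y)),
    )


def logistic_from_table(table: TwoByTwoTable, variable: str = "predictor") -> LogisticResult:
    """Univariable logistic fit reconstructed from 2x2 counts.

    Rows are outcome groups (improved first), columns predictor levels
    (coded-1 level first).
    """
    y = np.repeat([1.0, 1.0, 0.0, 0.0], [table.a, table.b, table.c, table.d])
    x = np.repeat([1.0, 0.0, 1.0, 0.0], [table.a, table.b, table.c, table.d])
    frame = pd.DataFrame({"outcome": np.where(y == 1, IMPROVED, NOT_IMPROVED), variable: x})
    # route through the generic fitter so the table path and cohort path agree
    frame[variable] = frame[variable].astype(float)
    res = univariable_logistic(frame, variable)
    return LogisticResult(
        variable=variable, odds_ratio=res.odds_ratio, ci_low=res.ci_low,
        ci_high=res.ci_high, p_value=res.p_value, coef=res.coef, se=res.se,
        predictor_coding="level-1 column first", separation=res.separation, n=res.n,
    )


def screen_and_fit_multivariable(
    cohort: Sequence[EyeRecord] | pd.DataFrame,
    variables: Sequence[str],
    entry_alpha: float = 0.1,
) -> tuple[list[LogisticResult], list[LogisticResult]]:
    """Univariable screen at ``entry_alpha`` then one joint logistic fit.

    Returns ``(univariable_results, multivariable_results)``; the second
    list is empty when no variable passes the screen.  Non-convergence of
    the joint fit raises with diagnostics.
    """
    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    uni: list[LogisticResult] = []
    for var in variables:
        try:
            uni.append(univariable_logistic(frame, var))
        except CohortError as exc:
            logger.warning("screening skipped %s: %s", var, exc)
    selected = [r for r in uni if not r.separation and r.p_value < entry_alpha]
    if not selected:
        logger.info("no variable passed screening at alpha=%s", entry_alpha)
        return uni, []

    cols = {}
    codings = {}
    for r in selected:
        col, coding = _predictor_column(frame, r.variable)
        cols[r.variable] = col
        codings[r.variable] = coding
    design = pd.DataFrame(cols)
    keep = design.notna().all(axis=1) & frame["outcome"].notna()
    design = design[keep]
    y = (frame.loc[keep, "outcome"] == IMPROVED).astype(float).to_numpy()
    X = sm.add_constant(design.to_numpy(dtype=float))
    fit = _fit_logit(y, X)
    if not fit.mle_retvals.get("converged", True):
        raise CohortError(
            f"multivariable fit did not converge: {fit.mle_retvals}"
        )
    multi = []
    for i, r in enumerate(selected, start=1):
        coef = float(fit.params[i])
        se = float(fit.bse[i])
        multi.append(
            LogisticResult(
                variable=r.variable,
                odds_ratio=math.exp(coef),
                ci_low=math.exp(coef - 1.96 * se),
                ci_high=math.exp(coef + 1.96 * se),
                p_value=float(fit.pvalues[i]),
                coef=coef,
                se=se,
                predictor_coding=codings[r.variable],
                n=int(len(y)),
            )
        )
    return uni, multi


def linear_regression_change(
    cohort: Sequence[EyeRecord] | pd.DataFrame,
    x: str = "sfct",
) -> tuple[float, float, float]:
    """OLS of (12-month BCVA - baseline BCVA) on ``x``.

    Returns ``(slope, pearson_r, two_sided_p)``.
    """
    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    sub = frame[[x, "bcva_baseline", "bcva_12m"]].dropna()
    if len(sub) < 3:
        raise CohortError("need at least 3 complete records")
    xv = sub[x].to_numpy(dtype=float)
    if np.unique(xv).size < 2:
        raise CohortError(f"{x} is constant")
    delta = sub["bcva_12m"].to_numpy(dtype=float) - sub["bcva_baseline"].to_numpy(dtype=float)
    res = stats.linregress(xv, delta)
    return float(res.slope), float(res.rvalue), float(res.pvalue)


def ez_subgroup_change(
    cohort: Sequence[EyeRecord] | pd.DataFrame,
) -> tuple[dict[int, dict[str, float]], float]:
    """Compare BCVA change between ellipsoid-zone grades by Mann-Whitney."""
    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    sub = frame[["ez_grade", "bcva_baseline", "bcva_12m"]].dropna()
    delta = sub["bcva_12m"] - sub["bcva_baseline"]
    groups = {}
    for grade in (0, 1):
        vals = delta[sub["ez_grade"] == grade]
        if len(vals) == 0:
            raise CohortError(f"ellipsoid-zone grade {grade} absent")
        groups[grade] = {
            "n": int(len(vals)),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
        }
    _, p = mann_whitney(
        delta[sub["ez_grade"] == 0].to_numpy(),
        delta[sub["ez_grade"] == 1].to_numpy(),
    )
    return groups, p
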