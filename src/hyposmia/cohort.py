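"""Core data model: subjects, cohorts, descriptive summaries and cohort comparisons.

A cohort is one row per patient: id, age at the olfaction test, gender,
disease duration (years, optional), the test taken (UPSIT40 or SS16) and the
raw integer score on that test's native scale.  After scale conversion every
subject additionally carries ``score_ss`` (0-16).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = [
    "id",
    "age_at_test",
    "gender",
    "disease_duration",
    "test_kind",
    "raw_score",
]

GENDERS = ("male", "female")
TEST_KINDS = ("UPSIT40", "SS16")
_SCALE_MAX = {"UPSIT40": 40, "SS16": 16}

AGE_RANGE = (18.0, 110.0)


class CohortValidationError(ValueError):
    """Raised when rows violate subject invariants; carries row diagnostics."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "invalid cohort rows:\n" + "\n".join(problems[:20])
            + ("" if len(problems) <= 20 else f"\n... and {len(problems) - 20} more")
        )


class CohortConfigError(ValueError):
    """Raised for structural problems (missing columns, bad dialect)."""


@dataclass(frozen=True)
class CohortDialect:
    """Column-name and category-spelling mapping for reading foreign CSV layouts.

    ``columns`` maps source column name -> canonical name; ``gender_map`` and
    ``test_kind_map`` map source category spellings to the canonical ones
    (``male``/``female``, ``UPSIT40``/``SS16``).
    """

    columns: dict = field(default_factory=dict)
    gender_map: dict = field(default_factory=dict)
    test_kind_map: dict = field(default_factory=dict)


def _validate_rows(df: pd.DataFrame) -> list[str]:
    problems = []
    for idx, row in df.iterrows():
        rid = row.get("id", idx)
        if row["gender"] not in GENDERS:
            problems.append(f"row {rid}: gender {row['gender']!r} not in {GENDERS}")
            continue
        if row["test_kind"] not in TEST_KINDS:
            problems.append(f"row {rid}: test_kind {row['test_kind']!r} not in {TEST_KINDS}")
            continue
        hi = _SCALE_MAX[row["test_kind"]]
        score = row["raw_score"]
        if not (float(score).is_integer() and 0 <= score <= hi):
            problems.append(
                f"row {rid}: raw_score {score} outside integer range 0..{hi} "
                f"for {row['test_kind']}"
            )
        age = row["age_at_test"]
        if not (AGE_RANGE[0] < age < AGE_RANGE[1]):
            problems.append(f"row {rid}: age_at_test {age} outside {AGE_RANGE}")
        dur = row["disease_duration"]
        if pd.notna(dur) and dur < 0:
            problems.append(f"row {rid}: disease_duration {dur} < 0")
    return problems


class Cohort:
    """Validated table of subjects (one row each).

    Thin wrapper over a pandas DataFrame; ``cohort.df`` exposes the table.
    Missing ``disease_duration`` is allowed and propagates as NaN into the
    models (which use complete cases and report the n actually fitted).
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise CohortConfigError(f"cohort missing required columns: {missing}")
        df = df.reset_index(drop=True).copy()
        df["age_at_test"] = df["age_at_test"].astype(float)
        df["disease_duration"] = pd.to_numeric(df["disease_duration"], errors="coerce")
        df["raw_score"] = df["raw_score"].astype(int)
        if validate:
            problems = _validate_rows(df)
            if problems:
                raise CohortValidationError(problems)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    def has_ss_scores(self) -> bool:
        return "score_ss" in self.df.columns and self.df["score_ss"].notna().all()


def read_cohort(path, dialect: CohortDialect | None = None) -> Cohort:
    """Read a cohort CSV, applying an optional column/category dialect."""
    df = pd.read_csv(path)
    if dialect is not None:
        df = df.rename(columns=dialect.columns)
        if dialect.gender_map and "gender" in df.columns:
            df["gender"] = df["gender"].map(lambda g: dialect.gender_map.get(g, g))
        if dialect.test_kind_map and "test_kind" in df.columns:
            df["test_kind"] = df["test_kind"].map(
                lambda t: dialect.test_kind_map.get(t, t)
            )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortConfigError(
            f"{path}: missing columns {missing}; check the dialect mapping"
        )
    return Cohort(df)


def write_cohort(cohort: Cohort, path) -> None:
    cols = REQUIRED_COLUMNS + [
        c for c in ("score_ss", "score_upsit") if c in cohort.df.columns
    ]
    cohort.df[cols].to_csv(path, index=False)


def summarize_cohort(cohort: Cohort) -> dict:
    """Descriptive summary in the style of a demographics table.

    Continuous variables as mean/SD (ddof=1), categorical as count/percent.
    """
    if cohort.n == 0:
        raise ValueError("cannot summarize an empty cohort")
    df = cohort.df
    out: dict = {"n": cohort.n}

    def mean_sd(x: pd.Series) -> dict:
        x = x.dropna()
        return {
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
            "n": int(len(x)),
        }

    out["age_at_test"] = mean_sd(df["age_at_test"])
    out["disease_duration"] = mean_sd(df["disease_duration"])
    n_male = int((df["gender"] == "male").sum())
    out["male"] = {"count": n_male, "percent": 100.0 * n_male / cohort.n}
    upsit = df.loc[df["test_kind"] == "UPSIT40", "raw_score"]
    if len(upsit):
        out["upsit_score"] = mean_sd(upsit.astype(float))
    ss_native = df.loc[df["test_kind"] == "SS16", "raw_score"]
    if len(ss_native):
        out["ss_score_native"] = mean_sd(ss_native.astype(float))
    if "score_ss" in df.columns:
        out["score_ss"] = mean_sd(df["score_ss"])
    return out


# Variable kind decides the two-sample test: t-test for continuous,
# chi-square for binary, Mann-Whitney for skewed clinical scales,
# Kruskal-Wallis for ordered grades.
VARIABLE_TESTS = {
    "age_at_test": "t",
    "disease_duration": "t",
    "raw_score": "t",
    "score_ss": "t",
    "score_upsit": "t",
    "gender": "chi2",
    "test_kind": "chi2",
    "moca": "mannwhitney",
    "updrs3": "mannwhitney",
    "hoehn_yahr": "mannwhitney",
    "method2_grade": "kruskal",
}


def compare_cohorts(a: Cohort, b: Cohort, variable: str, test: str | None = None):
    """Two-sided comparison of one variable between two cohorts.

    Returns ``(statistic, p_value)``.  The test is chosen by variable kind
    (independent-samples t-test, chi-square, Mann-Whitney or Kruskal-Wallis)
    unless overridden via ``test``.
    """
    if variable not in a.df.columns or variable not in b.df.columns:
        raise KeyError(f"variable {variable!r} not present in both cohorts")
    kind = test or VARIABLE_TESTS.get(variable)
    if kind is None:
        raise KeyError(f"no test registered for variable {variable!r}; pass test=")
    xa = a.df[variable].dropna()
    xb = b.df[variable].dropna()
    if kind == "t":
        res = stats.ttest_ind(xa.astype(float), xb.astype(float))
        return float(res.statistic), float(res.pvalue)
    if kind == "chi2":
        tab = pd.crosstab(
            np.r_[np.zeros(len(xa), int), np.ones(len(xb), int)],
            pd.concat([xa, xb]).to_numpy(),
        )
        if (tab.to_numpy().sum(axis=0) == 0).any() or tab.shape[1] < 2:
            # one category absent overall: no association testable
            return 0.0, 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy())
        return float(chi2), float(p)
    if kind == "mannwhitney":
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if kind == "kruskal":
        res = stats.kruskal(xa, xb)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test kind {kind!r}")
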