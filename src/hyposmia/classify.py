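"""The four published hyposmia definitions, per subject and per cohort.

All cut-offs are stated on the UPSIT (0-40) scale:

* Method 1 (age-corrected): hyposmic if score < 24 at age >= 60, < 29 under 60.
* Method 2 (gender-corrected, graded): ordinal grade from absolute score
  bands; males <19 anosmic, 19-25 severe, 26-29 moderate, 30-33 mild, else
  normosmic; females share the anosmic/severe bands, moderate 26-30, mild
  31-34.  Scores of exactly 34 (male) / 35 (female) fall between the quoted
  "mild" caps and the "above 34/35" normosmic floor; they are assigned
  normosmic, consistent with the mild caps.
* Method 3 (age- and gender-corrected): hyposmic if score at or below the
  15th-centile cut-off from a normative table, looked up by gender and age
  band.
* Method 4 (population centile): hyposmic if score at or below a fixed
  cut-off (27 as implemented in PREDICT-PD), or at or below an empirical
  within-cohort 15th-centile cut-off.

Subjects tested with Sniffin' Sticks are classified by converting the
cut-offs to the SS scale (the classified set is the image of the UPSIT-scale
set under the monotone conversion); alternatively their scores can be
back-converted to UPSIT units.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .conversion import ConversionTable, convert_cutoff


class HyposmiaGrade(IntEnum):
    """Ordered severity grades: normosmic < mild < moderate < severe < anosmic."""

    NORMOSMIC = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3
    ANOSMIC = 4


GRADE_NAMES = ["normosmic", "mild", "moderate", "severe", "anosmic"]

# Method 2 band upper bounds (inclusive, UPSIT units), most severe first.
_METHOD2_BANDS = {
    "male": [(18, HyposmiaGrade.ANOSMIC), (25, HyposmiaGrade.SEVERE),
             (29, HyposmiaGrade.MODERATE), (33, HyposmiaGrade.MILD)],
    "female": [(18, HyposmiaGrade.ANOSMIC), (25, HyposmiaGrade.SEVERE),
               (30, HyposmiaGrade.MODERATE), (34, HyposmiaGrade.MILD)],
}

METHOD1_CUTOFF_OLD = 24   # age >= 60: hyposmic if score < 24
METHOD1_CUTOFF_YOUNG = 29  # age < 60: hyposmic if score < 29
METHOD4_DEFAULT_CUTOFF = 27  # hyposmic if score <= 27


@dataclass(frozen=True)
class CutoffTable:
    """Gender x age-band -> integer UPSIT threshold (classify if score <= cutoff).

    Age bands are half-open [age_low, age_high).  Backing frame columns:
    gender, age_low, age_high, cutoff, scale.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"gender", "age_low", "age_high", "cutoff", "scale"}
        if not need <= set(self.df.columns):
            raise ValueError(f"cutoff table needs columns {sorted(need)}")

    def lookup(self, gender, age):
        """Vectorized cut-off lookup; raises naming any uncovered (gender, age)."""
        gender = np.atleast_1d(np.asarray(gender, dtype=object))
        age = np.atleast_1d(np.asarray(age, dtype=float))
        out = np.full(len(age), np.nan)
        for g in np.unique(gender):
            sub = self.df[self.df["gender"] == g]
            mask = gender == g
            lo = sub["age_low"].to_numpy(float)
            hi = sub["age_high"].to_numpy(float)
            cut = sub["cutoff"].to_numpy(float)
            for l, h, c in zip(lo, hi, cut):
                sel = mask & (age >= l) & (age < h)
                out[sel] = c
        if np.isnan(out).any():
            bad = [(str(g), float(a)) for g, a, o in zip(gender, age, out) if np.isnan(o)]
            raise LookupError(
                f"cutoff table does not cover (gender, age): {bad[:5]}"
                + ("" if len(bad) <= 5 else f" ... and {len(bad) - 5} more")
            )
        return out

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CutoffTable":
        return cls(pd.read_csv(path))


def classify_method1(age, score_upsit):
    """Age-corrected binary rule: below 24 at age >= 60, below 29 under 60."""
    age = np.asarray(age, dtype=float)
    score = np.asarray(score_upsit)
    thr = np.where(age >= 60, METHOD1_CUTOFF_OLD, METHOD1_CUTOFF_YOUNG)
    return score < thr


def classify_method2(gender, score_upsit):
    """Gender-corrected graded rule on absolute UPSIT values."""
    gender = np.atleast_1d(np.asarray(gender, dtype=object))
    score = np.atleast_1d(np.asarray(score_upsit))
    out = np.full(score.shape, int(HyposmiaGrade.NORMOSMIC))
    for g, bands in _METHOD2_BANDS.items():
        mask = gender == g
        assigned = np.zeros(score.shape, dtype=bool)
        for upper, grade in bands:
            sel = mask & ~assigned & (score <= upper)
            out[sel] = int(grade)
            assigned |= sel
    if np.isscalar(score_upsit):
        return HyposmiaGrade(int(out[0]))
    return out


def classify_method3(age, gender, score_upsit, cutoffs: CutoffTable):
    """Normative 15th-centile rule: hyposmic iff score at or below the
    gender/age cut-off (inclusive bound)."""
    cut = cutoffs.lookup(gender, age)
    score = np.atleast_1d(np.asarray(score_upsit))
    res = score <= cut
    return bool(res[0]) if np.isscalar(score_upsit) else res


def classify_method4(score_upsit, cutoff: int = METHOD4_DEFAULT_CUTOFF):
    """Fixed-threshold rule: hyposmic iff score at or below ``cutoff``."""
    score = np.asarray(score_upsit)
    return score <= cutoff


def empirical_centile_cutoff(scores, centile: float = 15.0) -> int:
    """Largest integer c with empirical P(score <= c) not exceeding centile %.

    Defines the within-cohort centile threshold (Method 4's empirical
    variant).  If even the minimum score is held by more than ``centile`` %
    of subjects, returns min(scores) - 1 so that nobody is classified.
    """
    scores = np.asarray(scores)
    if scores.size == 0:
        raise ValueError("empirical_centile_cutoff: empty score list")
    target = centile / 100.0
    lo = int(scores.min()) - 1
    best = lo
    for c in range(lo + 1, int(scores.max()) + 1):
        if np.mean(scores <= c) <= target:
            best = c
        else:
            break
    return best


def _grade_from_ss(gender, score_ss, table: ConversionTable):
    """Method 2 grades for SS-scale scores via converted band bounds."""
    gender = np.atleast_1d(np.asarray(gender, dtype=object))
    score = np.atleast_1d(np.asarray(score_ss, dtype=float))
    out = np.full(score.shape, int(HyposmiaGrade.NORMOSMIC))
    for g, bands in _METHOD2_BANDS.items():
        mask = gender == g
        assigned = np.zeros(score.shape, dtype=bool)
        for upper, grade in bands:
            thr = convert_cutoff(upper, table, "at_or_below")
            sel = mask & ~assigned & (score <= thr)
            out[sel] = int(grade)
            assigned |= sel
    return out


def classify_cohort(
    cohort,
    cutoffs: CutoffTable,
    conversion: ConversionTable | None = None,
    method4_cutoff: int = METHOD4_DEFAULT_CUTOFF,
    ss_strategy: str = "convert_cutoffs",
) -> pd.DataFrame:
    """Apply all four definitions to every subject.

    Returns a classification matrix indexed like the cohort with columns
    ``method1``, ``method2_grade``, ``method2_binary``, ``method3``,
    ``method4``.  UPSIT-tested subjects are classified natively; SS-tested
    subjects via converted cut-offs (default) or back-converted scores
    (``ss_strategy="back_convert_scores"``).
    """
    conversion = conversion or ConversionTable.default()
    df = cohort.df
    is_ss = (df["test_kind"] == "SS16").to_numpy()
    age = df["age_at_test"].to_numpy(float)
    gender = df["gender"].to_numpy(object)
    raw = df["raw_score"].to_numpy(int)

    if ss_strategy == "back_convert_scores":
        upsit_equiv = np.where(is_ss, conversion.to_upsit(np.where(is_ss, raw, 0)), raw)
        m1 = classify_method1(age, upsit_equiv)
        m2 = np.asarray(classify_method2(gender, upsit_equiv))
        m3 = classify_method3(age, gender, upsit_equiv, cutoffs)
        m4 = classify_method4(upsit_equiv, method4_cutoff)
    elif ss_strategy == "convert_cutoffs":
        m1 = np.empty(len(df), dtype=bool)
        m2 = np.empty(len(df), dtype=int)
        m3 = np.empty(len(df), dtype=bool)
        m4 = np.empty(len(df), dtype=bool)
        if (~is_ss).any():
            u = raw[~is_ss]
            m1[~is_ss] = classify_method1(age[~is_ss], u)
            m2[~is_ss] = np.asarray(classify_method2(gender[~is_ss], u))
            m3[~is_ss] = classify_method3(age[~is_ss], gender[~is_ss], u, cutoffs)
            m4[~is_ss] = classify_method4(u, method4_cutoff)
        if is_ss.any():
            s = raw[is_ss].astype(float)  # native SS score
            thr1 = np.where(
                age[is_ss] >= 60,
                convert_cutoff(METHOD1_CUTOFF_OLD, conversion, "below"),
                convert_cutoff(METHOD1_CUTOFF_YOUNG, conversion, "below"),
            )
            m1[is_ss] = s <= thr1
            m2[is_ss] = _grade_from_ss(gender[is_ss], s, conversion)
            cut3 = cutoffs.lookup(gender[is_ss], age[is_ss]).astype(int)
            m3[is_ss] = s <= conversion.to_ss(cut3)
            m4[is_ss] = s <= convert_cutoff(method4_cutoff, conversion, "at_or_below")
    else:
        raise ValueError(f"unknown ss_strategy {ss_strategy!r}")

    return pd.DataFrame(
        {
            "method1": m1,
            "method2_grade": m2,
            "method2_binary": m2 != int(HyposmiaGrade.NORMOSMIC),
            "method3": m3,
            "method4": m4,
        },
        index=df.index,
    )
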