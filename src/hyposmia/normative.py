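"""Synthetic-data engine: normative score model, smoothed centile cut-offs,
PD cohort generator and the counterfactual simulated-control procedure.

The patient-level data behind the original comparison are not public, so the
package ships a calibrated generator instead:

* ``NormativeModel`` is a parametric stand-in for published healthy-control
  UPSIT norms: a per-gender linear age trend with Gaussian residuals,
  discretized (round, clip to 0-40).  Healthy olfaction declines slowly with
  age and is slightly worse in men, which the defaults encode.
* ``derive_centile_cutoffs`` turns a normative reference sample into smoothed
  age/gender 15th-centile cut-offs (sliding age window, local-linear
  smoothing, floor to integer, isotonic non-increasing in age), emitted as
  5-year bands.
* ``generate_pd_cohort`` draws a PD cohort with a given demographic structure
  and a linear SS-scale score model in age, gender and disease duration.
* ``simulate_counterfactual`` asks what fraction of an observed cohort would
  be classified hyposmic if it did not have PD: each replicate redraws every
  subject's score from the normative model (keeping age and gender), applies
  all four classifiers, and the spread across replicates gives percentile
  ("empirical") confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .classify import (
    CutoffTable,
    GRADE_NAMES,
    METHOD4_DEFAULT_CUTOFF,
    HyposmiaGrade,
    empirical_centile_cutoff,
)
from .cohort import Cohort
from .conversion import ConversionTable

DEFAULT_SEED = 20210630


@dataclass(frozen=True)
class NormativeModel:
    """Per-gender linear-in-age healthy UPSIT score model.

    mean(age, gender) = intercept_at_50[gender] + slope * (age - 50);
    score = clip(round(mean + eps), 0, 40), eps ~ Normal(0, residual_sd).

    Defaults (configurable stand-ins, not published values): women score
    36.5 at age 50, men 1.5 points lower, both declining 0.10 points/year,
    residual SD 4.0.
    """

    intercept_female: float = 36.5  # UPSIT points at age 50
    intercept_male: float = 35.0
    age_slope: float = -0.10        # points per year
    residual_sd: float = 4.0

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")

    def mean(self, age, gender):
        age = np.asarray(age, dtype=float)
        gender = np.asarray(gender, dtype=object)
        icpt = np.where(gender == "male", self.intercept_male, self.intercept_female)
        return icpt + self.age_slope * (age - 50.0)

    def prob_at_or_below(self, cutoff, age, gender):
        """Exact P(discretized score <= cutoff) per subject.

        Rounding maps the latent normal x to round(x); clipping at 0 moves
        low mass up to 0 (still <= any cutoff >= 0), clipping at 40 moves
        high mass down to 40.  Hence for integer c in [0, 39]:
        P = Phi((c + 0.5 - mu) / sd); c >= 40 gives 1, c < 0 gives 0.
        """
        c = np.asarray(cutoff, dtype=float)
        mu = self.mean(age, gender)
        p = stats.norm.cdf((c + 0.5 - mu) / self.residual_sd)
        p = np.where(c >= 40, 1.0, p)
        p = np.where(c < 0, 0.0, p)
        return p


def sample_normative_scores(ages, genders, model: NormativeModel, seed=None, rng=None):
    """Integer healthy-control scores for given ages/genders; seeded."""
    rng = rng if rng is not None else np.random.default_rng(
        DEFAULT_SEED if seed is None else seed
    )
    mu = model.mean(ages, genders)
    x = mu + rng.normal(0.0, model.residual_sd, size=mu.shape)
    return np.clip(np.round(x), 0, 40).astype(int)


def sample_reference(
    n: int = 100_000,
    model: NormativeModel | None = None,
    age_range=(30.0, 95.0),
    male_fraction: float = 0.5,
    seed=None,
    rng=None,
) -> pd.DataFrame:
    """Normative reference sample (age, gender, score) for cut-off derivation.

    Ages uniform over ``age_range`` so every age band is equally supported.
    """
    model = model or NormativeModel()
    rng = rng if rng is not None else np.random.default_rng(
        DEFAULT_SEED if seed is None else seed
    )
    ages = rng.uniform(age_range[0], age_range[1], size=n)
    genders = np.where(rng.random(n) < male_fraction, "male", "female").astype(object)
    scores = sample_normative_scores(ages, genders, model, rng=rng)
    return pd.DataFrame({"age": ages, "gender": genders, "score": scores})


def derive_centile_cutoffs(
    reference: pd.DataFrame,
    centile: float = 15.0,
    window_halfwidth_years: float = 5.0,
    band_width_years: int = 5,
    min_window_n: int = 30,
) -> CutoffTable:
    """Smoothed age/gender centile cut-offs from a normative reference sample.

    Per gender and integer age: the empirical ``centile`` threshold of the
    scores within a +/- ``window_halfwidth_years`` sliding window (widened
    with a warning if it holds fewer than ``min_window_n`` points), smoothed
    by a local-linear (lowess) fit over age, floored to an integer threshold,
    then forced non-increasing in age.  The windowed threshold is the
    largest integer whose at-or-below fraction does not exceed the centile,
    so classification of draws from the reference distribution stays at or
    under ``centile`` percent.  Emitted as half-open ``band_width_years``-
    year bands on the UPSIT scale (classify if score <= cutoff).
    """
    for col in ("age", "gender", "score"):
        if col not in reference.columns:
            raise ValueError(f"reference sample missing column '{col}'")
    rows = []
    for g in ("male", "female"):
        sub = reference[reference["gender"] == g]
        if len(sub) < 500:
            raise ValueError(f"reference has only {len(sub)} rows for gender {g}; need >= 500")
        ages = sub["age"].to_numpy(float)
        scores = sub["score"].to_numpy(float)
        a_lo, a_hi = int(np.floor(ages.min())), int(np.ceil(ages.max()))
        grid = np.arange(a_lo, a_hi + 1)
        raw = np.empty(len(grid))
        for i, a in enumerate(grid):
            hw = window_halfwidth_years
            sel = np.abs(ages - a) <= hw
            while sel.sum() < min_window_n and hw < (a_hi - a_lo):
                hw += 1.0
                sel = np.abs(ages - a) <= hw
                warnings.warn(
                    f"sparse age window at {g} age {a}: widened to +/-{hw:g} years",
                    stacklevel=2,
                )
            raw[i] = empirical_centile_cutoff(scores[sel].astype(int), centile)
        smooth = lowess(raw, grid.astype(float), frac=0.4, it=0, return_sorted=False)
        # the windowed threshold is already integer-floored; after smoothing,
        # round to the nearest integer (flooring again would over-tighten)
        cut = np.round(smooth).astype(int)
        cut = np.minimum.accumulate(cut)  # non-increasing in age
        for lo in range(a_lo, a_hi + 1, band_width_years):
            hi = min(lo + band_width_years, a_hi + 1)
            mid = (lo + hi - 1) // 2
            rows.append(
                {
                    "gender": g,
                    "age_low": float(lo),
                    "age_high": float(lo + band_width_years),
                    "cutoff": int(cut[mid - a_lo]),
                    "scale": "UPSIT40",
                }
            )
    return CutoffTable(pd.DataFrame(rows))


@dataclass(frozen=True)
class PDGeneratorConfig:
    """Configuration of the synthetic PD cohort generator.

    Defaults emulate the Tracking Parkinson's structure: n=1674, age
    67.8 (9.2) years at test, 64.8% male, disease duration 1.9 (0.9) years,
    and an SS-scale (0-16) linear score model whose betas are the reported
    linear-regression effects (-0.09/year of age, -0.99 for male gender,
    -0.20/year of duration).  The intercept (14.52) and residual SD (2.84)
    are solved so the marginal SS score has mean 7.4 and SD 3.0 under that
    covariate structure.
    """

    n: int = 1674
    age_mean: float = 67.8
    age_sd: float = 9.2
    male_fraction: float = 0.648
    duration_mean: float = 1.9
    duration_sd: float = 0.9
    ss_intercept: float = 14.52
    beta_age: float = -0.09
    beta_male: float = -0.99
    beta_duration: float = -0.20
    residual_sd: float = 2.84
    ss_test_fraction: float = 0.27  # remainder take UPSIT
    age_bounds: tuple = (30.0, 95.0)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 <= self.male_fraction <= 1.0 and 0.0 <= self.ss_test_fraction <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.age_sd <= 0 or self.duration_sd <= 0 or self.residual_sd <= 0:
            raise ValueError("standard deviations must be > 0")


# PPMI-like structure: all UPSIT-tested, younger, shorter duration.  Betas are
# that cohort's reported linear effects; intercept (26.39) and residual SD
# (1.68) solved so converted SS has mean ~8.9 (UPSIT 22.3) and SD ~3.3 (8.2).
PPMI_CONFIG = PDGeneratorConfig(
    n=423,
    age_mean=61.6,
    age_sd=9.7,
    male_fraction=0.655,
    duration_mean=0.6,
    duration_sd=0.5,
    ss_intercept=26.39,
    beta_age=-0.26,
    beta_male=-2.61,
    beta_duration=0.42,
    residual_sd=1.68,
    ss_test_fraction=0.0,  # all UPSIT-tested
)


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_pd_cohort(
    config: PDGeneratorConfig | None = None,
    conversion: ConversionTable | None = None,
    rng=None,
) -> Cohort:
    """Draw a synthetic PD cohort under ``config``; reproducible under its seed.

    Ages are truncated normal on ``age_bounds``; durations truncated at 0;
    the continuous SS-scale score is linear in age, male gender and duration
    with Gaussian residuals, clipped to [0, 16].  A ``ss_test_fraction`` of
    subjects record a Sniffin' Sticks score (rounded); the rest record the
    UPSIT score whose conversion is nearest to their continuous SS value.
    """
    config = config or PDGeneratorConfig()
    conversion = conversion or ConversionTable.default()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n
    ages = _truncnorm(rng, config.age_mean, config.age_sd, *config.age_bounds, size=n)
    male = rng.random(n) < config.male_fraction
    dur = _truncnorm(rng, config.duration_mean, config.duration_sd, 0.0, np.inf, size=n)
    ss = (
        config.ss_intercept
        + config.beta_age * ages
        + config.beta_male * male
        + config.beta_duration * dur
        + rng.normal(0.0, config.residual_sd, size=n)
    )
    ss = np.clip(ss, 0.0, 16.0)
    is_ss = rng.random(n) < config.ss_test_fraction
    raw = np.where(
        is_ss,
        np.clip(np.round(ss), 0, 16).astype(int),
        conversion.nearest_upsit(ss),
    )
    df = pd.DataFrame(
        {
            "id": [f"S{i:05d}" for i in range(n)],
            "age_at_test": ages,
            "gender": np.where(male, "male", "female"),
            "disease_duration": dur,
            "test_kind": np.where(is_ss, "SS16", "UPSIT40"),
            "raw_score": raw,
        }
    )
    return Cohort(df)


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Percent classified hyposmic with a percentile ("empirical") 95% CI."""

    method: str
    stratum: str  # "male", "female" or "all"
    point: float  # percent
    ci_low: float
    ci_high: float
    replicates: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.point + 1e-9 and self.point <= self.ci_high + 1e-9):
            raise ValueError("CI must bracket the point estimate")


def _classify_score_matrix(scores, age, gender, cutoffs, method4_cutoff):
    """Binary/grade classifications for an (R, n) matrix of UPSIT scores."""
    thr1 = np.where(age >= 60, 24, 29)
    m1 = scores < thr1[None, :]
    grade = np.zeros(scores.shape, dtype=np.int8)
    for g in ("male", "female"):
        from .classify import _METHOD2_BANDS

        mask = (gender == g)[None, :]
        assigned = np.zeros(scores.shape, dtype=bool)
        for upper, gr in _METHOD2_BANDS[g]:
            sel = mask & ~assigned & (scores <= upper)
            grade[sel] = int(gr)
            assigned |= sel
    cut3 = cutoffs.lookup(gender, age)
    m3 = scores <= cut3[None, :]
    m4 = scores <= method4_cutoff
    return {"method1": m1, "method2_grade": grade, "method3": m3, "method4": m4}


def simulate_counterfactual(
    cohort: Cohort,
    model: NormativeModel | None = None,
    cutoffs: CutoffTable | None = None,
    replicates: int = 2000,
    seed=None,
    rng=None,
    method4_cutoff: int = METHOD4_DEFAULT_CUTOFF,
    include_grades: bool = True,
) -> list[PrevalenceEstimate]:
    """Counterfactual hyposmia prevalence if the cohort did not have PD.

    Each replicate draws one normative score per subject (keeping each
    subject's age and gender), classifies by all four methods, and records
    gender-stratified prevalences; the result per method and stratum is the
    mean and the 2.5th/97.5th percentile across replicates.
    """
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    model = model or NormativeModel()
    if cutoffs is None:
        ref = sample_reference(model=model, seed=seed)
        cutoffs = derive_centile_cutoffs(ref)
    if replicates < 100:
        warnings.warn(f"replicates={replicates} < 100: empirical CI will be unstable")
    rng = rng if rng is not None else np.random.default_rng(
        DEFAULT_SEED if seed is None else seed
    )
    age = cohort.df["age_at_test"].to_numpy(float)
    gender = cohort.df["gender"].to_numpy(object)
    n = cohort.n
    mu = model.mean(age, gender)
    x = mu[None, :] + rng.normal(0.0, model.residual_sd, size=(replicates, n))
    scores = np.clip(np.round(x), 0, 40).astype(np.int16)
    cls = _classify_score_matrix(scores, age, gender, cutoffs, method4_cutoff)

    strata = {
        "male": gender == "male",
        "female": gender == "female",
        "all": np.ones(n, dtype=bool),
    }
    outcomes = {
        "method1": cls["method1"],
        "method2_any": cls["method2_grade"] != int(HyposmiaGrade.NORMOSMIC),
        "method3": cls["method3"],
        "method4": cls["method4"],
    }
    if include_grades:
        for gr in (HyposmiaGrade.MILD, HyposmiaGrade.MODERATE,
                   HyposmiaGrade.SEVERE, HyposmiaGrade.ANOSMIC):
            outcomes[f"method2_{GRADE_NAMES[int(gr)]}"] = cls["method2_grade"] == int(gr)

    results = []
    for mname, mat in outcomes.items():
        for sname, smask in strata.items():
            if not smask.any():
                continue
            prev = 100.0 * mat[:, smask].mean(axis=1)
            results.append(
                PrevalenceEstimate(
                    method=mname,
                    stratum=sname,
                    point=float(prev.mean()),
                    ci_low=float(np.percentile(prev, 2.5)),
                    ci_high=float(np.percentile(prev, 97.5)),
                    replicates=replicates,
                )
            )
    return results


def expected_prevalence(
    cohort: Cohort,
    model: NormativeModel,
    cutoff,
) -> float:
    """Analytic counterfactual prevalence (percent) for an at-or-below rule.

    ``cutoff`` may be a scalar integer or a per-subject vector; the result is
    the mean over subjects of the exact discretized-normal mass at or below
    it — the closed-form limit the simulation converges to.
    """
    age = cohort.df["age_at_test"].to_numpy(float)
    gender = cohort.df["gender"].to_numpy(object)
    p = model.prob_at_or_below(cutoff, age, gender)
    return 100.0 * float(np.mean(p))


def prevalence_to_frame(estimates: list[PrevalenceEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "method": e.method,
                "stratum": e.stratum,
                "point": e.point,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "replicates": e.replicates,
            }
            for e in estimates
        ]
    )
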