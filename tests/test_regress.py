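import numpy as np
import pandas as pd
import pytest

from hyposmia import (
    Cohort,
    brant_test,
    classify_cohort,
    convert_scores,
    fit_binary_model,
    fit_linear_model,
    fit_ordered_model,
    generate_pd_cohort,
)
from hyposmia.normative import PDGeneratorConfig
from hyposmia.regress import METHOD_COVARIATES, ModelFitError, RegressionResult


@pytest.fixture(scope="module")
def classified(tracking_cohort, cutoffs, conversion):
    return classify_cohort(tracking_cohort, cutoffs, conversion)


def test_method_specific_covariate_sets(tracking_cohort, classified):
    """Each binary model adjusts only for what its definition does not
    already correct: Method 3 (age- and gender-corrected) keeps duration only."""
    for method, covs in METHOD_COVARIATES.items():
        res = fit_binary_model(tracking_cohort, classified, method)
        assert list(res.terms["term"]) == covs
    res3 = fit_binary_model(tracking_cohort, classified, 3)
    assert list(res3.terms["term"]) == ["disease_duration"]


def test_logistic_reports_or_scale(tracking_cohort, classified):
    res = fit_binary_model(tracking_cohort, classified, 4)
    assert (res.terms["estimate"] > 0).all()
    for _, row in res.terms.iterrows():
        assert row["ci_low"] <= row["estimate"] <= row["ci_high"]
    assert res.n <= tracking_cohort.n


def test_logistic_single_class_outcome_errors(tracking_cohort, classified):
    fake = classified.copy()
    fake["method4"] = True
    with pytest.raises(ModelFitError, match="single class"):
        fit_binary_model(tracking_cohort, fake, 4)


def test_zero_noise_linear_recovery(conversion):
    cfg = PDGeneratorConfig(n=800, residual_sd=1e-9, ss_test_fraction=1.0, seed=41)
    cohort = convert_scores(generate_pd_cohort(cfg), conversion)
    # raw SS scores are rounded to integers; refit on the exact linear part
    df = cohort.df
    exact = (cfg.ss_intercept + cfg.beta_age * df["age_at_test"]
             + cfg.beta_male * (df["gender"] == "male")
             + cfg.beta_duration * df["disease_duration"])
    cohort.df["score_ss"] = exact
    res = fit_linear_model(cohort)
    assert res.term("age_at_test")["estimate"] == pytest.approx(cfg.beta_age, abs=1e-8)
    assert res.term("gender_male")["estimate"] == pytest.approx(cfg.beta_male, abs=1e-8)
    assert res.term("disease_duration")["estimate"] == pytest.approx(
        cfg.beta_duration, abs=1e-8
    )


def test_linear_model_permutation_invariant(tracking_cohort):
    res1 = fit_linear_model(tracking_cohort)
    shuffled = Cohort(
        tracking_cohort.df.sample(frac=1.0, random_state=1).reset_index(drop=True)
    )
    res2 = fit_linear_model(shuffled)
    pd.testing.assert_frame_equal(res1.terms, res2.terms, atol=1e-10)


def test_linear_model_reports_residual_skewness(tracking_cohort):
    res = fit_linear_model(tracking_cohort)
    assert "residual_skewness" in res.diagnostics
    assert abs(res.diagnostics["residual_skewness"]) < 1.0  # near-normal residuals


def test_collinear_design_errors(tracking_cohort):
    cohort = Cohort(tracking_cohort.df.copy())
    cohort.df["disease_duration"] = 2.0 * cohort.df["age_at_test"]  # exact collinearity
    with pytest.raises(ModelFitError):
        fit_linear_model(cohort)


def test_null_logistic_covers_one(cutoffs, conversion):
    """Outcome independent of covariates: the OR CIs cover 1.0 at close to
    nominal rate across seeded replicates."""
    rng = np.random.default_rng(55)
    hits = 0
    runs = 30
    for _ in range(runs):
        cohort = generate_pd_cohort(
            PDGeneratorConfig(n=800, seed=int(rng.integers(2**31)))
        )
        matrix = classify_cohort(cohort, cutoffs, conversion)
        matrix["method4"] = rng.random(cohort.n) < 0.5  # sever the association
        res = fit_binary_model(cohort, matrix, 4)
        row = res.term("age_at_test")
        hits += row["ci_low"] <= 1.0 <= row["ci_high"]
    assert hits >= int(0.9 * runs)


def test_ordered_model_null_ors_near_one(tracking_cohort, classified):
    rng = np.random.default_rng(7)
    fake = classified.copy()
    fake["method2_grade"] = rng.integers(0, 5, len(fake))
    res = fit_ordered_model(tracking_cohort, fake)
    assert np.allclose(res.terms["estimate"], 1.0, atol=0.1)


def test_ordered_model_detects_strong_age_effect(tracking_cohort, classified):
    res = fit_ordered_model(tracking_cohort, classified)
    age = res.term("age_at_test")
    assert age["estimate"] > 1.0
    assert age["p"] < 1e-3
    assert res.diagnostics["levels"] == [0, 1, 2, 3, 4]


def test_ordered_model_too_few_levels_errors(tracking_cohort, classified):
    collapsed = classified.copy()
    collapsed["method2_grade"] = (collapsed["method2_grade"] > 0).astype(int)
    with pytest.raises(ModelFitError, match="3 grade levels"):
        fit_ordered_model(tracking_cohort, collapsed)


def _simulate_proportional_odds(n, rng, shift=0.0):
    """5-level ordinal outcome from a latent logistic regression; ``shift``
    adds a split-specific slope distortion when generating non-proportional
    data (applied to the top split only)."""
    x1 = np.clip(rng.normal(0, 1, n), -4, 4)
    x2 = np.clip(rng.normal(0, 1, n), -4, 4)
    latent = 0.8 * x1 + 0.5 * x2 + rng.logistic(0, 1, n)
    cuts = np.quantile(latent, [0.2, 0.4, 0.6, 0.8])
    y = np.digitize(latent, cuts)
    if shift:
        top = rng.logistic(0, 1, n) < (shift * x1)
        y = np.where((y == 3) & top, 4, y)
    return pd.DataFrame({"y": y, "x1": x1, "x2": x2})


def _ordered_fit_from(df):
    cohort = Cohort(pd.DataFrame({
        "id": [str(i) for i in range(len(df))],
        "age_at_test": 60.0 + df["x1"],       # covariate 1
        "disease_duration": 6.0 + df["x2"],    # covariate 2 (kept positive)
        "gender": "male",
        "test_kind": "UPSIT40",
        "raw_score": 20,
    }))
    matrix = pd.DataFrame({"method2_grade": df["y"].to_numpy()})
    return fit_ordered_model(cohort, matrix)


def test_brant_df_hand_count():
    """5 outcome levels x 2 covariates: (J-2)*p = 3*2 = 6 degrees of freedom."""
    rng = np.random.default_rng(9)
    res = _ordered_fit_from(_simulate_proportional_odds(1200, rng))
    assert res.diagnostics["brant_df"] == 6


def test_brant_power_against_nonproportional_slopes():
    """Split-specific slope distortion is detected most of the time."""
    rng = np.random.default_rng(10)
    rejections = 0
    runs = 10
    for _ in range(runs):
        res = _ordered_fit_from(_simulate_proportional_odds(1000, rng, shift=1.5))
        if res.diagnostics["brant_p"] < 0.05:
            rejections += 1
    assert rejections >= int(0.8 * runs)


def test_brant_requires_ordered_fit_context():
    res = RegressionResult(kind="linear", outcome="x", terms=pd.DataFrame(), n=0)
    with pytest.raises(ValueError):
        brant_test(res)


def test_latent_linear_grades_satisfy_proportional_odds(tracking_cohort, classified):
    """Grades generated from a single latent linear score satisfy the
    parallel-regression assumption, so the Brant test does not reject."""
    res = fit_ordered_model(tracking_cohort, classified)
    assert res.diagnostics["brant_p"] > 0.05


def test_dichotomization_loses_power_for_duration(cutoffs, conversion):
    """With the same generated duration effect, the continuous-outcome model
    yields a smaller duration p-value than the binary models in most runs."""
    runs = 20
    wins = {m: 0 for m in (1, 2, 3, 4)}
    for seed in range(200, 200 + runs):
        cohort = convert_scores(
            generate_pd_cohort(PDGeneratorConfig(n=1674, seed=seed)), conversion
        )
        matrix = classify_cohort(cohort, cutoffs, conversion)
        p_linear = fit_linear_model(cohort).term("disease_duration")["p"]
        for m in wins:
            p_binary = fit_binary_model(cohort, matrix, m).term("disease_duration")["p"]
            wins[m] += p_linear <= p_binary
    for m, w in wins.items():
        assert w >= int(0.7 * runs), (m, w)


def test_logistic_log_or_bias_small_at_large_n():
    """Bias of the log-OR estimator under the default age effect is < 0.02
    at n = 10,000 (averaged over seeded fits)."""
    import statsmodels.api as sm
    from scipy.special import expit

    beta = np.log(1.06)
    rng = np.random.default_rng(77)
    ests = []
    for _ in range(30):
        ages = rng.normal(67.8, 9.2, 10_000)
        p = expit(np.log(0.7 / 0.3) + beta * (ages - 67.8))
        y = (rng.random(10_000) < p).astype(float)
        fit = sm.Logit(y, sm.add_constant(ages)).fit(disp=0)
        ests.append(fit.params[1])
    assert abs(np.mean(ests) - beta) < 0.02
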