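import numpy as np
import pandas as pd
import pytest

from hyposmia import (
    Cohort,
    NormativeModel,
    PDGeneratorConfig,
    derive_centile_cutoffs,
    expected_prevalence,
    generate_pd_cohort,
    sample_normative_scores,
    sample_reference,
    simulate_counterfactual,
    summarize_cohort,
    convert_scores,
    classify_cohort,
)
from hyposmia.normative import PPMI_CONFIG, prevalence_to_frame


def _ages_genders(n, rng):
    return rng.uniform(40, 90, n), np.where(rng.random(n) < 0.5, "male", "female").astype(object)


def test_degenerate_model_all_scores_at_ceiling():
    model = NormativeModel(intercept_female=45.0, intercept_male=45.0,
                           age_slope=0.0, residual_sd=1e-9)
    scores = sample_normative_scores([60.0, 80.0], ["male", "female"], model, seed=0)
    assert np.array_equal(scores, [40, 40])


def test_same_seed_reproducible(normative_model):
    rng = np.random.default_rng(5)
    ages, genders = _ages_genders(100, rng)
    a = sample_normative_scores(ages, genders, normative_model, seed=9)
    b = sample_normative_scores(ages, genders, normative_model, seed=9)
    assert np.array_equal(a, b)


def test_sampled_mean_matches_exhaustive_summation_oracle(normative_model):
    """Empirical mean of 1e5 male draws at age 70 within 0.1 of the exact
    mean of the rounded/clipped normal, computed by summing c * P(score=c)
    over the 41 support points."""
    n = 100_000
    scores = sample_normative_scores(
        np.full(n, 70.0), np.full(n, "male", dtype=object), normative_model, seed=21
    )
    c = np.arange(41)
    cdf = normative_model.prob_at_or_below(c, np.full(41, 70.0),
                                           np.full(41, "male", dtype=object))
    pmf = np.diff(np.concatenate([[0.0], cdf]))
    exact_mean = float(np.sum(c * pmf))
    assert pmf.sum() == pytest.approx(1.0, abs=1e-9)
    assert scores.mean() == pytest.approx(exact_mean, abs=0.1)


def test_flat_reference_gives_marginal_centile_cutoff():
    """If score is independent of age, the derived cut-off is flat and equals
    the marginal threshold (largest value with at-or-below mass <= 15%)."""
    rng = np.random.default_rng(2)
    n = 20_000
    ages = rng.uniform(40, 80, n)
    scores = rng.integers(0, 41, n)  # uniform, ageless
    ref = pd.DataFrame({"age": ages, "gender": "male", "score": scores})
    ref = pd.concat([ref, ref.assign(gender="female")], ignore_index=True)
    table = derive_centile_cutoffs(ref)
    from hyposmia import empirical_centile_cutoff

    marginal = empirical_centile_cutoff(scores, 15)
    assert set(table.df["cutoff"]) <= {marginal, marginal - 1, marginal + 1}
    # flat trend: every band within one integer of the marginal threshold
    assert table.df["cutoff"].nunique() <= 2


def test_decreasing_scores_give_nonincreasing_cutoffs(reference, cutoffs):
    for g in ("male", "female"):
        sub = cutoffs.df[cutoffs.df["gender"] == g].sort_values("age_low")
        assert np.all(np.diff(sub["cutoff"].to_numpy()) <= 0)


def test_fresh_draws_classified_between_10_and_15_percent(normative_model, cutoffs):
    """By construction the smoothed 15th-centile cut-offs classify between
    10% and 15% of fresh draws from the same model, per gender."""
    fresh = sample_reference(n=200_000, model=normative_model, seed=77)
    for g in ("male", "female"):
        sub = fresh[fresh["gender"] == g]
        cut = cutoffs.lookup(sub["gender"], sub["age"])
        frac = float(np.mean(sub["score"].to_numpy() <= cut))
        assert 0.10 <= frac <= 0.15, (g, frac)


def test_sparse_window_widens_with_warning(normative_model):
    ref = sample_reference(n=1500, model=normative_model, seed=3, age_range=(50, 70))
    with pytest.warns(UserWarning, match="widened"):
        derive_centile_cutoffs(ref, min_window_n=200)


def test_generator_zero_noise_recovers_intercept():
    cfg = PDGeneratorConfig(n=200, beta_age=0.0, beta_male=0.0, beta_duration=0.0,
                            ss_intercept=9.0, residual_sd=1e-12, ss_test_fraction=1.0,
                            seed=4)
    cohort = generate_pd_cohort(cfg)
    assert np.array_equal(cohort.df["raw_score"].to_numpy(), np.full(200, 9))


def test_generator_infeasible_config_errors():
    with pytest.raises(ValueError):
        PDGeneratorConfig(n=0)
    with pytest.raises(ValueError):
        PDGeneratorConfig(age_sd=-1.0)
    with pytest.raises(ValueError):
        PDGeneratorConfig(male_fraction=1.5)


def test_generator_matches_score_targets(tracking_cohort):
    """Tracking defaults: mean SS score within 0.3 of 7.4 (the emulated
    cohort's mean), mean age within 0.5 of 67.8."""
    s = summarize_cohort(tracking_cohort)
    assert s["score_ss"]["mean"] == pytest.approx(7.4, abs=0.3)
    assert s["age_at_test"]["mean"] == pytest.approx(67.8, abs=0.5)


def test_ss_test_fraction_assignment(tracking_cohort):
    frac = float((tracking_cohort.df["test_kind"] == "SS16").mean())
    assert frac == pytest.approx(0.27, abs=0.04)


def _male_cohort(n=300, seed=8):
    rng = np.random.default_rng(seed)
    return Cohort(pd.DataFrame({
        "id": [f"m{i}" for i in range(n)],
        "age_at_test": rng.uniform(50, 85, n),
        "gender": "male",
        "disease_duration": 1.0,
        "test_kind": "UPSIT40",
        "raw_score": 20,
    }))


def test_counterfactual_ceiling_model_gives_zero_prevalence(cutoffs):
    model = NormativeModel(intercept_female=60.0, intercept_male=60.0,
                           age_slope=0.0, residual_sd=1e-9)
    res = simulate_counterfactual(_male_cohort(), model, cutoffs,
                                  replicates=200, seed=1)
    for e in res:
        assert e.point == 0.0
        assert e.ci_low == 0.0 and e.ci_high == 0.0


def test_counterfactual_converges_to_analytic_oracle(normative_model, cutoffs):
    """Simulated Method-3 prevalence converges to the exact expectation from
    per-subject discretized-normal summation (within 3 Monte-Carlo SEs)."""
    cohort = _male_cohort(n=500, seed=12)
    R = 2000
    res = simulate_counterfactual(cohort, normative_model, cutoffs,
                                  replicates=R, seed=13, include_grades=False)
    (m3,) = [e for e in res if e.method == "method3" and e.stratum == "male"]
    cut = cutoffs.lookup(cohort.df["gender"], cohort.df["age_at_test"])
    exact = expected_prevalence(cohort, normative_model, cut)
    p = exact / 100.0
    mc_se = 100.0 * np.sqrt(p * (1 - p) / (R * cohort.n))
    assert abs(m3.point - exact) < 3 * mc_se


def test_counterfactual_point_stable_when_doubling_replicates(normative_model, cutoffs):
    cohort = _male_cohort(n=400, seed=14)
    r1 = simulate_counterfactual(cohort, normative_model, cutoffs,
                                 replicates=1000, seed=15, include_grades=False)
    r2 = simulate_counterfactual(cohort, normative_model, cutoffs,
                                 replicates=2000, seed=16, include_grades=False)
    get = lambda res: next(e.point for e in res
                           if e.method == "method3" and e.stratum == "male")
    cut = cutoffs.lookup(cohort.df["gender"], cohort.df["age_at_test"])
    exact = expected_prevalence(cohort, normative_model, cut)
    p = exact / 100.0
    se1 = 100.0 * np.sqrt(p * (1 - p) / (1000 * cohort.n))
    assert abs(get(r1) - get(r2)) < 6 * se1


def test_counterfactual_low_replicates_warns(normative_model, cutoffs):
    with pytest.warns(UserWarning, match="unstable"):
        simulate_counterfactual(_male_cohort(100, 17), normative_model, cutoffs,
                                replicates=50, seed=18, include_grades=False)


def test_counterfactual_bit_reproducible(normative_model, cutoffs):
    cohort = _male_cohort(n=200, seed=19)
    a = simulate_counterfactual(cohort, normative_model, cutoffs,
                                replicates=300, seed=20, include_grades=False)
    b = simulate_counterfactual(cohort, normative_model, cutoffs,
                                replicates=300, seed=20, include_grades=False)
    assert prevalence_to_frame(a).equals(prevalence_to_frame(b))


def test_pd_prevalence_exceeds_counterfactual_every_method(
    tracking_cohort, normative_model, cutoffs, conversion
):
    """PD cases are classified hyposmic more often than their simulated
    healthy counterparts under every method (directional contrast)."""
    matrix = classify_cohort(tracking_cohort, cutoffs, conversion)
    cf = prevalence_to_frame(
        simulate_counterfactual(tracking_cohort, normative_model, cutoffs,
                                replicates=300, seed=22, include_grades=False)
    )
    pd_prev = {
        "method1": 100 * matrix["method1"].mean(),
        "method2_any": 100 * matrix["method2_binary"].mean(),
        "method3": 100 * matrix["method3"].mean(),
        "method4": 100 * matrix["method4"].mean(),
    }
    for method, prev in pd_prev.items():
        ctl = cf[(cf["method"] == method) & (cf["stratum"] == "all")]["point"].iloc[0]
        assert prev > ctl, method


def test_ppmi_preset_structure():
    cohort = generate_pd_cohort(PPMI_CONFIG)
    assert cohort.n == 423
    assert (cohort.df["test_kind"] == "UPSIT40").all()
    s = summarize_cohort(cohort)
    assert s["age_at_test"]["mean"] == pytest.approx(61.6, abs=1.0)
    assert s["upsit_score"]["mean"] == pytest.approx(22.3, abs=1.5)
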