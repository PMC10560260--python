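"""Association engine: scans, mirroring, contrasts, outcome models, AIC/LRT."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
import statsmodels.api as sm

import mbmi


def _lognormal_lipids(rng, n, p, betas=None, predictor=None):
    """Species on log10 scale with optional known per-unit loadings."""
    log10 = rng.normal(1.0, 0.2, size=(n, p))
    if betas is not None:
        log10 = log10 + np.outer(predictor, betas)
    return pd.DataFrame(10.0 ** log10, columns=[f"sp{j}" for j in range(p)])


def test_association_scan_matches_statsmodels_oracle(rng):
    n = 40
    predictor = pd.Series(rng.normal(27, 5, n), name="bmi")
    covars = pd.DataFrame({"age": rng.uniform(25, 80, n),
                           "sex": rng.integers(0, 2, n).astype(float)})
    lipids = _lognormal_lipids(rng, n, 6)
    records = mbmi.lipid_association(lipids, predictor, covars)
    for sp in lipids.columns:
        X = sm.add_constant(np.column_stack([predictor, covars["age"], covars["sex"]]))
        fit = sm.OLS(np.log10(lipids[sp].to_numpy()), X).fit()
        assert records.loc[sp, "beta"] == pytest.approx(fit.params[1], rel=1e-8)
        assert records.loc[sp, "p"] == pytest.approx(fit.pvalues[1], rel=1e-6)


def test_percent_difference_back_transform_and_q_ordering(rng):
    n = 5000
    predictor = pd.Series(rng.normal(27.0, 5.0, n), name="bmi")
    true_beta = np.log10(0.98)  # exact 2% decrease per unit of predictor
    lipids = _lognormal_lipids(rng, n, 3, betas=np.array([true_beta, 0.0, 0.0]),
                               predictor=predictor - 27.0)
    records = mbmi.lipid_association(lipids, predictor)
    assert records.loc["sp0", "percent_diff"] == pytest.approx(-2.0, abs=0.3)
    assert np.all(records["q"] >= records["p"])
    assert np.all(np.sign(records["percent_diff"]) == np.sign(records["beta"]))


def test_shuffled_predictor_controls_discoveries(rng):
    n = 400
    lipids = _lognormal_lipids(rng, n, 200)
    shuffled = pd.Series(rng.permutation(rng.normal(27, 5, n)), name="bmi")
    records = mbmi.lipid_association(lipids, shuffled)
    assert (records["q"] < 0.05).mean() <= 0.05


def test_zero_variance_species_skipped_with_flag(rng):
    lipids = _lognormal_lipids(rng, 30, 2)
    lipids["flat"] = 5.0
    records = mbmi.lipid_association(lipids, pd.Series(rng.normal(size=30), name="x"))
    assert "flat" not in records.index
    assert records.attrs["skipped_zero_variance"] == ["flat"]


# ----------------------------------------------------------------------
def test_coefficient_mirror_trivial_and_proportional_cases():
    rec = pd.DataFrame({"beta": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
    same = mbmi.coefficient_mirror(rec, rec)
    assert same.r_squared == pytest.approx(1.0)
    assert same.amplification == pytest.approx(1.0)
    doubled = pd.DataFrame({"beta": [2.0, 4.0, 6.0]}, index=["a", "b", "c"])
    prop = mbmi.coefficient_mirror(rec, doubled)
    assert prop.r_squared == pytest.approx(1.0)
    assert prop.amplification == pytest.approx(2.0)
    with pytest.raises(ValueError, match="species"):
        mbmi.coefficient_mirror(rec, doubled.iloc[::-1])


def test_full_pipeline_mirroring_on_scored_cohort(scored_cohort):
    """BMI and mBMIdelta effect profiles mirror with amplification > 1."""
    cohort, scores = scored_cohort
    ph = cohort.phenotypes
    data = cohort.lipids.cohort().data.loc[ph.index]
    covars = ph[["age", "sex"]]
    rec_bmi = mbmi.lipid_association(data, ph["bmi"], covars)
    rec_delta = mbmi.lipid_association(data, scores["mbmi_delta"], covars)
    stats = mbmi.coefficient_mirror(rec_bmi, rec_delta)
    assert stats.r_squared > 0.99
    assert stats.amplification > 1.0


# ----------------------------------------------------------------------
def test_zscore_contracts():
    np.testing.assert_allclose(mbmi.zscore([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])
    x = np.array([-1.0, 0.0, 1.0])
    np.testing.assert_allclose(mbmi.zscore(x), x, atol=1e-12)  # idempotent
    with pytest.raises(ValueError, match="constant"):
        mbmi.zscore([2.0, 2.0, 2.0])


def test_trait_quintile_trend_recovery(scored_cohort):
    cohort, scores = scored_cohort
    ph = cohort.phenotypes
    beta, p = mbmi.trait_quintile_trend(ph["homa_ir"], scores["quintile"])
    assert beta > 0 and p < 1e-6  # M-loaded trait rises across quintiles
    # trait equal to the quintile index: perfect positive trend
    qidx = scores["quintile"].str.removeprefix("Q").astype(float)
    beta2, p2 = mbmi.trait_quintile_trend(qidx, scores["quintile"])
    assert beta2 > 0 and p2 < 1e-12


def test_trait_quintile_trend_null_p_uniform(rng):
    quintiles = pd.Series([f"Q{i}" for i in rng.integers(1, 6, 200)])
    pvals = []
    for _ in range(200):
        trait = pd.Series(rng.normal(size=200))
        _, p = mbmi.trait_quintile_trend(trait, quintiles)
        pvals.append(p)
    assert st.kstest(pvals, "uniform").pvalue > 0.01


# ----------------------------------------------------------------------
def test_discordant_contrast_recovers_constructed_fold(rng):
    n = 4000
    q = pd.Series(np.where(rng.uniform(size=n) < 0.5, "Q1", "Q5"))
    trait = pd.Series(np.exp(rng.normal(0.3, 0.4, n)))
    trait[q == "Q5"] *= 1.5
    res = mbmi.discordant_contrast(trait, q)
    assert res["fold_difference"] == pytest.approx(1.5, rel=0.05)
    assert res["ci_low"] < 1.5 < res["ci_high"]


def test_discordant_contrast_null_and_covariate_irrelevance(rng):
    n = 2000
    q = pd.Series(np.where(rng.uniform(size=n) < 0.5, "Q1", "Q5"))
    trait = pd.Series(np.exp(rng.normal(0.0, 0.3, n)))
    base = mbmi.discordant_contrast(trait, q)
    assert base["ci_low"] < 1.0 < base["ci_high"]
    covars = pd.DataFrame({"noise": rng.normal(size=n)}, index=trait.index)
    adjusted = mbmi.discordant_contrast(trait, q, covars)
    assert adjusted["fold_difference"] == pytest.approx(
        base["fold_difference"], abs=0.02)


def test_discordant_contrast_requires_positive_trait(rng):
    q = pd.Series(["Q1", "Q5"] * 10)
    with pytest.raises(ValueError, match="positive"):
        mbmi.discordant_contrast(pd.Series([-1.0] + [1.0] * 19), q)


# ----------------------------------------------------------------------
def test_logistic_two_by_two_matches_cross_product_ratio():
    """(a,b,c,d) = (30,70,10,90): OR = 30*90/(70*10) = 3.857142857..."""
    y = np.concatenate([np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)])
    x = np.concatenate([np.ones(100), np.zeros(100)])
    res = mbmi.outcome_logistic(pd.Series(y), pd.Series(x, name="exposed"))
    assert res["estimate"].iloc[0] == pytest.approx(30 * 90 / (70 * 10), rel=1e-6)


def test_logistic_null_predictor_or_near_one(rng):
    n = 3000
    y = pd.Series((rng.uniform(size=n) < 0.2).astype(float))
    x = pd.Series(rng.normal(size=n), name="x")
    res = mbmi.outcome_logistic(y, x)
    assert res["ci_low"].iloc[0] < 1.0 < res["ci_high"].iloc[0]


def test_logistic_quintile_odds_increase_with_delta_effect(scored_cohort):
    cohort, scores = scored_cohort
    ph = cohort.phenotypes
    res = mbmi.outcome_logistic(ph["t2dm_prev"], scores["quintile"],
                                ph[["age", "sex", "bmi"]])
    ors = res["estimate"]
    assert ors.loc["Q5 vs Q1"] > ors.loc["Q2 vs Q1"]
    assert ors.loc["Q5 vs Q1"] > 1.5


# ----------------------------------------------------------------------
def test_cox_two_group_exponential_oracle(rng):
    n = 2000
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / (0.1 * np.exp(np.log(2.0) * x)))
    event = (t < 8.0).astype(float)
    res = mbmi.outcome_cox(
        pd.Series(event), pd.Series(np.zeros(n) - 1e-6),
        pd.Series(np.minimum(t, 8.0)), pd.Series(x, name="grp"))
    assert res["estimate"].iloc[0] == pytest.approx(2.0, rel=0.15)


def test_cox_null_predictor_hr_near_one(rng):
    n = 1500
    t = rng.exponential(10.0, n)
    event = (t < 8.0).astype(float)
    res = mbmi.outcome_cox(
        pd.Series(event), pd.Series(np.zeros(n) - 1e-6),
        pd.Series(np.minimum(t, 8.0)), pd.Series(rng.normal(size=n), name="x"))
    assert res["ci_low"].iloc[0] < 1.0 < res["ci_high"].iloc[0]


def test_cox_partial_likelihood_time_scale_invariance(rng):
    n = 800
    x = rng.normal(size=n)
    t = rng.exponential(1.0 / (0.1 * np.exp(0.5 * x)))
    event = np.ones(n)
    base = mbmi.outcome_cox(pd.Series(event), pd.Series(np.zeros(n) - 1e-9),
                            pd.Series(t), pd.Series(x, name="x"))
    doubled = mbmi.outcome_cox(pd.Series(event), pd.Series(np.zeros(n) - 1e-9),
                               pd.Series(2.0 * t), pd.Series(x, name="x"))
    assert base["estimate"].iloc[0] == pytest.approx(
        doubled["estimate"].iloc[0], rel=1e-6)


def test_cox_input_validation(rng):
    with pytest.raises(ValueError, match="exit age"):
        mbmi.outcome_cox(pd.Series([1.0]), pd.Series([5.0]), pd.Series([4.0]),
                         pd.Series([0.0]))
    with pytest.raises(ValueError, match="no events"):
        mbmi.outcome_cox(pd.Series([0.0, 0.0]), pd.Series([0.0, 0.0]),
                         pd.Series([1.0, 2.0]), pd.Series([0.0, 1.0]))


# ----------------------------------------------------------------------
def test_nested_comparison_redundant_term(rng):
    n = 800
    covars = pd.DataFrame({"age": rng.uniform(25, 80, n)})
    y = pd.Series((rng.uniform(size=n) < 0.3).astype(float), index=covars.index)
    duplicate = covars["age"].rename("age_copy") * 1.0
    res = mbmi.nested_model_comparison(y, covars, duplicate)
    assert res.lrt_stat == pytest.approx(0.0, abs=1e-6)
    assert res.aic_with == pytest.approx(res.aic_without + 2.0, abs=1e-4)
    assert res.df_diff == 1


def test_nested_comparison_detects_real_signal(scored_cohort):
    cohort, scores = scored_cohort
    ph = cohort.phenotypes
    res = mbmi.nested_model_comparison(
        ph["t2dm_prev"], ph[["age", "sex", "bmi"]], scores["mbmi_delta"])
    assert res.aic_with < res.aic_without
    assert res.lrt_p < 0.01


# ----------------------------------------------------------------------
def test_lifestyle_association_recovers_dose_response(scored_cohort):
    cohort, scores = scored_cohort
    ph = cohort.phenotypes
    fruit_q, _ = mbmi.assign_quintiles(ph["fruit_intake"])
    res = mbmi.lifestyle_association(
        scores["mbmi_delta"], fruit_q, ph[["age", "sex", "bmi"]])
    assert res.loc["Q5 vs Q1", "beta"] < 0  # fruit intake built as -0.3*M
    assert res.loc["Q5 vs Q1", "beta"] < res.loc["Q2 vs Q1", "beta"]


def test_lifestyle_association_null_exposure(rng):
    n = 1500
    delta = pd.Series(rng.normal(0, 1.5, n))
    exposure_q, _ = mbmi.assign_quintiles(pd.Series(rng.normal(size=n)))
    covars = pd.DataFrame({"age": rng.uniform(25, 80, n)})
    res = mbmi.lifestyle_association(delta, exposure_q, covars)
    assert (res["ci_low"] < 0).all() and (res["ci_high"] > 0).all()


def test_lifestyle_association_collinear_covariates_reported(rng):
    n = 100
    delta = pd.Series(rng.normal(size=n))
    q, _ = mbmi.assign_quintiles(pd.Series(rng.normal(size=n)))
    covars = pd.DataFrame({"a": rng.normal(size=n)})
    covars["b"] = 2.0 * covars["a"]
    with pytest.raises(ValueError, match="collinear"):
        mbmi.lifestyle_association(delta, q, covars)
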