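"""External-variance shrinkage estimator for usual intake."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import saltfort as sf
from saltfort.usual import StratumTooSmallError, handle_zeros

from test_synthetic import one_stratum_config


def lognormal_days(n=500, mu=1.5, sigma=0.6, seed=11):
    rng = np.random.default_rng(seed)
    return np.exp(mu + sigma * rng.standard_normal(n))


def test_zero_ratio_means_no_shrinkage():
    days = lognormal_days()
    model, t = sf.fit_usual_model(days, variance_ratio=0.0)
    assert model.shrinkage == 1.0
    assert model.var_between_t == pytest.approx(model.var_obs_t)
    np.testing.assert_allclose(sf.estimate_usual(t, model), days)


def test_adult_zinc_shrinkage_closed_form():
    """r = 0.61 gives shrinkage sqrt(1/1.61)."""
    model, _ = sf.fit_usual_model(lognormal_days(), variance_ratio=0.61)
    assert model.shrinkage == pytest.approx(np.sqrt(1 / 1.61))
    assert model.shrinkage == pytest.approx(0.7882, abs=5e-4)
    assert model.var_within_t == pytest.approx(
        model.var_obs_t * 0.61 / 1.61
    )


def test_variance_decomposition_identity():
    days = lognormal_days()
    model, t = sf.fit_usual_model(days, variance_ratio=0.89)
    assert model.var_between_t + model.var_within_t == pytest.approx(
        model.var_obs_t
    )
    usual_t = np.log(sf.estimate_usual(t, model))
    assert np.var(usual_t, ddof=1) == pytest.approx(
        model.shrinkage**2 * model.var_obs_t
    )
    assert np.var(usual_t, ddof=1) == pytest.approx(model.var_between_t)


def test_mean_participant_is_a_fixed_point():
    days = lognormal_days(n=101)
    model, t = sf.fit_usual_model(days, variance_ratio=0.61)
    at_mean = sf.estimate_usual(np.array([model.mu_t]), model)
    assert at_mean[0] == pytest.approx(np.exp(model.mu_t))


def test_shrinkage_preserves_rank_order():
    days = lognormal_days(n=200)
    model, t = sf.fit_usual_model(days, variance_ratio=0.89)
    usual = sf.estimate_usual(t, model)
    assert (np.argsort(usual) == np.argsort(days)).all()


def test_stratum_floor_enforced():
    with pytest.raises(StratumTooSmallError):
        sf.fit_usual_model(lognormal_days(n=10), variance_ratio=0.5)


def test_zero_handling_replaces_with_half_minimum():
    out = handle_zeros(np.array([0.0, 4.0, 2.0]))
    np.testing.assert_allclose(out, [1.0, 4.0, 2.0])
    with pytest.raises(ValueError):
        handle_zeros(np.array([0.0, 0.0]))


# -- covariate adjustment -------------------------------------------------


def test_constant_covariates_leave_intakes_unchanged():
    days = lognormal_days(n=120)
    cov = pd.DataFrame({"weekend": False, "sick": False, "unusual": False},
                       index=range(120))
    adjusted, coefs = sf.adjust_covariates(np.log(days), cov)
    np.testing.assert_allclose(adjusted, np.log(days))
    assert coefs == {}


def test_known_weekend_effect_recovered():
    """+0.3 log-unit weekend effect estimated within +-0.05 at n=5000."""
    cfg = one_stratum_config(n=5000)
    cfg = dataclasses.replace(
        cfg, covariate_effects={"weekend": 0.3, "sick": 0.0, "unusual": 0.0}
    )
    pop = sf.generate_population(cfg)
    _, coefs = sf.adjust_covariates(
        np.log(pop["zinc_mg_d"].to_numpy()),
        pop[["weekend", "sick", "unusual"]],
    )
    assert coefs["weekend"] == pytest.approx(0.3, abs=0.05)


def test_adjustment_removes_weekend_effect_from_output():
    cfg = one_stratum_config(n=5000)
    cfg = dataclasses.replace(
        cfg, covariate_effects={"weekend": 0.3, "sick": 0.0, "unusual": 0.0}
    )
    pop = sf.generate_population(cfg)
    adjusted, _ = sf.adjust_covariates(
        np.log(pop["zinc_mg_d"].to_numpy()),
        pop[["weekend", "sick", "unusual"]],
    )
    wk = pop["weekend"].to_numpy()
    gap = adjusted[wk].mean() - adjusted[~wk].mean()
    assert abs(gap) < 0.05


def test_zero_effect_covariate_is_inert():
    days = np.log(lognormal_days(n=2000, seed=5))
    rng = np.random.default_rng(0)
    cov = pd.DataFrame({
        "weekend": rng.random(2000) < 0.3,
        "sick": False,
        "unusual": False,
    })
    without, _ = sf.adjust_covariates(days, cov[["sick", "unusual"]],
                                      nuisance=("sick", "unusual"))
    np.testing.assert_allclose(without, days)
    with_zero, coefs = sf.adjust_covariates(days, cov)
    # weekend flag carries no true effect: adjustment is a small perturbation
    assert abs(coefs["weekend"]) < 0.1
    np.testing.assert_allclose(with_zero, days, atol=0.1)


# -- parameter recovery against the generator -----------------------------


@pytest.mark.parametrize("ratio", [0.47, 0.61, 0.72, 0.89])
def test_between_variance_recovered_from_synthetic_truth(ratio):
    """Generating var_between = 0.25; fit recovers it within 5% at n=10000."""
    cfg = one_stratum_config(ratio_adult=ratio, n=10000)
    pop = sf.generate_population(cfg)
    model, _ = sf.fit_usual_model(
        pop["zinc_mg_d"].to_numpy(), variance_ratio=ratio
    )
    assert model.var_between_t == pytest.approx(0.25, rel=0.05)


def test_usual_estimates_track_truth_better_than_observed_days():
    cfg = one_stratum_config(ratio_adult=0.89, n=4000)
    pop = sf.generate_population(cfg)
    model, t = sf.fit_usual_model(pop["zinc_mg_d"].to_numpy(),
                                  variance_ratio=0.89)
    usual = sf.estimate_usual(t, model)
    truth = pop["true_zinc_mg_d"].to_numpy()
    observed = pop["zinc_mg_d"].to_numpy()
    # natural scale: shrinkage is linear on the log scale, so the gain
    # shows up through the (nonlinear) back-transform
    r_usual = np.corrcoef(usual, truth)[0, 1]
    r_obs = np.corrcoef(observed, truth)[0, 1]
    assert r_usual > r_obs
    assert np.var(np.log(usual)) < np.var(np.log(observed))


def test_population_estimation_pools_undersized_strata(full_population, refs,
                                                       caplog):
    with caplog.at_level("WARNING"):
        long, models = sf.estimate_population_usual(full_population, refs)
    assert ("zinc", "pooled|man_19_45y") in models
    assert "region-pooled" in caplog.text
    # every participant gets an estimate for both nutrients
    assert len(long) == 2 * len(full_population)
    assert (long["usual_intake"] > 0).all()
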