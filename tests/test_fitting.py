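import numpy as np
import pandas as pd
import pytest

from priorlearn.fitting import (FitConfig, LoglikEngine, binarize_confidence,
                                compare_models, dataset_loglik, fit_lag_alpha,
                                fit_model, invert_confidence_to_counterfactual,
                                transform_confidence, trial_joint_likelihood)
from priorlearn.observer import ObserverParams, direction_posterior
from priorlearn.ddm import _simulate_paths

QUICK_CFG = FitConfig(maxfev=60, max_transform_iter=1)


def test_binarize_lowest_30_percent():
    t = pd.DataFrame({"subject_id": "S1",
                      "confidence_raw": np.linspace(0.5, 1.0, 10)})
    cat = binarize_confidence(t)
    assert (cat == "low").sum() == 3
    assert (cat[:3] == "low").all()


def test_binarize_degenerate_all_identical_warns():
    t = pd.DataFrame({"subject_id": "S1", "confidence_raw": [0.8] * 20})
    with pytest.warns(UserWarning):
        cat = binarize_confidence(t)
    assert (cat == "high").all()


def test_binarize_per_subject_not_pooled():
    """Two subjects with disjoint confidence ranges each get 30% low."""
    t = pd.DataFrame({
        "subject_id": ["A"] * 10 + ["B"] * 10,
        "confidence_raw": np.r_[np.linspace(0.5, 0.6, 10),
                                np.linspace(0.9, 1.0, 10)]})
    cat = binarize_confidence(t)
    assert (cat[t.subject_id == "A"] == "low").sum() == 3
    assert (cat[t.subject_id == "B"] == "low").sum() == 3


def test_transform_confidence_rank_matching():
    rng = np.random.default_rng(0)
    raw = rng.uniform(0.5, 1.0, 500)
    sim = rng.beta(5, 2, 500) * 0.5 + 0.5
    t = transform_confidence(raw, sim)
    from scipy.stats import spearmanr
    assert spearmanr(raw, t).statistic == pytest.approx(1.0)
    assert np.allclose(np.sort(t), np.sort(sim))  # identical distributions


def test_transform_confidence_ties_get_band_mean():
    raw = np.array([0.6, 0.6, 0.6, 0.9])
    sim = np.array([0.55, 0.65, 0.75, 0.95])
    t = transform_confidence(raw, sim)
    assert np.allclose(t[:3], (0.55 + 0.65 + 0.75) / 3)
    assert t[3] == pytest.approx(0.95)
    assert (np.diff(t[np.argsort(raw, kind="stable")]) >= 0).all()


def test_inversion_round_trip():
    rng = np.random.default_rng(1)
    x = rng.uniform(0.02, 0.98, 10_000)
    p = rng.uniform(0.02, 0.98, 10_000)
    conf = np.array([direction_posterior(xi, pi) for xi, pi in zip(x, p)])
    back = invert_confidence_to_counterfactual(conf, p, eps=0.0)
    assert np.max(np.abs(back - x)) < 1e-12
    # conf equal to the prior cancels the odds ratio
    assert invert_confidence_to_counterfactual(0.57, 0.57) == pytest.approx(0.5)
    # the worked map example run backwards
    assert invert_confidence_to_counterfactual(
        direction_posterior(0.7, 0.57), 0.57) == pytest.approx(0.70, abs=0.01)


def test_trial_joint_likelihood_sums_to_one(fit_maps):
    rng = np.random.default_rng(2)
    for _ in range(20):
        c = rng.choice([0.0, 0.032, -0.128, 0.512])
        T = rng.uniform(0.1, 0.9)
        qb = rng.uniform(0.05, 0.95)
        phi = rng.uniform(0.55, 0.95)
        m = trial_joint_likelihood(fit_maps, c, T, qb, phi)
        vals = np.array(list(m.values()))
        assert (vals >= 0).all()
        assert vals.sum() == pytest.approx(1.0, abs=1e-8)


def test_low_confidence_band_vanishes_as_phi_drops(fit_maps):
    """As phi -> 0.5+, only the grid atom at posterior exactly 0.5 (zero
    measure on the continuum) can remain in the low band."""
    c, T = 0.128, 0.6
    m = trial_joint_likelihood(fit_maps, c, T, 0.5, 0.5 + 1e-9)
    k = int(fit_maps.time_index(T))
    pu, mass = fit_maps.joint_atoms(c, k)
    atom = mass[np.abs(pu - 0.5) < 1e-9].sum()
    assert m[("L", "low")] + m[("R", "low")] <= atom + 1e-8


def test_outcome_frequencies_match_monte_carlo(fit_maps, gen_params):
    """The four-outcome masses agree with frequencies from simulated
    evidence pushed through the same choice/confidence rule."""
    c, T, qb, phi = 0.064, 0.6, 0.65, gen_params.phi
    m = trial_joint_likelihood(fit_maps, c, T, qb, phi)
    rng = np.random.default_rng(3)
    n = 40_000
    e, te, hit = _simulate_paths(fit_maps.params, np.full(n, c), np.full(n, T), rng)
    pu = fit_maps.pu_lookup(e, te, hit)
    post = qb * pu / (qb * pu + (1 - qb) * (1 - pu))
    is_r = post > 0.5
    conf = np.where(is_r, post, 1 - post)
    high = conf >= phi
    freq = {("L", "high"): np.mean(~is_r & high), ("L", "low"): np.mean(~is_r & ~high),
            ("R", "low"): np.mean(is_r & ~high), ("R", "high"): np.mean(is_r & high)}
    for key in m:
        se = np.sqrt(max(m[key] * (1 - m[key]), 1e-12) / n)
        assert abs(freq[key] - m[key]) < max(3 * se, 0.005), key


def _toy_dataset(behavior):
    return behavior.copy()


def test_noop_update_reduces_to_neutral_prior(fit_maps, behavior_small):
    """Choice-confidence propagation with all confidences at 0.5 never
    moves p(B) off the symmetric prior, so per-trial likelihoods equal the
    neutral-prior masses."""
    t = behavior_small.copy()
    t["confidence_raw"] = 0.5
    params = ObserverParams(kappa=14.0, bound=1.2, phi=0.75, omega1=1.0,
                            omega2=1.0, model_id="choice_confidence")
    eng = LoglikEngine(t, config=FitConfig(),
                       category=t["confidence_category"].to_numpy())
    ll_trial, _ = eng.loglik(params, per_trial=True)
    for i in (0, 5, 17, 100):
        row = t.iloc[i]
        m = trial_joint_likelihood(fit_maps, row.coherence_signed,
                                   row.duration_s, 0.5, params.phi)
        key = (row.choice, row.confidence_category)
        assert ll_trial[i] == pytest.approx(np.log(m[key]), abs=1e-9)


def test_loglik_additive_over_copies(behavior_small):
    params = ObserverParams(kappa=14.0, bound=1.2, phi=0.75, omega1=1.0,
                            omega2=0.6)
    single = dataset_loglik(behavior_small, params)
    twin = behavior_small.copy()
    twin["block_id"] = twin["block_id"] + behavior_small["block_id"].max()
    double = dataset_loglik(pd.concat([behavior_small, twin],
                                      ignore_index=True), params)
    assert double == pytest.approx(2 * single, abs=1e-6)


def test_generating_parameters_dominate_perturbed(behavior_small, gen_params):
    base = dataset_loglik(behavior_small, gen_params)
    for fac in (0.75, 1.25):
        pert = ObserverParams(kappa=gen_params.kappa * fac,
                              bound=gen_params.bound, phi=gen_params.phi,
                              omega1=gen_params.omega1, omega2=gen_params.omega2)
        assert base > dataset_loglik(behavior_small, pert)


def test_fit_deterministic_under_seed(behavior_small):
    f1 = fit_model(behavior_small, "bayesian", n_starts=2, rng=7, config=QUICK_CFG)
    f2 = fit_model(behavior_small, "bayesian", n_starts=2, rng=7, config=QUICK_CFG)
    assert f1.params == f2.params
    assert f1.llf == f2.llf
    assert f1.n_params == 5


def test_compare_models_table(behavior_small):
    f = fit_model(behavior_small, "bayesian", n_starts=1, rng=7, config=QUICK_CFG)
    tab = compare_models([f, f])
    assert (tab["d_llf"] == 0).all()
    assert (tab["d_aic"] == 0).all()
    # AIC = 2k - 2 logL, by hand
    assert f.aic == pytest.approx(2 * 5 - 2 * f.llf)
    assert f.bic == pytest.approx(5 * np.log(f.nobs) - 2 * f.llf)
    other = f.__class__(**{**f.__dict__, "dataset_fingerprint": "different"})
    with pytest.raises(ValueError):
        compare_models([f, other])


def test_fit_lag_alpha_recovery():
    rng = np.random.default_rng(4)
    block_ids = np.repeat(np.arange(40), 25)
    b = np.clip(rng.random(len(block_ids)) * 0.2
                + np.repeat(rng.random(40), 25), 0, 1)
    # noiseless lagged reports from known alpha
    alpha_true = 0.6
    f, reports = 0.5, []
    for i, bi in enumerate(b):
        if i % 25 == 0:
            f = 0.5
        f = f + (bi - f) * (1 - alpha_true)
        reports.append(f)
    reports = np.asarray(reports)
    assert abs(fit_lag_alpha(reports, b, block_ids) - alpha_true) < 0.1
    # reports identical to predictions: no lag at all
    assert fit_lag_alpha(b, b, block_ids) == pytest.approx(0.0, abs=1e-3)
    # flat reports at 1/2: the filter must shut off completely
    assert fit_lag_alpha(np.full_like(b, 0.5), b, block_ids) > 0.95


def test_mixture_and_empirical_fits_run(behavior_small):
    fm = fit_model(behavior_small, "mixture", n_starts=1, rng=0, config=QUICK_CFG)
    assert fm.n_params == 6 and 0.0 <= fm.params["beta_mix"] <= 1.0
    fe = fit_model(behavior_small, "empirical", n_starts=1, rng=0, config=QUICK_CFG)
    assert fe.n_params == 10 and "beta4" in fe.params


def test_update_lag_variant_fit_runs(behavior_small):
    f = fit_model(behavior_small, "bayesian", n_starts=1, rng=0,
                  config=QUICK_CFG, fit_update_lag=True)
    assert f.n_params == 6
    assert 0.0 <= f.params["alpha_lag_pb"] <= 0.95
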