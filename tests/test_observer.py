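import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from priorlearn.observer import (B_SUPPORT, BaseRateDistribution,
                                 DegenerateUpdateError, ObserverParams,
                                 ParameterError, UndefinedPosteriorError,
                                 belief_rightward, compute_nu,
                                 direction_posterior, expected_base_rate,
                                 lag_report, lag_update_pb, make_prior,
                                 simulate_observer,
                                 update_base_rate)
from priorlearn.task import ExperimentDesign, BlockDesign, StimulusTrial


def test_make_prior_cases():
    assert np.allclose(make_prior(1, 1).probs, np.full(6, 1 / 6))
    assert np.allclose(make_prior(0, 0).probs, [0, 0, 0.5, 0.5, 0, 0])
    assert np.allclose(make_prior(2, 4).probs,
                       np.array([4, 2, 1, 1, 2, 4]) / 14)
    with pytest.raises(ParameterError):
        make_prior(-1, 1)


def test_expected_base_rate_and_belief():
    assert expected_base_rate(make_prior(1, 1)) == pytest.approx(0.5)
    point8 = BaseRateDistribution(np.array([0, 0, 0, 0, 1.0, 0]))
    assert expected_base_rate(point8) == pytest.approx(0.8)
    tilted = BaseRateDistribution(np.arange(6) / 15)
    assert expected_base_rate(tilted) == pytest.approx(np.arange(6) @ B_SUPPORT / 15)
    assert belief_rightward(tilted) == pytest.approx(0.8)  # (3+4+5)/15
    assert belief_rightward(make_prior(1, 1)) == pytest.approx(0.5)
    point2 = BaseRateDistribution(np.array([0, 1.0, 0, 0, 0, 0]))
    assert belief_rightward(point2) == 0.0


def test_direction_posterior():
    # the worked combination of counterfactual 0.7 with prior expectation 0.57
    assert direction_posterior(0.7, 0.57) == pytest.approx(0.755, abs=0.01)
    assert direction_posterior(0.5, 0.5) == pytest.approx(0.5)
    assert direction_posterior(0.7, 0.5) == pytest.approx(0.7)  # neutral prior
    with pytest.raises(UndefinedPosteriorError):
        direction_posterior(1.0, 0.0)


@given(st.floats(0.01, 0.99), st.floats(0.51, 0.99), st.floats(0.01, 0.99),
       st.sampled_from(["R", "L"]))
@settings(max_examples=200, deadline=None)
def test_nu_mixture_endpoints_collapse(pu, conf, prior, choice):
    """beta=1 reduces the mixture rule to the Bayesian rule, beta=0 to the
    choice-confidence rule."""
    p1 = ObserverParams(kappa=10, bound=1, model_id="mixture", beta_mix=1.0)
    p0 = ObserverParams(kappa=10, bound=1, model_id="mixture", beta_mix=0.0)
    bay = compute_nu("bayesian", choice, conf, pu, prior)
    cc = compute_nu("choice_confidence", choice, conf, pu, prior)
    assert compute_nu("mixture", choice, conf, pu, prior, p1) == pytest.approx(bay)
    assert compute_nu("mixture", choice, conf, pu, prior, p0) == pytest.approx(cc)


def test_nu_rules():
    assert compute_nu("bayesian", "R", 0.9, 0.62, 0.5) == pytest.approx(0.62)
    assert compute_nu("choice_only", "L", 0.9, 0.62, 0.5) == 0.0
    assert compute_nu("choice_only", "R", 0.6, 0.62, 0.5) == 1.0
    assert compute_nu("choice_confidence", "R", 0.9, 0.62, 0.5) == pytest.approx(0.9)
    assert compute_nu("choice_confidence", "L", 0.9, 0.62, 0.5) == pytest.approx(0.1)
    # empirical rule maps back to the rightward convention
    pe = ObserverParams(kappa=10, bound=1, model_id="empirical",
                        empirical_betas=(0.0, 2.0, 0.0, 0.0, 0.0))
    nu_r = compute_nu("empirical", "R", 0.8, 0.6, 0.5, pe)
    nu_l = compute_nu("empirical", "L", 0.8, 0.4, 0.5, pe)
    assert nu_r == pytest.approx(1 / (1 + np.exp(-1.6)))
    assert nu_l == pytest.approx(1 - 1 / (1 + np.exp(-1.6)))


def test_update_base_rate():
    uniform = make_prior(1, 1)
    # nu = 0.5 multiplies every mass by the same constant: exact no-op
    assert np.array_equal(update_base_rate(uniform, 0.5).probs, uniform.probs)
    up = update_base_rate(uniform, 1.0).probs
    assert np.allclose(up, np.arange(6) / 15)
    down = update_base_rate(uniform, 0.0).probs
    assert np.allclose(down, up[::-1])
    with pytest.raises(DegenerateUpdateError):
        update_base_rate(BaseRateDistribution(np.array([1.0, 0, 0, 0, 0, 0])), 1.0)


def test_update_chain_normalization_and_batch_equivalence():
    rng = np.random.default_rng(0)
    nus = rng.random(400)
    p = make_prior(1.4, 0.3)
    seq = p
    for nu in nus:
        seq = update_base_rate(seq, nu)
        assert abs(seq.probs.sum() - 1.0) < 1e-12
    # one-shot posterior proportional to the product of the multipliers
    mult = np.prod(B_SUPPORT[None, :] * nus[:, None]
                   + (1 - B_SUPPORT[None, :]) * (1 - nus[:, None]), axis=0)
    batch = p.probs * mult
    batch /= batch.sum()
    assert np.max(np.abs(batch - seq.probs)) < 1e-10


def test_bayesian_update_is_martingale(fit_maps):
    """Averaging the updated p(B) over the model's own predictive
    distribution of (e, te) returns the current p(B) (exact enumeration
    over the joint grid at a fixed duration)."""
    p = make_prior(1.7, 0.4).probs
    k = int(fit_maps.time_index(0.5))
    # predictive over atoms: p(x|B) = B p(x|R) + (1-B) p(x|L), marginalized
    pR = np.concatenate([fit_maps.pR_interior[k], fit_maps.pR_top[: k + 1],
                         fit_maps.pR_bot[: k + 1]])
    pL = np.concatenate([fit_maps.pL_interior[k], fit_maps.pL_top[: k + 1],
                         fit_maps.pL_bot[: k + 1]])
    qb = B_SUPPORT @ p
    pred = qb * pR + (1 - qb) * pL
    with np.errstate(invalid="ignore", divide="ignore"):
        nu = np.where(pR + pL > 0, pR / (pR + pL), 0.5)
    post = p[None, :] * (B_SUPPORT[None, :] * nu[:, None]
                         + (1 - B_SUPPORT[None, :]) * (1 - nu[:, None]))
    post /= np.clip(post.sum(axis=1, keepdims=True), 1e-300, None)
    avg = (pred[:, None] * post).sum(axis=0) / pred.sum()
    assert np.max(np.abs(avg - p)) < 1e-8


def test_lag_report():
    assert lag_report(0.8, 0.5, 0.0) == pytest.approx(0.8)   # alpha=0: no lag
    assert lag_report(0.8, 0.5, 1.0 - 1e-12) == pytest.approx(0.5)
    assert lag_report(1.0, 0.5, 0.5) == pytest.approx(0.75)


def test_lag_update_pb():
    a = make_prior(1, 1)
    b = make_prior(0.2, 3.0)
    assert np.allclose(lag_update_pb(a, b, 0.0).probs, b.probs)
    mid = lag_update_pb(a, b, 0.5).probs
    assert np.allclose(mid, 0.5 * (a.probs + b.probs))
    rng = np.random.default_rng(1)
    for _ in range(20):
        w = rng.random(6)
        c = BaseRateDistribution(w / w.sum())
        out = lag_update_pb(a, c, rng.random() * 0.99)
        assert abs(out.probs.sum() - 1.0) < 1e-12


def test_simulation_deterministic_and_ceiling(small_design, gen_params, fit_maps):
    s1 = simulate_observer(small_design, gen_params, fit_maps,
                           np.random.default_rng(9))
    s2 = simulate_observer(small_design, gen_params, fit_maps,
                           np.random.default_rng(9))
    assert s1.equals(s2)
    assert s1["confidence_raw"].between(0.5, 1).all()
    assert s1["belief_report"].between(0, 1).all()


def test_accuracy_ceiling_in_easy_biased_blocks(gen_params, fit_maps):
    """B=1 blocks of 51.2% coherence only: accuracy approaches 1 late in
    the block."""
    rng = np.random.default_rng(3)
    trials = tuple(StimulusTrial(0.512, "R", 0.6) for _ in range(30))
    design = ExperimentDesign(blocks=tuple(
        BlockDesign(base_rate=1.0, trials=trials) for _ in range(30)))
    sim = simulate_observer(design, gen_params, fit_maps, rng)
    late = sim[sim["trial_index"] > 20]
    assert (late["choice"] == "R").mean() > 0.99


def test_confidence_increases_with_coherence_on_correct_trials(fit_maps):
    """Under a neutral prior (no base-rate updating) the mean confidence of
    correct decisions grows with motion strength."""
    from priorlearn.ddm import _simulate_paths
    rng = np.random.default_rng(12)
    n = 20_000
    means = []
    for c in (0.0, 0.064, 0.256, 0.512):
        e, te, hit = _simulate_paths(fit_maps.params, np.full(n, c),
                                     np.full(n, 0.6), rng)
        pu = np.asarray(fit_maps.pu_lookup(e, te, hit))
        correct = pu > 0.5 if c > 0 else np.ones(n, bool)
        conf = np.where(pu > 0.5, pu, 1 - pu)
        means.append(conf[correct].mean())
    assert np.all(np.diff(means) > 0)


def test_mismatched_maps_rejected(small_design, fit_maps, gen_params):
    from priorlearn.observer import ConfigurationError
    bad = ObserverParams(kappa=gen_params.kappa * 2, bound=gen_params.bound)
    with pytest.raises(ConfigurationError):
        simulate_observer(small_design, bad, fit_maps, np.random.default_rng(0))
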