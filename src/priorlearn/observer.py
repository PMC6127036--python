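"""Hierarchical belief layer: prior over base rates, biased direction
posterior, the update rules, belief readout, lag variants, and end-to-end
simulation of observer behavior.

The observer carries a six-point probability distribution p(B) over the
block's base rate.  On each trial the terminal accumulator state (e, te)
yields a counterfactual posterior pu(R | e, te); combining it with the
prior expectation E[B] gives the biased posterior that drives choice and
confidence.  p(B) is then multiplied by the linear-in-B factor
``B*nu_r + (1-B)*nu_l`` and renormalized, where nu encodes the update
rule: the counterfactual posterior (Bayesian), the choice indicator
(Choice-only), the reported posterior (Choice-confidence), a convex blend
of the two (mixture), or a flexible logistic map of confidence and prior
expectation (empirical).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ddm import LikelihoodMaps, _simulate_paths
from .task import BASE_RATES, ExperimentDesign

B_SUPPORT = np.array(BASE_RATES)

MODEL_IDS = ("bayesian", "choice_only", "choice_confidence", "empirical", "mixture")


class ParameterError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


class DegenerateUpdateError(ValueError):
    """The multiplicative update annihilated all probability mass."""


class UndefinedPosteriorError(ValueError):
    """0/0 in the biased posterior (degenerate prior meets certain evidence)."""


@dataclass(frozen=True)
class BaseRateDistribution:
    """Probability mass over the six base rates {0, .2, .4, .6, .8, 1}."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (6,):
            raise ParameterError("base-rate distribution needs 6 masses")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ParameterError("masses must be nonnegative and sum to 1")
        object.__setattr__(self, "probs", p)

    @property
    def support(self) -> np.ndarray:
        return B_SUPPORT


@dataclass(frozen=True)
class ObserverParams:
    """Full observer parameterization (accumulator + belief layer)."""

    kappa: float
    bound: float
    phi: float = 0.7
    omega1: float = 1.0
    omega2: float = 1.0
    model_id: str = "bayesian"
    beta_mix: float | None = None
    empirical_betas: tuple[float, ...] | None = None
    alpha_lag: float = 0.0        # first-order lag on the belief *report*
    alpha_lag_pb: float = 0.0     # first-order lag on the p(B) update itself

    def __post_init__(self):
        if not (0.5 < self.phi <= 1.0):
            raise ParameterError("phi must lie in (0.5, 1]")
        if self.omega1 < 0 or self.omega2 < 0:
            raise ParameterError("prior weights must be nonnegative")
        if self.model_id not in MODEL_IDS:
            raise ConfigurationError(f"unknown model_id {self.model_id!r}")
        if self.model_id == "mixture" and self.beta_mix is None:
            raise ConfigurationError("mixture model requires beta_mix")
        if self.model_id == "empirical":
            if self.empirical_betas is None or len(self.empirical_betas) != 5:
                raise ConfigurationError("empirical model requires 5 betas")
        for a in (self.alpha_lag, self.alpha_lag_pb):
            if not (0.0 <= a < 1.0):
                raise ParameterError("lag constants must lie in [0, 1)")


#: reference observer used by the synthetic-data generator: a sensitivity
#: and bound in the typical range for motion discrimination (overall
#: accuracy ~0.83 on this task), a confidence criterion near the 30th
#: percentile of the confidence distribution, and a mild under-weighting
#: of the extreme base rates in the initial prior
DEFAULT_GENERATOR_PARAMS: "ObserverParams"


# ---------------------------------------------------------------------------
# elementary operations on p(B)
# ---------------------------------------------------------------------------

def make_prior(omega1: float, omega2: float) -> BaseRateDistribution:
    """Initial prior p0(B): weights (w2, w1, 1, 1, w1, w2), normalized.

    The two central base rates carry unit weight; omega1 weights the
    intermediate pair (0.2, 0.8) and omega2 the extreme pair (0, 1).
    """
    if omega1 < 0 or omega2 < 0:
        raise ParameterError("prior weights must be nonnegative")
    w = np.array([omega2, omega1, 1.0, 1.0, omega1, omega2])
    return BaseRateDistribution(w / w.sum())


def expected_base_rate(pb) -> float:
    """E[B] = sum B p(B); also the prior probability of rightward motion."""
    return float(B_SUPPORT @ _probs(pb))


def prior_direction_right(pb) -> float:
    return expected_base_rate(pb)


def direction_posterior(pu_r: float, expected_b: float) -> float:
    """Biased posterior that motion is rightward.

    Multiplies the counterfactual posterior by the prior expectation of
    the base rate and normalizes over the two directions:
    ``E[B]*pu / (E[B]*pu + (1-E[B])*(1-pu))``.
    """
    num = expected_b * pu_r
    den = num + (1.0 - expected_b) * (1.0 - pu_r)
    if den == 0.0:
        raise UndefinedPosteriorError(
            f"0/0 posterior for pu={pu_r}, E[B]={expected_b}")
    return float(num / den)


def compute_nu(model_id: str, choice: str, conf_transformed: float,
               pu_r: float, prior_r: float,
               params: ObserverParams | None = None) -> float:
    """The rightward update weight nu_r for the given model.

    ``conf_transformed`` is the (transformed) posterior probability that
    the *chosen* direction is correct.
    """
    is_r = choice == "R"
    conf_r = conf_transformed if is_r else 1.0 - conf_transformed
    if model_id == "bayesian":
        return float(pu_r)
    if model_id == "choice_only":
        return 1.0 if is_r else 0.0
    if model_id == "choice_confidence":
        return float(conf_r)
    if model_id == "mixture":
        if params is None or params.beta_mix is None:
            raise ConfigurationError("mixture model requires beta_mix")
        b = params.beta_mix
        return float(b * pu_r + (1.0 - b) * conf_r)
    if model_id == "empirical":
        if params is None or params.empirical_betas is None:
            raise ConfigurationError("empirical model requires empirical_betas")
        p_d = prior_r if is_r else 1.0 - prior_r
        nu_d = empirical_nu(conf_transformed, p_d, params.empirical_betas)
        return float(nu_d if is_r else 1.0 - nu_d)
    raise ConfigurationError(f"unknown model_id {model_id!r}")


def empirical_nu(conf_d, p_d, betas):
    """Flexible logistic map from (confidence, prior expectation for the
    chosen direction) to the update weight nu_d."""
    b0, b1, b2, b3, b4 = betas
    z = b0 + b1 * conf_d + b2 * p_d + b3 * conf_d * p_d + b4 * conf_d ** 2
    return 1.0 / (1.0 + np.exp(-z))


def update_base_rate(pb, nu_r: float) -> BaseRateDistribution:
    """Multiply p(B) pointwise by ``B*nu_r + (1-B)*(1-nu_r)`` and renormalize.

    The posterior becomes the next trial's prior.
    """
    if not (0.0 <= nu_r <= 1.0):
        raise ParameterError("nu_r must lie in [0, 1]")
    p = _probs(pb)
    if nu_r == 0.5:  # constant multiplier: the update is exactly the identity
        return BaseRateDistribution(p.copy())
    new = p * (B_SUPPORT * nu_r + (1.0 - B_SUPPORT) * (1.0 - nu_r))
    s = new.sum()
    if s <= 0.0:
        raise DegenerateUpdateError("update annihilated all base-rate mass")
    return BaseRateDistribution(new / s)


def belief_rightward(pb) -> float:
    """Belief that the block favors rightward: mass of p(B) above 0.5."""
    return float(_probs(pb)[B_SUPPORT > 0.5].sum())


def lag_report(b_i: float, f_prev: float, alpha: float) -> float:
    """First-order lag on the belief report only: f_i = f_{i-1} + (b_i - f_{i-1})(1-alpha)."""
    if alpha == 0.0:  # no lag: the report is exactly the momentary belief
        return float(b_i)
    return float(f_prev + (b_i - f_prev) * (1.0 - alpha))


def lag_update_pb(pb_prev, pb_target, alpha: float) -> BaseRateDistribution:
    """Lagged p(B) update: convex combination of previous and no-lag-updated
    distributions (the non-Bayesian lag variant, affecting choice too)."""
    p_prev = _probs(pb_prev)
    p_new = _probs(pb_target)
    return BaseRateDistribution(p_prev + (p_new - p_prev) * (1.0 - alpha))


def _probs(pb) -> np.ndarray:
    if isinstance(pb, BaseRateDistribution):
        return pb.probs
    return np.asarray(pb, dtype=float)


# ---------------------------------------------------------------------------
# end-to-end behavioral simulation
# ---------------------------------------------------------------------------

def simulate_observer(design: ExperimentDesign, params: ObserverParams,
                      maps: LikelihoodMaps, rng: np.random.Generator,
                      debug: bool = False) -> pd.DataFrame:
    """Simulate observer behavior on a stimulus design.

    Per trial: draw a terminal accumulator state, look up the
    counterfactual posterior, combine with the current E[B] to choose and
    assign confidence (posterior for the chosen side; high when it
    reaches the criterion phi), update p(B) by the model's nu, and emit
    the (optionally lagged) belief report.  p(B) resets to the omega-prior
    at each block start; lagged reports seed from 0.5.
    """
    return simulate_from_table(design.to_frame(), params, maps, rng, debug=debug)


def simulate_from_table(table: pd.DataFrame, params: ObserverParams,
                        maps: LikelihoodMaps, rng: np.random.Generator,
                        debug: bool = False) -> pd.DataFrame:
    """Same as :func:`simulate_observer` but on an existing stimulus table
    (columns block_id, coherence_signed, duration_s), e.g. the stimulus
    sequence a subject actually saw."""
    if not (np.isclose(maps.params.kappa, params.kappa)
            and np.isclose(maps.params.bound, params.bound)):
        raise ConfigurationError(
            "likelihood maps were built with different kappa/bound than the observer")
    acc = maps.params
    e_arr, te_arr, hit_arr = _simulate_paths(
        acc, table["coherence_signed"].to_numpy(), table["duration_s"].to_numpy(), rng)
    pu_arr = np.asarray(maps.pu_lookup(e_arr, te_arr, hit_arr), dtype=float).reshape(-1)

    prior0 = make_prior(params.omega1, params.omega2).probs
    n = len(table)
    choice = np.empty(n, dtype="U1")
    conf = np.empty(n)
    cat = np.empty(n, dtype="U4")
    belief = np.empty(n)

    block_ids = table["block_id"].to_numpy()
    p = prior0.copy()
    f_prev = 0.5
    current_block = None
    for i in range(n):
        if block_ids[i] != current_block:
            current_block = block_ids[i]
            p = prior0.copy()
            f_prev = 0.5
        qb = float(B_SUPPORT @ p)
        post_r = direction_posterior(pu_arr[i], qb)
        if post_r > 0.5:
            is_r = True
        elif post_r < 0.5:
            is_r = False
        else:
            is_r = bool(rng.random() < 0.5)  # fair coin at an exact tie
        choice[i] = "R" if is_r else "L"
        conf_i = post_r if is_r else 1.0 - post_r
        conf[i] = conf_i
        cat[i] = "high" if conf_i >= params.phi else "low"

        nu_r = compute_nu(params.model_id, choice[i], conf_i, pu_arr[i], qb, params)
        mult = B_SUPPORT * nu_r + (1.0 - B_SUPPORT) * (1.0 - nu_r)
        p_new = p * mult
        s = p_new.sum()
        if s <= 0.0:
            raise DegenerateUpdateError("update annihilated all base-rate mass")
        p_new /= s
        if params.alpha_lag_pb > 0.0:
            p = p + (p_new - p) * (1.0 - params.alpha_lag_pb)
        else:
            p = p_new
        b_i = float(p[B_SUPPORT > 0.5].sum())
        if params.alpha_lag > 0.0:
            f_prev = f_prev + (b_i - f_prev) * (1.0 - params.alpha_lag)
            belief[i] = f_prev
        else:
            belief[i] = b_i

    out = table.copy()
    out["choice"] = choice
    out["confidence_raw"] = conf
    out["confidence_category"] = cat
    out["belief_report"] = belief
    if debug:
        out["e"] = e_arr
        out["te"] = te_arr
        out["bound_hit"] = hit_arr
        out["pu"] = pu_arr
    return out


DEFAULT_GENERATOR_PARAMS = ObserverParams(
    kappa=14.0, bound=1.2, phi=0.75, omega1=1.0, omega2=0.6,
    model_id="bayesian")
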