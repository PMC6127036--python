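# priorlearn

How do people learn a prior probability — a base rate — when nobody tells
them whether their decisions were right?  In a motion-discrimination task
where one direction is secretly more frequent within each short block,
observers gradually bias their choices toward the frequent direction,
grow more confident, and can explicitly report their evolving belief
about the block's bias, all without feedback.  `priorlearn` implements
the computational account of this behavior: a bounded drift-diffusion
decision stage feeding a hierarchical Bayesian belief stage that learns
the base rate from *counterfactual confidence* — the confidence the
observer would have under a neutral prior — together with the rival
update rules it is tested against, maximum-likelihood fitting, and the
downstream analyses.  It is aimed at computational cognitive scientists
who want to fit, compare or simulate these models on trial tables of
choice, confidence and belief reports.

## The model in brief

Evidence accumulates as `de = κc dt + dW` between absorbing bounds `±A`
(unit diffusion variance; `c` is signed motion coherence) until a bound
is hit or the stimulus ends, leaving a terminal state `(e, te)`.  From
the Fokker–Planck solution the observer evaluates the counterfactual
posterior `pu(R|e,te)` — the probability of rightward motion under a
neutral prior — and combines it with the prior expectation of the base
rate, `E[B]`:

    p(R | e, te, E) = E[B]·pu / (E[B]·pu + (1−E[B])(1−pu))

which drives choice (R iff > 1/2) and confidence (posterior for the
chosen side; criterion ϕ splits high/low).  Knowledge of the base rate
is a six-point distribution p(B) over {0, 0.2, 0.4, 0.6, 0.8, 1},
updated after every trial:

    p(B | e, te, E) ∝ (B·νr + (1−B)·νl) · p(B | E),    νl = 1−νr

The update weight νr is the counterfactual posterior in the Bayesian
model, the choice indicator in the Choice-only model, the reported
posterior in the Choice-confidence model, a β-blend in the mixture
model, or a flexible logistic map in the empirical model.  The reported
belief that the block favors rightward is `Σ_{B>0.5} p(B)`; first-order
lag variants on the report or on the update itself are included.  See
`docs/methods.md` for the full account.

## Worked example

Simulate a synthetic observer on the task, then fit the Bayesian model
back to its choices and (binarized) confidences:

```python
import numpy as np
from priorlearn import (AccumulatorParams, counterfactual_posterior_map,
                        DEFAULT_GENERATOR_PARAMS, generate_experiment,
                        simulate_observer, direction_posterior,
                        BaseRateLearningModel)

# the biased-posterior arithmetic: counterfactual 0.7, prior E[B]=0.57
print(direction_posterior(0.7, 0.57))         # 0.7556818181818181

gen = DEFAULT_GENERATOR_PARAMS                # kappa=14, A=1.2, phi=0.75
maps = counterfactual_posterior_map(
    AccumulatorParams(kappa=gen.kappa, bound=gen.bound,
                      dt=0.0075, n_evidence=181, dt_sim=0.001))
design = generate_experiment(n_blocks=60, rng_seed=7)
data = simulate_observer(design, gen, maps, np.random.default_rng(1))

model = BaseRateLearningModel(data, update_rule="bayesian")
res = model.fit(n_starts=5, seed=0)
print(res.summary())
```

```
Base-rate learning model results
============================================
Update rule:        bayesian
No. trials:         1437
No. parameters:     5
Log-likelihood:     -879.73
AIC:                1769.46
BIC:                1795.81
Restarts (best):    5 (1)
Converged:          False
Likelihood floors:  0
--------------------------------------------
parameter         estimate
kappa              13.7887
bound               1.1803
phi                 0.7355
omega1              0.6998
omega2              0.6889
============================================
```

The fitted sensitivity κ, bound A and confidence criterion ϕ sit close
to the generating values (14, 1.2, 0.75); ω1 and ω2 describe the
observer's initial prior over base rates (weights of the intermediate
and extreme base rates relative to the central ones).  `Converged` is a
strict diagnostic — it reports whether the confidence-transform/fit
alternation settled below 0.01 log-likelihood units within its budget,
not whether the estimates are usable.  The fit used only
choices and high/low confidences — belief reports were never seen — yet
`res.predict_beliefs()` now predicts the belief trajectories, and
`res.compare(...)` ranks the rival update rules by likelihood, AIC and
BIC on the same data.

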