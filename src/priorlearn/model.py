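"""Model/Results front end for fitting the belief-updating observer.

`BaseRateLearningModel` binds one subject's trial table and an update rule;
`fit()` runs the multi-start maximum-likelihood machinery and returns a
`BaseRateLearningResults` carrying estimates, fit statistics and
diagnostics, with simulation, belief prediction and plotting hanging off
the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .observer import ObserverParams, simulate_from_table
from .fitting import (FitConfig, FitResult, LoglikEngine, fit_model,
                      compare_models)
from .evaluation import (predict_beliefs, BeliefPrediction,
                         reported_end_of_block, end_of_block_mse)


class BaseRateLearningModel:
    """Hierarchical base-rate-learning observer bound to one subject's data.

    Parameters
    ----------
    data : DataFrame
        Trial table with columns block_id, trial_index, coherence_signed,
        duration_s, choice, confidence_raw (confidence_category optional).
    update_rule : str
        'bayesian' (counterfactual confidence), 'choice_only',
        'choice_confidence', 'mixture' or 'empirical'.
    fit_update_lag : bool
        Additionally fit a first-order lag on the p(B) update itself.
    config : FitConfig
        Numerical configuration (grids, clipping, optimizer effort).
    """

    def __init__(self, data: pd.DataFrame, update_rule: str = "bayesian",
                 fit_update_lag: bool = False, config: FitConfig | None = None):
        self.update_rule = update_rule
        self.fit_update_lag = fit_update_lag
        self.config = config or FitConfig()
        self.engine = LoglikEngine(data, config=self.config)
        self.data = self.engine.table

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "BaseRateLearningModel":
        return cls(data, **kwargs)

    @property
    def nobs(self) -> int:
        return self.engine.nobs

    def loglike(self, params: ObserverParams) -> float:
        """Dataset log-likelihood at the given observer parameters."""
        ll, _ = self.engine.loglik(params)
        return ll

    def fit(self, n_starts: int = 30, seed: int | None = None,
            use_transform: bool = True) -> "BaseRateLearningResults":
        res = fit_model(self.data, self.update_rule, n_starts=n_starts,
                        rng=seed, config=self.config,
                        fit_update_lag=self.fit_update_lag,
                        use_transform=use_transform)
        return BaseRateLearningResults(self, res)


class BaseRateLearningResults:
    """Maximum-likelihood results for one update rule on one subject."""

    def __init__(self, model: BaseRateLearningModel, fit: FitResult):
        self.model = model
        self.fit_result = fit

    # -- estimates and fit statistics -------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self.fit_result.params, name=self.fit_result.model_id)

    @property
    def llf(self) -> float:
        return self.fit_result.llf

    @property
    def llf_trial(self) -> np.ndarray:
        return self.fit_result.llf_trial

    @property
    def aic(self) -> float:
        return self.fit_result.aic

    @property
    def bic(self) -> float:
        return self.fit_result.bic

    @property
    def nobs(self) -> int:
        return self.fit_result.nobs

    def observer_params(self) -> ObserverParams:
        return self.fit_result.observer_params()

    def summary(self) -> str:
        f = self.fit_result
        lines = [
            "Base-rate learning model results",
            "=" * 44,
            f"Update rule:        {f.model_id}",
            f"No. trials:         {f.nobs}",
            f"No. parameters:     {f.n_params}",
            f"Log-likelihood:     {f.llf:.2f}",
            f"AIC:                {f.aic:.2f}",
            f"BIC:                {f.bic:.2f}",
            f"Restarts (best):    {f.n_starts} ({f.best_start})",
            f"Converged:          {f.converged}",
            f"Likelihood floors:  {f.floor_count}",
            "-" * 44,
            f"{'parameter':<14}{'estimate':>12}",
        ]
        for k, v in f.params.items():
            lines.append(f"{k:<14}{v:>12.4f}")
        lines.append("=" * 44)
        return "\n".join(lines)

    # -- simulation and prediction ----------------------------------------
    def _maps(self):
        return self.model.engine.maps_for(self.fit_result.params["kappa"],
                                          self.fit_result.params["bound"])

    def simulate(self, seed: int | None = None) -> pd.DataFrame:
        """One simulation of the fitted observer on the subject's stimuli."""
        return simulate_from_table(self.model.data, self.observer_params(),
                                   self._maps(), np.random.default_rng(seed))

    def predict_beliefs(self, n_sim: int = 200,
                        seed: int | None = None) -> BeliefPrediction:
        """Belief trajectories from ``n_sim`` simulations on the identical
        stimulus sequence."""
        return predict_beliefs(self.observer_params(), self.model.data,
                               self._maps(), n_sim=n_sim, rng=seed)

    def belief_mse(self, n_sim: int = 200, seed: int | None = None) -> float:
        """End-of-block MSE between predicted and reported beliefs."""
        pred = self.predict_beliefs(n_sim=n_sim, seed=seed)
        return end_of_block_mse(pred.mean_end_of_block().to_numpy(),
                                reported_end_of_block(self.model.data).to_numpy())

    def compare(self, *others: "BaseRateLearningResults") -> pd.DataFrame:
        return compare_models([self.fit_result]
                              + [o.fit_result for o in others])

    def plot_belief(self, n_sim: int = 20, seed: int | None = None, ax=None):
        """Mean belief trajectory by trial number, per base rate (data vs model)."""
        import matplotlib.pyplot as plt

        pred = self.predict_beliefs(n_sim=n_sim, seed=seed)
        data = self.model.data
        if ax is None:
            _, ax = plt.subplots()
        mean_traj = pred.mean_trajectory
        for b, grp in data.assign(pred=mean_traj).groupby("base_rate"):
            by_n = grp.groupby("trial_index")
            ax.plot(by_n["belief_report"].mean(), lw=2, label=f"B={b} data")
            ax.plot(by_n["pred"].mean(), lw=1, ls="--", label=f"B={b} model")
        ax.set_xlabel("trial number in block")
        ax.set_ylabel("belief (rightward bias)")
        ax.legend(fontsize=6, ncol=2)
        return ax
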