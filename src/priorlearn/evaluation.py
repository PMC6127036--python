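"""Post-fit analyses.

* Belief-trajectory prediction: repeated simulation of the fitted observer
  on the identical stimulus sequence (the 200-simulation protocol) and the
  end-of-block mean-squared-error comparison between update rules.
* The six regression analyses relating choice, confidence and belief to
  motion strength, duration, base rate and trial number.
* Zero-coherence diagnostics for the report-lag signature: under the
  no-lag Bayesian rule the mean belief change on 0%-coherence trials is
  zero; a lagged report makes it track the currently held belief.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ddm import LikelihoodMaps
from .observer import ObserverParams, simulate_from_table
from .fitting import FitConfig, FitResult, LoglikEngine

REGRESSION_SPECS = ("eq19_choice_bias", "eq20_confidence", "eq21_accuracy_course",
                    "eq22_highconf_course", "eq23_delta_belief", "eq24_consistency")


class DesignError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# belief prediction
# ---------------------------------------------------------------------------

@dataclass
class BeliefPrediction:
    """Predicted belief trajectories from repeated model simulation.

    ``beliefs[s, i]`` is simulation s's belief report on table row i.
    """

    beliefs: np.ndarray          # (n_sim, n_trials)
    block_ids: np.ndarray
    trial_index: np.ndarray

    @property
    def n_sim(self) -> int:
        return self.beliefs.shape[0]

    @property
    def mean_trajectory(self) -> np.ndarray:
        return self.beliefs.mean(axis=0)

    def end_of_block(self) -> pd.DataFrame:
        """Per (block, simulation) belief on the last trial of the block."""
        last = pd.Series(self.trial_index).groupby(self.block_ids).idxmax().to_numpy()
        return pd.DataFrame(self.beliefs[:, last].T,
                            index=pd.Index(np.unique(self.block_ids), name="block_id"))

    def mean_end_of_block(self) -> pd.Series:
        return self.end_of_block().mean(axis=1)


def predict_beliefs(params: ObserverParams, table: pd.DataFrame,
                    maps: LikelihoodMaps, n_sim: int = 200,
                    rng: np.random.Generator | int | None = None) -> BeliefPrediction:
    """Simulate the observer ``n_sim`` times on the identical stimulus sequence."""
    rng = np.random.default_rng(rng)
    sims = np.empty((n_sim, len(table)))
    for s in range(n_sim):
        sims[s] = simulate_from_table(table, params, maps, rng)["belief_report"].to_numpy()
    return BeliefPrediction(beliefs=sims,
                            block_ids=table["block_id"].to_numpy(),
                            trial_index=table["trial_index"].to_numpy())


def end_of_block_mse(predicted_end: pd.Series | np.ndarray,
                     reported_end: pd.Series | np.ndarray) -> float:
    """MSE over blocks between predicted and reported end-of-block beliefs."""
    p = np.asarray(predicted_end, dtype=float)
    r = np.asarray(reported_end, dtype=float)
    if p.shape != r.shape:
        raise AlignmentError("predicted and reported end-of-block beliefs must align")
    return float(np.mean((p - r) ** 2))


def reported_end_of_block(table: pd.DataFrame) -> pd.Series:
    last = table.sort_values(["block_id", "trial_index"]).groupby("block_id").tail(1)
    return last.set_index("block_id")["belief_report"]


def compare_belief_mse(params_a: ObserverParams, params_b: ObserverParams,
                       table: pd.DataFrame,
                       maps_a: LikelihoodMaps, maps_b: LikelihoodMaps,
                       n_rep: int = 200,
                       rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Paired end-of-block MSE comparison between two update rules.

    Each repetition simulates both models once on the identical stimulus
    sequence; the empirical p-value is the proportion of repetitions in
    which model b beats model a.  Each model's noise stream is keyed by its
    own identity, so swapping the two arguments exactly negates ``diff``.
    """
    rng = np.random.default_rng(rng)
    reports = reported_end_of_block(table).to_numpy()
    rows = []
    rep_seeds = rng.integers(2 ** 31, size=n_rep)

    def _stream(seed, params):
        key = hash((params.model_id, round(params.alpha_lag, 6),
                    round(params.alpha_lag_pb, 6))) % (2 ** 31)
        return np.random.default_rng([int(seed), key])

    for seed in rep_seeds:
        pa = predict_beliefs(params_a, table, maps_a, n_sim=1,
                             rng=_stream(seed, params_a))
        pb = predict_beliefs(params_b, table, maps_b, n_sim=1,
                             rng=_stream(seed, params_b))
        mse_a = end_of_block_mse(pa.mean_end_of_block().to_numpy(), reports)
        mse_b = end_of_block_mse(pb.mean_end_of_block().to_numpy(), reports)
        rows.append((mse_a, mse_b))
    df = pd.DataFrame(rows, columns=["mse_a", "mse_b"])
    df["diff"] = df["mse_a"] - df["mse_b"]
    df.attrs["p_b_beats_a"] = float((df["mse_b"] < df["mse_a"]).mean())
    return df


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

def _with_derived(table: pd.DataFrame) -> pd.DataFrame:
    t = table.sort_values(["subject_id", "block_id", "trial_index"],
                          kind="stable").reset_index(drop=True).copy()
    t["c"] = t["coherence_signed"].astype(float)
    t["abs_c"] = t["c"].abs()
    t["T"] = t["duration_s"].astype(float)
    t["choice_r"] = (t["choice"] == "R").astype(float)
    if "direction" in t.columns:
        t["correct"] = (t["choice"] == t["direction"]).astype(float)
    else:
        # fall back to the sign of the coherence (0% trials excluded there)
        t["correct"] = np.where(t["c"] > 0, t["choice_r"],
                                np.where(t["c"] < 0, 1 - t["choice_r"], np.nan))
    t["B"] = t["base_rate"].astype(float)
    t["Bs"] = np.abs(t["B"] - 0.5) + 0.5            # informativeness
    t["Bsr"] = np.where(t["choice_r"] > 0.5, t["B"], 1 - t["B"])
    grp = t.groupby(["subject_id", "block_id"], sort=False)
    if "belief_report" in t.columns:
        prev = grp["belief_report"].shift(1)
        t["belief_prev"] = prev.fillna(0.5)
        t["delta_belief"] = t["belief_report"] - t["belief_prev"]
        t["belief_c"] = np.where(t["choice_r"] > 0.5, t["belief_report"],
                                 1 - t["belief_report"])
    t["prev_c"] = grp["c"].shift(1)
    return t


def _dummies(values: pd.Series, prefix: str, omit_last: bool,
             scale: np.ndarray | None = None) -> pd.DataFrame:
    levels = sorted(values.unique())
    if omit_last:
        levels = levels[:-1]
    cols = {}
    for lv in levels:
        ind = (values == lv).astype(float).to_numpy()
        cols[f"{prefix}{lv}"] = ind if scale is None else ind * scale
    return pd.DataFrame(cols, index=values.index)


def build_design(spec_id: str, table: pd.DataFrame):
    """Response vector, design matrix and GLM family for one analysis.

    Categorical families keep all levels when no other column spans the
    intercept and omit their last level otherwise, so the matrix stays
    full rank (the rank is verified and a DesignError names the collinear
    columns if not).
    """
    t = _with_derived(table)
    subj = t["subject_id"]
    n_subj = subj.nunique()

    if spec_id == "eq19_choice_bias":
        y = t["choice_r"]
        X = pd.concat([
            pd.DataFrame({"T:c": t["T"] * t["c"]}),
            _dummies(t["B"], "c@B=", False, scale=t["c"].to_numpy()),
            _dummies(t["B"], "I@B=", False),
            _dummies(subj, "subj=", True),
        ], axis=1)
        family = "logistic"
    elif spec_id == "eq20_confidence":
        t = t[t["correct"] == 1.0]
        y = t["confidence_raw"].astype(float)
        X = pd.concat([
            pd.DataFrame({"abs_c": t["abs_c"], "Bsr": t["Bsr"],
                          "h": t["choice_r"]}),
            _dummies(t["subject_id"], "subj=", False),
        ], axis=1)
        family = "linear"
    elif spec_id == "eq21_accuracy_course":
        t = t[t["correct"].notna()]
        y = t["correct"]
        parts = [pd.DataFrame({"abs_c": t["abs_c"], "T": t["T"]})]
        if n_subj > 1:
            parts.append(_dummies(t["subject_id"], "subj=", True))
            parts.append(_dummies(t["subject_id"], "abs_c:subj=", True,
                                  scale=t["abs_c"].to_numpy()))
        parts.append(_dummies(t["trial_index"], "I@N=", False))
        parts.append(_dummies(t["trial_index"], "Bs@N=", False,
                              scale=t["Bs"].to_numpy()))
        X = pd.concat(parts, axis=1)
        family = "logistic"
    elif spec_id == "eq22_highconf_course":
        y = (t["confidence_category"] == "high").astype(float)
        parts = [pd.DataFrame({"abs_c": t["abs_c"], "T": t["T"],
                               "h": t["choice_r"], "a": t["correct"].fillna(0.0)})]
        if n_subj > 1:
            parts.append(_dummies(t["subject_id"], "subj=", True))
            parts.append(_dummies(t["subject_id"], "abs_c:subj=", True,
                                  scale=t["abs_c"].to_numpy()))
            parts.append(_dummies(t["subject_id"], "abs_c.a:subj=", True,
                                  scale=(t["abs_c"] * t["correct"].fillna(0.0)).to_numpy()))
        parts.append(_dummies(t["trial_index"], "I@N=", False))
        parts.append(_dummies(t["trial_index"], "Bsr@N=", False,
                              scale=t["Bsr"].to_numpy()))
        X = pd.concat(parts, axis=1)
        family = "logistic"
    elif spec_id == "eq23_delta_belief":
        t = t[t["correct"] == 1.0]
        sign = np.where(t["choice_r"] > 0.5, 1.0, -1.0)
        y = pd.Series(t["delta_belief"].to_numpy() * sign, index=t.index)
        X = pd.concat([
            pd.DataFrame({"abs_c": t["abs_c"], "T": t["T"],
                          "belief_c": t["belief_c"]}),
            _dummies(t["subject_id"], "subj=", False),
        ], axis=1)
        family = "linear"
    elif spec_id == "eq24_consistency":
        mask = (t["abs_c"] == 0.0) & ((t["belief_prev"] < 0.05)
                                      | (t["belief_prev"] > 0.95))
        t = t[mask]
        if len(t) == 0:
            raise DesignError("no 0%-coherence trials with near-certain prior belief")
        y = ((t["choice_r"] > 0.5) == (t["belief_prev"] > 0.5)).astype(float)
        X = pd.concat([
            pd.DataFrame({"Bs": t["Bs"], "T": t["T"]}),
            _dummies(t["subject_id"], "subj=", False),
        ], axis=1)
        family = "logistic"
    else:
        raise ValueError(f"unknown regression spec {spec_id!r}")

    X = X.astype(float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the columns involved in the deficiency
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[j] for j in range(X.shape[1])
               if abs(r[min(j, r.shape[0] - 1), j]) < 1e-8]
        raise DesignError(f"design matrix rank {rank} < {X.shape[1]}; "
                          f"collinear columns include {bad}")
    return np.asarray(y, dtype=float), X, family


def run_regression(spec_id: str, table: pd.DataFrame, drop_terms=()):
    """Fit one of the printed regression analyses by standard ML GLM/OLS.

    ``drop_terms`` removes named columns (for likelihood-ratio tests of
    nested nulls); returns the fitted statsmodels results object with the
    design columns attached as ``.design_columns``.
    """
    y, X, family = build_design(spec_id, table)
    if drop_terms:
        missing = [c for c in drop_terms if c not in X.columns]
        if missing:
            raise DesignError(f"cannot drop unknown columns {missing}")
        X = X.drop(columns=list(drop_terms))
    if family == "logistic":
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    else:
        res = sm.OLS(y, X).fit()
    res.design_columns = list(X.columns)
    res.spec_id = spec_id
    return res


def likelihood_ratio_test(spec_id: str, table: pd.DataFrame, null_terms):
    """LR test that the named coefficients are jointly zero."""
    from scipy.stats import chi2
    full = run_regression(spec_id, table)
    reduced = run_regression(spec_id, table, drop_terms=null_terms)
    stat = 2.0 * (full.llf - reduced.llf)
    df = len(null_terms)
    return dict(statistic=float(stat), df=df,
                pvalue=float(chi2.sf(stat, df)), full=full, reduced=reduced)


def regression_ensemble(spec_id: str, params: ObserverParams,
                        table: pd.DataFrame, maps: LikelihoodMaps,
                        n_sim: int = 200,
                        rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Model-side regression coefficients: the regression is run on each of
    ``n_sim`` independent simulations of the experiment and the
    coefficients averaged; the across-simulation SD is the SE estimate."""
    rng = np.random.default_rng(rng)
    coefs = []
    for _ in range(n_sim):
        sim = simulate_from_table(table, params, maps, rng)
        sim = sim.assign(
            confidence_category=np.where(
                sim["confidence_raw"] >= params.phi, "high", "low"))
        res = run_regression(spec_id, sim)
        coefs.append(res.params)
    df = pd.DataFrame(coefs)
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})


# ---------------------------------------------------------------------------
# zero-coherence (lag) diagnostics
# ---------------------------------------------------------------------------

def _percentile_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin labels by right-closed quantile edges, ties broken by stable rank."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(x))
    return np.minimum((ranks * n_bins) // len(x), n_bins - 1)


def zero_coherence_diagnostics(table: pd.DataFrame,
                               fit: FitResult | None = None,
                               pu: np.ndarray | None = None,
                               config: FitConfig | None = None) -> dict:
    """Belief-change summaries on 0%-coherence trials.

    Returns a dict with three tidy frames:

    ``belief_change_by_belief``: mean belief change vs currently held
    belief, 20 percentile bins — flat at zero for the no-lag Bayesian
    rule, positively sloped under a report lag.

    ``belief_change_by_prev_coherence``: as above in 5 bins, split by the
    sign of the previous trial's coherence.

    ``belief_change_by_counterfactual``: belief change vs the
    model-inferred counterfactual confidence, split by choice, as a
    centered 100-trial moving average.  Requires either an explicit ``pu``
    vector or a fit from which to infer it.
    """
    t = _with_derived(table)
    z = t[t["abs_c"] == 0.0].copy()
    if len(z) < 40:
        raise ValueError("too few 0%-coherence trials for the lag diagnostics")

    z["bin20"] = _percentile_bins(z["belief_prev"].to_numpy(), 20)
    d8d = z.groupby("bin20").agg(
        belief=("belief_prev", "mean"), dbelief=("delta_belief", "mean"),
        se=("delta_belief", lambda v: v.std(ddof=1) / np.sqrt(len(v))),
        n=("delta_belief", "size")).reset_index()

    zp = z[z["prev_c"].notna() & (z["prev_c"] != 0.0)].copy()
    zp["bin5"] = _percentile_bins(zp["belief_prev"].to_numpy(), 5)
    d8e = zp.groupby(["bin5", np.sign(zp["prev_c"]).rename("prev_sign")]).agg(
        belief=("belief_prev", "mean"),
        dbelief=("delta_belief", "mean"),
        n=("delta_belief", "size")).reset_index()

    d8f = None
    if pu is None and fit is not None:
        eng = LoglikEngine(table, config=config)
        qb = eng.prior_trajectory(fit.observer_params())
        from .fitting import invert_confidence_to_counterfactual
        conf_r = np.where(eng.choice_r > 0.5, eng.conf_transformed,
                          1 - eng.conf_transformed)
        pu_all = invert_confidence_to_counterfactual(conf_r, qb)
        pu = pu_all[t["abs_c"].to_numpy() == 0.0]
    if pu is not None:
        pu = np.asarray(pu, dtype=float)
        if len(pu) != len(z):
            raise AlignmentError("pu must align with the 0%-coherence trials")
        frames = []
        for label, mask in (("R", z["choice_r"].to_numpy() > 0.5),
                            ("L", z["choice_r"].to_numpy() <= 0.5)):
            pu_c = pu[mask]
            db = z["delta_belief"].to_numpy()[mask]
            order = np.argsort(pu_c, kind="stable")
            pu_s, db_s = pu_c[order], db[order]
            half = 50
            ma = np.array([db_s[max(0, i - half):i + half].mean()
                           for i in range(len(db_s))])
            frames.append(pd.DataFrame({"choice": label, "pu": pu_s,
                                        "dbelief_ma": ma}))
        d8f = pd.concat(frames, ignore_index=True)

    return {"belief_change_by_belief": d8d,
            "belief_change_by_prev_coherence": d8e,
            "belief_change_by_counterfactual": d8f}
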