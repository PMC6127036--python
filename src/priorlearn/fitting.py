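"""Maximum-likelihood fitting of the belief-updating models.

Each trial contributes the probability of the observed (choice,
high/low-confidence) pair, obtained by integrating the joint evidence
density p(e, te | c, T) over the region where the biased posterior for the
chosen side falls in the low band (0.5, phi) or the high band [phi, 1].
Because the biased posterior is a monotone function of the counterfactual
posterior pu at fixed E[B], the four outcome regions reduce to three
cutoffs on pu, and each trial's integral becomes a lookup in a
mass-vs-pu CDF precomputed from the Fokker–Planck solution.

Between trials the latent p(B) is propagated with the update weight nu
computed from the *subject's* observed choice and transformed confidence
(the counterfactual weight is recovered from reported confidence by
inverting the biased-posterior mapping).  The confidence transformation
rank-matches the raw reports onto simulated probability-correct values and
is refreshed iteratively during fitting.

Optimization is derivative-free (Nelder–Mead) from Latin-hypercube
restarts within box bounds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .ddm import AccumulatorParams, LikelihoodMaps, counterfactual_posterior_map
from .observer import (B_SUPPORT, MODEL_IDS, ObserverParams, make_prior,
                       simulate_from_table)

try:  # pragma: no cover - exercised implicitly
    from numba import njit
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]


LOG_FLOOR = 1e-10
CONF_EPS = 1e-4

_MODEL_CODES = {m: i for i, m in enumerate(MODEL_IDS)}

DEFAULT_BOUNDS = {
    "kappa": (1.0, 60.0),
    "bound": (0.3, 5.0),
    "phi": (0.501, 0.999),
    "omega1": (0.0, 20.0),
    "omega2": (0.0, 20.0),
    "beta_mix": (0.0, 1.0),
    "empirical_beta": (-20.0, 20.0),
    "alpha_lag_pb": (0.0, 0.95),
}


class SizeMismatchError(ValueError):
    pass


class OptimizationFailure(RuntimeError):
    pass


@dataclass
class FitConfig:
    """Numerical configuration of the fit (grids, clipping, optimizer effort)."""

    dt: float = 0.0075           # propagation step during fitting (s)
    n_evidence: int = 181        # evidence cells during fitting
    dt_sim: float = 0.002        # Euler step for transform simulations (s)
    conf_eps: float = CONF_EPS   # clip confidences before odds inversion
    log_floor: float = LOG_FLOOR
    maxfev: int = 400            # optimizer budget per restart
    transform_tol: float = 0.01  # stop transform/fit alternation below this |dLL|
    max_transform_iter: int = 3
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))


# ---------------------------------------------------------------------------
# confidence preprocessing
# ---------------------------------------------------------------------------

def binarize_confidence(table: pd.DataFrame, q: float = 0.3) -> pd.Series:
    """Label each trial's confidence 'low'/'high' at the per-subject q-quantile.

    The lowest ``q`` fraction of each subject's reports is low; ties at the
    threshold fall in 'low'.  A subject with all-identical reports gets all
    'high' (with a warning).
    """
    out = pd.Series(index=table.index, dtype=object)
    for _, idx in table.groupby("subject_id").groups.items():
        raw = table.loc[idx, "confidence_raw"].to_numpy(dtype=float)
        if len(raw) < 10:
            raise ValueError("need >= 10 trials per subject to binarize confidence")
        if raw.min() == raw.max():
            warnings.warn("all confidence reports identical; labeling all 'high'")
            out.loc[idx] = "high"
            continue
        thr = np.quantile(raw, q, method="inverted_cdf")
        out.loc[idx] = np.where(raw <= thr, "low", "high")
    return out


def transform_confidence(raw: np.ndarray, simulated: np.ndarray) -> np.ndarray:
    """Rank-match raw confidence reports onto simulated probability-correct.

    The trial with the k-th smallest raw report receives the k-th smallest
    simulated value, so the transformed distribution equals the simulated
    one; tied raw reports receive the mean of their simulated band, keeping
    the map weakly monotone.
    """
    raw = np.asarray(raw, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if raw.shape != simulated.shape:
        raise SizeMismatchError(
            f"raw ({raw.shape}) and simulated ({simulated.shape}) differ in length")
    order = np.argsort(raw, kind="stable")
    t = np.empty_like(raw)
    t[order] = np.sort(simulated)
    vals, inv = np.unique(raw, return_inverse=True)
    if len(vals) < len(raw):  # average within tied bands
        sums = np.bincount(inv, weights=t)
        cnts = np.bincount(inv)
        t = (sums / cnts)[inv]
    return t


def invert_confidence_to_counterfactual(conf_r: float, prior_r: float,
                                        eps: float = CONF_EPS):
    """Recover the counterfactual posterior from reported confidence.

    Exact inverse of the biased posterior: odds(pu) = odds(conf_R) *
    (1 - prior_R) / prior_R.  Confidences at the scale endpoints are
    clipped to [eps, 1-eps] to keep the odds finite.
    """
    c = np.clip(conf_r, eps, 1.0 - eps)
    p = np.clip(prior_r, eps, 1.0 - eps)
    odds = (c / (1.0 - c)) * ((1.0 - p) / p)
    return odds / (1.0 + odds)


# ---------------------------------------------------------------------------
# per-trial outcome masses
# ---------------------------------------------------------------------------

def _pu_cutoffs(qb: float, phi: float):
    """Cutoffs on pu for the four (choice, confidence) regions at prior E[B]=qb."""
    u0 = 1.0 - qb
    u_rh = phi * (1.0 - qb) / (qb * (1.0 - phi) + phi * (1.0 - qb))
    u_lh = (1.0 - phi) * (1.0 - qb) / (qb * phi + (1.0 - phi) * (1.0 - qb))
    return u_lh, u0, u_rh


def _masses_from_cdf(pu_sorted, cum, qb, phi):
    """Outcome masses (Lhigh, Llow, Rlow, Rhigh) from a mass-vs-pu CDF.

    High bands are closed ([phi, 1] in posterior units); an atom exactly at
    the choice boundary splits evenly between the two low cells (a tie in
    posterior is decided by a fair coin).
    """
    u_lh, u0, u_rh = _pu_cutoffs(qb, phi)
    total = cum[-1]

    def f_left(x):
        i = np.searchsorted(pu_sorted, x, side="left")
        return cum[i - 1] if i > 0 else 0.0

    def f_right(x):
        i = np.searchsorted(pu_sorted, x, side="right")
        return cum[i - 1] if i > 0 else 0.0

    m_lh = f_right(u_lh)
    atom0 = f_right(u0) - f_left(u0)
    m_l = f_left(u0) + 0.5 * atom0
    m_rh = total - f_left(u_rh)
    m_llow = max(m_l - m_lh, 0.0)
    m_rlow = max(total - m_l - m_rh, 0.0)
    return np.array([m_lh, m_llow, m_rlow, m_rh]) / total


def trial_joint_likelihood(maps: LikelihoodMaps, c: float, T: float,
                           expected_b: float, phi: float) -> dict:
    """Probabilities of the four (choice, confidence) outcomes for one trial.

    Integrates p(e, te | c, T) over the regions where the biased posterior
    of the chosen side is in (0.5, phi) (low) or [phi, 1] (high).
    """
    k = int(maps.time_index(T))
    pu, mass = maps.joint_atoms(c, k)
    mass = np.clip(mass, 0.0, None)
    order = np.argsort(pu)
    m = _masses_from_cdf(pu[order], np.cumsum(mass[order]),
                         float(np.clip(expected_b, 1e-9, 1 - 1e-9)), phi)
    return {("L", "high"): m[0], ("L", "low"): m[1],
            ("R", "low"): m[2], ("R", "high"): m[3]}


# ---------------------------------------------------------------------------
# dataset log-likelihood engine
# ---------------------------------------------------------------------------

@njit(cache=True)
def _loglik_kernel(new_block, obs_code, choice_r, conf_r,
                   pu_flat, cum_flat, off, ln,
                   prior0, b_support, model_code, phi,
                   beta_mix, betas, alpha_pb, log_floor):  # pragma: no cover
    n = len(obs_code)
    ll_trial = np.empty(n)
    floor_count = 0
    p = prior0.copy()
    for i in range(n):
        if new_block[i]:
            p = prior0.copy()
        qb = 0.0
        for j in range(6):
            qb += b_support[j] * p[j]
        if qb < 1e-9:
            qb = 1e-9
        elif qb > 1.0 - 1e-9:
            qb = 1.0 - 1e-9
        u0 = 1.0 - qb
        u_rh = phi * (1.0 - qb) / (qb * (1.0 - phi) + phi * (1.0 - qb))
        u_lh = (1.0 - phi) * (1.0 - qb) / (qb * phi + (1.0 - phi) * (1.0 - qb))

        o = off[i]
        l = ln[i]
        pu = pu_flat[o:o + l]
        cum = cum_flat[o:o + l]
        total = cum[l - 1]

        i_lh = np.searchsorted(pu, u_lh, side='right')
        m_lh = cum[i_lh - 1] if i_lh > 0 else 0.0
        i0l = np.searchsorted(pu, u0, side='left')
        i0r = np.searchsorted(pu, u0, side='right')
        f0l = cum[i0l - 1] if i0l > 0 else 0.0
        f0r = cum[i0r - 1] if i0r > 0 else 0.0
        m_l = f0l + 0.5 * (f0r - f0l)
        i_rh = np.searchsorted(pu, u_rh, side='left')
        m_rh = total - (cum[i_rh - 1] if i_rh > 0 else 0.0)
        m_llow = m_l - m_lh
        if m_llow < 0.0:
            m_llow = 0.0
        m_rlow = total - m_l - m_rh
        if m_rlow < 0.0:
            m_rlow = 0.0

        oc = obs_code[i]
        if oc == 0:
            m = m_lh
        elif oc == 1:
            m = m_llow
        elif oc == 2:
            m = m_rlow
        else:
            m = m_rh
        m = m / total
        if m < log_floor:
            m = log_floor
            floor_count += 1
        ll_trial[i] = np.log(m)

        # propagate p(B) with the model's update weight from the observed
        # choice and transformed confidence
        cr = conf_r[i]
        if model_code == 0:  # bayesian: invert confidence to counterfactual
            odds = (cr / (1.0 - cr)) * ((1.0 - qb) / qb)
            nu_r = odds / (1.0 + odds)
        elif model_code == 1:  # choice only
            nu_r = choice_r[i]
        elif model_code == 2:  # choice confidence
            nu_r = cr
        elif model_code == 4:  # mixture
            odds = (cr / (1.0 - cr)) * ((1.0 - qb) / qb)
            pu_inv = odds / (1.0 + odds)
            nu_r = beta_mix * pu_inv + (1.0 - beta_mix) * cr
        else:  # empirical
            if choice_r[i] > 0.5:
                conf_d = cr
                p_d = qb
            else:
                conf_d = 1.0 - cr
                p_d = 1.0 - qb
            z = (betas[0] + betas[1] * conf_d + betas[2] * p_d
                 + betas[3] * conf_d * p_d + betas[4] * conf_d * conf_d)
            nu_d = 1.0 / (1.0 + np.exp(-z))
            nu_r = nu_d if choice_r[i] > 0.5 else 1.0 - nu_d

        s = 0.0
        p_new = np.empty(6)
        for j in range(6):
            p_new[j] = p[j] * (b_support[j] * nu_r
                               + (1.0 - b_support[j]) * (1.0 - nu_r))
            s += p_new[j]
        if s > 1e-300:
            if alpha_pb > 0.0:
                w = 1.0 - alpha_pb
                for j in range(6):
                    p[j] = p[j] + (p_new[j] / s - p[j]) * w
            else:
                for j in range(6):
                    p[j] = p_new[j] / s
        # else: degenerate update; keep previous p(B)
    return ll_trial, floor_count


class LoglikEngine:
    """Evaluates the dataset log-likelihood for one subject.

    Binds the dataset's stimulus sequence and observed reports; each call
    to :meth:`loglik` rebuilds the Fokker–Planck maps for the candidate
    (kappa, A), assembles per-trial mass-vs-pu CDFs, and runs the
    sequential p(B) propagation.
    """

    def __init__(self, table: pd.DataFrame, config: FitConfig | None = None,
                 category: np.ndarray | None = None):
        self.config = config or FitConfig()
        table = validate_fit_table(table)
        self.table = table
        self.c_signed = table["coherence_signed"].to_numpy(dtype=float)
        self.T = table["duration_s"].to_numpy(dtype=float)
        self.choice_r = (table["choice"].to_numpy() == "R").astype(float)
        self.raw_conf = table["confidence_raw"].to_numpy(dtype=float)
        if category is None:
            if "confidence_category" in table.columns and table["confidence_category"].notna().all():
                category = table["confidence_category"].to_numpy()
            else:
                category = binarize_confidence(table).to_numpy()
        high = np.asarray(category) == "high"
        # outcome codes: 0 L-high, 1 L-low, 2 R-low, 3 R-high
        self.obs_code = np.where(self.choice_r > 0.5,
                                 np.where(high, 3, 2),
                                 np.where(high, 0, 1)).astype(np.int64)
        bid = table["block_id"].to_numpy()
        self.new_block = np.concatenate(([True], bid[1:] != bid[:-1]))
        self.nobs = len(table)
        self._maps_cache: tuple[tuple[float, float], LikelihoodMaps] | None = None
        # default transform: raw reports used as posterior directly
        self.conf_transformed = self.raw_conf.copy()

    # -- confidence transform ------------------------------------------------
    def refresh_transform(self, params: ObserverParams, rng: np.random.Generator):
        """Rank-match raw confidences onto a fresh model simulation."""
        maps = self.maps_for(params.kappa, params.bound)
        sim = simulate_from_table(self.table, params, maps, rng)
        self.conf_transformed = transform_confidence(
            self.raw_conf, sim["confidence_raw"].to_numpy())

    def maps_for(self, kappa: float, bound: float) -> LikelihoodMaps:
        key = (round(float(kappa), 12), round(float(bound), 12))
        if self._maps_cache is not None and self._maps_cache[0] == key:
            return self._maps_cache[1]
        acc = AccumulatorParams(kappa=kappa, bound=bound, dt=self.config.dt,
                                n_evidence=self.config.n_evidence,
                                dt_sim=self.config.dt_sim)
        maps = counterfactual_posterior_map(acc)
        self._maps_cache = (key, maps)
        return maps

    # -- evaluation ----------------------------------------------------------
    def _trial_cdfs(self, maps: LikelihoodMaps):
        k_arr = maps.time_index(self.T)
        ckey = np.round(self.c_signed, 6)
        groups: dict[tuple[float, int], int] = {}
        pu_parts, cum_parts, offsets, lengths = [], [], [], []
        off_of_group, len_of_group = [], []
        pos = 0
        uidx = np.empty(self.nobs, dtype=np.int64)
        for i in range(self.nobs):
            key = (ckey[i], int(k_arr[i]))
            g = groups.get(key)
            if g is None:
                pu, mass = maps.joint_atoms(key[0], key[1])
                mass = np.clip(mass, 0.0, None)
                order = np.argsort(pu)
                pu_parts.append(pu[order])
                cum_parts.append(np.cumsum(mass[order]))
                g = len(off_of_group)
                groups[key] = g
                off_of_group.append(pos)
                len_of_group.append(len(pu))
                pos += len(pu)
            uidx[i] = g
        pu_flat = np.concatenate(pu_parts)
        cum_flat = np.concatenate(cum_parts)
        off = np.asarray(off_of_group, dtype=np.int64)[uidx]
        ln = np.asarray(len_of_group, dtype=np.int64)[uidx]
        return pu_flat, cum_flat, off, ln

    def prior_trajectory(self, params: ObserverParams) -> np.ndarray:
        """Per-trial prior expectation E[B] implied by the observed reports.

        Propagates p(B) exactly as the likelihood does (from the subject's
        choices and transformed confidences) and returns E[B] *before* each
        trial's update — the prior the model says the subject held.
        """
        from .observer import compute_nu  # local import to avoid cycle at import time
        eps = self.config.conf_eps
        prior0 = make_prior(params.omega1, params.omega2).probs
        qb_out = np.empty(self.nobs)
        p = prior0.copy()
        for i in range(self.nobs):
            if self.new_block[i]:
                p = prior0.copy()
            qb = float(np.clip(B_SUPPORT @ p, 1e-9, 1 - 1e-9))
            qb_out[i] = qb
            conf = float(np.clip(self.conf_transformed[i], 0.5, 1.0 - eps))
            choice = "R" if self.choice_r[i] > 0.5 else "L"
            conf_r = conf if choice == "R" else 1.0 - conf
            pu_inv = float(invert_confidence_to_counterfactual(conf_r, qb, eps))
            nu_r = compute_nu(params.model_id, choice, conf, pu_inv, qb, params)
            mult = B_SUPPORT * nu_r + (1.0 - B_SUPPORT) * (1.0 - nu_r)
            p_new = p * mult
            s = p_new.sum()
            if s > 1e-300:
                p_new /= s
                if params.alpha_lag_pb > 0.0:
                    p = p + (p_new - p) * (1.0 - params.alpha_lag_pb)
                else:
                    p = p_new
        return qb_out

    def loglik(self, params: ObserverParams, per_trial: bool = False):
        maps = self.maps_for(params.kappa, params.bound)
        pu_flat, cum_flat, off, ln = self._trial_cdfs(maps)
        eps = self.config.conf_eps
        conf_r = np.where(self.choice_r > 0.5, self.conf_transformed,
                          1.0 - self.conf_transformed)
        conf_r = np.clip(conf_r, eps, 1.0 - eps)
        prior0 = make_prior(params.omega1, params.omega2).probs
        betas = np.asarray(params.empirical_betas
                           if params.empirical_betas is not None else np.zeros(5),
                           dtype=float)
        ll_trial, floor_count = _loglik_kernel(
            self.new_block, self.obs_code, self.choice_r, conf_r,
            pu_flat, cum_flat, off, ln, prior0, B_SUPPORT,
            _MODEL_CODES[params.model_id],
            float(np.clip(params.phi, 0.5 + 1e-9, 1.0 - 1e-9)),
            float(params.beta_mix if params.beta_mix is not None else 1.0),
            betas, float(params.alpha_lag_pb), self.config.log_floor)
        if per_trial:
            return ll_trial, floor_count
        return float(ll_trial.sum()), floor_count


def validate_fit_table(table: pd.DataFrame) -> pd.DataFrame:
    required = ["block_id", "trial_index", "coherence_signed", "duration_s",
                "choice", "confidence_raw"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"fit table is missing columns: {missing}")
    if "subject_id" in table.columns and table["subject_id"].nunique() > 1:
        raise ValueError("fit one subject at a time")
    if "subject_id" not in table.columns:
        table = table.assign(subject_id="S1")
    return table.sort_values(["block_id", "trial_index"], kind="stable").reset_index(drop=True)


def dataset_loglik(table: pd.DataFrame, params: ObserverParams,
                   config: FitConfig | None = None,
                   conf_transformed: np.ndarray | None = None) -> float:
    """Total log-likelihood of (choice, confidence-category) data.

    With ``conf_transformed=None`` the raw confidence reports are used
    directly as posterior probabilities in the p(B) propagation; pass a
    transformed vector (see :func:`transform_confidence`) to reproduce the
    full fitting pipeline.
    """
    eng = LoglikEngine(table, config=config)
    if conf_transformed is not None:
        eng.conf_transformed = np.asarray(conf_transformed, dtype=float)
    ll, _ = eng.loglik(params)
    return ll


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _param_names(model_id: str, fit_update_lag: bool) -> list[str]:
    names = ["kappa", "bound", "phi", "omega1", "omega2"]
    if model_id == "mixture":
        names.append("beta_mix")
    elif model_id == "empirical":
        names += [f"beta{i}" for i in range(5)]
    if fit_update_lag:
        names.append("alpha_lag_pb")
    return names


def _bounds_for(names, bounds) -> list[tuple[float, float]]:
    out = []
    for nm in names:
        if nm.startswith("beta") and nm != "beta_mix":
            out.append(bounds["empirical_beta"])
        else:
            out.append(bounds[nm])
    return out


def _vector_to_params(x, model_id: str, fit_update_lag: bool) -> ObserverParams:
    kappa, bound, phi, om1, om2 = x[:5]
    extra = list(x[5:])
    beta_mix = None
    betas = None
    alpha_pb = 0.0
    if model_id == "mixture":
        beta_mix = float(extra.pop(0))
    elif model_id == "empirical":
        betas = tuple(float(v) for v in extra[:5])
        extra = extra[5:]
    if fit_update_lag:
        alpha_pb = float(extra.pop(0))
    return ObserverParams(kappa=float(kappa), bound=float(bound),
                          phi=float(min(max(phi, 0.5 + 1e-9), 1.0)),
                          omega1=float(max(om1, 0.0)), omega2=float(max(om2, 0.0)),
                          model_id=model_id, beta_mix=beta_mix,
                          empirical_betas=betas, alpha_lag_pb=alpha_pb)


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model to one subject's data."""

    model_id: str
    params: dict
    llf: float
    llf_trial: np.ndarray
    nobs: int
    n_params: int
    n_starts: int
    best_start: int
    converged: bool
    floor_count: int
    dataset_fingerprint: str
    fit_update_lag: bool = False

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.llf

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.nobs) - 2.0 * self.llf

    def observer_params(self) -> ObserverParams:
        p = self.params
        betas = tuple(p[f"beta{i}"] for i in range(5)) if "beta0" in p else None
        return ObserverParams(kappa=p["kappa"], bound=p["bound"], phi=p["phi"],
                              omega1=p["omega1"], omega2=p["omega2"],
                              model_id=self.model_id,
                              beta_mix=p.get("beta_mix"),
                              empirical_betas=betas,
                              alpha_lag_pb=p.get("alpha_lag_pb", 0.0))

    def to_json(self) -> str:
        d = asdict(self)
        d["llf_trial"] = None  # keep serialized results compact
        d["aic"] = self.aic
        d["bic"] = self.bic
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "FitResult":
        d = json.loads(s)
        d.pop("aic", None)
        d.pop("bic", None)
        d["llf_trial"] = np.array([])
        return cls(**d)


def _fingerprint(table: pd.DataFrame) -> str:
    import hashlib
    h = hashlib.sha256()
    for col in ("block_id", "trial_index", "coherence_signed", "duration_s",
                "choice", "confidence_raw"):
        h.update(np.ascontiguousarray(table[col].to_numpy()).tobytes()
                 if table[col].dtype != object
                 else "".join(map(str, table[col])).encode())
    return h.hexdigest()[:16]


def fit_model(table: pd.DataFrame, model_id: str = "bayesian",
              n_starts: int = 30, rng: np.random.Generator | int | None = None,
              config: FitConfig | None = None, fit_update_lag: bool = False,
              use_transform: bool = True) -> FitResult:
    """Fit one model to one subject by multi-start bounded Powell search.

    All restarts are scored under a common initial confidence transform
    (the raw reports); the rank-matching transform is then alternated with
    re-optimization at the incumbent optimum until the log-likelihood
    change drops below ``config.transform_tol``.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    rng = np.random.default_rng(rng)
    config = config or FitConfig()
    eng = LoglikEngine(table, config=config)
    names = _param_names(model_id, fit_update_lag)
    bounds = _bounds_for(names, config.bounds)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    sampler = qmc.LatinHypercube(d=len(names), seed=int(rng.integers(2 ** 31)))
    starts = lo + sampler.random(n_starts) * (hi - lo)

    def neg_ll(x):
        params = _vector_to_params(np.clip(x, lo, hi), model_id, fit_update_lag)
        ll, _ = eng.loglik(params)
        return -ll

    def _minimize(x0, budget):
        # ftol is relative: at |logL| ~ 1e3 it must sit well below 1e-5
        # or the search stops on likelihood plateaus far from the optimum
        return optimize.minimize(neg_ll, x0, method="Powell", bounds=bounds,
                                 options=dict(maxfev=budget, xtol=1e-4,
                                              ftol=1e-7))

    # all restarts share the same confidence transform (the raw reports,
    # already on the probability-correct scale) so their objectives are
    # directly comparable; the rank-matching transform is then alternated
    # with re-optimization at the incumbent optimum
    best = None
    results = []
    for s_idx in range(n_starts):
        res = _minimize(starts[s_idx], config.maxfev)
        results.append(res)
        if best is None or res.fun < best[1].fun:
            best = (s_idx, res)
    if best is None:
        raise OptimizationFailure("no optimizer start produced a result")
    s_idx, res = best

    settled = not use_transform
    if use_transform:
        prev_ll = -res.fun
        for _ in range(config.max_transform_iter):
            eng.refresh_transform(
                _vector_to_params(res.x, model_id, fit_update_lag),
                np.random.default_rng(rng.integers(2 ** 31)))
            res = _minimize(res.x, config.maxfev // 2)
            if abs(-res.fun - prev_ll) < config.transform_tol:
                settled = True
                break
            prev_ll = -res.fun

    params = _vector_to_params(np.clip(res.x, lo, hi), model_id, fit_update_lag)
    ll_trial, floor_count = eng.loglik(params, per_trial=True)
    pdict = dict(zip(names, [float(v) for v in np.clip(res.x, lo, hi)]))
    return FitResult(model_id=model_id, params=pdict,
                     llf=float(ll_trial.sum()), llf_trial=ll_trial,
                     nobs=eng.nobs, n_params=len(names),
                     n_starts=n_starts, best_start=s_idx,
                     converged=bool(settled or res.success),
                     floor_count=int(floor_count),
                     dataset_fingerprint=_fingerprint(eng.table),
                     fit_update_lag=fit_update_lag)


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """Comparison table: log-likelihood, AIC and BIC deltas vs the best model."""
    if len({f.dataset_fingerprint for f in fits}) > 1:
        raise ValueError("fits being compared were obtained on different datasets")
    df = pd.DataFrame([dict(model_id=f.model_id, llf=f.llf, n_params=f.n_params,
                            aic=f.aic, bic=f.bic) for f in fits])
    df["d_llf"] = df["llf"].max() - df["llf"]
    df["d_aic"] = df["aic"] - df["aic"].min()
    df["d_bic"] = df["bic"] - df["bic"].min()
    return df


def fit_lag_alpha(reports: np.ndarray, predictions: np.ndarray,
                  block_ids: np.ndarray) -> float:
    """Report-lag time constant minimizing the MSE to the reports.

    Applies the first-order report filter (seeded at 0.5 per block) to the
    no-lag predicted beliefs and returns the alpha in [0, 1) with minimal
    mean squared error (coarse grid, then golden-section refinement).
    """
    reports = np.asarray(reports, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    block_ids = np.asarray(block_ids)
    if not (len(reports) == len(predictions) == len(block_ids)):
        raise SizeMismatchError("reports, predictions and block_ids must align")
    new_block = np.concatenate(([True], block_ids[1:] != block_ids[:-1]))

    def mse(alpha):
        f = 0.5
        err = 0.0
        w = 1.0 - alpha
        for i in range(len(reports)):
            if new_block[i]:
                f = 0.5
            f = f + (predictions[i] - f) * w
            err += (f - reports[i]) ** 2
        return err / len(reports)

    grid = np.linspace(0.0, 0.99, 34)
    vals = [mse(a) for a in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if lo == hi:
        return float(grid[k])
    res = optimize.minimize_scalar(mse, bounds=(lo, hi), method="bounded",
                                   options=dict(xatol=1e-4))
    return float(res.x) if res.fun <= vals[k] else float(grid[k])
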