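"""Bounded drift-diffusion core.

The decision variable ``e`` accumulates momentary evidence with drift
``kappa*c`` per second and unit diffusion variance per second, between
absorbing bounds at ``±A``.  A trial terminates when a bound is reached
(time ``te``, ``|e| = A``) or when the stimulus is curtailed at duration
``T`` (``te = T``).

Two routes to the same physics are provided:

* :func:`propagate_density` evolves the evidence distribution numerically
  (Fokker–Planck / forward Kolmogorov with absorbing boundaries), yielding
  the joint mass ``p(e, te | c)`` used in likelihood computations.
* :func:`simulate_trial_evidence` draws individual Euler–Maruyama sample
  paths (with an optional Brownian-bridge correction for intra-step bound
  crossings), used by the synthetic observer.

From the per-coherence densities, :func:`counterfactual_posterior_map`
builds the counterfactual posterior ``pu(R | e, te)`` — the probability
that motion is rightward given the terminal state under a fictitious
neutral prior — by marginalizing over the coherences compatible with each
direction.

The propagation uses a Crank–Nicolson step over a conservative
Scharfetter–Gummel (exponential-fitting) discretization of the
advection-diffusion operator.  Cell centers are placed so that the ghost
(absorbing) cells sit exactly at ``±A``; the resulting Markov chain
reproduces the continuous first-passage ("gambler's ruin") splitting
probabilities exactly at the cell centers, and mass is conserved to solver
round-off at every step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import diags
from scipy.sparse.linalg import factorized

from .task import COHERENCES

_DIFFUSION = 0.5  # sigma^2/2 with unit variance per second; not a free parameter

MIN_EVIDENCE_BINS = 17


class ResolutionError(ValueError):
    """Evidence grid too coarse to resolve the bounds."""


@dataclass(frozen=True)
class AccumulatorParams:
    """Accumulator configuration.

    kappa : signal-to-noise scale; drift is ``kappa*c`` per second.
    bound : absorbing bounds at ``±bound`` (evidence units).
    dt : time step (s) for density propagation.
    n_evidence : number of interior evidence cells (odd, so one cell sits
        exactly at ``e = 0``); ghost cells at ``±bound`` are absorbing.
    dt_sim : Euler–Maruyama step (s) for path simulation.
    t_max : largest supported time (s); the task curtails at 0.9 s.
    """

    kappa: float
    bound: float
    dt: float = 0.001
    n_evidence: int = 513
    dt_sim: float = 0.0005
    t_max: float = 0.9

    def __post_init__(self):
        if self.kappa <= 0 or self.bound <= 0 or self.dt <= 0:
            raise ValueError("kappa, bound and dt must be positive")
        if self.n_evidence < MIN_EVIDENCE_BINS:
            raise ResolutionError(
                f"n_evidence={self.n_evidence} < minimum {MIN_EVIDENCE_BINS}")
        if self.n_evidence % 2 == 0:
            raise ValueError("n_evidence must be odd (center cell at e=0)")

    @property
    def h(self) -> float:
        # ghost centers at +-bound => spacing 2A/(n+1)
        return 2.0 * self.bound / (self.n_evidence + 1)

    @property
    def evidence_grid(self) -> np.ndarray:
        j = np.arange(self.n_evidence)
        return -self.bound + (j + 1) * self.h

    @property
    def n_steps(self) -> int:
        return int(round(self.t_max / self.dt))

    @property
    def time_grid(self) -> np.ndarray:
        return self.dt * np.arange(1, self.n_steps + 1)


@dataclass(frozen=True)
class EvidenceOutcome:
    """Terminal accumulator state of one trial."""

    e: float
    te: float
    bound_hit: bool


@dataclass
class DensityPropagation:
    """Joint mass p(e, te | c) on the (evidence x time) grid for one coherence.

    ``interior[k, j]`` is the mass in evidence cell j at time step k+1
    (not yet absorbed); ``absorbed_top[k]`` / ``absorbed_bot[k]`` are the
    masses absorbed at +A / -A during step k+1 (te assigned to the end of
    the step).
    """

    c: float
    params: AccumulatorParams
    interior: np.ndarray       # (n_t, n_e)
    absorbed_top: np.ndarray   # (n_t,)
    absorbed_bot: np.ndarray   # (n_t,)

    @property
    def t_grid(self) -> np.ndarray:
        n_t = self.interior.shape[0]
        return self.params.dt * np.arange(1, n_t + 1)

    def total_mass(self, k: int) -> float:
        """Interior mass at step k plus all mass absorbed up to step k (0-based)."""
        return float(self.interior[k].sum()
                     + self.absorbed_top[: k + 1].sum()
                     + self.absorbed_bot[: k + 1].sum())

    def p_choice_right(self, k: int) -> float:
        """P(e > 0 or absorbed at +A) by step k, under sign(e) readout.

        The center cell sits exactly at e = 0; its mass is split evenly
        (a decision at exactly zero evidence is a fair coin).
        """
        jc = self.interior.shape[1] // 2
        inter = self.interior[k]
        return float(inter[jc + 1:].sum() + 0.5 * inter[jc]
                     + self.absorbed_top[: k + 1].sum())


def _sg_rates(mu: float, h: float) -> tuple[float, float]:
    """Scharfetter–Gummel up/down hop rates for drift mu, spacing h."""
    pe = mu * h / _DIFFUSION
    base = _DIFFUSION / h ** 2

    def bern(x):
        if abs(x) < 1e-10:
            return 1.0 - 0.5 * x
        return x / np.expm1(x)

    return base * bern(-pe), base * bern(pe)  # (rate up, rate down)


def propagate_density(params: AccumulatorParams, c: float,
                      t_max: float | None = None) -> DensityPropagation:
    """Numerically propagate the evidence density for signed coherence ``c``.

    Crank–Nicolson in time over the Scharfetter–Gummel master-equation
    generator; mass starts as a point at e = 0 and leaks only through the
    absorbing ghost cells at ``±A``.
    """
    if abs(c) > 1.0:
        raise ValueError("signed coherence must satisfy |c| <= 1")
    if t_max is None:
        t_max = params.t_max
    n = params.n_evidence
    h = params.h
    dt = params.dt
    n_t = int(round(t_max / dt))
    mu = params.kappa * c
    r_up, r_dn = _sg_rates(mu, h)

    # generator L: sub-diag r_up, super-diag r_dn, diag -(r_up+r_dn)
    diag = np.full(n, -(r_up + r_dn))
    L = diags([np.full(n - 1, r_up), diag, np.full(n - 1, r_dn)], [-1, 0, 1],
              format="csc")
    I = diags([np.ones(n)], [0], format="csc")
    solve_cn = factorized((I - 0.5 * dt * L).tocsc())
    solve_ie = factorized((I - 0.5 * dt * L).tocsc())  # implicit Euler, step dt/2
    M_rhs = (I + 0.5 * dt * L).tocsr()

    q = np.zeros(n)
    q[n // 2] = 1.0  # point mass at e = 0

    # Rannacher startup: the first two steps are taken as implicit-Euler
    # half-steps, which damp the Crank–Nicolson oscillations a point-mass
    # initial condition would otherwise excite (undershoots to negative
    # density).  Subsequent steps are plain Crank–Nicolson.
    n_smooth = 2
    interior = np.empty((n_t, n), dtype=float)
    a_top = np.empty(n_t)
    a_bot = np.empty(n_t)
    for k in range(n_t):
        if k < n_smooth:
            a_t = a_b = 0.0
            for _ in range(2):
                q = solve_ie(q)
                a_t += 0.5 * dt * r_up * q[-1]
                a_b += 0.5 * dt * r_dn * q[0]
            a_top[k], a_bot[k] = a_t, a_b
        else:
            q_new = solve_cn(M_rhs @ q)
            # CN-consistent boundary losses; their sum equals the mass deficit
            a_top[k] = 0.5 * dt * r_up * (q[-1] + q_new[-1])
            a_bot[k] = 0.5 * dt * r_dn * (q[0] + q_new[0])
            q = q_new
        interior[k] = q
    return DensityPropagation(c=c, params=params, interior=interior,
                              absorbed_top=a_top, absorbed_bot=a_bot)


def p_hit_upper_closed_form(mu: float, bound: float) -> float:
    """Gambler's-ruin probability of absorbing at +A before -A (unit variance,
    start at 0, unlimited time): logistic(2*mu*A)."""
    return float(1.0 / (1.0 + np.exp(-2.0 * mu * bound)))


@dataclass
class LikelihoodMaps:
    """Per-coherence joints, direction marginals and the counterfactual map.

    ``pu_interior[k, j]`` is pu(R | e_j, t_{k+1}) for non-absorbed states;
    ``pu_top`` / ``pu_bot`` are the corresponding values for trials absorbed
    at ``+A`` / ``-A`` during step k+1.  Grid nodes that no coherence can
    reach carry the tail-limit values (1 above, 0 below) and are flagged in
    ``reachable``.
    """

    params: AccumulatorParams
    coherences: tuple[float, ...]
    include_zero_both: bool
    densities: dict[float, DensityPropagation]
    pR_interior: np.ndarray
    pL_interior: np.ndarray
    pR_top: np.ndarray
    pL_top: np.ndarray
    pR_bot: np.ndarray
    pL_bot: np.ndarray
    pu_interior: np.ndarray
    pu_top: np.ndarray
    pu_bot: np.ndarray
    reachable: np.ndarray

    @property
    def e_grid(self) -> np.ndarray:
        return self.params.evidence_grid

    @property
    def t_grid(self) -> np.ndarray:
        n_t = self.pu_interior.shape[0]
        return self.params.dt * np.arange(1, n_t + 1)

    # -- lookups ----------------------------------------------------------
    def time_index(self, te) -> np.ndarray:
        """Nearest time-step index (0-based) for time(s) te."""
        n_t = self.pu_interior.shape[0]
        k = np.rint(np.asarray(te, dtype=float) / self.params.dt).astype(int) - 1
        return np.clip(k, 0, n_t - 1)

    def pu_lookup(self, e, te, bound_hit):
        """Counterfactual posterior for terminal states (vectorized).

        Interior states use bilinear interpolation on (t, e); absorbed
        states use the bound columns at the nearest time step.
        """
        e = np.atleast_1d(np.asarray(e, dtype=float))
        te = np.atleast_1d(np.asarray(te, dtype=float))
        bound_hit = np.atleast_1d(np.asarray(bound_hit, dtype=bool))
        out = np.empty(e.shape, dtype=float)

        kf = np.clip(te / self.params.dt - 1.0, 0.0, self.pu_interior.shape[0] - 1.0)
        k0 = np.floor(kf).astype(int)
        k1 = np.minimum(k0 + 1, self.pu_interior.shape[0] - 1)
        wt = kf - k0

        grid = self.e_grid
        jf = np.clip((e - grid[0]) / self.params.h, 0.0, len(grid) - 1.0)
        j0 = np.floor(jf).astype(int)
        j1 = np.minimum(j0 + 1, len(grid) - 1)
        we = jf - j0

        pu00 = self.pu_interior[k0, j0]
        pu01 = self.pu_interior[k0, j1]
        pu10 = self.pu_interior[k1, j0]
        pu11 = self.pu_interior[k1, j1]
        interior_val = ((1 - wt) * ((1 - we) * pu00 + we * pu01)
                        + wt * ((1 - we) * pu10 + we * pu11))

        top = e > 0
        bound_val = np.where(top,
                             (1 - wt) * self.pu_top[k0] + wt * self.pu_top[k1],
                             (1 - wt) * self.pu_bot[k0] + wt * self.pu_bot[k1])
        out = np.where(bound_hit, bound_val, interior_val)
        return out if out.shape != (1,) else float(out[0])

    def joint_atoms(self, c: float, k: int):
        """All (pu, mass) atoms of p(e, te | c, T = t_{k+1}).

        Interior cells at step k plus both absorbed streams up to step k.
        """
        dens = self.densities[_ckey(c)]
        pu = np.concatenate([self.pu_interior[k], self.pu_top[: k + 1],
                             self.pu_bot[: k + 1]])
        mass = np.concatenate([dens.interior[k], dens.absorbed_top[: k + 1],
                               dens.absorbed_bot[: k + 1]])
        return pu, mass

    def choice_prob_right(self, c: float, T: float, expected_b: float = 0.5) -> float:
        """P(choice = R | c, T) under prior expectation ``expected_b``.

        The choice is rightward when the biased posterior exceeds 0.5,
        i.e. when pu exceeds 1 - E[B]; mass exactly at the cut splits evenly.
        """
        k = int(self.time_index(T))
        pu, mass = self.joint_atoms(c, k)
        u0 = 1.0 - expected_b
        return float(mass[pu > u0].sum() + 0.5 * mass[np.isclose(pu, u0)].sum())


def _ckey(c: float) -> float:
    return round(float(c), 6)


def _signed_set(coherences, include_zero_both: bool):
    mags = sorted({_ckey(abs(c)) for c in coherences})
    right = [m for m in mags if m > 0]
    zero = [0.0] if 0.0 in mags else []
    r_set = ([0.0] if (zero and include_zero_both) else []) + right
    l_set = ([0.0] if (zero and include_zero_both) else []) + [-m for m in right]
    all_signed = sorted({*r_set, *l_set})
    return all_signed, r_set, l_set


def counterfactual_posterior_map(params: AccumulatorParams,
                                 coherences: tuple[float, ...] = COHERENCES,
                                 include_zero_both: bool = True,
                                 t_max: float | None = None) -> LikelihoodMaps:
    """Build p(e, te | c) for every signed coherence and the pu(R | e, te) map.

    ``p(e, te | d)`` marginalizes over the coherences compatible with
    direction ``d`` with uniform weight; by default 0% coherence counts as
    compatible with both directions (configurable via
    ``include_zero_both``).
    """
    all_signed, r_set, l_set = _signed_set(coherences, include_zero_both)
    densities = {c: propagate_density(params, c, t_max=t_max) for c in all_signed}

    def _avg(cs, attr):
        return np.mean([getattr(densities[c], attr) for c in cs], axis=0)

    pR_int = _avg(r_set, "interior")
    pL_int = _avg(l_set, "interior")
    pR_top = _avg(r_set, "absorbed_top")
    pL_top = _avg(l_set, "absorbed_top")
    pR_bot = _avg(r_set, "absorbed_bot")
    pL_bot = _avg(l_set, "absorbed_bot")

    tot_int = pR_int + pL_int
    reachable = tot_int > 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        pu_int = np.where(reachable, pR_int / np.where(reachable, tot_int, 1.0), np.nan)
    # tail limit at unreachable nodes: evidence that extreme can only mean
    # the corresponding direction
    e_grid = params.evidence_grid
    fill = np.where(e_grid > 0, 1.0, np.where(e_grid < 0, 0.0, 0.5))
    pu_int = np.where(reachable, pu_int, fill[None, :])

    tot_top = pR_top + pL_top
    tot_bot = pR_bot + pL_bot
    with np.errstate(invalid="ignore", divide="ignore"):
        pu_top = np.where(tot_top > 0, pR_top / np.where(tot_top > 0, tot_top, 1.0), 1.0)
        pu_bot = np.where(tot_bot > 0, pR_bot / np.where(tot_bot > 0, tot_bot, 1.0), 0.0)

    return LikelihoodMaps(params=params, coherences=tuple(all_signed),
                          include_zero_both=include_zero_both,
                          densities=densities,
                          pR_interior=pR_int, pL_interior=pL_int,
                          pR_top=pR_top, pL_top=pL_top,
                          pR_bot=pR_bot, pL_bot=pL_bot,
                          pu_interior=pu_int, pu_top=pu_top, pu_bot=pu_bot,
                          reachable=reachable)


def simulate_trial_evidence(params: AccumulatorParams, c: float, T: float,
                            rng: np.random.Generator,
                            bridge: bool = True) -> EvidenceOutcome:
    """Euler–Maruyama sample path; stops at the first bound crossing or at T.

    With ``bridge=True`` (default) a Brownian-bridge correction samples
    intra-step crossings that the discrete path misses, removing the
    O(sqrt(dt)) first-passage bias.  Crossings are assigned to the end of
    the step in which they occur; curtailed trials end at exactly T.
    """
    e, te, hit = _simulate_paths(params, np.array([c]), np.array([T]), rng, bridge)
    return EvidenceOutcome(e=float(e[0]), te=float(te[0]), bound_hit=bool(hit[0]))


def _simulate_paths(params: AccumulatorParams, c_arr: np.ndarray,
                    T_arr: np.ndarray, rng: np.random.Generator,
                    bridge: bool = True):
    """Vectorized-per-trial path simulation; returns (e, te, bound_hit) arrays."""
    dt = params.dt_sim
    A = params.bound
    sd = np.sqrt(dt)
    n = len(c_arr)
    e_out = np.empty(n)
    te_out = np.empty(n)
    hit_out = np.zeros(n, dtype=bool)
    for i in range(n):
        n_steps = max(1, int(round(T_arr[i] / dt)))
        steps = params.kappa * c_arr[i] * dt + sd * rng.standard_normal(n_steps)
        path = np.cumsum(steps)
        crossed = np.abs(path) >= A
        if bridge:
            prev = np.concatenate(([0.0], path[:-1]))
            with np.errstate(over="ignore"):
                p_up = np.exp(-2.0 * np.clip(A - prev, 0, None)
                              * np.clip(A - path, 0, None) / dt)
                p_dn = np.exp(-2.0 * np.clip(A + prev, 0, None)
                              * np.clip(A + path, 0, None) / dt)
            u = rng.random(n_steps)
            crossed = crossed | (u < np.maximum(p_up, p_dn))
        if crossed.any():
            k = int(np.argmax(crossed))
            # sign of the crossing: hard hits use the path sign; bridge hits
            # use whichever bound was (far) more probable to have been grazed
            if np.abs(path[k]) >= A:
                e_out[i] = A * np.sign(path[k])
            else:
                e_out[i] = A if p_up[k] >= p_dn[k] else -A
            te_out[i] = min((k + 1) * dt, T_arr[i])
            hit_out[i] = True
        else:
            e_out[i] = path[-1]
            te_out[i] = T_arr[i]
    return e_out, te_out, hit_out
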