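"""Stimulus-side generator for the biased random-dot-motion task.

Trials are organized in blocks that share a concealed base rate ``B`` (the
probability that motion is rightward), drawn uniformly from
``{0, 0.2, 0.4, 0.6, 0.8, 1}``.  Within a block the motion strength
(coherence magnitude) is approximately balanced across the six standard
values, stimulus duration follows a truncated exponential, and block length
a truncated geometric distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: the six admissible base rates (probability that motion is rightward)
BASE_RATES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

#: coherence magnitudes as fractions (0%..51.2%)
COHERENCES = (0.0, 0.032, 0.064, 0.128, 0.256, 0.512)

#: block-length distribution: geometric(p) truncated to [lo, hi]
BLOCK_LENGTH_P = 1.0 / 15.0
BLOCK_LENGTH_RANGE = (15, 42)

#: stimulus duration: exponential(tau) truncated to [lo, hi], seconds
DURATION_TAU = 0.6
DURATION_RANGE = (0.1, 0.9)


class InvalidDesignError(ValueError):
    """A requested stimulus design violates the task's constraints."""


@dataclass(frozen=True)
class StimulusTrial:
    """One trial's stimulus: signed coherence direction, magnitude, duration."""

    coherence_magnitude: float
    direction: str  # 'L' or 'R'; nominal direction, defines sign of c
    duration_s: float

    @property
    def coherence_signed(self) -> float:
        return self.coherence_magnitude if self.direction == "R" else -self.coherence_magnitude


@dataclass(frozen=True)
class BlockDesign:
    base_rate: float
    trials: tuple[StimulusTrial, ...]

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class ExperimentDesign:
    blocks: tuple[BlockDesign, ...]
    rng_seed: int | None = None
    subject_id: str = "S1"

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a tidy trial table (one row per trial)."""
        rows = []
        for bi, block in enumerate(self.blocks, start=1):
            for ti, tr in enumerate(block.trials, start=1):
                rows.append(
                    dict(
                        subject_id=self.subject_id,
                        block_id=bi,
                        trial_index=ti,
                        base_rate=block.base_rate,
                        coherence_signed=tr.coherence_signed,
                        direction=tr.direction,
                        duration_s=tr.duration_s,
                    )
                )
        return pd.DataFrame(rows)


def sample_block_length(rng: np.random.Generator, p: float = BLOCK_LENGTH_P,
                        lo: int = BLOCK_LENGTH_RANGE[0], hi: int = BLOCK_LENGTH_RANGE[1],
                        size: int | None = None):
    """Draw block length(s) from geometric(p) conditioned on ``lo <= n <= hi``.

    Implemented by inverse-CDF sampling on the renormalized support, so a
    single uniform draw is consumed per value.
    """
    n = np.arange(lo, hi + 1)
    if p >= 1.0:  # degenerate: all mass at the lower truncation
        return lo if size is None else np.full(size, lo)
    pmf = p * (1.0 - p) ** (n - 1)
    cdf = np.cumsum(pmf / pmf.sum())
    u = rng.random() if size is None else rng.random(size)
    idx = np.searchsorted(cdf, u, side="right").clip(max=len(n) - 1)
    return int(n[idx]) if size is None else n[idx]


def truncated_geometric_mean(p: float = BLOCK_LENGTH_P,
                             lo: int = BLOCK_LENGTH_RANGE[0], hi: int = BLOCK_LENGTH_RANGE[1]) -> float:
    """Exact mean of the truncated block-length distribution."""
    n = np.arange(lo, hi + 1)
    pmf = p * (1.0 - p) ** (n - 1)
    pmf = pmf / pmf.sum()
    return float(n @ pmf)


def sample_duration(rng: np.random.Generator, tau: float = DURATION_TAU,
                    lo: float = DURATION_RANGE[0], hi: float = DURATION_RANGE[1],
                    size: int | None = None):
    """Stimulus duration(s) from an exponential(tau) truncated to [lo, hi] seconds."""
    if np.isinf(tau):
        out = rng.uniform(lo, hi, size=size)
        return float(out) if size is None else out
    u = rng.random() if size is None else rng.random(size)
    # inverse CDF of the truncated exponential
    flo, fhi = np.expm1(-lo / tau), np.expm1(-hi / tau)
    out = -tau * np.log1p(flo + u * (fhi - flo))
    return float(out) if size is None else out


def truncated_exponential_mean(tau: float = DURATION_TAU,
                               lo: float = DURATION_RANGE[0], hi: float = DURATION_RANGE[1]) -> float:
    """Exact mean of the truncated stimulus-duration distribution."""
    if np.isinf(tau):
        return 0.5 * (lo + hi)
    # E[T | lo<=T<=hi] for T ~ Exp(tau)
    num = (lo + tau) * np.exp(-lo / tau) - (hi + tau) * np.exp(-hi / tau)
    den = np.exp(-lo / tau) - np.exp(-hi / tau)
    return float(num / den)


def _round_half_away(x: float) -> int:
    # np.round ties to even; the task calls for round half away from zero.
    # No B*ntr in-domain actually lands on .5, but fix the convention anyway.
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def assign_directions(n_trials: int, base_rate: float, rng: np.random.Generator) -> list[str]:
    """Directions for a block: exactly round(B*ntr) rightward, randomly ordered."""
    if not any(np.isclose(base_rate, b) for b in BASE_RATES):
        raise InvalidDesignError(f"base_rate {base_rate!r} not in {BASE_RATES}")
    n_right = _round_half_away(base_rate * n_trials)
    dirs = np.array(["R"] * n_right + ["L"] * (n_trials - n_right))
    rng.shuffle(dirs)
    return dirs.tolist()


def build_coherence_list(n_trials: int, rng: np.random.Generator,
                         coherences: tuple[float, ...] = COHERENCES) -> list[float]:
    """Coherence magnitudes for a block, approximately balanced.

    The six magnitudes are repeated up to the first multiple of six strictly
    larger than ``n_trials``; the pool is shuffled and the first ``n_trials``
    values are used.  Per-magnitude counts are therefore a hypergeometric
    draw from the balanced pool: at most pool/6 and at least
    pool/6 - (pool - n_trials) of each.
    """
    k = len(coherences)
    pool_size = ((n_trials // k) + 1) * k
    pool = np.tile(coherences, pool_size // k)
    rng.shuffle(pool)
    return pool[:n_trials].tolist()


def generate_block(rng: np.random.Generator, base_rate: float | None = None) -> BlockDesign:
    """Assemble one block from the three samplers.

    Coherence magnitudes are sampled independently of the base rate; each
    trial's sign comes from its nominal direction (0% trials keep a nominal
    direction so the rightward-trial count matches round(B*ntr)).
    """
    if base_rate is None:
        base_rate = float(BASE_RATES[rng.integers(len(BASE_RATES))])
    n = sample_block_length(rng)
    dirs = assign_directions(n, base_rate, rng)
    mags = build_coherence_list(n, rng)
    trials = tuple(
        StimulusTrial(coherence_magnitude=float(m), direction=d,
                      duration_s=sample_duration(rng))
        for m, d in zip(mags, dirs)
    )
    return BlockDesign(base_rate=float(base_rate), trials=trials)


def generate_experiment(n_blocks: int, rng_seed: int, subject_id: str = "S1") -> ExperimentDesign:
    """Reproducible experiment: per-block substreams spawned from one seed."""
    if n_blocks < 1:
        raise InvalidDesignError("n_blocks must be >= 1")
    root = np.random.SeedSequence(rng_seed)
    blocks = tuple(generate_block(np.random.Generator(np.random.PCG64(child)))
                   for child in root.spawn(n_blocks))
    return ExperimentDesign(blocks=blocks, rng_seed=rng_seed, subject_id=subject_id)
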