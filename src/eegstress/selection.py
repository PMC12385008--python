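"""Channel selection by an improved crow search algorithm (CSA).

Crows live in the continuous unit cube [0, 1]^d (d = number of channels);
a position decodes to the k channels with the largest coordinates (ties
break toward the lower index). The fitness of a subset combines the mean
normalized amplitude entropy of the selected channels (information) with a
redundancy penalty of one minus their mean absolute pairwise correlation,
weighted w1/w2 with w1 + w2 = 1; higher is better.

Beyond the classic follow-a-random-crow update, each iteration applies two
extra moves: a Levy-flight elite step that perturbs the best solution along
the best-to-second-best direction (accepted greedily), and a replace-worst
move that pulls the worst member onto the segment toward the best memory.
Per-crow memories are updated greedily, so the best-memory fitness trace is
non-decreasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .data import TrialSet
from .features import ENTROPY_BINS, shannon_amplitude_entropy

__all__ = [
    "ICSAParams",
    "ChannelStats",
    "compute_channel_stats",
    "decode_position",
    "channel_fitness",
    "crow_step",
    "levy_flight",
    "levy_elite_proposal",
    "replace_worst",
    "select_channels",
    "CrowSearchChannelSelector",
]


@dataclass
class ICSAParams:
    """Swarm-size, step and weighting parameters for the selector."""

    k: int = 15
    flock_size: int = 20
    flight_length: float = 2.0
    awareness_prob: float = 0.1
    iter_max: int = 100
    w1: float = 0.5
    w2: float = 0.5
    levy_beta: float = 1.5
    cv_mode: str = "penalize"
    seed: int | None = None

    def validate(self, d: int) -> None:
        if self.flock_size < 4:
            raise ValueError("flock_size must be >= 4")
        if not 1 <= self.k <= d:
            raise ValueError(f"k={self.k} must be in [1, {d}]")
        if abs(self.w1 + self.w2 - 1.0) > 1e-12:
            raise ValueError("w1 + w2 must equal 1")
        if not 0.0 <= self.awareness_prob <= 1.0:
            raise ValueError("awareness_prob must be in [0, 1]")
        if not 1.0 < self.levy_beta <= 2.0:
            raise ValueError("levy_beta must be in (1, 2]")
        if self.cv_mode not in ("penalize", "reward"):
            raise ValueError("cv_mode must be 'penalize' or 'reward'")


@dataclass
class ChannelStats:
    """Per-channel entropy and pairwise |correlation|, averaged over trials."""

    entropy: np.ndarray  # (d,), normalized to [0, 1]
    abs_corr: np.ndarray  # (d, d)


def compute_channel_stats(trials: TrialSet) -> ChannelStats:
    """Precompute the sufficient statistics of the subset fitness.

    Entropy is the 64-bin amplitude entropy normalized by ln(64); the
    correlation matrix is the trial-averaged absolute Pearson correlation.
    Both are fixed for a given trial set, so subset fitness evaluation is
    O(k^2) afterwards.
    """
    if len(trials) == 0:
        raise ValueError("empty trial set")
    d = trials.n_channels
    ent = np.zeros(d)
    corr = np.zeros((d, d))
    for rec in trials.trials:
        ent += [shannon_amplitude_entropy(ch) for ch in rec.data]
        with np.errstate(invalid="ignore"):
            c = np.abs(np.corrcoef(rec.data))
        corr += np.nan_to_num(c)
    n = len(trials)
    return ChannelStats(entropy=ent / n / math.log(ENTROPY_BINS), abs_corr=corr / n)


def decode_position(position: np.ndarray, k: int) -> np.ndarray:
    """Top-k coordinates of a continuous position, ties toward lower index."""
    position = np.asarray(position, dtype=float)
    order = np.argsort(-position, kind="stable")
    return np.sort(order[:k])


def channel_fitness(
    position: np.ndarray, stats: ChannelStats, params: ICSAParams
) -> float:
    """Entropy/redundancy fitness of the subset a position decodes to."""
    d = stats.entropy.size
    params.validate(d)
    sel = decode_position(position, params.k)
    en = float(stats.entropy[sel].mean())
    if params.k < 2:
        cv = 0.0
    else:
        sub = stats.abs_corr[np.ix_(sel, sel)]
        iu = np.triu_indices(params.k, 1)
        cv = float(sub[iu].mean())
    cv_term = cv if params.cv_mode == "reward" else 1.0 - cv
    return params.w1 * en + params.w2 * cv_term


def crow_step(
    x_i: np.ndarray,
    m_j: np.ndarray,
    r_i: float,
    r_j: float,
    params: ICSAParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One crow position update.

    If the watched crow is unaware (r_j >= AP) the crow moves toward that
    crow's memory with step r_i * flight_length; otherwise it relocates
    uniformly at random. The result is clamped to [0, 1].
    """
    if r_j >= params.awareness_prob:
        new = x_i + r_i * params.flight_length * (m_j - x_i)
    else:
        new = rng.uniform(0.0, 1.0, size=x_i.shape)
    return np.clip(new, 0.0, 1.0)


def levy_flight(
    beta: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Mantegna-algorithm Levy(beta) step sample."""
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    sigma_u = (num / den) ** (1.0 / beta)
    u = rng.normal(0.0, sigma_u, size=size)
    v = rng.normal(0.0, 1.0, size=size)
    return u / np.abs(v) ** (1.0 / beta)


def levy_elite_proposal(
    x_best1: np.ndarray, x_best2: np.ndarray, r1: float, levy_draw: np.ndarray
) -> np.ndarray:
    """Levy-scaled elite proposal along the best-to-second-best direction."""
    return np.clip(x_best1 + (2.0 * r1 - 1.0) * levy_draw * (x_best1 - x_best2), 0.0, 1.0)


def replace_worst(
    x_worst: np.ndarray, x_best: np.ndarray, r2: float
) -> np.ndarray:
    """Pull the worst member onto the segment toward the best (r2 in [0, 1])."""
    return x_worst + r2 * (x_best - x_worst)


def select_channels(
    trials: TrialSet, params: ICSAParams
) -> tuple[np.ndarray, np.ndarray]:
    """Run the improved crow search and return (channels, fitness trace).

    The trace holds the best memory fitness after each iteration and is
    non-decreasing by the greedy memory rule. Deterministic given
    ``params.seed``. ``iter_max=0`` returns the best of the random initial
    flock.
    """
    if len(trials) == 0:
        raise ValueError("empty trial set")
    stats = compute_channel_stats(trials)
    d = stats.entropy.size
    params.validate(d)
    rng = np.random.default_rng(params.seed)
    n = params.flock_size

    positions = rng.uniform(0.0, 1.0, size=(n, d))
    memories = positions.copy()
    mem_fit = np.array([channel_fitness(p, stats, params) for p in positions])
    trace = np.empty(params.iter_max)

    for it in range(params.iter_max):
        for i in range(n):
            j = int(rng.integers(n - 1))
            j = j if j < i else j + 1  # any crow but itself
            positions[i] = crow_step(
                positions[i], memories[j], rng.random(), rng.random(), params, rng
            )
        # Levy-flight elite learning: greedy update of the best solution
        top2 = np.argsort(-mem_fit, kind="stable")[:2]
        proposal = levy_elite_proposal(
            memories[top2[0]],
            memories[top2[1]],
            rng.random(),
            levy_flight(params.levy_beta, d, rng),
        )
        if channel_fitness(proposal, stats, params) > mem_fit[top2[0]]:
            positions[top2[0]] = proposal
        # replace-worst move toward the best memory, always applied
        pos_fit = np.array([channel_fitness(p, stats, params) for p in positions])
        worst = int(np.argmin(pos_fit))
        best = int(np.argmax(mem_fit))
        positions[worst] = np.clip(
            replace_worst(positions[worst], memories[best], rng.random()), 0.0, 1.0
        )
        pos_fit[worst] = channel_fitness(positions[worst], stats, params)
        improved = pos_fit > mem_fit
        memories[improved] = positions[improved]
        mem_fit[improved] = pos_fit[improved]
        trace[it] = mem_fit.max()

    best = int(np.argmax(mem_fit))
    return decode_position(memories[best], params.k), trace


class CrowSearchChannelSelector(BaseEstimator):
    """Improved crow-search channel selection as an estimator.

    ``fit`` expects a :class:`TrialSet` and exposes ``selected_channels_``,
    ``fitness_trace_`` and ``best_fitness_``; ``transform`` restricts a
    trial set to the selected channels.
    """

    def __init__(
        self,
        k=15,
        flock_size=20,
        flight_length=2.0,
        awareness_prob=0.1,
        iter_max=100,
        w1=0.5,
        w2=0.5,
        levy_beta=1.5,
        cv_mode="penalize",
        random_state=None,
    ):
        self.k = k
        self.flock_size = flock_size
        self.flight_length = flight_length
        self.awareness_prob = awareness_prob
        self.iter_max = iter_max
        self.w1 = w1
        self.w2 = w2
        self.levy_beta = levy_beta
        self.cv_mode = cv_mode
        self.random_state = random_state

    def _params(self) -> ICSAParams:
        return ICSAParams(
            k=self.k,
            flock_size=self.flock_size,
            flight_length=self.flight_length,
            awareness_prob=self.awareness_prob,
            iter_max=self.iter_max,
            w1=self.w1,
            w2=self.w2,
            levy_beta=self.levy_beta,
            cv_mode=self.cv_mode,
            seed=self.random_state,
        )

    def fit(self, X: TrialSet, y=None):
        if X.n_channels < 2:
            raise ValueError("channel selection needs at least 2 channels")
        channels, trace = select_channels(X, self._params())
        self.selected_channels_ = channels
        self.fitness_trace_ = trace
        self.best_fitness_ = float(trace[-1]) if trace.size else float("nan")
        return self

    def transform(self, X: TrialSet) -> TrialSet:
        from .data import MultiChannelRecording, TrialSet as TS

        sel = self.selected_channels_
        return TS(
            [
                MultiChannelRecording(
                    t.data[sel], t.fs, [t.channel_names[c] for c in sel]
                )
                for t in X.trials
            ],
            X.arousal,
            X.valence,
            X.labels,
        )

    def fit_transform(self, X: TrialSet, y=None) -> TrialSet:
        return self.fit(X, y).transform(X)
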