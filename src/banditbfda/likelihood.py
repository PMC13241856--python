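"""Exact per-game likelihood of the aversive-outcome count by path enumeration.

The number of aversive outcomes in a game's free-choice phase has an exact
probability mass function under the softmax/Q-learning agent: every sequence
of (choice, outcome) pairs over the free trials — 4**n_free paths for a
two-armed task — has probability equal to the product of its softmax choice
probabilities and Bernoulli outcome probabilities, with Q-values updated
along the path.  Summing path probabilities by their aversive count gives
p(n_a | tau) for every tau on a discrete grid, which is the engine behind
all inference in this package.

The PMF depends on the game only through the arm probabilities and the
Q-values at the end of the forced phase, so under a fixed forced allocation
the set of distinct tables is small and is cached (:class:`PmfBank`).
Likelihoods condition on the realized forced outcomes of each game: those
outcomes are observed data, not latent quantities to marginalize.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import log_expit

from .errors import ConfigurationError, InvalidInputError, InvalidParameterError
from .task import GameConfig, ParticipantDataset, simulate_many_games

__all__ = [
    "TauGrid",
    "q_after_forced",
    "enumerate_outcome_pmf",
    "monte_carlo_pmf",
    "PmfBank",
    "participant_loglik",
    "group_loglik",
    "games_loglik",
]


@dataclass(frozen=True)
class TauGrid:
    """Strictly increasing grid of exploration parameters.

    The default spans [0.01, 3] in steps of 0.01, matching the bounded
    support of the discrete uniform prior placed on tau.
    """

    values: np.ndarray
    step: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) < 2 or np.any(np.diff(v) <= 0):
            raise InvalidParameterError("tau grid must be strictly increasing")
        if v[0] <= 0:
            raise InvalidParameterError("tau grid must be positive")
        object.__setattr__(self, "values", v)

    @classmethod
    def default(cls, lo: float = 0.01, hi: float = 3.0, step: float = 0.01) -> "TauGrid":
        # integer-based construction keeps the grid exactly representable
        i0, i1 = round(lo / step), round(hi / step)
        return cls(values=np.arange(i0, i1 + 1) * step, step=step)

    def __len__(self) -> int:
        return len(self.values)


def q_after_forced(
    config: GameConfig,
    forced_outcomes: Sequence[int],
    alpha: float,
    q_init: tuple[float, float] = (0.0, 0.0),
) -> tuple[float, float]:
    """Q-value pair after applying the forced outcomes along the allocation."""
    if len(forced_outcomes) != config.n_forced:
        raise InvalidInputError(
            f"expected {config.n_forced} forced outcomes, got {len(forced_outcomes)}"
        )
    q = [q_init[0], q_init[1]]
    for arm, out in zip(config.forced_allocation, forced_outcomes):
        a = arm - 1
        q[a] = q[a] + alpha * (out - q[a])
    return (q[0], q[1])


def enumerate_outcome_pmf(
    config: GameConfig,
    q_post_forced: tuple[float, float],
    tau_grid: TauGrid,
    alpha: float = 0.1,
) -> np.ndarray:
    """Exact PMF of the free-trial aversive count over the tau grid.

    Expands all 4**n_free (choice, outcome) paths, carrying per-path state
    (Q-value pair, running aversive count) and per-tau probabilities, and
    bins final path probabilities by aversive count.

    Returns a ``(len(tau_grid), n_free + 1)`` matrix whose rows sum to 1.
    The enumerator is generic in ``config.n_free``; cost grows as
    4**n_free.
    """
    if config.n_free > 10:
        raise ConfigurationError(
            f"path enumeration over {config.n_free} free trials is intractable"
        )
    taus = tau_grid.values
    T = len(taus)
    p_av = config.arms.as_tuple
    # per-path state arrays; probabilities carried per tau
    q1 = np.array([q_post_forced[0]])
    q2 = np.array([q_post_forced[1]])
    ks = np.zeros(1, dtype=np.int64)
    prob = np.ones((1, T))
    for _ in range(config.n_free):
        # log choice probabilities, stable for extreme Q/tau ratios
        d = (q1 - q2)[:, None] / taus[None, :]
        logp_arm = (log_expit(d), log_expit(-d))
        new_q1, new_q2, new_ks, new_prob = [], [], [], []
        for a in (0, 1):
            for out in (0, -1):
                p_out = p_av[a] if out == -1 else 1.0 - p_av[a]
                new_prob.append(prob * np.exp(logp_arm[a]) * p_out)
                if a == 0:
                    new_q1.append(q1 + alpha * (out - q1))
                    new_q2.append(q2)
                else:
                    new_q1.append(q1)
                    new_q2.append(q2 + alpha * (out - q2))
                new_ks.append(ks + (1 if out == -1 else 0))
        q1 = np.concatenate(new_q1)
        q2 = np.concatenate(new_q2)
        ks = np.concatenate(new_ks)
        prob = np.concatenate(new_prob, axis=0)
    pmf = np.zeros((T, config.n_free + 1))
    for k in range(config.n_free + 1):
        sel = ks == k
        if np.any(sel):
            pmf[:, k] = prob[sel].sum(axis=0)
    # rows sum to 1 by construction; renormalize to remove accumulation error
    pmf /= pmf.sum(axis=1, keepdims=True)
    return pmf


def monte_carlo_pmf(
    config: GameConfig,
    q_post_forced: tuple[float, float],
    tau: float,
    n_sims: int,
    rng: np.random.Generator,
    alpha: float = 0.1,
) -> np.ndarray:
    """Empirical PMF of the aversive count from simulated free-choice phases.

    Test oracle for :func:`enumerate_outcome_pmf`: plays only the free phase,
    starting from the supplied post-forced Q pair.
    """
    if n_sims < 1000:
        raise InvalidParameterError("n_sims must be >= 1000 for a usable oracle")
    p_av = np.tile(np.asarray(config.arms.as_tuple), (n_sims, 1))
    taus = np.full(n_sims, float(tau))
    _, _, n_a = simulate_many_games(
        p_av,
        taus,
        alpha,
        allocation=(),
        n_free=config.n_free,
        rng=rng,
        q_init=q_post_forced,
    )
    counts = np.bincount(n_a, minlength=config.n_free + 1)
    return counts / n_sims


class PmfBank:
    """Cache of enumerated PMF tables keyed by (arm pair, post-forced Q pair).

    Q pairs are rounded to ``q_decimals`` for keying; under a balanced forced
    allocation they form a small finite set, so a full design sweep touches
    at most a few dozen distinct tables.
    """

    def __init__(self, tau_grid: TauGrid, alpha: float = 0.1, q_decimals: int = 12):
        self.tau_grid = tau_grid
        self.alpha = alpha
        self.q_decimals = q_decimals
        self._index: dict[tuple[float, float, float, float], int] = {}
        self._tables: list[np.ndarray] = []
        self._log_pmf: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self._tables)

    def _key(self, arms: tuple[float, float], q_post: tuple[float, float]):
        return (
            arms[0],
            arms[1],
            round(float(q_post[0]), self.q_decimals),
            round(float(q_post[1]), self.q_decimals),
        )

    def index(self, config: GameConfig, q_post: tuple[float, float]) -> int:
        """Row index of the PMF table for this (config, Q) pair, built on demand."""
        key = self._key(config.arms.as_tuple, q_post)
        idx = self._index.get(key)
        if idx is None:
            table = enumerate_outcome_pmf(config, q_post, self.tau_grid, self.alpha)
            idx = len(self._tables)
            self._tables.append(table)
            self._index[key] = idx
            self._log_pmf = None
        return idx

    def pmf(self, config: GameConfig, q_post: tuple[float, float]) -> np.ndarray:
        return self._tables[self.index(config, q_post)]

    @property
    def log_pmf(self) -> np.ndarray:
        """Stacked log tables, shape (n_entries, len(tau_grid), n_free + 1)."""
        if self._log_pmf is None:
            self._log_pmf = np.log(np.stack(self._tables))
        return self._log_pmf

    def to_frame(self) -> pd.DataFrame:
        """Long-format export of the cache (one row per table cell)."""
        rows = []
        for key, idx in self._index.items():
            table = self._tables[idx]
            for i, tau in enumerate(self.tau_grid.values):
                for k in range(table.shape[1]):
                    rows.append(
                        {
                            "p_arm1": key[0],
                            "p_arm2": key[1],
                            "q1_post": key[2],
                            "q2_post": key[3],
                            "tau": tau,
                            "n_aversive": k,
                            "probability": table[i, k],
                        }
                    )
        return pd.DataFrame(rows)


def games_loglik(
    bank: PmfBank,
    configs: Sequence[GameConfig],
    q_posts: Sequence[tuple[float, float]],
    n_aversive: Sequence[int],
) -> np.ndarray:
    """Joint log-likelihood over the tau grid for a batch of games.

    Sums ``log p(n_a | tau)`` across games; this is the shared-tau likelihood
    used both per participant and per group.
    """
    n_a = np.asarray(n_aversive, dtype=np.int64)
    n_free = configs[0].n_free if len(configs) else 0
    if len(n_a) and (n_a.min() < 0 or n_a.max() > n_free):
        raise InvalidInputError(f"n_aversive outside 0..{n_free}")
    idx = np.fromiter(
        (bank.index(c, q) for c, q in zip(configs, q_posts)),
        dtype=np.int64,
        count=len(n_a),
    )
    return bank.log_pmf[idx, :, n_a].sum(axis=0)


def participant_loglik(dataset: ParticipantDataset, bank: PmfBank) -> np.ndarray:
    """Log-likelihood vector over the tau grid for one participant.

    Conditions on each game's realized forced outcomes (through the
    post-forced Q pair) and multiplies per-game likelihoods of the observed
    aversive counts.
    """
    configs, q_posts, n_as = [], [], []
    for config, forced, n_a in dataset.games:
        configs.append(config)
        q_posts.append(q_after_forced(config, forced, bank.alpha))
        n_as.append(n_a)
    return games_loglik(bank, configs, q_posts, n_as)


def group_loglik(participant_logliks: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise sum of participant log-likelihood vectors (shared tau)."""
    vecs = [np.asarray(v, dtype=float) for v in participant_logliks]
    if not vecs:
        raise InvalidInputError("no participant log-likelihoods supplied")
    n = len(vecs[0])
    if any(len(v) != n for v in vecs):
        raise InvalidInputError("participant log-likelihoods on mismatched grids")
    return np.sum(vecs, axis=0)
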