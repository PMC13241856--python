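"""Generative model of the binary two-armed horizon task.

A game consists of a short forced-choice phase -- the agent observes the
outcome of a fixed allocation of trials to each arm -- followed by a fixed
number of free choices.  Outcomes are binary and coded ``0`` (neutral) or
``-1`` (aversive), as in pain-learning variants of the bandit task.  Free
choices follow a softmax policy on running action values (Q-values) that are
updated after every trial, forced or free, with a constant learning rate.
The per-game summary statistic used for inference downstream is the number
of aversive outcomes received over the free trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError, InvalidInputError, InvalidParameterError

__all__ = [
    "ArmPair",
    "GameConfig",
    "AgentParams",
    "GameRecord",
    "ParticipantDataset",
    "TaskSpec",
    "softmax_probs",
    "update_q",
    "sample_game_config",
    "simulate_game",
    "simulate_participant",
    "simulate_many_games",
    "dataset_to_frame",
    "frame_to_datasets",
]

#: Aversive-outcome probabilities from which each game's arms are drawn.
DEFAULT_PROBABILITIES = (0.1, 0.3, 0.9)

#: Default forced-trial allocation: two trials per arm, alternating.
DEFAULT_ALLOCATION = (1, 2, 1, 2)


@dataclass(frozen=True)
class ArmPair:
    """Aversive-outcome probabilities of the two arms."""

    p_aversive_1: float
    p_aversive_2: float

    def __post_init__(self) -> None:
        for p in (self.p_aversive_1, self.p_aversive_2):
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError(f"arm probability {p} outside [0, 1]")

    @property
    def as_tuple(self) -> tuple[float, float]:
        return (self.p_aversive_1, self.p_aversive_2)


@dataclass(frozen=True)
class GameConfig:
    """One game of the horizon task: arms plus trial structure."""

    arms: ArmPair
    n_forced: int = 4
    forced_allocation: tuple[int, ...] = DEFAULT_ALLOCATION
    n_free: int = 6

    def __post_init__(self) -> None:
        if len(self.forced_allocation) != self.n_forced:
            raise ConfigurationError(
                "forced_allocation length must equal n_forced "
                f"({len(self.forced_allocation)} != {self.n_forced})"
            )
        if any(a not in (1, 2) for a in self.forced_allocation):
            raise ConfigurationError("forced_allocation entries must be 1 or 2")
        if self.n_free < 1:
            raise ConfigurationError("n_free must be >= 1")

    @property
    def horizon(self) -> int:
        return self.n_forced + self.n_free


@dataclass(frozen=True)
class AgentParams:
    """Softmax / Q-learning agent parameters.

    ``tau`` is the softmax temperature (degree of random exploration),
    ``alpha`` the learning rate of the running-average value update and
    ``q_init`` the initial action values of the two arms.
    """

    tau: float
    alpha: float = 0.1
    q_init: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise InvalidParameterError(f"tau must be > 0, got {self.tau}")
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidParameterError(f"alpha must be in [0, 1], got {self.alpha}")


@dataclass(frozen=True)
class GameRecord:
    """Realized trajectory of one simulated game."""

    forced_outcomes: tuple[int, ...]
    free_choices: tuple[int, ...]
    free_outcomes: tuple[int, ...]
    n_aversive: int


@dataclass
class ParticipantDataset:
    """Per-participant observations: (config, forced outcomes, aversive count)."""

    games: list[tuple[GameConfig, tuple[int, ...], int]]

    @property
    def n_games(self) -> int:
        return len(self.games)


@dataclass(frozen=True)
class TaskSpec:
    """Admissible game configurations and the forced-allocation rule."""

    probabilities: tuple[float, ...] = DEFAULT_PROBABILITIES
    n_forced: int = 4
    forced_allocation: tuple[int, ...] = DEFAULT_ALLOCATION
    n_free: int = 6
    include_equal_pairs: bool = False

    def admissible_pairs(self) -> list[ArmPair]:
        """All ordered arm pairs the sampler may draw.

        By default the two arms always carry distinct probabilities so that
        every game poses an explore/exploit trade-off.
        """
        pairs = [
            ArmPair(p1, p2)
            for p1 in self.probabilities
            for p2 in self.probabilities
            if self.include_equal_pairs or p1 != p2
        ]
        if not pairs:
            raise ConfigurationError("admissible arm-pair set is empty")
        return pairs


def softmax_probs(q_values: Sequence[float], tau: float) -> np.ndarray:
    """Softmax choice probabilities over two action values at temperature tau.

    Uses max-subtraction before exponentiation, so it is stable for extreme
    Q/tau ratios.
    """
    if not tau > 0:
        raise InvalidParameterError(f"tau must be > 0, got {tau}")
    q = np.asarray(q_values, dtype=float)
    if not np.all(np.isfinite(q)):
        raise InvalidInputError(f"non-finite Q-values: {q_values}")
    z = q / tau
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def update_q(q: float, reward: float, alpha: float) -> float:
    """Constant-step-size running-average update of an action value."""
    if not 0.0 <= alpha <= 1.0:
        raise InvalidParameterError(f"alpha must be in [0, 1], got {alpha}")
    return q + alpha * (reward - q)


def sample_game_config(task_spec: TaskSpec, rng: np.random.Generator) -> GameConfig:
    """Draw a game configuration uniformly from the admissible arm pairs."""
    pairs = task_spec.admissible_pairs()
    arms = pairs[rng.integers(len(pairs))]
    return GameConfig(
        arms=arms,
        n_forced=task_spec.n_forced,
        forced_allocation=task_spec.forced_allocation,
        n_free=task_spec.n_free,
    )


def simulate_game(
    config: GameConfig, params: AgentParams, rng: np.random.Generator
) -> GameRecord:
    """Simulate one game: forced phase, then softmax free choices.

    Q-values start at ``params.q_init`` and are updated after every trial,
    including the forced ones.  ``n_aversive`` counts aversive outcomes over
    the free trials only.
    """
    p_av = config.arms.as_tuple
    q = [params.q_init[0], params.q_init[1]]
    forced_outcomes = []
    for arm in config.forced_allocation:
        a = arm - 1
        out = -1 if rng.random() < p_av[a] else 0
        forced_outcomes.append(out)
        q[a] = update_q(q[a], out, params.alpha)
    free_choices, free_outcomes = [], []
    for _ in range(config.n_free):
        p = softmax_probs(q, params.tau)
        a = 0 if rng.random() < p[0] else 1
        out = -1 if rng.random() < p_av[a] else 0
        free_choices.append(a + 1)
        free_outcomes.append(out)
        q[a] = update_q(q[a], out, params.alpha)
    return GameRecord(
        forced_outcomes=tuple(forced_outcomes),
        free_choices=tuple(free_choices),
        free_outcomes=tuple(free_outcomes),
        n_aversive=sum(1 for o in free_outcomes if o == -1),
    )


def simulate_participant(
    tau: float,
    task_spec: TaskSpec,
    n_games: int,
    rng: np.random.Generator,
    alpha: float = 0.1,
) -> ParticipantDataset:
    """Simulate a participant playing ``n_games`` independent games.

    Each game gets a freshly sampled configuration.  The dataset retains the
    realized forced outcomes (they are observed data for inference) and the
    free-trial aversive count.
    """
    if n_games < 1:
        raise InvalidParameterError(f"n_games must be >= 1, got {n_games}")
    params = AgentParams(tau=tau, alpha=alpha)
    games = []
    for _ in range(n_games):
        config = sample_game_config(task_spec, rng)
        rec = simulate_game(config, params, rng)
        games.append((config, rec.forced_outcomes, rec.n_aversive))
    return ParticipantDataset(games=games)


def simulate_many_games(
    p_aversive: np.ndarray,
    taus: np.ndarray,
    alpha: float,
    allocation: Sequence[int],
    n_free: int,
    rng: np.random.Generator,
    q_init: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized game simulation across G independent games.

    Parameters
    ----------
    p_aversive
        ``(G, 2)`` aversive probabilities per game.
    taus
        ``(G,)`` softmax temperature per game (a participant's tau repeated
        over their games).

    Returns
    -------
    forced_outcomes : ``(G, n_forced)`` int array in {0, -1}
    q_post : ``(G, 2)`` Q-values after the forced phase
    n_aversive : ``(G,)`` free-trial aversive counts

    Statistically identical to looping :func:`simulate_game`, but draws its
    random numbers trial-by-trial across games, so the two are not
    stream-for-stream identical under a shared generator.
    """
    p_av = np.asarray(p_aversive, dtype=float)
    taus = np.asarray(taus, dtype=float)
    G = taus.shape[0]
    if np.any(taus <= 0):
        raise InvalidParameterError("all taus must be > 0")
    q = np.empty((G, 2))
    q[:, 0], q[:, 1] = q_init
    forced = np.empty((G, len(allocation)), dtype=np.int64)
    for t, arm in enumerate(allocation):
        a = arm - 1
        out = -(rng.random(G) < p_av[:, a]).astype(np.int64)
        forced[:, t] = out
        q[:, a] += alpha * (out - q[:, a])
    q_post = q.copy()
    n_a = np.zeros(G, dtype=np.int64)
    rows = np.arange(G)
    for _ in range(n_free):
        p_arm1 = expit((q[:, 0] - q[:, 1]) / taus)
        a = np.where(rng.random(G) < p_arm1, 0, 1)
        out = -(rng.random(G) < p_av[rows, a]).astype(np.int64)
        n_a += out == -1
        q[rows, a] += alpha * (out - q[rows, a])
    return forced, q_post, n_a


def dataset_to_frame(
    datasets: Sequence[ParticipantDataset],
    participant_ids: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Flatten participant datasets to the long CSV schema.

    Columns: participant_id, game_index, p_arm1, p_arm2, forced_outcomes
    (comma-joined string), n_aversive.
    """
    if participant_ids is None:
        participant_ids = range(len(datasets))
    rows = []
    for pid, ds in zip(participant_ids, datasets):
        for g, (config, forced, n_a) in enumerate(ds.games):
            rows.append(
                {
                    "participant_id": pid,
                    "game_index": g,
                    "p_arm1": config.arms.p_aversive_1,
                    "p_arm2": config.arms.p_aversive_2,
                    "forced_outcomes": ",".join(str(int(o)) for o in forced),
                    "n_aversive": int(n_a),
                }
            )
    return pd.DataFrame(rows)


def frame_to_datasets(
    frame: pd.DataFrame, task_spec: TaskSpec | None = None
) -> dict[int, ParticipantDataset]:
    """Inverse of :func:`dataset_to_frame`, keyed by participant id."""
    spec = task_spec or TaskSpec()
    out: dict[int, ParticipantDataset] = {}
    for pid, sub in frame.groupby("participant_id"):
        games = []
        for _, row in sub.sort_values("game_index").iterrows():
            config = GameConfig(
                arms=ArmPair(float(row["p_arm1"]), float(row["p_arm2"])),
                n_forced=spec.n_forced,
                forced_allocation=spec.forced_allocation,
                n_free=spec.n_free,
            )
            forced = tuple(int(x) for x in str(row["forced_outcomes"]).split(","))
            games.append((config, forced, int(row["n_aversive"])))
        out[int(pid)] = ParticipantDataset(games=games)
    return out
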