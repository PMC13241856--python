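"""Bayes factor design analysis for the two-group exploration comparison.

One replicate of the design loop: draw the two population means, draw each
participant's exploration parameter from a narrow normal around their group
mean, simulate every participant's games, form the group likelihoods over
the tau grid by exact enumeration, convolve them into the density of the
mean difference, and reduce that to a Bayes factor against the point null,
a posterior-mean difference estimate and an HPDI.  A condition repeats this
``n_sims`` times with deterministically derived, order-independent seeds and
summarizes the distribution of Bayes factors and the error rates a design
analyst cares about (Type S, Type M exceedance, MSEE, HPDI length).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError
from .inference import (
    GridPrior,
    HPDInterval,
    bayes_factor_difference,
    classify_evidence,
    difference_log_density,
    hpdi,
    make_delta_grid,
    point_estimate,
    posterior_from_loglik,
)
from .likelihood import PmfBank, TauGrid, games_loglik, q_after_forced
from .task import GameConfig, TaskSpec, simulate_many_games

__all__ = [
    "PopulationSpec",
    "BFDACondition",
    "ReplicateResult",
    "BFDAResult",
    "sample_population_means",
    "draw_group_taus",
    "simulate_group_loglik",
    "estimate_group_mean",
    "run_replicate",
    "run_condition",
    "summarize_evidence",
    "error_metrics",
    "replicates_to_frame",
]

#: BF thresholds at which exceedance rates are reported.
EVIDENCE_THRESHOLDS = (3.0, 10.0, 30.0, 100.0)


@dataclass(frozen=True)
class PopulationSpec:
    """Two normal populations of the exploration parameter."""

    mu_group1: float
    mu_group2: float
    sigma: float = 0.02

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidParameterError("sigma must be >= 0")


@dataclass(frozen=True)
class BFDACondition:
    """One design cell: effect size, group size, games per participant."""

    delta_mu: float
    n_per_group: int
    n_games: int
    n_sims: int
    seed: int
    task: TaskSpec = field(default_factory=TaskSpec)
    alpha: float = 0.1
    sigma: float = 0.02
    tau_grid: TauGrid = field(default_factory=TauGrid.default)
    delta_prior_bounds: tuple[float, float] = (-3.0, 3.0)
    hpdi_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.n_games < 1 or self.n_sims < 1:
            raise InvalidParameterError("n_per_group, n_games, n_sims must be >= 1")


@dataclass(frozen=True)
class ReplicateResult:
    """Inference outputs of a single simulated experiment."""

    bf10: float
    delta_hat: float
    hpdi: HPDInterval
    category: str
    mu1: float
    mu2: float
    seed: int


@dataclass
class BFDAResult:
    """All replicates of one condition."""

    condition: BFDACondition
    replicates: list[ReplicateResult]

    @property
    def bf10(self) -> np.ndarray:
        return np.array([r.bf10 for r in self.replicates])

    @property
    def delta_hat(self) -> np.ndarray:
        return np.array([r.delta_hat for r in self.replicates])

    @property
    def hpdi_lengths(self) -> np.ndarray:
        return np.array([r.hpdi.length for r in self.replicates])


def sample_population_means(
    delta_mu: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw the pair of population means for a given true difference.

    The first mean is uniform on [0, 1 - delta_mu]; the second is offset by
    the true difference, so means stay inside [0, 1].
    """
    if not 0.0 <= delta_mu <= 1.0:
        raise InvalidParameterError(f"delta_mu must be in [0, 1], got {delta_mu}")
    mu1 = rng.uniform(0.0, 1.0 - delta_mu)
    return mu1, mu1 + delta_mu


def draw_group_taus(
    mu: float,
    sigma: float,
    n: int,
    rng: np.random.Generator,
    lo: float = 0.01,
    hi: float = 3.0,
) -> np.ndarray:
    """Normal draws of individual exploration parameters, truncated to the grid.

    Draws outside [lo, hi] are resampled (not clipped), avoiding a point
    mass at the boundary; with sigma = 0 the draws are the mean itself,
    clipped into the grid.
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    if sigma == 0.0:
        return np.full(n, min(max(mu, lo), hi))
    taus = rng.normal(mu, sigma, size=n)
    bad = (taus < lo) | (taus > hi)
    while np.any(bad):
        taus[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
        bad = (taus < lo) | (taus > hi)
    return taus


def simulate_group_loglik(
    taus: np.ndarray,
    condition: BFDACondition,
    bank: PmfBank,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate a whole group's games and return the group log-likelihood.

    Every participant plays ``condition.n_games`` games with freshly sampled
    arm pairs; the returned vector is the shared-tau group log-likelihood
    over the tau grid, conditioning on the realized forced outcomes.
    """
    task = condition.task
    pairs = task.admissible_pairs()
    pair_probs = np.array([p.as_tuple for p in pairs])
    n_games_total = len(taus) * condition.n_games
    pair_idx = rng.integers(len(pairs), size=n_games_total)
    p_av = pair_probs[pair_idx]
    game_taus = np.repeat(taus, condition.n_games)
    forced, q_post, n_a = simulate_many_games(
        p_av, game_taus, condition.alpha, task.forced_allocation, task.n_free, rng
    )
    configs = [
        GameConfig(
            arms=pairs[i],
            n_forced=task.n_forced,
            forced_allocation=task.forced_allocation,
            n_free=task.n_free,
        )
        for i in pair_idx
    ]
    q_posts = [(q_post[g, 0], q_post[g, 1]) for g in range(n_games_total)]
    return games_loglik(bank, configs, q_posts, n_a)


def estimate_group_mean(
    loglik: np.ndarray, tau_grid: TauGrid
) -> tuple[float, HPDInterval]:
    """Posterior mean and 95% HPDI of tau under the uniform grid prior."""
    prior = GridPrior.uniform(tau_grid.values)
    post = posterior_from_loglik(loglik, prior)
    return point_estimate(post), hpdi(post)


def run_replicate(
    condition: BFDACondition,
    rng: np.random.Generator,
    bank: PmfBank | None = None,
    seed: int = -1,
) -> ReplicateResult:
    """One simulated experiment pushed through the full inference stack.

    The difference is oriented as group 2 minus group 1, so its sign matches
    the generative ``delta_mu`` (group 2 carries the larger mean).
    """
    if bank is None:
        bank = PmfBank(condition.tau_grid, condition.alpha)
    mu1, mu2 = sample_population_means(condition.delta_mu, rng)
    lo, hi = condition.tau_grid.values[0], condition.tau_grid.values[-1]
    taus1 = draw_group_taus(mu1, condition.sigma, condition.n_per_group, rng, lo, hi)
    taus2 = draw_group_taus(mu2, condition.sigma, condition.n_per_group, rng, lo, hi)
    ll1 = simulate_group_loglik(taus1, condition, bank, rng)
    ll2 = simulate_group_loglik(taus2, condition, bank, rng)
    delta_grid = make_delta_grid(condition.tau_grid, condition.delta_prior_bounds)
    log_dens = difference_log_density(ll2, ll1, delta_grid, condition.tau_grid)
    prior = GridPrior.uniform(delta_grid)
    bf10 = bayes_factor_difference(log_dens, prior)
    post = posterior_from_loglik(log_dens, prior)
    delta_hat = point_estimate(post)
    interval = hpdi(post, condition.hpdi_level)
    return ReplicateResult(
        bf10=bf10,
        delta_hat=delta_hat,
        hpdi=interval,
        category=classify_evidence(bf10),
        mu1=mu1,
        mu2=mu2,
        seed=seed,
    )


def run_condition(
    condition: BFDACondition, bank: PmfBank | None = None
) -> BFDAResult:
    """Run all replicates of a condition with order-independent seeding.

    Per-replicate generators are spawned from ``SeedSequence(condition.seed)``
    so any replicate can be recomputed in isolation and execution order never
    changes the results.
    """
    if bank is None:
        bank = PmfBank(condition.tau_grid, condition.alpha)
    children = np.random.SeedSequence(condition.seed).spawn(condition.n_sims)
    replicates = [
        run_replicate(condition, np.random.default_rng(child), bank, seed=i)
        for i, child in enumerate(children)
    ]
    return BFDAResult(condition=condition, replicates=replicates)


def summarize_evidence(result: BFDAResult) -> dict:
    """Evidence-category frequencies and threshold exceedance rates."""
    if not result.replicates:
        raise InvalidInputError("cannot summarize an empty result")
    bf = result.bf10
    n = len(bf)
    categories: dict[str, float] = {}
    for r in result.replicates:
        categories[r.category] = categories.get(r.category, 0.0) + 1.0 / n
    return {
        "n_sims": n,
        "categories": categories,
        "pr_bf_above": {t: float(np.mean(bf > t)) for t in EVIDENCE_THRESHOLDS},
        "pr_bf_below": {t: float(np.mean(bf < 1.0 / t)) for t in EVIDENCE_THRESHOLDS},
    }


def error_metrics(
    result: BFDAResult,
    magnitude_threshold: float = 0.10,
    strong_threshold: float = 10.0,
    null_threshold: float = 1.0 / 3.0,
    signed: bool = True,
) -> dict:
    """Design error rates of a condition.

    * ``type_s_rate`` — replicates supporting the null (BF10 below
      ``null_threshold``) although the true difference is nonzero.
    * ``type_m_exceedance`` — among replicates with strong evidence
      (BF10 above ``strong_threshold``), the fraction overestimating the
      true difference by more than ``magnitude_threshold`` in relative
      terms; ``signed=False`` counts absolute relative errors instead.
    * ``msee`` — mean squared estimation error of the difference estimate.

    Type S and Type M are undefined (``None``, flagged) when the true
    difference is zero; Type M additionally when no replicate reaches strong
    evidence.
    """
    if not result.replicates:
        raise InvalidInputError("cannot compute error metrics on an empty result")
    delta = result.condition.delta_mu
    bf = result.bf10
    est = result.delta_hat
    out: dict = {
        "msee": float(np.mean((est - delta) ** 2)),
        "pr_bf_lt_1_3": float(np.mean(bf < 1.0 / 3.0)),
        "pr_bf_lt_1_10": float(np.mean(bf < 1.0 / 10.0)),
        "type_m_defined": True,
    }
    if delta == 0.0:
        out["type_s_rate"] = None
        out["type_m_exceedance"] = None
        out["type_m_defined"] = False
        return out
    out["type_s_rate"] = float(np.mean(bf < null_threshold))
    strong = bf > strong_threshold
    if not np.any(strong):
        out["type_m_exceedance"] = None
        out["type_m_defined"] = False
    else:
        rel = (est[strong] - delta) / delta
        if not signed:
            rel = np.abs(rel)
        out["type_m_exceedance"] = float(np.mean(rel > magnitude_threshold))
    return out


def replicates_to_frame(result: BFDAResult, condition_id: str = "") -> pd.DataFrame:
    """Per-replicate long table (the exportable record of a condition)."""
    rows = []
    for i, r in enumerate(result.replicates):
        rows.append(
            {
                "condition_id": condition_id,
                "replicate": i,
                "seed": r.seed,
                "mu1": r.mu1,
                "mu2": r.mu2,
                "bf10": r.bf10,
                "delta_hat": r.delta_hat,
                "hpdi_lower": r.hpdi.lower,
                "hpdi_upper": r.hpdi.upper,
                "category": r.category,
            }
        )
    return pd.DataFrame(rows)
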