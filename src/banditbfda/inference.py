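"""Discrete-grid Bayesian machinery.

All integrals over parameters are finite sums over bounded grids: posteriors
are normalized weight vectors, the group-difference density is a discrete
cross-correlation of the two group likelihoods, and the Bayes factor against
the point null Delta = 0 is a ratio of finite sums.  Everything heavy is
carried in log space with max-shifts, so group likelihoods from thousands of
games cannot underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import (
    DegenerateLikelihoodError,
    InvalidInputError,
    InvalidParameterError,
    UndefinedEvidenceError,
)
from .likelihood import TauGrid

__all__ = [
    "GridPrior",
    "GridPosterior",
    "HPDInterval",
    "EVIDENCE_LABELS",
    "posterior_from_loglik",
    "point_estimate",
    "make_delta_grid",
    "difference_log_density",
    "bayes_factor_difference",
    "hpdi",
    "classify_evidence",
]


@dataclass(frozen=True)
class GridPrior:
    """Discrete prior over a parameter grid; weights sum to 1."""

    values: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        if v.shape != p.shape or v.ndim != 1:
            raise InvalidInputError("prior values/probabilities shape mismatch")
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-10):
            raise InvalidInputError("prior weights must be non-negative and sum to 1")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "probabilities", p)

    @classmethod
    def uniform(cls, values: np.ndarray) -> "GridPrior":
        values = np.asarray(values, dtype=float)
        return cls(values=values, probabilities=np.full(len(values), 1.0 / len(values)))


@dataclass(frozen=True)
class GridPosterior:
    """Normalized discrete posterior over a parameter grid."""

    values: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-10:
            raise InvalidInputError("posterior must be non-negative and sum to 1")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "probabilities", p)


@dataclass(frozen=True)
class HPDInterval:
    """Highest-posterior-density interval on a grid.

    ``contiguous`` is False when the highest-density set is multimodal; the
    interval then spans the set so that its length is still a single number.
    """

    lower: float
    upper: float
    mass: float
    contiguous: bool

    @property
    def length(self) -> float:
        return self.upper - self.lower


def posterior_from_loglik(loglik: np.ndarray, prior: GridPrior) -> GridPosterior:
    """Posterior by Bayes' rule on the grid: exp(loglik) x prior, normalized.

    The normalizer (marginal density) is the finite sum over the grid; the
    max-shift makes the construction safe for very peaked likelihoods.
    """
    ll = np.asarray(loglik, dtype=float)
    if ll.shape != prior.values.shape:
        raise InvalidInputError("log-likelihood and prior on mismatched grids")
    with np.errstate(divide="ignore"):
        logw = ll + np.log(prior.probabilities)
    m = logw.max()
    if not np.isfinite(m):
        raise DegenerateLikelihoodError("likelihood places zero mass on the whole grid")
    w = np.exp(logw - m)
    return GridPosterior(values=prior.values, probabilities=w / w.sum())


def point_estimate(posterior: GridPosterior) -> float:
    """Posterior mean (grid-weighted sum)."""
    return float(np.dot(posterior.values, posterior.probabilities))


def make_delta_grid(tau_grid: TauGrid, bounds: tuple[float, float] = (-3.0, 3.0)) -> np.ndarray:
    """Uniform grid for the group difference Delta = tau_2 - tau_1.

    Step equals the tau-grid step; support is the achievable range
    [-(tau_max - tau_min), +(tau_max - tau_min)] intersected with the stated
    prior bounds.  Zero is always a grid point.
    """
    step = tau_grid.step
    span = tau_grid.values[-1] - tau_grid.values[0]
    m = round(span / step)
    grid = np.arange(-m, m + 1) * step
    return grid[(grid >= bounds[0] - 1e-12) & (grid <= bounds[1] + 1e-12)]


def difference_log_density(
    loglik1: np.ndarray,
    loglik2: np.ndarray,
    delta_grid: np.ndarray,
    tau_grid: TauGrid,
) -> np.ndarray:
    """Unnormalized log density of Delta = theta_1 - theta_2.

    Discrete analogue of the convolution p(Y | Delta) =
    sum_theta1 L1(theta1) L2(theta1 - Delta): L2 is evaluated off-grid by
    linear interpolation of its log-likelihood and treated as zero outside
    the tau grid.  Computed with a common max-shift so the result is finite
    wherever any term contributes.
    """
    l1 = np.asarray(loglik1, dtype=float)
    l2 = np.asarray(loglik2, dtype=float)
    t = tau_grid.values
    if l1.shape != t.shape or l2.shape != t.shape:
        raise InvalidInputError("likelihood vectors do not match the tau grid")
    m1, m2 = l1.max(), l2.max()
    if not (np.isfinite(m1) and np.isfinite(m2)):
        raise InvalidInputError("likelihood vectors carry no finite mass")
    # shift to 0 max and floor at an exp-underflow level: keeps np.interp free
    # of -inf (whose zero-weight products are NaN) without changing any
    # representable density value
    floor = -1e6
    l2s = np.maximum(l2 - m2, floor)
    x = t[:, None] - np.asarray(delta_grid)[None, :]
    inside = (x >= t[0] - 1e-12) & (x <= t[-1] + 1e-12)
    # snap round-off stragglers onto the boundary so the mask and the
    # interpolator agree about which terms exist
    l2x = np.interp(np.clip(x, t[0], t[-1]), t, l2s)
    terms = np.where(inside, (l1 - m1)[:, None] + l2x, -np.inf)
    with np.errstate(invalid="ignore"):
        return logsumexp(terms, axis=0) + m1 + m2


def bayes_factor_difference(log_density: np.ndarray, prior: GridPrior) -> float:
    """Bayes factor BF10 of a nonzero difference against the point null.

    BF10 = [sum_Delta p(Y|Delta) pi(Delta)] / p(Y|Delta=0), evaluated as
    finite sums after a common max-shift.  Returns ``inf`` when the null
    density underflows to zero while the numerator is positive.
    """
    ld = np.asarray(log_density, dtype=float)
    if ld.shape != prior.values.shape:
        raise InvalidInputError("density and prior on mismatched grids")
    i0 = np.flatnonzero(np.isclose(prior.values, 0.0, atol=1e-12))
    if len(i0) != 1:
        raise InvalidInputError("Delta = 0 must be a unique grid point")
    m = ld.max()
    if not np.isfinite(m):
        raise UndefinedEvidenceError("difference density is zero everywhere")
    with np.errstate(divide="ignore"):
        log_num = logsumexp(ld - m, b=prior.probabilities)
    log_den = ld[i0[0]] - m
    if np.exp(log_den) == 0.0:
        return np.inf
    with np.errstate(over="ignore"):
        return float(np.exp(log_num - log_den))


def hpdi(posterior: GridPosterior, level: float = 0.95) -> HPDInterval:
    """Highest-posterior-density interval at the given credibility level.

    Grid points are admitted in order of decreasing probability until their
    cumulative mass reaches the level; the interval spans the admitted set.
    """
    if not 0.0 < level < 1.0:
        raise InvalidParameterError(f"level must be in (0, 1), got {level}")
    p = posterior.probabilities
    order = np.argsort(-p, kind="stable")
    cum = np.cumsum(p[order])
    m = int(np.searchsorted(cum, level - 1e-12) + 1)
    chosen = np.sort(order[:m])
    return HPDInterval(
        lower=float(posterior.values[chosen[0]]),
        upper=float(posterior.values[chosen[-1]]),
        mass=float(p[chosen].sum()),
        contiguous=bool(np.all(np.diff(chosen) == 1)),
    )


#: Jeffreys evidence categories, strongest H1 first.
EVIDENCE_LABELS = (
    "extreme evidence for H1",
    "very strong evidence for H1",
    "strong evidence for H1",
    "moderate evidence for H1",
    "anecdotal evidence for H1",
    "no evidence",
    "anecdotal evidence for H0",
    "moderate evidence for H0",
    "strong evidence for H0",
    "very strong evidence for H0",
    "extreme evidence for H0",
)


def classify_evidence(bf10: float) -> str:
    """Jeffreys category of a Bayes factor.

    Thresholds are 1/100, 1/30, 1/10, 1/3, 1, 3, 10, 30, 100; a value
    sitting exactly on a threshold is assigned the weaker category, keeping
    evidence claims conservative.
    """
    if not bf10 > 0:
        raise InvalidInputError(f"Bayes factor must be positive, got {bf10}")
    if bf10 > 100:
        return EVIDENCE_LABELS[0]
    if bf10 > 30:
        return EVIDENCE_LABELS[1]
    if bf10 > 10:
        return EVIDENCE_LABELS[2]
    if bf10 > 3:
        return EVIDENCE_LABELS[3]
    if bf10 > 1:
        return EVIDENCE_LABELS[4]
    if bf10 == 1:
        return EVIDENCE_LABELS[5]
    if bf10 >= 1 / 3:
        return EVIDENCE_LABELS[6]
    if bf10 >= 1 / 10:
        return EVIDENCE_LABELS[7]
    if bf10 >= 1 / 30:
        return EVIDENCE_LABELS[8]
    if bf10 >= 1 / 100:
        return EVIDENCE_LABELS[9]
    return EVIDENCE_LABELS[10]
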