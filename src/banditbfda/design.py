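"""Design-quality metrics across conditions.

Builds on the BFDA engine to answer design questions: how long is the HPDI
of the difference on average (and the smallest group size keeping it under a
preset maximum — the average length criterion), and how do evidence rates,
error rates and estimation accuracy move across a grid of sample sizes,
effect sizes and games per participant.  The trend diagnostics at the bottom
are deliberately descriptive (rank correlations, least-squares fits): they
sit outside the Bayesian inference path and only check that the simulated
summaries carry the signal they should.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .bfda import (
    BFDACondition,
    BFDAResult,
    error_metrics,
    estimate_group_mean,
    run_condition,
    simulate_group_loglik,
    summarize_evidence,
)
from .errors import InvalidInputError, InvalidParameterError
from .likelihood import PmfBank
from .bfda import draw_group_taus

__all__ = [
    "SweepTable",
    "average_hpdi_length",
    "alc_sample_size",
    "condition_summary",
    "run_sweep",
    "run_validation",
    "descriptive_trends",
]


@dataclass
class SweepTable:
    """Long-format summaries of a grid of design cells."""

    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def average_hpdi_length(
    condition: BFDACondition,
    level: float = 0.95,
    result: BFDAResult | None = None,
    bank: PmfBank | None = None,
) -> float:
    """Average HPDI length of the difference posterior for a design cell.

    Monte-Carlo approximation of the posterior-predictive average: the BFDA
    replicate datasets are draws from the same generative model, so the mean
    of their per-replicate HPDI lengths estimates the predictive integral
    without a second simulation layer.
    """
    if result is None:
        cond = condition if level == condition.hpdi_level else replace(condition, hpdi_level=level)
        result = run_condition(cond, bank=bank)
    if not result.replicates:
        raise InvalidInputError("no replicates to average over")
    return float(np.mean(result.hpdi_lengths))


def alc_sample_size(
    l_max: float,
    candidate_n: Sequence[int],
    template: BFDACondition,
    bank: PmfBank | None = None,
    lengths: dict[int, float] | None = None,
) -> int | None:
    """Average length criterion: smallest group size meeting a length budget.

    Returns the smallest candidate ``n`` whose average HPDI length is at
    most ``l_max``, or ``None`` when no candidate qualifies.  Precomputed
    ``lengths`` (n -> average length) may be supplied to avoid re-running
    conditions; otherwise each candidate is simulated with a seed derived
    from the template seed and the candidate value, so results do not depend
    on the order or subset of candidates evaluated.
    """
    if not l_max > 0:
        raise InvalidParameterError(f"l_max must be > 0, got {l_max}")
    if len(candidate_n) == 0:
        raise InvalidParameterError("candidate_n must be non-empty")
    for n in sorted(candidate_n):
        if lengths is not None and n in lengths:
            avg = lengths[n]
        else:
            cond = replace(
                template,
                n_per_group=int(n),
                seed=_cell_seed(template.seed, (-1, float(n))),
            )
            avg = average_hpdi_length(cond, level=template.hpdi_level, bank=bank)
        if avg <= l_max:
            return int(n)
    return None


def condition_summary(result: BFDAResult) -> dict:
    """One sweep-cell row: evidence rates, error metrics, HPDI length."""
    ev = summarize_evidence(result)
    err = error_metrics(result)
    return {
        "rate_bf_gt_10": ev["pr_bf_above"][10.0],
        "rate_bf_lt_1_3": err["pr_bf_lt_1_3"],
        "rate_bf_lt_1_10": err["pr_bf_lt_1_10"],
        "type_m_exceedance": err["type_m_exceedance"],
        "msee": err["msee"],
        "avg_hpdi_length": float(np.mean(result.hpdi_lengths)),
        "n_sims": ev["n_sims"],
    }


def _cell_seed(root_seed: int, key: tuple[int, float]) -> int:
    """Deterministic per-cell seed below 2**31, independent of sweep order.

    ``key`` must be numeric: numeric hashes are stable across processes
    (string hashes are not).
    """
    ss = np.random.SeedSequence([root_seed, key[0] % (2**31), round(1000 * key[1]) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_sweep(
    n_values: Sequence[int],
    template: BFDACondition,
    delta_values: Sequence[float] | None = None,
    n_games_values: Sequence[int] | None = None,
    bank: PmfBank | None = None,
) -> SweepTable:
    """Grid of conditions over n x delta_mu or n x n_games.

    Exactly one of ``delta_values`` / ``n_games_values`` must be given; the
    other axis is held at the template's value.  Every cell gets its own
    derived seed, so deleting and recomputing a cell reproduces it exactly.
    """
    if (delta_values is None) == (n_games_values is None):
        raise InvalidParameterError(
            "supply exactly one of delta_values or n_games_values"
        )
    if bank is None:
        bank = PmfBank(template.tau_grid, template.alpha)
    axis2_name = "delta_mu" if delta_values is not None else "n_games"
    axis2 = delta_values if delta_values is not None else n_games_values
    rows = []
    for n in n_values:
        for v in axis2:
            overrides = {"n_per_group": int(n), axis2_name: v if axis2_name == "delta_mu" else int(v)}
            cond = replace(
                template,
                **overrides,
                seed=_cell_seed(template.seed, (int(n), float(v))),
            )
            result = run_condition(cond, bank=bank)
            row = {"n": int(n), axis2_name: v}
            row.update(condition_summary(result))
            rows.append(row)
    return SweepTable(frame=pd.DataFrame(rows))


def run_validation(
    mu_values: Sequence[float],
    n_values: Sequence[int],
    n_games: int,
    reps_per_cell: int,
    seed: int,
    template: BFDACondition | None = None,
    bank: PmfBank | None = None,
) -> pd.DataFrame:
    """Single-group parameter recovery across (population mean, group size).

    For each cell and repeat: draw participant exploration parameters around
    the true mean, simulate their games, and estimate the mean as the
    posterior mean of the shared-tau grid posterior.  Returns one row per
    repeat with the truth and the estimate — the raw material for recovery
    regressions and MSEE trends.
    """
    cond0 = template or BFDACondition(
        delta_mu=0.0, n_per_group=1, n_games=n_games, n_sims=1, seed=seed
    )
    if bank is None:
        bank = PmfBank(cond0.tau_grid, cond0.alpha)
    lo, hi = cond0.tau_grid.values[0], cond0.tau_grid.values[-1]
    rows = []
    for mu in mu_values:
        for n in n_values:
            cell_ss = np.random.SeedSequence(
                [seed, round(1000 * mu), int(n)]
            ).spawn(reps_per_cell)
            cond = replace(cond0, n_per_group=int(n), n_games=n_games)
            for rep, child in enumerate(cell_ss):
                rng = np.random.default_rng(child)
                taus = draw_group_taus(mu, cond.sigma, int(n), rng, lo, hi)
                ll = simulate_group_loglik(taus, cond, bank, rng)
                est, interval = estimate_group_mean(ll, cond.tau_grid)
                rows.append(
                    {
                        "mu": mu,
                        "n": int(n),
                        "rep": rep,
                        "estimate": est,
                        "error_sq": (est - mu) ** 2,
                        "hpdi_length": interval.length,
                    }
                )
    return pd.DataFrame(rows)


def descriptive_trends(
    table: pd.DataFrame,
    estimate_col: str = "estimate",
    truth_col: str = "mu",
    n_col: str = "n",
    msee_col: str | None = None,
) -> dict:
    """Descriptive diagnostics of a validation or sweep table.

    Reports Spearman rank correlations of the key summaries against the
    design axes, an OLS fit of estimates on truth (with truth x n
    interaction), and an OLS fit of the MSEE on a log-transformed group size
    and an exponentially transformed truth, the transform's scaling constant
    being fitted from the data.  Constant columns yield an
    ``undefined-correlation`` flag rather than an error.  Everything here is
    a plain least-squares summary, outside the Bayesian path.
    """
    if len(table) < 3 or table[n_col].nunique() < 2:
        raise InvalidInputError("need >= 3 rows and >= 2 distinct axis values")
    report: dict = {"spearman": {}, "flags": []}

    def _spearman(x, y, name):
        if np.ptp(np.asarray(x, float)) == 0 or np.ptp(np.asarray(y, float)) == 0:
            report["spearman"][name] = None
            report["flags"].append(f"undefined-correlation:{name}")
        else:
            rho, p = stats.spearmanr(x, y)
            report["spearman"][name] = {"rho": float(rho), "p": float(p)}

    # recovery fit: estimate ~ truth + n + truth:n
    truth = table[truth_col].to_numpy(float)
    n = table[n_col].to_numpy(float)
    est = table[estimate_col].to_numpy(float)
    X = sm.add_constant(np.column_stack([truth, n, truth * n]))
    fit = sm.OLS(est, X).fit()
    report["recovery_fit"] = {
        "slope_truth": float(fit.params[1]),
        "r_squared": float(fit.rsquared),
        "params": [float(b) for b in fit.params],
    }

    # cell-level recovery: mean estimate per (truth, n) cell against truth.
    # Replicate noise averages out, so this is the cleaner recovery summary.
    cell_est = table.groupby([truth_col, n_col])[estimate_col].mean().reset_index()
    if np.ptp(cell_est[truth_col].to_numpy(float)) > 0:
        Xs = sm.add_constant(cell_est[truth_col].to_numpy(float))
        sfit = sm.OLS(cell_est[estimate_col].to_numpy(float), Xs).fit()
        report["recovery_fit_cell_means"] = {
            "slope": float(sfit.params[1]),
            "r_squared": float(sfit.rsquared),
        }
    else:
        report["recovery_fit_cell_means"] = None
        report["flags"].append("undefined-correlation:recovery_cell_means")

    # MSEE per cell and its trends
    if msee_col is None:
        cell = (
            table.assign(_sq=(est - truth) ** 2)
            .groupby([truth_col, n_col])["_sq"]
            .mean()
            .reset_index()
            .rename(columns={"_sq": "msee"})
        )
        msee_col_name = "msee"
    else:
        cell = table[[truth_col, n_col, msee_col]].copy()
        msee_col_name = msee_col
    _spearman(cell[n_col], cell[msee_col_name], "msee_vs_n")
    for mu, sub in cell.groupby(truth_col):
        if sub[n_col].nunique() >= 3:
            _spearman(sub[n_col], sub[msee_col_name], f"msee_vs_n@mu={mu:g}")

    # msee ~ log(n) * exp(c * truth); scaling constant c fitted from the data
    m = cell[msee_col_name].to_numpy(float)
    cn = cell[n_col].to_numpy(float)
    cmu = cell[truth_col].to_numpy(float)

    def _sse(c: float) -> float:
        z = np.exp(np.clip(c, -20, 20) * cmu)
        Xc = sm.add_constant(np.column_stack([np.log(cn), z, np.log(cn) * z]))
        return float(sm.OLS(m, Xc).fit().ssr)

    if np.ptp(cmu) > 0:
        res = optimize.minimize_scalar(_sse, bounds=(-10.0, 10.0), method="bounded")
        c_hat = float(res.x)
    else:
        c_hat = 0.0
    z = np.exp(c_hat * cmu)
    Xc = sm.add_constant(np.column_stack([np.log(cn), z, np.log(cn) * z]))
    mfit = sm.OLS(m, Xc).fit()
    report["msee_fit"] = {
        "scaling_constant": c_hat,
        "r_squared": float(mfit.rsquared),
        "params": [float(b) for b in mfit.params],
    }
    return report
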