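"""Unit tests for the path-enumeration likelihood engine."""

import math

import numpy as np
import pytest
from scipy import stats

from banditbfda import (
    ArmPair,
    GameConfig,
    ParticipantDataset,
    PmfBank,
    TauGrid,
    enumerate_outcome_pmf,
    group_loglik,
    monte_carlo_pmf,
    participant_loglik,
    q_after_forced,
)
from banditbfda.errors import (
    ConfigurationError,
    InvalidInputError,
    InvalidParameterError,
)

SMALL_CFG = GameConfig(
    arms=ArmPair(0.1, 0.9), n_forced=2, forced_allocation=(1, 2), n_free=2
)

# Frozen expected PMFs for the 16-path reduced task at tau = 1, alpha = 0.1,
# computed by an explicit written-out enumeration over all
# (choice1, outcome1, choice2, outcome2) combinations (see pmf_by_hand).
HAND_PMF = {
    (0.0, 0.0): (0.250000000000, 0.507993339993, 0.242006660007),
    (-0.1, 0.0): (0.231269093710, 0.506939562958, 0.261791343332),
}


def pmf_by_hand(p_av, q0, tau, alpha=0.1):
    """Independent 16-path enumeration (pure python, explicit loops)."""
    pmf = [0.0, 0.0, 0.0]
    for a1 in (0, 1):
        for r1 in (0, -1):
            for a2 in (0, 1):
                for r2 in (0, -1):
                    q = list(q0)
                    prob, k = 1.0, 0
                    for a, r in ((a1, r1), (a2, r2)):
                        e = (math.exp(q[0] / tau), math.exp(q[1] / tau))
                        prob *= e[a] / (e[0] + e[1])
                        prob *= p_av[a] if r == -1 else 1 - p_av[a]
                        k += r == -1
                        q[a] += alpha * (r - q[a])
                    pmf[k] += prob
    return pmf


class TestQAfterForced:
    def test_no_prediction_error(self):
        cfg = GameConfig(arms=ArmPair(0.1, 0.9))
        assert q_after_forced(cfg, (0, 0, 0, 0), 0.1) == (0.0, 0.0)

    def test_two_step_hand_arithmetic(self):
        # arm 1 sees -1 then 0: -0.1, then -0.1 + 0.1 * 0.1 = -0.09
        cfg = GameConfig(arms=ArmPair(0.1, 0.9))
        q1, q2 = q_after_forced(cfg, (-1, 0, 0, 0), 0.1)
        assert q1 == pytest.approx(-0.09)
        assert q2 == pytest.approx(0.0)

    def test_order_dependence(self):
        cfg = GameConfig(arms=ArmPair(0.1, 0.9))
        q_late = q_after_forced(cfg, (0, 0, -1, 0), 0.1)[0]
        q_early = q_after_forced(cfg, (-1, 0, 0, 0), 0.1)[0]
        assert q_late == pytest.approx(-0.1)
        assert q_early == pytest.approx(-0.09)

    def test_length_mismatch(self):
        cfg = GameConfig(arms=ArmPair(0.1, 0.9))
        with pytest.raises(InvalidInputError):
            q_after_forced(cfg, (0, 0), 0.1)


class TestEnumerateOutcomePmf:
    def test_sixteen_path_oracle_exact(self):
        grid = TauGrid(values=np.array([1.0, 2.0]), step=1.0)
        for q0, frozen in HAND_PMF.items():
            pmf = enumerate_outcome_pmf(SMALL_CFG, q0, grid)
            np.testing.assert_allclose(pmf[0], frozen, atol=1e-12)
            np.testing.assert_allclose(pmf[0], pmf_by_hand((0.1, 0.9), q0, 1.0), atol=1e-14)

    def test_rows_sum_to_one(self, coarse_grid):
        cfg = GameConfig(arms=ArmPair(0.1, 0.9))
        pmf = enumerate_outcome_pmf(cfg, (-0.09, -0.1), coarse_grid)
        np.testing.assert_allclose(pmf.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(pmf >= 0)

    def test_equal_arms_binomial_independent_of_tau(self, coarse_grid):
        # with identical arms the count law is Binomial(6, p) whatever the policy
        cfg = GameConfig(arms=ArmPair(0.3, 0.3))
        pmf = enumerate_outcome_pmf(cfg, (-0.1, 0.0), coarse_grid)
        binom = stats.binom.pmf(np.arange(7), 6, 0.3)
        np.testing.assert_allclose(pmf, np.tile(binom, (len(coarse_grid), 1)), atol=1e-10)

    def test_high_temperature_equal_arms(self):
        grid = TauGrid(values=np.array([1e4, 2e4]), step=1e4)
        cfg = GameConfig(arms=ArmPair(0.9, 0.9))
        pmf = enumerate_outcome_pmf(cfg, (0.0, 0.0), grid)
        np.testing.assert_allclose(pmf[0], stats.binom.pmf(np.arange(7), 6, 0.9), atol=1e-8)

    def test_zero_aversive_probability_decreases_with_tau(self):
        # arms (0.1, 0.9): more exploration visits the bad arm more often
        grid = TauGrid.default(lo=0.05, step=0.05)
        cfg = GameConfig(arms=ArmPair(0.1, 0.9))
        pmf = enumerate_outcome_pmf(cfg, (0.0, 0.0), grid)
        p0 = pmf[:, 0]
        assert np.all(np.diff(p0) <= 1e-12)

    def test_intractable_horizon_rejected(self, coarse_grid):
        cfg = GameConfig(
            arms=ArmPair(0.1, 0.9), n_forced=4, forced_allocation=(1, 2, 1, 2), n_free=12
        )
        with pytest.raises(ConfigurationError):
            enumerate_outcome_pmf(cfg, (0.0, 0.0), coarse_grid)


class TestMonteCarloPmf:
    def test_frequencies_sum_to_one_and_reproducible(self):
        cfg = GameConfig(arms=ArmPair(0.1, 0.9))
        f1 = monte_carlo_pmf(cfg, (0.0, 0.0), 0.5, 2000, np.random.default_rng(2))
        f2 = monte_carlo_pmf(cfg, (0.0, 0.0), 0.5, 2000, np.random.default_rng(2))
        assert f1.sum() == pytest.approx(1.0)
        np.testing.assert_array_equal(f1, f2)

    def test_agrees_with_enumeration(self):
        cfg = GameConfig(arms=ArmPair(0.1, 0.9))
        grid = TauGrid(values=np.array([0.5, 1.0]), step=0.5)
        exact = enumerate_outcome_pmf(cfg, (0.0, 0.0), grid)[0]
        n = 40_000
        freq = monte_carlo_pmf(cfg, (0.0, 0.0), 0.5, n, np.random.default_rng(7))
        se = np.sqrt(exact * (1 - exact) / n)
        assert np.all(np.abs(freq - exact) < 3 * se + 1e-9)

    def test_too_few_sims_rejected(self):
        with pytest.raises(InvalidParameterError):
            monte_carlo_pmf(SMALL_CFG, (0.0, 0.0), 1.0, 10, np.random.default_rng(0))


class TestPmfBankAndLogliks:
    def test_cache_identical_to_fresh(self, coarse_grid):
        bank = PmfBank(coarse_grid)
        cfg = GameConfig(arms=ArmPair(0.1, 0.3))
        cached = bank.pmf(cfg, (-0.1, 0.0))
        fresh = enumerate_outcome_pmf(cfg, (-0.1, 0.0), coarse_grid)
        np.testing.assert_array_equal(cached, fresh)
        assert len(bank) == 1
        bank.pmf(cfg, (-0.1, 0.0))
        assert len(bank) == 1  # no duplicate entry

    def test_single_game_is_log_pmf_entry(self, coarse_grid):
        bank = PmfBank(coarse_grid)
        cfg = GameConfig(arms=ArmPair(0.1, 0.9))
        ds = ParticipantDataset(games=[(cfg, (0, 0, 0, 0), 2)])
        ll = participant_loglik(ds, bank)
        expected = np.log(enumerate_outcome_pmf(cfg, (0.0, 0.0), coarse_grid)[:, 2])
        np.testing.assert_allclose(ll, expected, atol=1e-12)

    def test_concatenation_sums_logliks(self, coarse_grid):
        bank = PmfBank(coarse_grid)
        cfg1 = GameConfig(arms=ArmPair(0.1, 0.9))
        cfg2 = GameConfig(arms=ArmPair(0.3, 0.1))
        ds_a = ParticipantDataset(games=[(cfg1, (0, -1, 0, 0), 1)])
        ds_b = ParticipantDataset(games=[(cfg2, (0, 0, -1, 0), 4)])
        both = ParticipantDataset(games=ds_a.games + ds_b.games)
        np.testing.assert_allclose(
            participant_loglik(both, bank),
            participant_loglik(ds_a, bank) + participant_loglik(ds_b, bank),
            atol=1e-12,
        )

    def test_three_game_linear_space_product(self, coarse_grid):
        bank = PmfBank(coarse_grid)
        cfg = GameConfig(arms=ArmPair(0.1, 0.3))
        games = [(cfg, (0, 0, 0, 0), 0), (cfg, (-1, 0, 0, 0), 1), (cfg, (0, -1, -1, 0), 3)]
        ll = participant_loglik(ParticipantDataset(games=games), bank)
        product = np.ones(len(coarse_grid))
        for _, forced, n_a in games:
            q = q_after_forced(cfg, forced, 0.1)
            product *= enumerate_outcome_pmf(cfg, q, coarse_grid)[:, n_a]
        np.testing.assert_allclose(np.exp(ll), product, rtol=1e-10)

    def test_invalid_count_rejected(self, coarse_grid):
        bank = PmfBank(coarse_grid)
        cfg = GameConfig(arms=ArmPair(0.1, 0.9))
        ds = ParticipantDataset(games=[(cfg, (0, 0, 0, 0), 7)])
        with pytest.raises(InvalidInputError):
            participant_loglik(ds, bank)

    def test_export_frame_schema(self):
        grid = TauGrid(values=np.array([0.5, 1.0]), step=0.5)
        bank = PmfBank(grid)
        bank.pmf(SMALL_CFG, (0.0, 0.0))
        frame = bank.to_frame()
        assert len(frame) == 2 * 3  # two taus, counts 0..2
        np.testing.assert_allclose(
            frame.groupby("tau")["probability"].sum().to_numpy(), 1.0, atol=1e-10
        )


class TestGroupLoglik:
    def test_identity_linearity_and_brute_force(self, rng):
        v = rng.normal(size=(3, 10))
        np.testing.assert_array_equal(group_loglik([v[0]]), v[0])
        np.testing.assert_allclose(group_loglik([v[0]] * 4), 4 * v[0], atol=1e-12)
        np.testing.assert_allclose(group_loglik(list(v)), v[0] + v[1] + v[2], atol=1e-12)

    def test_grid_mismatch(self):
        with pytest.raises(InvalidInputError):
            group_loglik([np.zeros(5), np.zeros(6)])
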