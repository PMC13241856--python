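"""Estimate a group's mean exploration parameter from simulated play.

Simulates a group of participants on the horizon task, forms the exact
grid likelihood of their per-game aversive counts, and reports the
posterior mean and 95% HPDI of the shared exploration parameter.
"""

import numpy as np

from banditbfda import (
    PmfBank,
    TaskSpec,
    TauGrid,
    estimate_group_mean,
    group_loglik,
    participant_loglik,
    simulate_participant,
)

rng = np.random.default_rng(7)
task = TaskSpec()
grid = TauGrid.default()
bank = PmfBank(grid)

true_mu, sigma, n, n_games = 0.4, 0.02, 12, 150
taus = rng.normal(true_mu, sigma, size=n)
datasets = [simulate_participant(t, task, n_games, rng) for t in taus]

loglik = group_loglik([participant_loglik(ds, bank) for ds in datasets])
estimate, interval = estimate_group_mean(loglik, grid)

print(f"true population mean     : {true_mu}")
print(f"posterior mean estimate  : {estimate:.3f}")
print(f"95% HPDI                 : [{interval.lower:.2f}, {interval.upper:.2f}]")
print(f"games used               : {n} participants x {n_games} games")

# Reading: with ~1800 games the posterior concentrates tightly around the
# generative mean; the HPDI width is the resolution the design buys you.
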