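"""Fit a normal-CDF viability-loss curve to storage survival data.

Seed viability during ambient storage declines as Phi((mu - p)/sigma):
mu is the storage time at which half the lot is dead (the P50), sigma
the spread of lifetimes.  Here we fit noisy survival fractions.
"""

import numpy as np
from scipy.stats import norm

import germthresh as gt

rng = np.random.default_rng(3)
days = np.array([0, 5, 10, 15, 20, 25, 45, 65], dtype=float)
true_mu, true_sigma = 38.0, 16.0
viability = norm.cdf((true_mu - days) / true_sigma)
observed = rng.binomial(75, viability) / 75  # 3 replicates of 25 seeds

fit = gt.fit_viability_normal(days, observed)
print("storage (d)   true    observed")
for d, v, o in zip(days, viability, observed):
    print(f"   {d:5.0f}      {v:.3f}    {o:.3f}")
print(f"\nfitted P50 lifetime mu = {fit.mu:.1f} d (true {true_mu}),"
      f" spread sigma = {fit.sigma:.1f} d (true {true_sigma})")
print("Half this lot is dead after about five and a half weeks of storage.")
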