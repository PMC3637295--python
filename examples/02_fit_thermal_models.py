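"""Fit and compare the one- and two-phased thermal time models.

Simulates a control-seed experiment (6 temperatures, 3 x 50 seeds, hourly
scoring) from a two-phased generator — low temperatures governed by a
distributed minimum temperature, high temperatures by classic thermal
time — then fits both descriptions and ranks them by AIC.
"""

import germthresh as gt

generator = gt.MTTParams(
    low=gt.MTTLowParams(theta_Tm=383.9, T_m50=4.4, sigma_Tm=3.79),
    high=gt.TTParams(theta_T50=149.1, T_b=9.5, sigma_lnTheta=0.56),
)
design = gt.SimulationDesign(storage_days=(0.0,), rng_seed=42)
lot = gt.simulate_lot(generator, design)
print(f"simulated {len(lot)} recordings "
      f"({design.n_replicates} x {design.n_seeds} seeds per temperature)")

table = gt.compare_run(lot, pair="tt_vs_mtt")
print("\nModel comparison (lower AIC = likelier):")
print(table[["model", "n_obs", "k_params", "aic", "rmse", "preferred"]]
      .to_string(index=False))

pts = gt.regression_points(lot)
low, high = gt.fit_mtt(pts)
print("\nRecovered two-phased constants (generating values in brackets):")
print(f"  low range: theta_Tm={low.params.theta_Tm:.1f} [383.9] degC*h, "
      f"T_m50={low.params.T_m50:.2f} [4.4] degC, sigma_Tm={low.params.sigma_Tm:.2f} [3.79]")
print(f"  high range: theta_T50={high.params.theta_T50:.1f} [149.1] degC*h, "
      f"T_b={high.params.T_b:.2f} [9.5] degC")
print("\nThe two-phased fit wins because cold-range germination really is")
print("limited by a seed-specific minimum temperature, not by thermal time.")
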