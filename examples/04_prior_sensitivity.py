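"""Check that the posterior is driven by the data, not the priors.

Refits one synthetic study with all half-normal prior standard deviations at
half, baseline, and double scale, then correlates the posterior-mean vectors.
Values near 1 mean the likelihood dominates. Runs a few minutes.
"""

import burstvar as bv

sim = bv.simulate_dataset(
    40, seed=3,
    design=bv.BurstDesign(n_bursts=2, burst_length=10, burst_offsets_months=(0, 4)),
)
ds = bv.build_model_dataset(sim.daily, sim.participants)

report = bv.prior_sensitivity(
    ds, multipliers=(0.5, 1.0, 2.0),
    mcmc=bv.McmcConfig(chains=2, warmup=400, draws=600, seed=4),
)
for a, b, corr in report.correlations:
    print(f"prior scales x{a} vs x{b}: posterior-mean correlation {corr:.6f}")
print(f"minimum: {report.min_correlation():.6f} "
      "(the study reports 0.9999 and higher at full scale)")
print(f"largest per-parameter shift: {report.max_abs_diff.max():.4f} "
      f"({report.max_abs_diff.idxmax()})")
print(f"prior-dominated flag: {report.prior_dominated}")
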