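"""Generate a small synthetic burst study and look at what it contains.

Builds 25 participants with study-like covariates, a four-burst calendar,
daily latent (L, P) series from the VAR truth, MAR masking, and the daily
observation table. Prints the composition and missingness so you can see the
generator reproducing the study conditions.
"""

import burstvar as bv

sim = bv.simulate_dataset(25, seed=42)

print(f"participants: {len(sim.participants)}")
print(f"  runners: {sim.participants['runner'].mean():.2f} "
      "(study share 0.568)")
print(f"  women:   {(sim.participants['gender'] == 'female').mean():.2f} "
      "(study share 0.463)")
print(f"person-days: {len(sim.daily)} "
      f"({sim.calendar['burst_index'].nunique()} bursts x 14 days each)")
print(f"LS missing:  {sim.daily['ls_mean'].isna().mean():.3f} "
      "(evening survey skipped, MAR)")
print(f"PA missing:  {sim.daily['pa_rate'].isna().mean():.3f} "
      "(no valid wear time that day)")
print("\nfirst rows of the daily table:")
print(sim.daily.head(5).to_string(index=False))
print("\nground truth (for recovery checks): "
      f"beta_LL={sim.truth.beta[0, 0]}, alpha0={sim.truth.alpha0}, "
      f"sigma_L={sim.truth.sigma_L}")
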