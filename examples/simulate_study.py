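"""Generate the default synthetic study and look at what it contains.

A century of per-year temperature predictors with a warming trend, latent
true flowering dates for four phenophases, and the sparse observation
record: website-era records from 1989 (2002 for last flowering) only.
"""

from phenossm import default_study_config, simulate_dataset

cfg = default_study_config(seed=42)
ds = simulate_dataset(cfg)

print("predictors (first 3 years):")
print(ds.predictors.head(3).round(2).to_string(index=False))

obs = ds.observations.frame
print("\nobservations per phenophase (first year, count):")
for phase in ("FFL", "FFB", "LFB", "LFL"):
    sub = obs[obs["phenophase"] == phase]
    print(f"  {phase}: first {sub['year'].min()}, n = {len(sub)}, "
          f"mean DOY {sub['doy'].mean():.1f}, SD {sub['doy'].std():.1f}")

truth = ds.truth["FFL"].frame
print("\ntrue FFL date, first vs last decade means:")
print(f"  1924-1933: DOY {truth['alpha'][:10].mean():.1f}")
print(f"  2015-2024: DOY {truth['alpha'][-10:].mean():.1f}")
print("the gap is the simulated climate-warming advance of flowering")
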