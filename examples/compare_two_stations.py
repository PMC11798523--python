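"""Two weather stations, one tree: the estimated dates barely change.

A station at different altitude sees the same weather shifted by a
roughly constant offset.  Fitting the same observations with offset
predictors moves the intercept, not the estimated true dates — the model
needs no lapse-rate correction.
"""

from phenossm import (
    VarianceParams,
    build_model,
    compare_stations,
    default_study_config,
    sample_posterior,
    simulate_dataset,
    summarize_posterior,
    with_station_offset,
)

MCMC = {"chains": 2, "iterations": 2000, "burnin": 500, "thin": 1}
VAR = VarianceParams(sigma_omega=0.2, sigma_tau=0.05, sigma_phi=2.0, sigma_upsilon=0.05)

cfg = default_study_config(seed=13)
ds = simulate_dataset(cfg)
offset = -3.4  # degC, e.g. a valley station vs a hillside one

fits = []
for pred in (ds.predictors, with_station_offset(ds.predictors, offset)):
    spec = build_model("FFL", pred, ds.observations)
    draws = sample_posterior(spec, {**MCMC, "seed": 9}, fixed_variances=VAR)
    fits.append(summarize_posterior(draws))

per_year, coefs = compare_stations(*fits)
print(f"station B runs {offset:+.1f} degC relative to station A\n")
print(f"mean |difference| of estimated true FFL dates: "
      f"{per_year['delta'].abs().mean():.2f} days")
print("\npooled coefficient medians:")
print(coefs.round(2).to_string(index=False))
print("\nthe intercept soaks up the temperature offset; "
      "the reconstructed flowering dates are essentially unchanged")
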