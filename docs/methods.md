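# Methods and design notes

## Model

Each phenophase is modelled independently as a linear-Gaussian state-space
model over consecutive calendar years.  The latent state is the vector of
regression quantities — intercept `mu_t` (days) and one or two temperature
coefficients `beta_t`, `gamma_t` (days/°C) — evolving as independent
Gaussian random walks.  The latent true date is the deterministic
combination `alpha_t = mu_t + beta_t·ex1_t + gamma_t·ex2_t` (first
flowering / first full bloom) or `alpha_t = mu_t + beta_t·ex3_t` (last full
bloom / last flowering), and an observed date, where one exists, is
`alpha_t` plus Gaussian noise.

Assumptions worth keeping in mind:

* the temperature→date relationship is linear in the windowed predictors,
  with coefficients allowed to drift slowly across decades rather than
  jump;
* observation errors are independent Gaussians — adequate for dates read
  off a website or a diary to the nearest day, questionable for, say, a
  photograph that brackets a range of dates;
* years with no observation still carry state equations, so the model
  extrapolates backwards across unobserved decades with honestly widening
  uncertainty.

The intercepts are deliberately of order 100–140 days because predictors
enter uncentered and unscaled; this keeps fitted coefficient magnitudes
directly comparable to published per-°C sensitivities.

## Predictors

* `ex1`: mean daily *minimum* over 1 Dec (t−1) … 28/29 Feb (t) — 90 days,
  or 91 when February of year t has 29 days.  Leap status is keyed to the
  February year, not the December year.
* `ex2`: mean daily *mean* over 1–31 March.  "Monthly mean" is computed as
  the mean of daily means, the convention of JMA monthly normals.
* `ex3`: mean daily *mean* over 1–10 April.

A window tolerates up to 10% missing days by default (configurable per
window); beyond that the predictor is marked missing and the year is
excluded from the modelled contiguous run.  Readers never impute, and the
predictor for year t provably never reads a date outside
[1 Dec t−1, 10 Apr t] (property-tested).  Day-of-year is 1-based
(1 Jan = 1), so 1–2 April ≈ DOY 92.

## Priors

The paper-style "non-informative" initial state is implemented as a proper
diffuse prior Normal(0, init_sd²) with init_sd = 100 days (variance 10⁴).
The same finite initialization is used in both the sampler and the Kalman
smoother so that the two inference routes answer exactly the same
question; exact diffuse filtering would have made their comparison
apples-to-oranges at the first time step.

Variance SDs (`sigma_omega`, `sigma_tau`, `sigma_upsilon`, `sigma_phi`)
get half-normal(scale 10 days) priors by default — weakly informative, and
proper, which matters when two-thirds of the series is unobserved.  An
improper flat-on-positive option (`sigma_prior: flat`) is available for
sensitivity checks.

## Sampling

A Gibbs sampler tailored to the model's conditional structure:

1. **States | variances** — forward-filter backward-sampler (FFBS): one
   exact joint draw of the whole path per sweep.  No tuning parameters,
   no rejections; all chains are advanced simultaneously with batched
   linear algebra.
2. **Variances | states** — univariate slice sampling of each log-SD
   (stepping-out + shrinkage, width 1, hard bounds 10⁻⁶…10⁴ days).
3. **Interweaving** — after the centered update, each process SD is
   redrawn in the non-centered parameterization (path expressed as
   initial value plus SD times standardized increments), where its
   conditional is Gaussian, and the path is rebuilt.  Without this move
   the process SDs mix very slowly when long stretches are unobserved
   (ESS ≈ 20 per 8 000 sweeps); with it, ESS improves by roughly an order
   of magnitude.

Defaults: 4 chains, 5 000 sweeps, burn-in 1 000, thin 2 → 2 000 retained
draws per chain.  These are scaled-down working settings chosen so a
century-long fit takes tens of seconds; the config file accepts arbitrary
larger values.  Split-R̂ and bulk ESS (via ArviZ) are computed for every
SD parameter and a spread of `alpha_t` years; R̂ ≥ 1.05 raises a warning
and clears the `converged` flag rather than failing, since a user may
legitimately want short exploratory runs.

The per-draw identity `alpha_t = c_t'x_t` holds exactly by construction,
and with variances held fixed the sampler reduces to exact iid joint
draws — the basis of the equivalence tests against the Kalman smoother
and against a dense joint-Gaussian conditioning oracle.

## Summaries

Per-year medians and central 95% intervals use linear-interpolation
(type-7) empirical quantiles over all chains pooled.  Because a published
"average coefficient" table can mean two things, the summary reports
both: the median/SD **pooled** over years × draws, and the median/SD of
**per-draw time averages**.  The two agree closely when coefficient paths
are nearly constant and diverge when they drift.

## Observation handling

Observation tables keep every (year, phenophase, source) row; conflicts
within a year are resolved only at fitting time by a configurable source
precedence, by default `website > municipal > private > literature >
photograph` (website feeds are the primary record; the rest are
recovered validation material).  Unlisted sources rank last and
tie-break alphabetically, so resolution is deterministic.  An
observation-mask config can withhold year ranges from fitting — e.g. an
era when the tree itself was in poor health and its record reflects
biology, not climate — without deleting the data.

## Synthetic data

The generator draws yearly predictors from a warming climatology
(interannual Gaussians around a linear trend referenced to 2006), evolves
per-phenophase coefficient random walks, and emits integer-DOY
observations from the configured first-recorded year onward.  The default
study config encodes the study conditions the package is designed around:

* years 1924–2024; observations from 1989 (FFL/FFB/LFB) and 2002 (LFL),
  every year once recording starts;
* coefficient magnitudes `beta ≈ −3.1, gamma ≈ −3.75` days/°C (FFL), with
  intercepts set so simulated phase means land on the observed summaries
  (FFL ≈ DOY 92 with SD ≈ 6, …, LFL ≈ 106);
* winter-minimum / March / early-April climatologies of 2.0 / 7.15 /
  13.0 °C warming at 0.25–0.28 °C/decade, which through the negative
  coefficients implies an FFL advance of roughly 1.9 days/decade;
* small process SDs (0.1 day/yr intercept, 0.02 day/°C/yr slopes) — the
  coefficient paths are nearly constant across the century — and
  observation noise of 2 days.

What it deliberately does **not** emulate: calendar-date observation
semantics (observations are rounded DOY), heteroscedastic or biased
historical sources, correlated predictor errors between stations (the
two-station helper applies a clean additive offset), and any biological
feedback such as vigor loss.  Passing recovery tests on this generator
therefore demonstrates correctness of the inference machinery under the
model's own assumptions, not robustness to real-data pathologies.

An optional daily mode generates a plausible daily temperature series
whose window means reproduce the yearly targets exactly, then derives
predictors through the full ingestion path (CSV → reader → window means),
so the whole pipeline is exercised rather than bypassed.

## Numerical choices

* Covariances are symmetrized after every filter update; backward-sampling
  covariances get an escalating jitter (from 10⁻¹²) before Cholesky if
  needed.
* SDs are floored at 10⁻⁶ days: in exactly-degenerate data (zero noise)
  the SD posterior collapses toward zero and the floor keeps the
  arithmetic finite without visibly affecting any estimate.
* Kalman/oracle agreement is asserted to 10⁻⁵ absolute — the dense
  conditioning route inverts matrices containing the diffuse-prior
  variance 10⁴, which limits agreement to float round-off well above
  machine epsilon.
* Temperatures are written to 0.1 °C (station-export convention) but
  carried at full precision internally.

## Validation design

The test suite checks the machinery at three levels: unit oracles
(brute-force window means, dense joint-Gaussian conditioning, closed-form
OLS), property tests (shift invariance, interval ordering, round trips,
seed determinism), and replicate recovery studies at reduced MCMC scale
(4 chains × 1 000 retained for the 20-replicate study; a 10-year
fixed-variance model at 4 × 2 000 for the exact-inference check).  These
sizes are the package's chosen working scale: large enough for stable
Monte-Carlo comparisons, small enough to run routinely.

A known property of the default study conditions: with nearly constant
generating coefficient paths and only 36 observed years, the variance
posteriors sit above the tiny generating SDs (the data cannot rule out
moderate drift), so credible intervals over the unobserved era are
conservative — empirical coverage of the true dates approaches 100%
rather than the nominal 95%.  The intervals err on the side of width,
never overconfidence; point-estimate accuracy is unaffected (RMSE at
observed years ≈ 1 day against 2-day observation noise).

## Limitations

* Linear temperature response with Gaussian drift; no degree-day or
  chilling-unit accumulation mechanism, by design.
* One value per (year, phenophase) reaches the likelihood; conflicting
  sources are resolved by precedence, not jointly modelled with
  per-source error variances.
* Trend regression treats posterior medians as data points
  (`fit_trend`); the draw-wise slope distribution (`trend_over_draws`)
  is provided as an extension for uncertainty-aware trends.
* Phenophases are fitted independently; ordering constraints
  (FFL ≤ FFB ≤ LFB ≤ LFL) are not enforced.
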