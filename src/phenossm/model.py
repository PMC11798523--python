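"""Time-varying-coefficient state-space models for flowering dates.

Two linear-Gaussian model forms, one per pair of phenophases:

* first flowering / first full bloom (FFL, FFB) — the latent true date is
  ``alpha_t = mu_t + beta_t * ex1_t + gamma_t * ex2_t``;
* last full bloom / last flowering (LFB, LFL) —
  ``alpha_t = mu_t + beta_t * ex3_t``.

The intercept and each regression coefficient evolve as independent
Gaussian random walks (process SDs ``sigma_omega``, ``sigma_tau`` and,
in the first form, ``sigma_upsilon``), and the observed date is the true
date plus Gaussian noise with SD ``sigma_phi``.  Years without a record
keep their state equations — the walk propagates, the observation
equation is skipped — which is what lets a model fitted to recent records
extrapolate a full century with honestly widening credible intervals.

:func:`kalman_smoother` gives exact Gaussian marginals at fixed variances
and doubles as an internal oracle for the MCMC sampler in
:mod:`phenossm.sampler`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    DEFAULT_SOURCE_PRECEDENCE,
    PHENOPHASES,
    ObservationTable,
    select_observations,
)

__all__ = [
    "PriorConfig",
    "VarianceParams",
    "ModelSpec",
    "LatentStatePath",
    "StateSummary",
    "SmootherResult",
    "build_model",
    "kalman_smoother",
    "summarize_posterior",
]

logger = logging.getLogger(__name__)

_TWO_PREDICTOR_PHASES = ("FFL", "FFB")  # use (ex1, ex2); LFB/LFL use ex3 only


@dataclass(frozen=True)
class PriorConfig:
    """Priors for the initial states and the variance parameters.

    The initial intercept/coefficients get a diffuse Normal(0, init_sd^2)
    prior — a proper stand-in for a flat prior.  Each process/observation
    SD gets a half-normal(scale ``sigma_scale``) prior by default;
    ``sigma_prior="flat"`` uses an improper flat-on-positive prior
    instead.
    """

    init_sd: float = 100.0
    sigma_prior: str = "halfnormal"
    sigma_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.init_sd <= 0:
            raise ValueError("init_sd must be positive")
        if self.sigma_prior not in ("halfnormal", "flat"):
            raise ValueError(f"unknown sigma_prior {self.sigma_prior!r}")
        if self.sigma_scale <= 0:
            raise ValueError("sigma_scale must be positive")


@dataclass(frozen=True)
class VarianceParams:
    """SDs of the random-walk process errors and the observation error.

    ``sigma_upsilon`` (the gamma walk) exists only for the two-predictor
    FFL/FFB form and is ``None`` otherwise.  All units are days (per year
    of walk for the process SDs).
    """

    sigma_omega: float
    sigma_tau: float
    sigma_phi: float
    sigma_upsilon: float | None = None

    def __post_init__(self) -> None:
        for name in ("sigma_omega", "sigma_tau", "sigma_phi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sigma_upsilon is not None and self.sigma_upsilon < 0:
            raise ValueError("sigma_upsilon must be non-negative")

    def process_sds(self, n_coefs: int) -> np.ndarray:
        if not 1 <= n_coefs <= 3:
            raise ValueError("n_coefs must be 1, 2 or 3")
        if n_coefs == 3 and self.sigma_upsilon is None:
            raise ValueError("sigma_upsilon required for the two-predictor form")
        sds = [self.sigma_omega, self.sigma_tau, self.sigma_upsilon]
        return np.asarray(sds[:n_coefs], dtype=float)


@dataclass(frozen=True)
class ModelSpec:
    """A fully assembled model: years, design matrix, observations, priors.

    ``design`` has one row per year: columns (1, ex1, ex2) for FFL/FFB or
    (1, ex3) for LFB/LFL.  ``y`` holds the per-year observed DOY with NaN
    for unobserved years.
    """

    phenophase: str
    years: np.ndarray = field(repr=False)
    design: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    prior: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self) -> None:
        if self.phenophase not in PHENOPHASES:
            raise ValueError(f"unknown phenophase {self.phenophase!r}")
        if len(self.years) != len(self.y) or self.design.shape[0] != len(self.years):
            raise ValueError("years, design and y must have equal length")
        if not np.all(np.diff(self.years) == 1):
            raise ValueError("modelled years must be contiguous")
        if np.isnan(self.design).any():
            raise ValueError("design matrix must not contain missing predictors")
        if self.n_observed == 0:
            raise ValueError("model needs at least one observed year")

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_coefs(self) -> int:
        return self.design.shape[1]

    @property
    def coef_names(self) -> tuple:
        return ("mu", "beta", "gamma")[: self.n_coefs]

    @property
    def sigma_names(self) -> tuple:
        names = ["sigma_omega", "sigma_tau", "sigma_upsilon"][: self.n_coefs]
        return tuple(names + ["sigma_phi"])

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.y)

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum())


@dataclass(frozen=True)
class LatentStatePath:
    """Per-year latent values, e.g. the generating truth of a simulation.

    ``frame`` columns: year, mu, beta, gamma (NaN for the one-predictor
    form), alpha.
    """

    phenophase: str
    frame: pd.DataFrame = field(repr=False)


@dataclass(frozen=True)
class StateSummary:
    """Posterior summaries of a fitted model.

    ``per_year``: one row per (year, quantity in alpha/mu/beta/gamma) with
    the posterior median and central 95% credible interval.
    ``coefficients``: for each coefficient path, the median/SD pooled over
    years and draws (``pooled_*``) and the median/SD over per-draw
    time-averages (``time_avg_*``) — two defensible readings of a single
    "average coefficient" table.
    ``sigmas``: posterior median and 95% interval of each SD parameter.
    """

    phenophase: str
    per_year: pd.DataFrame = field(repr=False)
    coefficients: pd.DataFrame = field(repr=False)
    sigmas: pd.DataFrame = field(repr=False)

    def quantity(self, name: str) -> pd.DataFrame:
        """Rows of ``per_year`` for one quantity, indexed by year."""
        sub = self.per_year[self.per_year["quantity"] == name]
        if sub.empty:
            raise KeyError(f"no quantity {name!r} in summary")
        return sub.set_index("year")


def build_model(
    phenophase: str,
    predictors: pd.DataFrame,
    observations: ObservationTable,
    prior_config: PriorConfig | None = None,
    precedence=DEFAULT_SOURCE_PRECEDENCE,
    observation_mask=None,
) -> ModelSpec:
    """Assemble a :class:`ModelSpec` for one phenophase.

    The model spans the longest contiguous run of years whose required
    predictors are all present (excluded years are logged).  Observations
    are resolved to one value per year by source precedence; records
    outside predictor coverage are dropped with a warning.
    ``observation_mask`` is an optional list of inclusive ``(first, last)``
    year ranges whose observations are withheld from fitting — e.g. to
    exclude an era when the tree itself was unhealthy and its records are
    not representative of a climate signal.
    """
    if phenophase not in PHENOPHASES:
        raise ValueError(f"unknown phenophase {phenophase!r}")
    needed = ["ex1", "ex2"] if phenophase in _TWO_PREDICTOR_PHASES else ["ex3"]
    pred = predictors.dropna(subset=needed).sort_values("year")
    if pred.empty:
        raise ValueError(f"no years with complete predictors {needed} for {phenophase}")
    years = _longest_contiguous(pred["year"].to_numpy(dtype=int))
    dropped = sorted(set(pred["year"].astype(int)) - set(years))
    if dropped:
        logger.warning(
            "%s: %d year(s) with predictors outside the contiguous modelled run "
            "%d-%d were excluded: %s",
            phenophase, len(dropped), years[0], years[-1], dropped,
        )
    pred = pred.set_index("year").loc[years]

    obs = select_observations(observations, phenophase, precedence=precedence)
    if observation_mask:
        for first, last in observation_mask:
            obs = obs[(obs.index < first) | (obs.index > last)]
    outside = obs.index[(obs.index < years[0]) | (obs.index > years[-1])]
    if len(outside):
        logger.warning(
            "%s: dropping %d observation(s) outside predictor coverage %d-%d: %s",
            phenophase, len(outside), years[0], years[-1], list(outside),
        )
        obs = obs.drop(outside)
    if obs.empty:
        raise ValueError(f"no usable observations for {phenophase}")

    y = np.full(len(years), np.nan)
    y[np.searchsorted(years, obs.index.to_numpy())] = obs.to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(years))] + [pred[c].to_numpy(dtype=float) for c in needed])
    return ModelSpec(
        phenophase=phenophase,
        years=years,
        design=design,
        y=y,
        prior=prior_config or PriorConfig(),
    )


@dataclass(frozen=True)
class SmootherResult:
    """Exact Gaussian marginals from the Kalman smoother at fixed variances."""

    years: np.ndarray
    coef_names: tuple
    state_mean: np.ndarray  # (T, k) smoothed means of (mu, beta[, gamma])
    state_cov: np.ndarray  # (T, k, k) smoothed covariances
    alpha_mean: np.ndarray  # (T,)
    alpha_sd: np.ndarray  # (T,)


def kalman_smoother(
    spec: ModelSpec,
    variances: VarianceParams,
    initial_sd: float | None = None,
) -> SmootherResult:
    """Exact filtered-then-smoothed Gaussian marginals at fixed variances.

    Runs a standard Kalman filter (identity transition, diagonal process
    covariance from ``variances``, scalar observation ``y_t = c_t'x_t +
    noise``) followed by a Rauch-Tung-Striebel smoother.  Missing years are
    prediction-only steps.  The derived true date ``alpha_t = c_t'x_t``
    gets mean ``c_t'm_t`` and SD ``sqrt(c_t'V_t c_t)``.
    """
    T, k = spec.design.shape
    q = variances.process_sds(k) ** 2
    r = float(variances.sigma_phi) ** 2
    if np.any(q < 0) or r < 0:
        raise ValueError("variances must be non-negative")
    init_sd = float(initial_sd if initial_sd is not None else spec.prior.init_sd)
    Q = np.diag(q)
    obs = spec.observed_mask

    m = np.zeros(k)
    P = np.eye(k) * init_sd**2
    filt_m = np.empty((T, k))
    filt_P = np.empty((T, k, k))
    pred_P = np.empty((T, k, k))  # P_{t|t-1}, needed by the smoother
    for t in range(T):
        if t > 0:
            P = P + Q
        pred_P[t] = P
        if obs[t]:
            c = spec.design[t]
            S = c @ P @ c + r
            if S <= 0:
                raise np.linalg.LinAlgError(
                    f"non-positive innovation variance at year {spec.years[t]}"
                )
            K = (P @ c) / S
            m = m + K * (spec.y[t] - c @ m)
            P = P - np.outer(K, c @ P)
            P = 0.5 * (P + P.T)
        filt_m[t] = m
        filt_P[t] = P

    sm_m = np.empty((T, k))
    sm_P = np.empty((T, k, k))
    sm_m[-1] = filt_m[-1]
    sm_P[-1] = filt_P[-1]
    for t in range(T - 2, -1, -1):
        G = np.linalg.solve(pred_P[t + 1].T, filt_P[t].T).T  # filt_P @ inv(pred_P[t+1])
        sm_m[t] = filt_m[t] + G @ (sm_m[t + 1] - filt_m[t])
        sm_P[t] = filt_P[t] + G @ (sm_P[t + 1] - pred_P[t + 1]) @ G.T
        sm_P[t] = 0.5 * (sm_P[t] + sm_P[t].T)
        if np.any(np.diag(sm_P[t]) < -1e-8):
            raise np.linalg.LinAlgError(
                f"non-positive-definite smoothed covariance at year {spec.years[t]}"
            )

    alpha_mean = np.einsum("tk,tk->t", spec.design, sm_m)
    alpha_var = np.einsum("tk,tkl,tl->t", spec.design, sm_P, spec.design)
    return SmootherResult(
        years=spec.years,
        coef_names=spec.coef_names,
        state_mean=sm_m,
        state_cov=sm_P,
        alpha_mean=alpha_mean,
        alpha_sd=np.sqrt(np.maximum(alpha_var, 0.0)),
    )


def summarize_posterior(draws, interval: float = 0.95) -> StateSummary:
    """Per-year medians and central credible intervals from retained draws.

    Quantiles use linear interpolation (numpy's default, the classical
    type-7 rule).  All chains are pooled.
    """
    if draws.alpha.size == 0:
        raise ValueError("no retained draws to summarize")
    lo_q, hi_q = (1 - interval) / 2, 1 - (1 - interval) / 2
    years = np.asarray(draws.years)

    def _rows(name: str, samples: np.ndarray) -> pd.DataFrame:
        # samples: (chains, draws, T) -> pooled quantiles per year
        flat = samples.reshape(-1, samples.shape[-1])
        return pd.DataFrame(
            {
                "year": years,
                "quantity": name,
                "median": np.median(flat, axis=0),
                "lo95": np.quantile(flat, lo_q, axis=0),
                "hi95": np.quantile(flat, hi_q, axis=0),
            }
        )

    per_year = [_rows("alpha", draws.alpha)]
    for j, name in enumerate(draws.coef_names):
        per_year.append(_rows(name, draws.states[:, :, :, j]))

    coef_rows = []
    for j, name in enumerate(draws.coef_names):
        path = draws.states[:, :, :, j]
        pooled = path.ravel()
        time_avg = path.mean(axis=2).ravel()  # one average per draw
        coef_rows.append(
            {
                "quantity": name,
                "pooled_median": float(np.median(pooled)),
                "pooled_sd": float(np.std(pooled, ddof=1)),
                "time_avg_median": float(np.median(time_avg)),
                "time_avg_sd": float(np.std(time_avg, ddof=1)),
            }
        )

    sig_rows = []
    for j, name in enumerate(draws.sigma_names):
        s = draws.sigmas[:, :, j].ravel()
        sig_rows.append(
            {
                "parameter": name,
                "median": float(np.median(s)),
                "lo95": float(np.quantile(s, lo_q)),
                "hi95": float(np.quantile(s, hi_q)),
            }
        )

    return StateSummary(
        phenophase=draws.phenophase,
        per_year=pd.concat(per_year, ignore_index=True),
        coefficients=pd.DataFrame(coef_rows),
        sigmas=pd.DataFrame(sig_rows),
    )


def _longest_contiguous(years: np.ndarray) -> np.ndarray:
    years = np.unique(years)
    breaks = np.flatnonzero(np.diff(years) != 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(years) - 1]])
    lengths = ends - starts + 1
    best = int(np.argmax(lengths))  # ties -> earliest run
    return years[starts[best] : ends[best] + 1]
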