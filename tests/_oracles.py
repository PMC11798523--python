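"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own recursions: the state-space
checks build the full joint Gaussian over all states and condition on the
observed years with dense linear algebra, and the predictor checks
enumerate window dates one by one.
"""

import numpy as np


def joint_gaussian_posterior(spec, variances, init_sd=None):
    """Exact posterior of all states by dense multivariate-normal conditioning.

    Stacks z = (x_1, ..., x_T) (each x_t of dim k), builds the prior
    covariance implied by the diffuse start and the random walks
    (coordinates independent, Cov(x_t_j, x_s_j) = init_sd^2 +
    q_j * (min(t, s) - 1)), and conditions on y = H z + noise.

    Returns (mean, cov) over the stacked state vector plus derived
    (alpha_mean, alpha_sd).
    """
    T, k = spec.design.shape
    q = variances.process_sds(k) ** 2
    r = float(variances.sigma_phi) ** 2
    s0 = float(init_sd if init_sd is not None else spec.prior.init_sd) ** 2

    n = T * k
    Sigma = np.zeros((n, n))
    for j in range(k):
        idx = np.arange(T) * k + j
        tt = np.arange(1, T + 1)
        Sigma[np.ix_(idx, idx)] = s0 + q[j] * (np.minimum.outer(tt, tt) - 1)

    obs_t = np.flatnonzero(spec.observed_mask)
    H = np.zeros((len(obs_t), n))
    for row, t in enumerate(obs_t):
        H[row, t * k : (t + 1) * k] = spec.design[t]
    y = spec.y[obs_t]

    S = H @ Sigma @ H.T + r * np.eye(len(obs_t))
    K = Sigma @ H.T @ np.linalg.inv(S)
    mean = K @ y
    cov = Sigma - K @ H @ Sigma

    A = np.zeros((T, n))
    for t in range(T):
        A[t, t * k : (t + 1) * k] = spec.design[t]
    alpha_mean = A @ mean
    alpha_sd = np.sqrt(np.einsum("tn,nm,tm->t", A, cov, A))
    return mean.reshape(T, k), cov, alpha_mean, alpha_sd


def brute_force_window_mean(series_frame, dates, field):
    """Arithmetic mean over explicitly enumerated dates, ignoring missing."""
    by_date = series_frame.set_index("date")[field]
    vals = [by_date.get(d, np.nan) for d in dates]
    vals = [v for v in vals if not np.isnan(v)]
    return float(np.mean(vals)) if vals else np.nan


def ols_normal_equations(x, y):
    """Closed-form OLS slope/intercept/R^2 from the normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    coef = np.linalg.solve(X.T @ X, X.T @ y)
    fitted = X @ coef
    ss_res = np.sum((y - fitted) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return coef[1], coef[0], r2
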