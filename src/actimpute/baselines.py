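"""Classical imputation baselines: per-minute mean imputation and multiple
imputation by chained equations (MICE) with either a zero-inflated Poisson
(ZIP) or a Bayesian linear regressor.

The ZIP model is the standard two-part mixture for activity counts:

    P(Y = 0 | x)     = pi(x) + (1 - pi(x)) * exp(-lam(x))
    P(Y = y > 0 | x) = (1 - pi(x)) * Poisson(y; lam(x))

with logit pi = x . gamma and log lam = x . beta, fitted by direct maximum
likelihood (L-BFGS with the analytic gradient).  The Bayesian regressor is a
conjugate normal-inverse-gamma linear model whose posterior predictive is
sampled with a seed; negative draws are clamped to zero since counts are
nonnegative.

The chained-equations pass follows the usual recipe: initialise every masked
cell with the per-minute mean, then cycle over minute positions, regressing
each position on its neighbouring lead/lag minutes across records and
re-filling the masked cells from the fitted regressor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import optimize, special

from .records import ActivityRecord, MissingMask, RecordSet


# ---------------------------------------------------------------------------
# Mean imputation
# ---------------------------------------------------------------------------

@dataclass
class MeanModel:
    """Per-minute mean of valid (unmasked) data across training records."""

    per_minute_mean: np.ndarray

    def __post_init__(self) -> None:
        self.per_minute_mean = np.asarray(self.per_minute_mean, dtype=float)
        if not np.all(np.isfinite(self.per_minute_mean)):
            raise ValueError("per-minute means must be finite")
        if np.any(self.per_minute_mean < 0):
            raise ValueError("per-minute means must be nonnegative")


def fit_mean_model(train: RecordSet) -> MeanModel:
    """Column means over unmasked cells; errors if a column has no valid cell."""
    if len(train) == 0:
        raise ValueError("need at least one training record")
    x = train.values_matrix()
    if train.masks is not None:
        valid = ~train.mask_matrix()
    else:
        valid = np.ones_like(x, dtype=bool)
    counts = valid.sum(axis=0)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(f"no valid data at position(s) {empty.tolist()[:5]}")
    sums = np.where(valid, x, 0.0).sum(axis=0)
    return MeanModel(sums / counts)


def mean_impute(model: MeanModel, record: ActivityRecord, mask: MissingMask) -> ActivityRecord:
    """Replace masked positions with the model's per-minute means."""
    if len(record) != len(mask) or len(record) != model.per_minute_mean.size:
        raise ValueError("record, mask and model lengths must agree")
    values = record.values.copy()
    values[mask.flags] = model.per_minute_mean[mask.flags]
    return dc_replace(record, values=values)


# ---------------------------------------------------------------------------
# Zero-inflated Poisson regression
# ---------------------------------------------------------------------------

@dataclass
class ZipParams:
    gamma: np.ndarray   # zero-component logit coefficients
    beta: np.ndarray    # count-component log-link coefficients
    converged: bool


def _zip_negloglik_and_grad(theta, X, y, p):
    gamma, beta = theta[:p], theta[p:]
    eta_pi = X @ gamma
    eta_lam = np.clip(X @ beta, -30.0, 30.0)
    lam = np.exp(eta_lam)
    zero = y == 0
    # stable pieces: log pi = eta - log(1+e^eta); log(1-pi) = -log(1+e^eta)
    log1pe = np.logaddexp(0.0, eta_pi)
    # y == 0: log( e^{eta_pi} + e^{-lam} ) - log(1+e^{eta_pi})
    log_num0 = np.logaddexp(eta_pi[zero], -lam[zero])
    ll_zero = log_num0 - log1pe[zero]
    # y > 0: -log(1+e^eta) - lam + y*log lam - log y!
    yp = y[~zero]
    ll_pos = -log1pe[~zero] - lam[~zero] + yp * eta_lam[~zero] - special.gammaln(yp + 1.0)
    nll = -(ll_zero.sum() + ll_pos.sum())

    # gradient
    sig = special.expit(eta_pi)
    dg = np.empty_like(eta_pi)
    db = np.empty_like(eta_pi)
    # zero rows: w = e^{eta}/(e^{eta}+e^{-lam})
    w = special.expit(eta_pi[zero] + lam[zero])
    dg[zero] = w - sig[zero]
    db[zero] = -(1.0 - w) * lam[zero]
    dg[~zero] = -sig[~zero]
    db[~zero] = yp - lam[~zero]
    grad = -np.concatenate([X.T @ dg, X.T @ db])
    return nll, grad


def _poisson_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Plain Poisson regression MLE (used as the non-convergence fallback)."""

    def nll_grad(beta):
        eta = np.clip(X @ beta, -30.0, 30.0)
        lam = np.exp(eta)
        nll = float(np.sum(lam - y * eta + special.gammaln(y + 1.0)))
        return nll, X.T @ (lam - y)

    beta0 = np.zeros(X.shape[1])
    beta0[0] = math.log(max(y.mean(), 1e-8))
    res = optimize.minimize(nll_grad, beta0, jac=True, method="L-BFGS-B")
    return res.x


def fit_zip_regression(
    design: np.ndarray, response: np.ndarray, theta0: np.ndarray | None = None
) -> ZipParams:
    """Maximum-likelihood ZIP fit; falls back to plain Poisson on failure.

    ``design`` must include its own intercept column.  ``theta0`` optionally
    warm-starts the optimizer with [gamma, beta] stacked.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design and response are not aligned")
    y = np.round(np.maximum(y, 0.0))
    p = X.shape[1]

    if np.all(y == 0):
        # degenerate likelihood: zero probability -> 1
        gamma = np.zeros(p)
        gamma[0] = 25.0
        beta = np.zeros(p)
        beta[0] = -25.0
        return ZipParams(gamma, beta, converged=True)

    if theta0 is not None and theta0.size == 2 * p and np.all(np.isfinite(theta0)):
        theta0 = np.asarray(theta0, dtype=float)
    else:
        beta0 = np.zeros(p)
        beta0[0] = math.log(max(y[y > 0].mean(), 1e-8))
        gamma0 = np.zeros(p)
        frac_zero = float(np.mean(y == 0))
        gamma0[0] = special.logit(np.clip(frac_zero, 1e-6, 1 - 1e-6))
        theta0 = np.concatenate([gamma0, beta0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            _zip_negloglik_and_grad,
            theta0,
            args=(X, y, p),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 200},
        )
    if res.success and np.all(np.isfinite(res.x)):
        return ZipParams(res.x[:p], res.x[p:], converged=True)
    beta = _poisson_fit(X, y)
    gamma = np.full(p, 0.0)
    gamma[0] = -25.0  # pi ~ 0: fallback is a plain Poisson model
    return ZipParams(gamma, beta, converged=False)


def zip_zero_prob(params: ZipParams, design: np.ndarray) -> np.ndarray:
    """Structural-zero probability pi(x)."""
    return special.expit(np.asarray(design, float) @ params.gamma)


def zip_predict(params: ZipParams, design: np.ndarray) -> np.ndarray:
    """Expected count (1 - pi) * lam; the point value used to fill a cell."""
    X = np.asarray(design, dtype=float)
    pi = special.expit(X @ params.gamma)
    lam = np.exp(np.clip(X @ params.beta, -30.0, 30.0))
    return (1.0 - pi) * lam


# ---------------------------------------------------------------------------
# Bayesian linear regression (conjugate normal-inverse-gamma)
# ---------------------------------------------------------------------------

@dataclass
class BayesLinearPosterior:
    """Posterior over (coefficients, noise variance) of a linear model.

    coef | sigma2 ~ N(mean, sigma2 * cov_scale);  sigma2 ~ InvGamma(a, b).
    """

    mean: np.ndarray
    cov_scale: np.ndarray
    a: float
    b: float

    def sample_predictive(self, design: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        X = np.atleast_2d(np.asarray(design, dtype=float))
        sigma2 = self.b / rng.gamma(self.a) if self.b > 0 else 0.0
        if sigma2 > 0:
            chol = np.linalg.cholesky(self.cov_scale + 1e-12 * np.eye(self.mean.size))
            coef = self.mean + math.sqrt(sigma2) * (chol @ rng.standard_normal(self.mean.size))
            return X @ coef + math.sqrt(sigma2) * rng.standard_normal(X.shape[0])
        return X @ self.mean


def fit_bayes_linear(
    design: np.ndarray,
    response: np.ndarray,
    prior_precision: float = 1e-6,
    a0: float = 1e-3,
    b0: float = 1e-3,
) -> BayesLinearPosterior:
    """Conjugate fit with a weakly-informative zero-mean prior.

    ``prior_precision`` doubles as a ridge term, keeping the posterior proper
    for singular designs.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design and response are not aligned")
    n, p = X.shape
    lam0 = prior_precision * np.eye(p)
    precision = X.T @ X + lam0
    # bump the ridge until the system is solvable
    ridge = prior_precision
    while True:
        try:
            cov = np.linalg.inv(precision)
            break
        except np.linalg.LinAlgError:
            ridge *= 100.0
            precision = X.T @ X + ridge * np.eye(p)
    mean = cov @ (X.T @ y)
    a = a0 + 0.5 * n
    b = b0 + 0.5 * float(y @ y - mean @ precision @ mean)
    b = max(b, 0.0)
    return BayesLinearPosterior(mean=mean, cov_scale=cov, a=a, b=b)


# ---------------------------------------------------------------------------
# MICE
# ---------------------------------------------------------------------------

@dataclass
class MiceConfig:
    regressor: str = "zip"      # "zip" or "bayes"
    n_lead: int = 5
    n_lag: int = 5
    n_cycles: int = 5
    n_imputations: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.regressor not in ("zip", "bayes"):
            raise ValueError("regressor must be 'zip' or 'bayes'")
        if self.n_lead < 1 or self.n_lag < 1:
            raise ValueError("n_lead and n_lag must be >= 1")
        if self.n_cycles < 0 or self.n_imputations < 1:
            raise ValueError("n_cycles >= 0 and n_imputations >= 1 required")


def _covariate_columns(t: int, n_cols: int, n_lead: int, n_lag: int) -> np.ndarray:
    lead = np.arange(max(0, t - n_lead), t)
    lag = np.arange(t + 1, min(n_cols, t + 1 + n_lag))
    return np.concatenate([lead, lag])


def _mice_single(
    data: np.ndarray,
    flags: np.ndarray,
    config: MiceConfig,
    init: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One completed dataset from one chained-equations pass.

    Covariates are standardized per position before fitting (the log link of
    the ZIP model is badly conditioned on raw thousand-count scales), and ZIP
    point predictions are capped at the largest observed response for that
    position so the exponential link cannot extrapolate beyond the data.
    """
    completed = data.copy()
    completed[flags] = init[flags]
    n_rows, n_cols = data.shape
    positions = np.flatnonzero(flags.any(axis=0))
    warm: dict[int, np.ndarray] = {}
    for _ in range(config.n_cycles):
        for t in positions:
            cols = _covariate_columns(t, n_cols, config.n_lead, config.n_lag)
            masked = flags[:, t]
            obs = ~masked
            raw = completed[:, cols]
            center = raw[obs].mean(axis=0)
            spread = raw[obs].std(axis=0)
            spread[spread == 0] = 1.0
            X = np.column_stack([np.ones(n_rows), (raw - center) / spread])
            if config.regressor == "zip":
                params = fit_zip_regression(X[obs], completed[obs, t], theta0=warm.get(t))
                warm[t] = np.concatenate([params.gamma, params.beta])
                cap = completed[obs, t].max()
                completed[masked, t] = np.minimum(zip_predict(params, X[masked]), cap)
            else:
                post = fit_bayes_linear(X[obs], completed[obs, t])
                draws = post.sample_predictive(X[masked], rng)
                completed[masked, t] = np.maximum(draws, 0.0)
    return completed


def mice_impute(record_set: RecordSet, config: MiceConfig) -> RecordSet:
    """Chained-equations multiple imputation combined by the per-cell mean.

    The masked cells are initialised with per-minute means (the mean-imputation
    model built from this dataset's unmasked cells), then each of
    ``n_imputations`` chains runs ``n_cycles`` sweeps over the positions that
    contain masked cells.  With the ZIP regressor each chain produces the same
    deterministic point predictions, so a single chain is computed and reused.
    """
    if record_set.masks is None:
        raise ValueError("MICE requires masks")
    if len(record_set) < 2:
        raise ValueError("MICE requires at least two records")
    data = record_set.values_matrix()
    flags = record_set.mask_matrix()
    if not flags.any():
        return RecordSet(
            [dc_replace(r, values=r.values.copy()) for r in record_set.records],
            record_set.masks,
            record_set.split_labels,
        )
    fully_masked = np.flatnonzero(flags.all(axis=0))
    if fully_masked.size:
        raise ValueError(
            f"position(s) {fully_masked.tolist()[:5]} are masked in every record"
        )
    mean_model = fit_mean_model(record_set)
    init = np.broadcast_to(mean_model.per_minute_mean, data.shape)

    root = np.random.default_rng(config.rng_seed)
    n_chains = 1 if config.regressor == "zip" else config.n_imputations
    completed_sum = np.zeros_like(data)
    for _ in range(n_chains):
        rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        completed_sum += _mice_single(data, flags, config, init, rng)
    combined = completed_sum / n_chains
    # unmasked cells stay bit-identical to the input
    combined[~flags] = data[~flags]

    records = [
        dc_replace(rec, values=combined[i]) for i, rec in enumerate(record_set.records)
    ]
    return RecordSet(records, record_set.masks, record_set.split_labels)
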