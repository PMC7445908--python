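"""Intrinsic-estimator fit of the Poisson log-linear APC model.

The model for cell (i, j) on cohort diagonal k is

    D_ijk ~ Poisson(N_ijk * exp(mu + alpha_i + beta_j + gamma_k)),

with each effect block constrained to sum to zero.  Effect coding
enforces the sum-to-zero constraints but leaves one direction — the
null vector b0 of the design — undetermined.  The intrinsic estimator
(IE) picks the unique maximiser of the Poisson likelihood that is
orthogonal to b0, equivalently the minimum-norm solution among all
coefficient vectors giving the same fitted rates.

Fitting reparametrises theta = V w, with V an orthonormal basis of the
orthogonal complement of b0, and runs iteratively reweighted least
squares (IRLS) on the full-rank design X V with offset ln N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.special import gammaln, xlogy

from .design import DesignSpec, build_design, null_vector
from .errors import ConvergenceError, ValidationError
from .lexis import AGE_WIDTH, RateTable, cohort_layout

MAX_ITER = 100
DEVIANCE_RTOL = 1e-10


def deviance(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Poisson deviance 2 * sum[ D ln(D / Dhat) - (D - Dhat) ].

    A zero-count cell contributes 2 * Dhat (the D ln D term vanishes).
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.shape != fitted.shape:
        raise ValidationError("observed and fitted must have equal length")
    if np.any(observed < 0):
        raise ValidationError("observed counts must be nonnegative")
    if np.any(fitted <= 0):
        raise ValidationError("fitted means must be positive")
    return float(2.0 * np.sum(xlogy(observed, observed / fitted) - (observed - fitted)))


def poisson_log_likelihood(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Full Poisson log likelihood sum[ D ln(mu) - mu - ln(D!) ]."""
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    return float(np.sum(xlogy(observed, fitted) - fitted - gammaln(observed + 1.0)))


def information_criteria(
    deviance_value: float, log_lik: float, n_obs: int, model_rank: int
) -> tuple[float, float]:
    """Per-observation AIC and the deviance-based BIC.

    BIC follows the convention ``deviance - (n_obs - model_rank) * ln(n_obs)``
    (residual degrees of freedom times log sample size subtracted from
    the deviance).  AIC is reported per observation,
    ``(-2 lnL + 2 k) / n_obs`` with ``k = model_rank + 1``.
    """
    if n_obs <= model_rank:
        raise ValidationError(
            f"need more observations ({n_obs}) than estimable directions ({model_rank})"
        )
    bic = deviance_value - (n_obs - model_rank) * np.log(n_obs)
    aic_per_obs = (-2.0 * log_lik + 2.0 * (model_rank + 1)) / n_obs
    return float(aic_per_obs), float(bic)


@dataclass
class APCFit:
    """Result of an intrinsic-estimator fit.

    Effects are on the log-rate scale; each block sums to zero.  ``theta``
    is the constrained coefficient vector in effect coding (intercept
    first), orthogonal to ``b0_used``.  No standard errors are computed.
    """

    intercept: float
    age_effects: np.ndarray
    period_effects: np.ndarray
    cohort_effects: np.ndarray
    age_labels: tuple[str, ...]
    period_labels: tuple[str, ...]
    cohort_labels: tuple[str, ...]
    fitted_deaths: np.ndarray
    deviance: float
    log_lik: float
    aic_per_obs: float
    bic: float
    n_obs: int
    model_rank: int
    converged: bool
    iterations: int
    b0_used: np.ndarray
    theta: np.ndarray
    deviance_trace: list = field(default_factory=list)

    def effects_frame(self) -> pd.DataFrame:
        """All expanded category effects: A + P + C rows (37 for the 13x6 grid)."""
        rows = []
        for dim, labels, values in (
            ("age", self.age_labels, self.age_effects),
            ("period", self.period_labels, self.period_effects),
            ("cohort", self.cohort_labels, self.cohort_effects),
        ):
            rows.extend((dim, lab, float(v)) for lab, v in zip(labels, values))
        return pd.DataFrame(rows, columns=["dimension", "category_label", "effect"])

    def stats_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "deviance": self.deviance,
            "log_lik": self.log_lik,
            "aic_per_obs": self.aic_per_obs,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "model_rank": self.model_rank,
            "iterations": self.iterations,
            "converged": self.converged,
        }


def expand_effects(theta: np.ndarray, spec: DesignSpec):
    """Split an effect-coded coefficient vector into full sum-to-zero blocks.

    The reference (last) category of each dimension is recovered as minus
    the sum of the coded categories.
    """
    A, P, C = spec.n_age, spec.n_period, spec.n_cohort
    mu = float(theta[0])
    blocks = []
    pos = 1
    for n in (A, P, C):
        coded = np.asarray(theta[pos : pos + n - 1], dtype=float)
        blocks.append(np.append(coded, -coded.sum()))
        pos += n - 1
    return mu, blocks[0], blocks[1], blocks[2]


def fit_ie(table: RateTable, max_iter: int = MAX_ITER, tol: float = DEVIANCE_RTOL) -> APCFit:
    """Fit the APC model to a Lexis table by the intrinsic estimator.

    The table's periods must be spaced exactly one age-interval width
    apart (five years), so that grid diagonals are genuine five-year
    birth cohorts; use :func:`apcie.lexis.subsample_periods` on annual
    data first.

    Steps: build the effect-coded design X and its null vector b0; form
    an orthonormal basis V of the complement of b0; run IRLS on the
    Poisson GLM with design X V and offset ln N (intercept initialised at
    the crude log rate, all other coefficients zero; stop when the
    relative deviance change drops below ``tol``); map back theta = V w
    and expand reference categories.
    """
    steps = np.diff(table.periods)
    if not np.all(steps == AGE_WIDTH):
        raise ValidationError(
            f"modelled periods must be spaced {AGE_WIDTH} years apart (the age-interval "
            f"width) for diagonals to be 5-year birth cohorts; got spacings {steps.tolist()}"
        )
    spec = DesignSpec(table.n_age, table.n_period)
    design = build_design(spec)
    X = design.values
    b0 = null_vector(design)
    V = scipy.linalg.null_space(b0[None, :])  # q x (q-1), orthonormal

    y = table.deaths.reshape(-1)  # age-major, matching design row order
    offset = np.log(table.population.reshape(-1))
    XV = X @ V

    theta0 = np.zeros(spec.n_cols)
    theta0[0] = np.log(y.sum() / table.population.sum())
    w = V.T @ theta0

    dev_prev = np.inf
    trace = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        eta = offset + XV @ w
        mu = np.exp(eta)
        dev = deviance(y, mu)
        trace.append(dev)
        if np.isfinite(dev_prev) and abs(dev_prev - dev) <= tol * (1.0 + abs(dev_prev)):
            converged = True
            break
        dev_prev = dev
        z = (eta - offset) + (y - mu) / mu
        sw = np.sqrt(mu)
        w, *_ = np.linalg.lstsq(XV * sw[:, None], z * sw, rcond=None)
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge within {max_iter} iterations", deviance_trace=trace
        )

    theta = V @ w
    mu_hat, alpha, beta, gamma = expand_effects(theta, spec)
    fitted = np.exp(offset + X @ theta)
    dev = deviance(y, fitted)
    ll = poisson_log_likelihood(y, fitted)
    model_rank = spec.n_cols - 1
    aic_per_obs, bic = information_criteria(dev, ll, y.size, model_rank)

    layout = cohort_layout(table)
    return APCFit(
        intercept=mu_hat,
        age_effects=alpha,
        period_effects=beta,
        cohort_effects=gamma,
        age_labels=tuple(table.age_labels()),
        period_labels=tuple(str(y_) for y_ in table.periods),
        cohort_labels=layout.cohort_labels,
        fitted_deaths=fitted,
        deviance=dev,
        log_lik=ll,
        aic_per_obs=aic_per_obs,
        bic=bic,
        n_obs=int(y.size),
        model_rank=model_rank,
        converged=converged,
        iterations=iterations,
        b0_used=b0,
        theta=theta,
        deviance_trace=trace,
    )
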