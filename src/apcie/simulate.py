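"""Synthetic Lexis tables with known age-period-cohort structure.

The generator draws smooth ground-truth effect curves (centred random
walks, so synthetic age/period/cohort curves bend gradually the way
real mortality effects do), combines them on the log-rate scale with an
intercept, and samples Poisson death counts over large person-year
denominators.  Breast-cancer death in any one cell is rare (rates on
the order of 1e-5 to 1e-4), which is exactly the regime where the
Poisson approximation to the underlying binomial is appropriate.

Because the APC design is rank-deficient by one, a simulation truth is
only fully recoverable when it is orthogonal to the design's null
vector; ``make_true_params(..., orthogonalize=True)`` projects the
truth accordingly so recovery experiments have a well-defined estimand.

``study_config`` mimics the structure of the motivating study data:
13 five-year age groups (20-24 ... 80-84) by annual calendar years
1990-2015, with crude rates per 100,000 women in the 5-15 range.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np

from .design import DesignSpec, build_design, null_vector, project_out_null
from .errors import ValidationError
from .estimator import expand_effects
from .lexis import RateTable

#: Baseline log rate used when a config gives none: 8.5 deaths per 100,000.
DEFAULT_INTERCEPT = float(np.log(8.5e-5))


@dataclass(frozen=True)
class SimConfig:
    """Settings for one synthetic experiment.

    ``population`` is person-years per cell (scalar, broadcast, or a full
    A x P matrix); ``effect_scale`` is the innovation standard deviation
    of the random walks generating each effect curve (log-rate units per
    category step); ``seed`` drives two independent substreams, one for
    parameter draws and one for Poisson noise.
    """

    n_age: int = 13
    n_period: int = 6
    age_start: int = 20
    first_period: int = 1990
    period_step: int = 5
    population: Union[float, np.ndarray] = 2e7
    effect_scale: float = 0.1
    intercept: float = DEFAULT_INTERCEPT
    seed: int = 0
    emulate_study: bool = False

    def __post_init__(self):
        if self.effect_scale < 0:
            raise ValidationError("effect_scale must be nonnegative")
        if np.any(np.asarray(self.population, dtype=float) <= 0):
            raise ValidationError("population must be positive")
        if self.n_age < 1 or self.n_period < 1:
            raise ValidationError("grid dimensions must be positive")

    @property
    def n_cohort(self) -> int:
        return self.n_age + self.n_period - 1

    def age_groups(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.age_start + 5 * u, self.age_start + 5 * u + 4) for u in range(self.n_age)
        )

    def periods(self) -> tuple[int, ...]:
        return tuple(self.first_period + self.period_step * j for j in range(self.n_period))

    def population_matrix(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.population, dtype=float), (self.n_age, self.n_period)
        ).copy()


def study_config(seed: int = 0, effect_scale: float = 0.08) -> SimConfig:
    """Config emulating the motivating study layout: 13 age groups x 26 annual years."""
    return SimConfig(
        n_age=13,
        n_period=26,
        age_start=20,
        first_period=1990,
        period_step=1,
        population=2e7,
        effect_scale=effect_scale,
        intercept=DEFAULT_INTERCEPT,
        seed=seed,
        emulate_study=True,
    )


def resolve_config(config: SimConfig) -> SimConfig:
    """Force the study layout when ``emulate_study`` is set."""
    if not config.emulate_study:
        return config
    return replace(
        config,
        n_age=13,
        n_period=26,
        age_start=20,
        first_period=1990,
        period_step=1,
    )


@dataclass(frozen=True)
class TrueParams:
    """Ground-truth model parameters on the log-rate scale.

    Each effect block sums to zero; ``orthogonalized`` records whether the
    concatenated effect-coded vector was projected orthogonal to the
    design null vector (so that it is exactly recoverable by the
    intrinsic estimator).
    """

    intercept: float
    age_effects: np.ndarray
    period_effects: np.ndarray
    cohort_effects: np.ndarray
    orthogonalized: bool = False

    def __post_init__(self):
        for name in ("age_effects", "period_effects", "cohort_effects"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.size and abs(v.sum()) > 1e-9 * max(1.0, np.abs(v).max()):
                raise ValidationError(f"{name} must sum to zero (got {v.sum():.2e})")
        if self.cohort_effects.size != self.age_effects.size + self.period_effects.size - 1:
            raise ValidationError("cohort block must have A + P - 1 entries")
        if np.max(self.log_rate_grid()) >= 0:
            raise ValidationError("implied rates must lie strictly below 1 per person-year")

    @property
    def n_age(self) -> int:
        return self.age_effects.size

    @property
    def n_period(self) -> int:
        return self.period_effects.size

    def log_rate_grid(self) -> np.ndarray:
        """A x P grid of log rates mu + alpha_i + beta_j + gamma_k, k = (A - i) + j."""
        A, P = self.n_age, self.n_period
        eta = np.empty((A, P))
        for i in range(A):
            for j in range(P):
                k = (A - (i + 1)) + (j + 1)  # 1-based diagonal index
                eta[i, j] = (
                    self.intercept
                    + self.age_effects[i]
                    + self.period_effects[j]
                    + self.cohort_effects[k - 1]
                )
        return eta

    def to_theta(self) -> np.ndarray:
        """Effect-coded coefficient vector [mu, alpha_1..A-1, beta_1..P-1, gamma_1..C-1]."""
        return np.concatenate(
            (
                [self.intercept],
                self.age_effects[:-1],
                self.period_effects[:-1],
                self.cohort_effects[:-1],
            )
        )

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "age_effects": self.age_effects.tolist(),
            "period_effects": self.period_effects.tolist(),
            "cohort_effects": self.cohort_effects.tolist(),
            "orthogonalized": self.orthogonalized,
        }


def _param_rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])


def _noise_rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])


def _centered_walk(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    walk = np.cumsum(rng.normal(0.0, scale, size=n))
    return walk - walk.mean()


def make_true_params(config: SimConfig, orthogonalize: bool = False) -> TrueParams:
    """Draw smooth sum-to-zero effect curves for each APC dimension.

    With ``orthogonalize=True`` the effect-coded parameter vector is
    projected orthogonal to the null vector of the matching design (the
    intercept coordinate of the null vector is zero, so the intercept is
    untouched) and re-expanded into sum-to-zero blocks.
    """
    config = resolve_config(config)
    rng = _param_rng(config)
    alpha = _centered_walk(rng, config.n_age, config.effect_scale)
    beta = _centered_walk(rng, config.n_period, config.effect_scale)
    gamma = _centered_walk(rng, config.n_cohort, config.effect_scale)
    params = TrueParams(config.intercept, alpha, beta, gamma, orthogonalized=False)
    if not orthogonalize:
        return params
    spec = DesignSpec(config.n_age, config.n_period)
    b0 = null_vector(build_design(spec))
    theta = project_out_null(params.to_theta(), b0)
    mu, alpha, beta, gamma = expand_effects(theta, spec)
    return TrueParams(mu, alpha, beta, gamma, orthogonalized=True)


def simulate_table(params: TrueParams, config: SimConfig) -> RateTable:
    """Sample D_ij ~ Poisson(N_ij * exp(eta_ij)) and wrap as a RateTable."""
    config = resolve_config(config)
    if (params.n_age, params.n_period) != (config.n_age, config.n_period):
        raise ValidationError(
            f"parameter dimensions ({params.n_age}, {params.n_period}) do not match "
            f"config grid ({config.n_age}, {config.n_period})"
        )
    N = config.population_matrix()
    lam = N * np.exp(params.log_rate_grid())
    if np.any(lam > N):
        raise ValidationError("expected deaths exceed population in at least one cell")
    deaths = _noise_rng(config).poisson(lam).astype(float)
    return RateTable(config.age_groups(), config.periods(), deaths, N)


def simulate(config: SimConfig, orthogonalize: bool = False) -> tuple[RateTable, TrueParams]:
    """Convenience wrapper: draw parameters, then a table, from one seed."""
    params = make_true_params(config, orthogonalize=orthogonalize)
    return simulate_table(params, config), params
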