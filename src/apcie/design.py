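"""Effect-coded age-period-cohort design matrix and its null space.

The log-rate model ln r_ij = mu + alpha_i + beta_j + gamma_k with
k = (A - i) + j and sum-to-zero constraints on each effect block is
written in effect (deviation) coding: the last category of every
dimension is the reference and its effect is minus the sum of the
others.  Because age, period and cohort indices satisfy the exact
linear relation cohort = period - age, the resulting m x q matrix
(m = A*P cells, q = 1 + (A-1) + (P-1) + (C-1) columns) has rank q - 1.
The single direction it annihilates — the null vector b0 — is the
linear-trend trade-off between the three dimensions; adding any
multiple of b0 to the coefficients leaves every fitted rate unchanged.
The intrinsic estimator resolves this ambiguity by restricting the
coefficients to the orthogonal complement of b0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IdentificationError, ValidationError


@dataclass(frozen=True)
class DesignSpec:
    """Dimensions of an APC grid: A age groups x P periods, C = A+P-1 cohorts."""

    n_age: int
    n_period: int

    def __post_init__(self):
        if self.n_age < 2 or self.n_period < 2:
            raise ValidationError(
                f"APC decomposition needs at least 2 age groups and 2 periods, "
                f"got A={self.n_age}, P={self.n_period}"
            )

    @property
    def n_cohort(self) -> int:
        return self.n_age + self.n_period - 1

    @property
    def n_cols(self) -> int:
        return 1 + (self.n_age - 1) + (self.n_period - 1) + (self.n_cohort - 1)


@dataclass(frozen=True)
class DesignMatrix:
    """Effect-coded design: values (m x q), column labels, and the (i, j, k) of each row."""

    spec: DesignSpec
    values: np.ndarray
    columns: tuple[str, ...]
    cells: tuple[tuple[int, int, int], ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.columns))


def _effect_code(category: int, n_levels: int) -> np.ndarray:
    """Deviation-coded row for a 1-based category; reference is the last level."""
    row = np.zeros(n_levels - 1)
    if category == n_levels:
        row[:] = -1.0
    else:
        row[category - 1] = 1.0
    return row


def build_design(spec: DesignSpec) -> DesignMatrix:
    """Assemble the m x q effect-coded design, rows in age-major cell order."""
    A, P, C = spec.n_age, spec.n_period, spec.n_cohort
    rows, cells = [], []
    for i in range(1, A + 1):
        for j in range(1, P + 1):
            k = (A - i) + j
            rows.append(
                np.concatenate(
                    ([1.0], _effect_code(i, A), _effect_code(j, P), _effect_code(k, C))
                )
            )
            cells.append((i, j, k))
    columns = (
        ("intercept",)
        + tuple(f"age_{i}" for i in range(1, A))
        + tuple(f"period_{j}" for j in range(1, P))
        + tuple(f"cohort_{k}" for k in range(1, C))
    )
    return DesignMatrix(spec, np.array(rows), columns, tuple(cells))


def null_vector(design: DesignMatrix) -> np.ndarray:
    """Unit vector b0 spanning the null space of the design matrix.

    Computed from a full singular-value decomposition with threshold
    ``max(m, q) * eps * sigma_max``.  The sign is fixed so the first
    coordinate exceeding 1e-12 in magnitude is positive, and the
    intercept coordinate (which is zero analytically) is zeroed exactly
    before renormalisation, so repeated calls return identical vectors.
    """
    X = design.values
    m, q = X.shape
    _, s, Vt = np.linalg.svd(X)
    tol = max(m, q) * np.finfo(float).eps * s[0]
    rank = int(np.sum(s > tol))
    null_dim = q - rank
    if null_dim != 1:
        raise IdentificationError(
            f"design null space has dimension {null_dim}, expected 1 "
            f"(A={design.spec.n_age}, P={design.spec.n_period})",
            null_dim=null_dim,
        )
    b0 = Vt[-1].copy()
    if abs(b0[0]) > 1e-8:
        raise IdentificationError(
            f"null vector has intercept component {b0[0]:.2e}; design is malformed"
        )
    b0[0] = 0.0
    b0 /= np.linalg.norm(b0)
    lead = np.flatnonzero(np.abs(b0) > 1e-12)[0]
    if b0[lead] < 0:
        b0 = -b0
    return b0


def trend_null_direction(spec: DesignSpec) -> np.ndarray:
    """Closed-form (unnormalised) null direction.

    In full category coordinates the null space is the linear-trend
    trade-off  d_alpha_i = i - (A+1)/2,  d_beta_j = -(j - (P+1)/2),
    d_gamma_k = k - (C+1)/2;  each block is a centred linear ramp, and
    because k = (A - i) + j the three contributions cancel cell by cell.
    Expressed in effect coding (drop each block's last category) this
    gives a vector the design matrix maps to zero — used as an analytic
    cross-check of the SVD route.
    """
    A, P, C = spec.n_age, spec.n_period, spec.n_cohort
    d_age = np.arange(1, A) - (A + 1) / 2
    d_period = -(np.arange(1, P) - (P + 1) / 2)
    d_cohort = np.arange(1, C) - (C + 1) / 2
    return np.concatenate(([0.0], d_age, d_period, d_cohort))


def project_out_null(theta: np.ndarray, b0: np.ndarray) -> np.ndarray:
    """Component of ``theta`` orthogonal to the null direction ``b0``."""
    theta = np.asarray(theta, dtype=float)
    b0 = np.asarray(b0, dtype=float)
    if theta.shape != b0.shape:
        raise ValidationError(
            f"parameter vector length {theta.shape} does not match null vector {b0.shape}"
        )
    return theta - (theta @ b0) * b0
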