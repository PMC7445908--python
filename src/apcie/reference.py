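"""Published intrinsic-estimator effect estimates used as worked-example inputs.

These are the age, period and cohort effects (log-rate scale) from a
published APC analysis of breast-cancer mortality among Chinese women,
fitted to single-year data five years apart over 1990-2015 (13 age
groups 20-24 ... 80-84, six periods, eighteen birth cohorts back to
1906-1910).  They serve as fixed inputs for the post-processing
operations in :mod:`apcie.effects` — rate ratios between cohorts or
periods, net changes, percent declines — and for documentation
examples.  The underlying mortality extract itself is not bundled.
"""

from __future__ import annotations

from .effects import EffectSeries

PUBLISHED_AGE_EFFECTS = EffectSeries(
    name="age",
    labels=(
        "20-24", "25-29", "30-34", "35-39", "40-44", "45-49", "50-54",
        "55-59", "60-64", "65-69", "70-74", "75-79", "80-84",
    ),
    values=(
        -2.995, -1.822, -0.792, -0.350, 0.034, 0.394, 0.525,
        0.643, 0.692, 0.764, 0.843, 0.968, 1.096,
    ),
)

PUBLISHED_PERIOD_EFFECTS = EffectSeries(
    name="period",
    labels=("1990", "1995", "2000", "2005", "2010", "2015"),
    values=(-0.141, -0.114, -0.073, -0.020, 0.090, 0.258),
)

PUBLISHED_COHORT_EFFECTS = EffectSeries(
    name="cohort",
    labels=(
        "1906-1910", "1911-1915", "1916-1920", "1921-1925", "1926-1930",
        "1931-1935", "1936-1940", "1941-1945", "1946-1950", "1951-1955",
        "1956-1960", "1961-1965", "1966-1970", "1971-1975", "1976-1980",
        "1981-1985", "1986-1990", "1991-1995",
    ),
    values=(
        0.626, 0.577, 0.565, 0.554, 0.550, 0.518, 0.487, 0.414, 0.407,
        0.306, 0.099, -0.028, -0.223, -0.514, -0.726, -0.841, -1.020, -1.752,
    ),
)

#: Fit statistics reported alongside the published effects (78 cells,
#: 34 estimable directions).
PUBLISHED_FIT_STATS = {
    "deviance": 1.246,
    "aic": 5.092,
    "bic": -190.449,
    "n_obs": 78,
    "model_rank": 34,
}

#: Crude all-age mortality rates per 100,000 women at the endpoints of
#: the observation window.
PUBLISHED_CRUDE_RATES = {1990: 6.83, 2015: 12.07}
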