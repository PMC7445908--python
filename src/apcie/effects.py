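"""Post-processing of fitted log-linear effects.

Numerical differentiation, relative risks and simple trend arithmetic
on an ordered series of effect estimates (age, period or cohort).
Because effects live on the log-rate scale, a difference of two effects
exponentiates to a rate ratio, and declines convert to percentages via
``(1 - RR) * 100``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class EffectSeries:
    """One dimension's effect curve: ordered category labels and log-scale values."""

    labels: tuple[str, ...]
    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)
        if len(labels) != values.size:
            raise ValidationError("labels and values must have equal length")
        if len(set(labels)) != len(labels):
            raise ValidationError("labels must be unique")
        if not np.all(np.isfinite(values)):
            raise ValidationError("effect values must be finite")

    def __len__(self) -> int:
        return len(self.labels)

    def value(self, label: str) -> float:
        try:
            return float(self.values[self.labels.index(str(label))])
        except ValueError:
            raise KeyError(f"label {label!r} not in series {self.name or '<unnamed>'}")


def numerical_diff(series: EffectSeries) -> EffectSeries:
    """First differences value(t+1) - value(t), labelled at the earlier category t."""
    if len(series) < 2:
        raise ValidationError("need at least 2 values to differentiate")
    return EffectSeries(
        labels=series.labels[:-1],
        values=np.diff(series.values),
        name=f"d_{series.name}" if series.name else "diff",
    )


def relative_risk(effect_from: float, effect_to: float) -> float:
    """Rate ratio exp(effect_to - effect_from) between two categories."""
    return math.exp(effect_to - effect_from)


def net_change(series: EffectSeries, label_from: str, label_to: str) -> float:
    """value(label_to) - value(label_from) on the log-rate scale."""
    return series.value(label_to) - series.value(label_from)


def percent_decline(effect_from: float, effect_to: float) -> float:
    """Percent decline in risk, (1 - exp(effect_to - effect_from)) * 100."""
    return (1.0 - relative_risk(effect_from, effect_to)) * 100.0


def annualized_change(
    diff_early: float, span_early: float, diff_late: float, span_late: float
) -> tuple[float, float, float]:
    """Per-year change in two windows and the late/early speed ratio."""
    if span_early <= 0 or span_late <= 0:
        raise ValidationError("window spans must be positive")
    rate_early = diff_early / span_early
    rate_late = diff_late / span_late
    if rate_early == 0:
        raise ValidationError("speed ratio undefined when the early rate is zero")
    return rate_early, rate_late, rate_late / rate_early
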