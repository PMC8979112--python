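"""Serial-sampling (trapezoidal) and pooled-sample AUC estimation.

The central identity of the pooled method: pooling a profile with the exact
Hamilton-weight design and multiplying the pooled value by the schedule span
reproduces the linear trapezoidal AUC of the serial profile exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import ValidationError
from .pooling import PoolingDesign, SamplingSchedule


@dataclass(frozen=True)
class ConcentrationProfile:
    """Per-compound value-vs-time series (concentration or peak-area units).

    Values flagged ``below_lloq`` are treated as zero in all AUC and pooling
    arithmetic (censored measurements carry no signal).
    """

    compound_id: str
    times: tuple[float, ...]
    values: tuple[float, ...]
    unit_label: str = "ng/mL"
    below_lloq: tuple[bool, ...] = ()

    def __post_init__(self):
        if len(self.times) != len(self.values):
            raise ValidationError("times and values must have equal length")
        t = np.asarray(self.times)
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValidationError("profile times must be strictly increasing")
        if any(v < 0 for v in self.values):
            raise ValidationError("profile values must be >= 0")
        if not self.below_lloq:
            object.__setattr__(self, "below_lloq", (False,) * len(self.values))
        elif len(self.below_lloq) != len(self.values):
            raise ValidationError("below_lloq flags must match values in length")

    def censored_values(self) -> np.ndarray:
        """Values with below-LLOQ points zeroed."""
        v = np.asarray(self.values, dtype=float)
        v[np.asarray(self.below_lloq, dtype=bool)] = 0.0
        return v


@dataclass(frozen=True)
class AUCEstimate:
    """AUC over ``[t_start, t_end]`` in ``unit_label × hours``."""

    compound_id: str
    value: float
    method: Literal["trapezoid", "pooled"]
    t_start: float
    t_end: float
    unit_label: str = "ng/mL*h"

    def __post_init__(self):
        if self.value < 0:
            raise ValidationError("AUC must be >= 0")
        if self.t_end <= self.t_start:
            raise ValidationError("t_end must exceed t_start")


@dataclass(frozen=True)
class MethodComparison:
    compound_id: str
    auc_traditional: AUCEstimate
    auc_pooled: AUCEstimate
    percent_difference: float


def trapezoid_auc(profile: ConcentrationProfile) -> AUCEstimate:
    """Linear trapezoidal AUC of a serial profile (the traditional method)."""
    if len(profile.times) < 2:
        raise ValidationError("trapezoid AUC needs at least 2 points")
    t = np.asarray(profile.times)
    value = float(np.trapezoid(profile.censored_values(), t))
    return AUCEstimate(
        compound_id=profile.compound_id,
        value=value,
        method="trapezoid",
        t_start=float(t[0]),
        t_end=float(t[-1]),
        unit_label=f"{profile.unit_label}*h",
    )


def pool_concentration(profile: ConcentrationProfile, design: PoolingDesign) -> float:
    """Volume-weighted mean concentration of the pooled sample.

    This is the value an instrument would measure on the physically mixed
    sample: sum(v_i * C_i) / sum(v_i).
    """
    if not np.allclose(profile.times, design.schedule.times, rtol=0, atol=1e-12):
        raise ValidationError("profile times do not match the design schedule")
    v = np.asarray(design.volumes)
    c = profile.censored_values()
    return float(np.dot(v, c) / v.sum())


def pooled_auc(
    pooled_value: float,
    schedule: SamplingSchedule,
    compound_id: str = "",
    unit_label: str = "ng/mL",
) -> AUCEstimate:
    """AUC from a single pooled measurement: pooled value × (t_n − t_0)."""
    if pooled_value < 0:
        raise ValidationError("pooled value must be >= 0")
    return AUCEstimate(
        compound_id=compound_id,
        value=float(pooled_value) * schedule.span_h,
        method="pooled",
        t_start=schedule.times[0],
        t_end=schedule.times[-1],
        unit_label=f"{unit_label}*h",
    )


def percent_difference(
    auc_traditional: AUCEstimate, auc_pooled: AUCEstimate
) -> float:
    """Unsigned relative difference of the pooled estimate vs the traditional
    (serial trapezoid) reference, in percent."""
    if auc_traditional.value <= 0:
        raise ValidationError("traditional AUC must be > 0 to serve as reference")
    return (
        abs(auc_pooled.value - auc_traditional.value) / auc_traditional.value * 100.0
    )


def compare_methods(
    auc_traditional: AUCEstimate, auc_pooled: AUCEstimate
) -> MethodComparison:
    if auc_traditional.compound_id != auc_pooled.compound_id:
        raise ValidationError("method comparison requires a single compound")
    return MethodComparison(
        compound_id=auc_traditional.compound_id,
        auc_traditional=auc_traditional,
        auc_pooled=auc_pooled,
        percent_difference=percent_difference(auc_traditional, auc_pooled),
    )


def replicate_summary(estimates: Sequence[AUCEstimate]) -> tuple[float, float]:
    """Mean and sample standard deviation (n−1) of replicate AUC estimates.

    All estimates must share one compound and one method; a single estimate
    yields SD 0.
    """
    if not estimates:
        raise ValidationError("replicate summary needs at least one estimate")
    compounds = {e.compound_id for e in estimates}
    methods = {e.method for e in estimates}
    if len(compounds) > 1 or len(methods) > 1:
        raise ValidationError(
            f"mixed replicate set: compounds={sorted(compounds)}, "
            f"methods={sorted(methods)}"
        )
    values = np.asarray([e.value for e in estimates], dtype=float)
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return float(values.mean()), sd
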