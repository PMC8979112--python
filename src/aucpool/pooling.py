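"""Pooling design for the AUC-pooled (Hamilton) plasma method.

A single pooled plasma sample can encode the linear-trapezoidal AUC of a
serial sampling schedule: mix per-time-point aliquots with volumes
proportional to the trapezoid (half-interval) weights, and the pooled
concentration times the schedule span equals AUC over the schedule.

This module computes those weights and realizes them as pipettable volumes
for a given total pooled volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError

#: Default pipetting resolution in microliters.
DEFAULT_ROUNDING_INCREMENT_UL = 0.1


@dataclass(frozen=True)
class SamplingSchedule:
    """Ordered blood-collection times in hours.

    The first time is the pre-dose sample (typically 0 h); schedules with
    ``times[0] > 0`` are allowed and all span arithmetic uses
    ``times[-1] - times[0]``.
    """

    times: tuple[float, ...]

    def __init__(self, times: Sequence[float]):
        t = tuple(float(x) for x in times)
        if len(t) < 2:
            raise ValidationError("schedule needs at least 2 collection times")
        arr = np.asarray(t)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("collection times must be finite")
        if np.any(arr < 0):
            raise ValidationError("collection times must be >= 0")
        if np.any(np.diff(arr) <= 0):
            raise ValidationError("collection times must be strictly increasing")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def span_h(self) -> float:
        """Schedule span ``t_n - t_0`` in hours (the AUC truncation window)."""
        return self.times[-1] - self.times[0]


@dataclass(frozen=True)
class PoolingDesign:
    """Per-time-point plasma volumes (μL) realizing the pooling weights."""

    schedule: SamplingSchedule
    volumes: tuple[float, ...]
    total_volume: float
    rounding_increment: float = 0.0
    diagnostics: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self):
        if len(self.volumes) != len(self.schedule):
            raise ValidationError("one volume per schedule time required")
        if any(v <= 0 for v in self.volumes):
            raise ValidationError("all pooling volumes must be > 0")
        tol = max(self.rounding_increment * len(self.volumes), 1e-9 * self.total_volume)
        if abs(sum(self.volumes) - self.total_volume) > tol:
            raise ValidationError(
                f"volumes sum to {sum(self.volumes):g}, expected "
                f"{self.total_volume:g} within {tol:g}"
            )


def hamilton_weights(schedule: SamplingSchedule) -> np.ndarray:
    """Half-interval trapezoid weights for each collection time, in hours.

    w_0 = (t_1 - t_0)/2, w_k = (t_{k+1} - t_{k-1})/2 for interior points,
    w_n = (t_n - t_{n-1})/2. The weights telescope: sum(w) = t_n - t_0.
    These are the volume ratios of the pooled method (the conventional
    printed ratio chain is these weights with the common factor 1/2
    cancelled).
    """
    t = np.asarray(schedule.times)
    w = np.empty(len(t))
    w[0] = (t[1] - t[0]) / 2.0
    w[-1] = (t[-1] - t[-2]) / 2.0
    if len(t) > 2:
        w[1:-1] = (t[2:] - t[:-2]) / 2.0
    return w


def pooling_volumes(
    schedule: SamplingSchedule,
    total_volume: float,
    rounding_increment: float = DEFAULT_ROUNDING_INCREMENT_UL,
) -> PoolingDesign:
    """Scale the Hamilton weights to per-time-point volumes summing to
    ``total_volume`` μL, optionally rounded to a pipetting increment.

    A diagnostic warning is attached (and emitted) when rounding moves any
    volume more than 1% away from its exact value; rounding a volume all
    the way to zero is an error.
    """
    if total_volume <= 0:
        raise ValidationError("total_volume must be > 0")
    if rounding_increment < 0:
        raise ValidationError("rounding_increment must be >= 0")
    w = hamilton_weights(schedule)
    exact = total_volume * w / w.sum()
    if rounding_increment > 0:
        rounded = np.round(exact / rounding_increment) * rounding_increment
    else:
        rounded = exact.copy()
    if np.any(rounded <= 0):
        bad = int(np.argmin(rounded))
        raise ValidationError(
            f"rounding increment {rounding_increment:g} μL drives the volume at "
            f"t={schedule.times[bad]:g} h to zero; use a finer increment"
        )
    diagnostics = []
    rel = np.abs(rounded - exact) / exact
    for i in np.flatnonzero(rel > 0.01):
        msg = (
            f"rounded volume at t={schedule.times[i]:g} h deviates "
            f"{100 * rel[i]:.2f}% from exact ({rounded[i]:g} vs {exact[i]:.4g} μL)"
        )
        diagnostics.append(msg)
        warnings.warn(msg, stacklevel=2)
    return PoolingDesign(
        schedule=schedule,
        volumes=tuple(float(v) for v in rounded),
        total_volume=float(total_volume),
        rounding_increment=float(rounding_increment),
        diagnostics=tuple(diagnostics),
    )
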