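"""Subjective durations of objective intervals, and the speed of time.

Discrete mode sums the per-unit subjective units over an interval,
``d_s = sum_{t=t1+1..t2} 1/t**a`` — a difference of (generalized) harmonic
numbers.  Continuous mode integrates instead, giving ``ln(t2/t1)`` at
``a = 1`` and ``(t2**(1-a) - t1**(1-a)) / (1-a)`` otherwise.  The subjective
speed of time is the ratio of subjective to objective duration; the objective
speed is identically 1.

Durations starting at ``t1 = 0`` are rejected here: the age-0 term is a hard
infinity, and infinity bookkeeping lives in :mod:`subjective_time.horizons`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .core import EULER_GAMMA, gen_harmonic

__all__ = [
    "DurationResult",
    "SpeedResult",
    "discrete_duration",
    "continuous_duration",
    "subjective_speed",
    "discrete_continuous_gap",
]

Mode = Literal["discrete", "continuous"]


@dataclass(frozen=True)
class DurationResult:
    """Subjective duration (in Uo) of the objective interval [t1, t2]."""

    t1: float
    t2: float
    mode: Mode
    exponent: float
    value: float


@dataclass(frozen=True)
class SpeedResult:
    """Dimensionless subjective speed of time over [t1, t2]."""

    t1: float
    t2: float
    mode: Mode
    exponent: float
    value: float


def _check_exponent(a: float) -> None:
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"exponent must lie in [0, 1], got {a}")


def discrete_duration(t1: int, t2: int, a: float = 1.0) -> DurationResult:
    """Discrete subjective duration sum_{t=t1+1..t2} 1/t**a, in Uo.

    Requires 1 <= t1 < t2.  An interval starting at age 0 would include a
    hard-infinity term; use the horizons module for those sums.
    """
    if t1 != int(t1) or t2 != int(t2):
        raise ValueError("discrete durations take integer ages")
    if t1 < 1:
        raise ValueError(
            "t1 must be >= 1: the age-0 term is a hard infinity, handled by the horizons module"
        )
    if t2 <= t1:
        raise ValueError(f"need t2 > t1, got t1={t1}, t2={t2}")
    _check_exponent(a)
    value = gen_harmonic(int(t2), a) - gen_harmonic(int(t1), a)
    return DurationResult(int(t1), int(t2), "discrete", a, value)


def continuous_duration(t1: float, t2: float, a: float = 1.0) -> DurationResult:
    """Continuous subjective duration — the integral of 1/t**a over [t1, t2].

    Equals ``ln(t2/t1)`` at a=1 and ``(t2**(1-a) - t1**(1-a))/(1-a)`` for
    a<1.  The power-law branch is evaluated as
    ``(expm1(eps*ln t2) - expm1(eps*ln t1)) / eps`` with ``eps = 1 - a``,
    which stays fully accurate as eps -> 0, so the two branches agree at the
    a=1 boundary to machine precision.
    """
    if t1 < 1:
        raise ValueError(f"need t1 >= 1, got {t1}")
    if t2 <= t1:
        raise ValueError(f"need t2 > t1, got t1={t1}, t2={t2}")
    _check_exponent(a)
    eps = 1.0 - a
    if eps == 0.0:
        value = math.log(t2 / t1)
    else:
        value = (math.expm1(eps * math.log(t2)) - math.expm1(eps * math.log(t1))) / eps
    return DurationResult(t1, t2, "continuous", a, value)


def subjective_speed(t1: float, t2: float, a: float = 1.0, mode: Mode = "discrete") -> SpeedResult:
    """Subjective speed of time over [t1, t2]: duration / (t2 - t1).

    Dimensionless (subjective Uo per objective Uo).  With a=0 every unit is
    one Uo and the speed is the objective speed, exactly 1.
    """
    if mode == "discrete":
        duration = discrete_duration(int(t1), int(t2), a)
    elif mode == "continuous":
        duration = continuous_duration(t1, t2, a)
    else:
        raise ValueError(f"mode must be 'discrete' or 'continuous', got {mode!r}")
    return SpeedResult(duration.t1, duration.t2, mode, a, duration.value / (t2 - t1))


def discrete_continuous_gap(t2: int, a: float = 1.0) -> float:
    """|discrete − continuous| duration gap from t1=1 out to t2.

    For a=1 this is |H_{t2} − 1 − ln t2|, which converges to 1 − gamma
    ≈ 0.4228 (gamma the Euler–Mascheroni constant) as t2 grows; the model's
    "around 0.42" plateau is this limit approached from below.
    """
    if t2 < 2 or t2 != int(t2):
        raise ValueError(f"need an integer t2 >= 2, got {t2}")
    return abs(discrete_duration(1, int(t2), a).value - continuous_duration(1.0, float(t2), a).value)


#: Asymptote of the a=1 discrete–continuous gap, 1 − gamma.
GAP_ASYMPTOTE = 1.0 - EULER_GAMMA
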