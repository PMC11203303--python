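"""Past and future horizons under stacked clocks.

The past horizon is the backward sum of every subjective unit already lived:
walking back year by year from the present to birth, each past year
contributes the unit that was current then, computed with the clocks active
at that time.  Every clock-start year contributes one hard infinity (its age
was 0), so a past horizon always carries at least one — the birth term.

The future horizon sums the coming ``m`` per-year units
``prod_i 1/(t_i + k)**a`` for k = 1..m (or from k = 0 when the current year's
unit is included).  With no deadline (``m`` unbounded) the series either
diverges — a "soft" infinity, which happens exactly when the total term
exponent (number of active clocks × a) is <= 1 — or converges to a finite
limit: the first social birth turns the anticipated future from endless to
bounded.

Segment bookkeeping for the past horizon follows the model's worked
arithmetic: each boundary date (a clock's start) is counted in *both*
adjacent segments — once as the zero-age hard-infinity term of the newer
segment, once as an ordinary term of the older one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import mpmath

from .core import ExtendedValue, PersonClock, _unit_from_ages

__all__ = [
    "HorizonResult",
    "SingularCurrentUnitError",
    "past_horizon",
    "future_horizon",
    "classify_infinity",
]

UNBOUNDED = "unbounded"

#: absolute accuracy requested from the convergent-series evaluator
_SERIES_TOL = 1e-12


class SingularCurrentUnitError(ValueError):
    """Raised when a future horizon is requested while some clock has age 0.

    The current unit is then itself infinite; the horizon sum is not defined
    until the first unit of the newest clock completes.
    """


@dataclass(frozen=True)
class HorizonResult:
    """An extended-valued horizon, with its direction and bookkeeping.

    ``segments`` (past horizons only) lists the per-segment extended values,
    oldest segment first — e.g. the birth-clock-only segment, then the
    two-clock segment after the first social birth.
    """

    value: ExtendedValue
    direction: Literal["past", "future"]
    m: int | str | None
    ages: tuple[int, ...]
    segments: tuple[ExtendedValue, ...] = ()


def past_horizon(clock: PersonClock, eval_date: int) -> HorizonResult:
    """Backward sum of all per-year subjective units from ``eval_date`` to birth.

    Returns an :class:`HorizonResult` whose value separates the finite part
    from the count of hard infinities (one per clock-start year crossed,
    including birth).  The per-segment decomposition is exposed in
    ``segments``, oldest first.
    """
    starts = clock.active_starts(eval_date)  # ascending; validates eval_date
    a = clock.exponent
    segments: list[ExtendedValue] = []
    # segment j runs from its clock-start date up to the next start (or the
    # present), inclusive at both ends: boundary dates belong to both segments
    for j, seg_start in enumerate(starts):
        seg_end = eval_date if j == len(starts) - 1 else starts[j + 1]
        active = starts[: j + 1]
        seg_value = ExtendedValue()
        for date in range(seg_start, seg_end + 1):
            seg_value += _unit_from_ages([date - s for s in active], a)
        segments.append(seg_value)
    total = sum(segments, ExtendedValue())
    return HorizonResult(total, "past", None, clock.ages(eval_date), tuple(segments))


def _future_term_ages(ages: tuple[int, ...], k: int) -> list[int]:
    return [t + k for t in ages]


def future_horizon(
    clock: PersonClock,
    eval_date: int,
    m: int | str,
    include_current: bool = False,
) -> HorizonResult:
    """Forward sum of the next ``m`` per-year subjective units.

    Parameters
    ----------
    m:
        Positive integer lookahead, or the string ``"unbounded"`` for the
        open-ended horizon (no deadline).
    include_current:
        When True the sum starts at the current year's unit (k = 0) rather
        than the next one (k = 1).  The model's default convention excludes
        the current unit; worked examples that quote the current year's term
        use the inclusive form.

    An unbounded horizon is divergent — soft infinity — exactly when the
    total term exponent, (number of active clocks) × a, is <= 1; otherwise
    its finite limit is returned (series-accelerated summation, cross-checked
    in the test-suite against the telescoping closed form available at a=1
    with two clocks).
    """
    ages = clock.ages(eval_date)
    if any(t == 0 for t in ages):
        raise SingularCurrentUnitError(
            f"a clock has age 0 at {eval_date}: the current unit is itself infinite"
        )
    a = clock.exponent
    k0 = 0 if include_current else 1

    if m == UNBOUNDED:
        if len(ages) * a <= 1.0:
            value = ExtendedValue(0.0, divergent=True)
        else:
            with mpmath.workdps(30):
                total = mpmath.nsum(
                    lambda k: mpmath.fprod([(t + k) ** (-a) for t in ages]),
                    [k0, mpmath.inf],
                    tol=_SERIES_TOL,
                )
            value = ExtendedValue(float(total))
        return HorizonResult(value, "future", UNBOUNDED, ages)

    if m != int(m) or int(m) < 0:
        raise ValueError(f"m must be a non-negative integer or 'unbounded', got {m!r}")
    m = int(m)
    total = 0.0
    for k in range(m, k0 - 1, -1):  # smallest terms first
        term = 1.0
        for t in _future_term_ages(ages, k):
            term /= float(t) ** a
        total += term
    return HorizonResult(ExtendedValue(total), "future", m, ages)


def classify_infinity(result: HorizonResult) -> str:
    """Classify a horizon's infinity content: 'none', 'hard', 'soft' or 'mixed'.

    Hard infinities are localized single-term divergences (a clock's first
    unit); soft infinity is the blurred divergence of an infinite series.
    """
    hard = result.value.hard_infinities > 0
    soft = result.value.divergent
    if hard and soft:
        return "mixed"
    if hard:
        return "hard"
    if soft:
        return "soft"
    return "none"
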