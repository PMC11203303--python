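"""Person clocks, extended-value algebra, and the subjective unit of time.

The model mirrors each objective unit of time (a year, say, written ``Uo``)
with a person-specific subjective unit ``Us``.  A person who has lived ``t``
complete objective units perceives the next one as ``Us = Uo / t**a``, with a
damping exponent ``a`` in [0, 1]: ``a = 1`` is the pure inverse-proportional
model, ``a = 0`` abolishes shrinking altogether.  Ritualized socializations
("social births": weddings, graduations, ...) each start an extra counting
clock; active clocks multiply, giving ``Us = Uo / prod_i t_i**a``.

During the first unit after any clock starts, that clock's age is 0 and the
subjective unit is infinite.  This singular value is never represented as a
float ``inf``: it is counted symbolically by :class:`ExtendedValue`, whose
``hard_infinities`` field records how many zero-age factors entered a sum.
A separate ``divergent`` flag marks the "soft" infinity of a non-summable
infinite series (an unbounded future horizon) — a divergence that no single
term causes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.special import digamma

__all__ = [
    "EULER_GAMMA",
    "ExtendedValue",
    "PersonClock",
    "SubjectiveUnit",
    "harmonic_number",
    "gen_harmonic",
    "subjective_unit",
    "subjective_unit_stacked",
]

#: Euler–Mascheroni constant, the H_n − ln n limit.
EULER_GAMMA = float(np.euler_gamma)


@dataclass(frozen=True)
class ExtendedValue:
    """A finite amount of subjective time plus symbolic infinity bookkeeping.

    Parameters
    ----------
    finite:
        Finite part, in units of Uo.
    hard_infinities:
        Number of summed terms (zero-age clock factors) that were each
        individually infinite — the "hard", localized infinities.
    divergent:
        True when the value includes a non-summable infinite series — the
        "soft", unlocalized infinity.  The finite part is then the finite
        remainder tracked alongside the divergence, conventionally 0.

    Addition acts componentwise: finite parts add, hard-infinity counts add,
    divergence flags OR.  A value with ``hard_infinities == 0`` and
    ``divergent == False`` is an ordinary finite number.
    """

    finite: float = 0.0
    hard_infinities: int = 0
    divergent: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.finite):
            raise ValueError("finite part must be a finite float; infinities are counted symbolically")
        if self.hard_infinities < 0 or self.hard_infinities != int(self.hard_infinities):
            raise ValueError("hard_infinities must be a non-negative integer")

    @property
    def is_finite(self) -> bool:
        return self.hard_infinities == 0 and not self.divergent

    def __add__(self, other: "ExtendedValue | float | int") -> "ExtendedValue":
        if isinstance(other, ExtendedValue):
            return ExtendedValue(
                self.finite + other.finite,
                self.hard_infinities + other.hard_infinities,
                self.divergent or other.divergent,
            )
        if isinstance(other, (int, float)):
            return ExtendedValue(self.finite + other, self.hard_infinities, self.divergent)
        return NotImplemented

    __radd__ = __add__

    def __str__(self) -> str:
        parts = [f"{self.finite:.4f}"]
        if self.hard_infinities:
            parts.append(f"{self.hard_infinities}×∞")
        out = " + ".join(parts)
        if self.divergent:
            out += " (divergent)"
        return f"{out} Uo"


ZERO = ExtendedValue()


@dataclass(frozen=True)
class PersonClock:
    """A person's timeline: birth date, social-birth dates, damping exponent.

    Dates are plain integers in a single calendar (CE years by default); ages
    are integer counts of completed objective units.  ``event_dates`` must be
    strictly increasing and no earlier than ``birth_date``.
    """

    birth_date: int
    event_dates: tuple[int, ...] = ()
    exponent: float = 1.0
    unit_name: str = "year"

    def __post_init__(self) -> None:
        object.__setattr__(self, "event_dates", tuple(int(d) for d in self.event_dates))
        if any(b >= a for b, a in zip(self.event_dates, self.event_dates[1:])):
            raise ValueError("event_dates must be strictly increasing")
        if any(d < self.birth_date for d in self.event_dates):
            raise ValueError("every event date must be on or after the birth date")
        if not 0.0 <= self.exponent <= 1.0:
            raise ValueError(f"exponent must lie in [0, 1], got {self.exponent}")

    @property
    def start_dates(self) -> tuple[int, ...]:
        """Birth date followed by the event dates, ascending."""
        return (self.birth_date, *self.event_dates)

    def active_starts(self, eval_date: int) -> tuple[int, ...]:
        """Start dates of the clocks already running at ``eval_date``."""
        if eval_date < self.birth_date:
            raise ValueError(f"evaluation date {eval_date} precedes birth date {self.birth_date}")
        return tuple(d for d in self.start_dates if d <= eval_date)

    def ages(self, eval_date: int) -> tuple[int, ...]:
        """Integer ages t_i = eval_date − T_i of every activated clock."""
        return tuple(eval_date - d for d in self.active_starts(eval_date))

    @classmethod
    def from_config(cls, path: str | Path) -> "PersonClock":
        """Load a clock from a YAML or JSON config file.

        Recognized keys: ``birth_date`` (int, required), ``events`` (list of
        int), ``exponent`` (float, default 1.0), ``unit_name`` (str, default
        "year").
        """
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(
            birth_date=int(data["birth_date"]),
            event_dates=tuple(data.get("events", ())),
            exponent=float(data.get("exponent", 1.0)),
            unit_name=str(data.get("unit_name", "year")),
        )


@dataclass(frozen=True)
class SubjectiveUnit:
    """The subjective mirror of one objective unit at a given age vector."""

    value: ExtendedValue
    ages: tuple[int, ...]
    exponent: float


def harmonic_number(n: int) -> float:
    """n-th harmonic number H_n = sum_{k=1..n} 1/k, with H_0 = 0.

    Evaluated through the digamma function, H_n = psi(n+1) + gamma, which is
    accurate to machine precision for any n reachable in practice.
    """
    if n < 0 or n != int(n):
        raise ValueError(f"harmonic_number requires a non-negative integer, got {n}")
    if n == 0:
        return 0.0
    return float(digamma(n + 1)) + EULER_GAMMA


def gen_harmonic(n: int, a: float) -> float:
    """Generalized harmonic number sum_{t=1..n} 1/t**a for a in [0, 1].

    Reduces to :func:`harmonic_number` at ``a = 1`` and to ``n`` at ``a = 0``.
    """
    if n < 0 or n != int(n):
        raise ValueError(f"gen_harmonic requires a non-negative integer n, got {n}")
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"exponent must lie in [0, 1], got {a}")
    if a == 1.0:
        return harmonic_number(n)
    if a == 0.0:
        return float(n)
    if n == 0:
        return 0.0
    # summed smallest-first to limit rounding error
    terms = np.arange(n, 0, -1, dtype=float) ** (-a)
    return float(terms.sum())


def _unit_from_ages(ages: Sequence[int], a: float) -> ExtendedValue:
    """Product unit prod_i 1/t_i**a with zero ages counted as hard infinities."""
    hard = sum(1 for t in ages if t == 0)
    if hard:
        return ExtendedValue(0.0, hard_infinities=hard)
    value = 1.0
    for t in ages:
        value /= float(t) ** a
    return ExtendedValue(value)


def subjective_unit(t: int, a: float = 1.0) -> SubjectiveUnit:
    """Single-clock subjective unit Us = Uo / t**a at integer age ``t``.

    Age 0 — the first objective unit after birth — yields a hard infinity,
    regardless of the exponent: the singularity belongs to the discretization
    of time, not to the arithmetic of 0**a.
    """
    if t < 0 or t != int(t):
        raise ValueError(f"age must be a non-negative integer, got {t}")
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"exponent must lie in [0, 1], got {a}")
    return SubjectiveUnit(_unit_from_ages((int(t),), a), (int(t),), a)


def subjective_unit_stacked(clock: PersonClock, eval_date: int) -> SubjectiveUnit:
    """Stacked-clock subjective unit Us = Uo / prod_i t_i**a at ``eval_date``.

    The product runs over the birth clock and every event clock already
    started (T_i <= eval_date); clocks not yet activated contribute nothing.
    Each activated clock currently in its first unit (age 0) contributes one
    hard infinity.
    """
    ages = clock.ages(eval_date)
    return SubjectiveUnit(_unit_from_ages(ages, clock.exponent), ages, clock.exponent)
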