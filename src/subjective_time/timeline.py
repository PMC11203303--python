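"""Per-year timeline reports, figure-series regeneration, synthetic persons.

A :class:`TimelineReport` tabulates, for each age of a person, the subjective
unit current that year, the cumulative subjective age, the past-horizon
finite part, and optionally a fixed-lookahead future horizon.  Extended
values are serialized as separate numeric columns (finite part, hard-infinity
count, divergence flag) — never as the string "inf" in a numeric field — so
reports survive CSV/JSON round trips bit-for-bit.

:func:`figure_data` regenerates the numeric series behind the model's
standard illustrative plots (unit-shrinking curves, duration and speed
curves, horizon term profiles, power-law damping, stacked-clock piecewise
units), and :func:`generate_fixtures` draws seeded synthetic person clocks
for property testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ExtendedValue, PersonClock, subjective_unit_stacked
from .durations import continuous_duration, discrete_duration, subjective_speed
from .horizons import future_horizon, past_horizon

__all__ = [
    "TimelineReport",
    "FixtureSpec",
    "build_timeline",
    "figure_data",
    "generate_fixtures",
    "SUPPORTED_FIGURES",
]


@dataclass
class TimelineReport:
    """A per-age table of subjective-time quantities for one person."""

    data: pd.DataFrame
    clock: PersonClock | None = None
    lookahead: int | None = None

    def round(self, decimals: int = 4) -> pd.DataFrame:
        """Display copy at the default report precision (full precision is kept internally)."""
        return self.data.round(decimals)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, clock: PersonClock | None = None) -> "TimelineReport":
        return cls(pd.read_csv(path), clock=clock)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "clock": None
            if self.clock is None
            else {
                "birth_date": self.clock.birth_date,
                "events": list(self.clock.event_dates),
                "exponent": self.clock.exponent,
                "unit_name": self.clock.unit_name,
            },
            "lookahead": self.lookahead,
            "rows": self.data.to_dict(orient="records"),
        }
        import json

        Path(path).write_text(json.dumps(payload, indent=1, allow_nan=False, default=_jsonify))

    @classmethod
    def from_json(cls, path: str | Path) -> "TimelineReport":
        import json

        payload = json.loads(Path(path).read_text())
        clock = None
        if payload["clock"] is not None:
            c = payload["clock"]
            clock = PersonClock(c["birth_date"], tuple(c["events"]), c["exponent"], c["unit_name"])
        df = pd.DataFrame(payload["rows"])
        return cls(df, clock=clock, lookahead=payload.get("lookahead"))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def build_timeline(
    clock: PersonClock,
    from_age: int,
    to_age: int,
    lookahead: int | None = None,
) -> TimelineReport:
    """One row per age from ``from_age`` to ``to_age`` inclusive.

    Columns: the subjective unit and the cumulative subjective age (each as
    finite part + hard-infinity count), the past-horizon finite part and its
    hard-infinity count, and — when ``lookahead`` is given — the finite
    future horizon over the next ``lookahead`` units (empty on singular rows,
    where a clock is in its first unit and the current unit is infinite).

    The cumulative subjective age accumulates the units from age 0, so the
    row at ``from_age`` already carries the person's whole lived time; rows
    telescope exactly (cumulative at t = cumulative at t−1 + unit at t).
    """
    if not 0 <= from_age <= to_age:
        raise ValueError(f"need 0 <= from_age <= to_age, got {from_age}..{to_age}")
    rows = []
    cumulative = ExtendedValue()
    for age in range(0, to_age + 1):
        date = clock.birth_date + age
        unit = subjective_unit_stacked(clock, date).value
        cumulative += unit
        if age < from_age:
            continue
        past = past_horizon(clock, date).value
        row = {
            "age": age,
            "unit_finite": unit.finite,
            "unit_hard": unit.hard_infinities,
            "cumulative_finite": cumulative.finite,
            "cumulative_hard": cumulative.hard_infinities,
            "past_finite": past.finite,
            "past_hard": past.hard_infinities,
        }
        if lookahead is not None:
            singular = any(t == 0 for t in clock.ages(date))
            row["future_finite"] = (
                math.nan if singular else future_horizon(clock, date, lookahead).value.finite
            )
        rows.append(row)
    return TimelineReport(pd.DataFrame(rows), clock=clock, lookahead=lookahead)


# ---------------------------------------------------------------------------
# figure series

SUPPORTED_FIGURES = (2, 3, 4, 5, 6, 7, 8, 9, 10, 11)

_POWER_LAW_EXPONENTS = (1.0, 0.5, 0.4, 0.3, 0.2, 0.1, 0.0)


def _unit_series(clock: PersonClock, ages: Sequence[int]) -> pd.DataFrame:
    rows = []
    for t in ages:
        u = subjective_unit_stacked(clock, clock.birth_date + t).value
        rows.append({"t": t, "unit": u.finite if u.hard_infinities == 0 else math.nan,
                     "hard": u.hard_infinities})
    return pd.DataFrame(rows)


def figure_data(figure_id: int) -> pd.DataFrame:
    """Regenerate the numeric series behind one of the standard figures (2–11).

    2:  single-clock unit 1/t over the first 30 years (a=1)
    3:  discrete vs continuous duration from t1=1, and their gap
    4:  discrete/continuous speeds and durations from t1=1; objective speed 1
    5:  backward per-year terms of a 20-year-old's past horizon (finite ones)
    6:  forward per-year terms of a 20-year-old's 10-year future horizon
    7:  figures 5 and 6 combined, tagged by direction
    8:  power-law units 1/t**a for a in {1, 0.5, 0.4, 0.3, 0.2, 0.1, 0}
    9:  square-root damping a=0.5 over 30 years (a=1 inset column)
    10: two clocks — social birth at age 20 — over 50 years, a=1
    11: three clocks — social births at ages 10 and 30 — over 50 years, a=0.2
    """
    if figure_id not in SUPPORTED_FIGURES:
        raise ValueError(f"unknown figure id {figure_id}; supported: {SUPPORTED_FIGURES}")

    if figure_id == 2:
        return _unit_series(PersonClock(0), range(1, 31))

    if figure_id in (3, 4):
        rows = []
        for t2 in range(2, 101):
            d = discrete_duration(1, t2).value
            c = continuous_duration(1, t2).value
            row = {"t2": t2, "duration_discrete": d, "duration_continuous": c}
            if figure_id == 3:
                row["gap"] = abs(d - c)
            else:
                row["speed_discrete"] = subjective_speed(1, t2, mode="discrete").value
                row["speed_continuous"] = subjective_speed(1, t2, mode="continuous").value
                row["speed_objective"] = 1.0
            rows.append(row)
        return pd.DataFrame(rows)

    if figure_id in (5, 6, 7):
        t = 20
        past = pd.DataFrame(
            {"offset": range(0, t), "term": [1.0 / (t - k) for k in range(0, t)],
             "direction": "past"}
        )
        future = pd.DataFrame(
            {"offset": range(0, 11), "term": [1.0 / (t + k) for k in range(0, 11)],
             "direction": "future"}
        )
        if figure_id == 5:
            return past.drop(columns="direction")
        if figure_id == 6:
            return future.drop(columns="direction")
        return pd.concat([past, future], ignore_index=True)

    if figure_id == 8:
        rows = []
        for a in _POWER_LAW_EXPONENTS:
            for t in range(1, 31):
                rows.append({"t": t, "exponent": a, "unit": 1.0 / t**a})
        return pd.DataFrame(rows)

    if figure_id == 9:
        df = _unit_series(PersonClock(0, exponent=0.5), range(1, 31))
        df["unit_inset_a1"] = [1.0 / t for t in range(1, 31)]
        return df.drop(columns="hard")

    if figure_id == 10:
        clock = PersonClock(0, event_dates=(20,), exponent=1.0)
        return _unit_series(clock, range(0, 51))

    # figure 11
    clock = PersonClock(0, event_dates=(10, 30), exponent=0.2)
    return _unit_series(clock, range(0, 51))


# ---------------------------------------------------------------------------
# synthetic persons

@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for seeded synthetic person clocks.

    Defaults mirror the model's framing of ritual socializations: each person
    has few of them (0–4) and they fall within the first thirty years of
    life.  The exponent is fixed at 1.0 unless a range is supplied.
    """

    count: int = 100
    birth_range: tuple[int, int] = (1950, 2010)
    events_range: tuple[int, int] = (0, 4)
    event_age_window: tuple[int, int] = (1, 30)
    exponent_range: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.count <= 0:
            raise ValueError("count must be positive")
        for name in ("birth_range", "events_range", "event_age_window", "exponent_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is empty: {(lo, hi)}")
        if self.events_range[1] - self.events_range[0] + 1 > 0 and self.events_range[0] < 0:
            raise ValueError("events_range must be non-negative")


def generate_fixtures(spec: FixtureSpec) -> list[PersonClock]:
    """Draw ``spec.count`` synthetic person clocks, deterministic under seed."""
    rng = np.random.default_rng(spec.seed)
    lo_age, hi_age = spec.event_age_window
    n_ages = hi_age - lo_age + 1
    clocks = []
    for _ in range(spec.count):
        birth = int(rng.integers(spec.birth_range[0], spec.birth_range[1] + 1))
        n_events = int(rng.integers(spec.events_range[0], spec.events_range[1] + 1))
        n_events = min(n_events, n_ages)  # strict ordering needs distinct ages
        ages = sorted(rng.choice(np.arange(lo_age, hi_age + 1), size=n_events, replace=False))
        lo_a, hi_a = spec.exponent_range
        a = float(lo_a) if lo_a == hi_a else float(rng.uniform(lo_a, hi_a))
        clocks.append(PersonClock(birth, tuple(birth + int(x) for x in ages), a))
    return clocks
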