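# subjective-time

A calculator and simulator for the individual, subjective passage of time.
It implements a simple quantitative model in which each objective unit of
time `Uo` (the year, say) is mirrored by a person-specific subjective unit

    Us = Uo / ∏ᵢ tᵢᵃ ,

where the `tᵢ` are the integer ages of the person's counting clocks — the
birth clock plus one clock per ritual socialization ("social birth":
wedding, graduation, ... each starting a new count) — and `a ∈ [0, 1]` is a
power-law damping exponent (`a = 1` is the pure inverse-proportional model,
`a = 0` abolishes shrinking).

From the unit follow, for any person timeline:

- **subjective durations** of objective intervals: discrete mode sums the
  per-year units (`d_s = H_{t2} − H_{t1}` in harmonic numbers at `a = 1`,
  generalized power sums otherwise), continuous mode integrates
  (`ln(t2/t1)`, or `(t2^{1−a} − t1^{1−a})/(1−a)`);
- the **speed of time**, the dimensionless ratio of subjective to objective
  duration;
- the **past horizon**, the backward sum of every subjective year already
  lived, and the **future horizon**, the forward sum over the next `m`
  years or over an unbounded future.

Horizons are not plain floats: every clock's first year is an infinite term.
The package tracks these symbolically in an extended value — a finite part,
a count of localized **hard infinities** (zero-age terms), and a flag for
the **soft infinity** of a divergent series (an unbounded future horizon
with `L` active clocks diverges exactly when `L·a ≤ 1`). The model's
signature result falls out of that bookkeeping: with a single clock the
anticipated future is endless, and the first social birth makes it finite.

Intended for anyone exploring psychophysical / sociophysical models of time
perception who wants the model's arithmetic — worked examples included —
reproducible from Python or a shell.

## Worked example

```python
from subjective_time import PersonClock, past_horizon, future_horizon

person = PersonClock(birth_date=2004)            # evaluated in 2024, age 20
print(past_horizon(person, 2024).value)           # 3.5977 + 1×∞ Uo
print(future_horizon(person, 2024, 10, include_current=True).value)  # 0.4472 Uo

married = PersonClock(birth_date=2004, event_dates=(2034,))
h = past_horizon(married, 2044)                   # two clocks, age 40 and 10
print([str(s) for s in h.segments])
# ['3.9950 + 1×∞ Uo', '0.0882 + 1×∞ Uo']  ->  total 4.0832 + 2×∞ Uo
```

The first line says 20 lived years feel, summed backwards, like 3.598 felt
years plus the single hard infinity of the birth year; the second that the
coming decade feels like less than half a year. After a social birth at age
30 the past horizon splits into a birth-clock segment (`H_30 ≈ 3.995`) and a
two-clock segment (`Σ 1/(k(k+30)) ≈ 0.088`) carrying a second hard infinity.

The scripts in `examples/` tell the same stories end to end
(`python examples/horizons.py`, etc.), and the same operations are exposed
by a thin CLI:

```bash
subjective-time horizon --birth 2004 --now 2024 --direction past
subjective-time timeline --birth 2004 --events 2034 --to-age 50 --format csv
```

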