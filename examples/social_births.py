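"""Stacked clocks: what a ritual socialization does to felt time.

A "social birth" (wedding, graduation, ...) starts an extra counting clock;
active clocks multiply, Us = Uo / (t * t1 * ...).  The event year is a new
moment of infinity, afterwards time shrinks faster — and the open-ended
future horizon, divergent with one clock, becomes finite: the person exits
"eternity".
"""

from subjective_time import PersonClock, build_timeline, future_horizon, past_horizon

person = PersonClock(birth_date=2004, event_dates=(2034,))

print("Units around the social birth at age 30:")
report = build_timeline(person, 28, 33)
for _, row in report.data.iterrows():
    mark = " <- social birth (hard infinity)" if row["unit_hard"] else ""
    print(f"  age {int(row['age'])}: {row['unit_finite']:.6f} Uo"
          f" + {int(row['unit_hard'])}x inf{mark}")

print()
past = past_horizon(person, 2044)
print("Past horizon at 2044:", past.value)
print("  segments (oldest first):", ", ".join(str(s) for s in past.segments))

before = future_horizon(PersonClock(2004), 2024, "unbounded")
after = future_horizon(person, 2044, "unbounded")
print()
print("Open-ended future before the ritual:", before.value)
print("Open-ended future after the ritual: ", after.value)
print()
print("The ritual's price: the endless (soft-infinite) future becomes a")
print("finite remainder; its reward: one more lived moment of infinity.")
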