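"""Past and future horizons of a 20-year-old, and their infinities.

Looking back, the backward sum of all lived subjective years is finite
except for the single infinite birth-year term — a localized "hard"
infinity.  Looking 10 years ahead gives less than half a felt year; looking
ahead without a deadline diverges — the blurred "soft" infinity of an
endless anticipated life.
"""

from subjective_time import PersonClock, classify_infinity, future_horizon, past_horizon

person = PersonClock(birth_date=2004)

past = past_horizon(person, 2024)
print("Past horizon at age 20:   ", past.value, f"[{classify_infinity(past)}]")

ahead10 = future_horizon(person, 2024, 10, include_current=True)
print("Next 10 years (inclusive):", ahead10.value)

open_ended = future_horizon(person, 2024, "unbounded")
print("Open-ended future:        ", open_ended.value, f"[{classify_infinity(open_ended)}]")

print()
print("20 lived years feel like ~3.6 felt years plus one sudden infinity;")
print("the next decade feels like under half a year; an unbounded future")
print("still feels endless — until a second clock starts (see social_births).")
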