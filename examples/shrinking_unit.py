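"""How one objective year feels at different ages.

The subjective unit of time is Us = Uo / t**a: for a person who has lived t
complete years, the next year feels like 1/t**a of a year.  With a = 1 a
20-year-old's year feels like 5% of a year; damping with a = 0.5 softens the
shrinking.
"""

from subjective_time import subjective_unit

print("age   a=1      a=0.5")
for t in (1, 4, 10, 20, 30):
    u1 = subjective_unit(t, 1.0).value.finite
    u5 = subjective_unit(t, 0.5).value.finite
    print(f"{t:3d}   {u1:.4f}   {u5:.4f}")

print()
print("Each value is the felt length of one year, in objective years (Uo).")
print("At age 0 the unit is a hard infinity:", subjective_unit(0).value)
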