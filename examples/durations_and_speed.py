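"""Felt length of life intervals, and the speed at which time passes.

Discrete durations are harmonic-number differences; in continuous time they
become logarithms, so any interval whose endpoints are both scaled by k is
felt identically: 6->12, 12->24, 24->48 years all feel like ln 2 ~ 0.69 of a
year.  Meanwhile the felt speed of time (subjective per objective year)
keeps slowing.
"""

from subjective_time import continuous_duration, discrete_duration, subjective_speed

print("Doubling intervals, continuous mode (all equal ln 2):")
for t1, t2 in [(6, 12), (12, 24), (24, 48), (48, 96)]:
    d = continuous_duration(t1, t2).value
    print(f"  [{t1:2d}, {t2:2d}] years  ->  {d:.4f} Uo")

print()
print("Duration grows while speed slows (from age 1 out to t2):")
print("t2   duration(Uo)  speed")
for t2 in (2, 5, 10, 20, 50, 100):
    d = discrete_duration(1, t2).value
    v = subjective_speed(1, t2).value
    print(f"{t2:3d}   {d:.4f}       {v:.4f}")
print()
print("The longer the lived stretch, the longer it feels in total — yet the")
print("slower each of its years passes: the model's young/old paradox.")
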