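# Methods

## Model

Time is counted in discrete objective units `Uo` (years by default). A
person is a set of counting clocks: the birth clock starting at date `T0`
and zero or more social-birth clocks starting at strictly increasing dates
`T1 < T2 < …`, each created by a ritual socialization. At an evaluation
date `T`, clock `i` is *active* if `Tᵢ ≤ T`, and its age is the integer
count of completed units `tᵢ = T − Tᵢ`. The subjective mirror of one
objective unit is

    Us = Uo / ∏_{active i} tᵢᵃ ,   a ∈ [0, 1].

Ages are completed units, so during the first unit after any clock's start
that clock's age is 0 and `Us` is infinite. This singularity is a property
of the discretization (the first unit of a new count has no earlier units to
compare against), not of `0ᵃ` arithmetic; it is therefore kept for every
exponent, including `a = 0`. Clocks not yet started contribute a factor of
exactly 1 — they do not exist yet — which is what makes stacked-unit curves
piecewise, with one singular year at each activation.

### Extended values

Infinite terms are never represented as float `inf`. Every sum of units
returns an extended value `(finite, hard_infinities, divergent)`:

- `finite` — the sum of the ordinary terms, in `Uo`;
- `hard_infinities` — the number of zero-age factors encountered, each a
  localized, single-term ("hard") divergence;
- `divergent` — set when a non-summable infinite series ("soft" infinity)
  is part of the value.

Addition is componentwise (finite parts add, counts add, flags OR), which
makes the algebra associative and commutative with the zero value as
identity — so a result like "3.995 + 0.088 + 2×∞" is representable and
testable exactly.

### Durations and speed

For integer ages `1 ≤ t1 < t2` the discrete subjective duration is the
power sum `Σ_{t=t1+1..t2} t^{−a}` — a difference of generalized harmonic
numbers, `H_{t2} − H_{t1}` at `a = 1`. The continuous counterpart is the
integral, `ln(t2/t1)` at `a = 1` and `(t2^{1−a} − t1^{1−a})/(1−a)` below
it. The subjective speed of time over an interval is duration divided by
`t2 − t1`; with `a = 0` it equals the objective speed, exactly 1.

Intervals starting at age 0 are rejected by the duration functions: the
age-0 term is a hard infinity, and all infinity bookkeeping lives in the
horizon functions.

The discrete−continuous gap from `t1 = 1`, `|H_{t2} − 1 − ln t2|` at
`a = 1`, plateaus quickly near 0.42 and converges to `1 − γ ≈ 0.4228`
(γ the Euler–Mascheroni constant); the package reports the gap pointwise
and exposes the asymptote as a constant, since the plateau value depends
(weakly) on where one reads it.

### Horizons

The **past horizon** at date `T` walks backwards over every lived year and
adds the unit that was current then, evaluated with the clocks active at
that time. The walk is organized in segments delimited by clock starts,
and each boundary date is counted in *both* adjacent segments: once as the
zero-age hard-infinity term that opens the newer segment, and once as the
ordinary oldest term of the older one (for a social birth at age 30 seen
ten years later, the boundary year contributes both `1/(0·30)` and `1/30`).
This double counting is the model's own worked bookkeeping — it is the only
reading that reproduces the reference decomposition `3.995 + 0.088 + 2×∞` —
and means a horizon with one social birth has `t + 2` terms rather than
`t + 1`. Segment subtotals are returned alongside the total, oldest first.
A past horizon always carries at least the birth hard infinity. The damping
exponent applies uniformly to every factor of every segment.

The **future horizon** sums the coming per-year units
`∏ᵢ (tᵢ + k)^{−a}` for `k = 1..m`. The default convention excludes the
current year's unit (`k` starts at 1); the inclusive convention (`k = 0`)
is available via `include_current=True`, because the model's worked
10-year example quotes the current year's term. `m = 0` with the exclusive
convention is the empty sum, 0, not an error. If any active clock has age 0
at evaluation the current unit is itself infinite and a dedicated
`SingularCurrentUnitError` is raised rather than summing.

With `m` unbounded and `L` active clocks, the terms decay like `k^{−La}`,
so by comparison with the harmonic series the horizon diverges — soft
infinity — iff `L·a ≤ 1`. The boundary case (e.g., two clocks at
`a = 0.5`) diverges and is flagged as such. Convergent cases are evaluated
with mpmath's accelerated series summation (`nsum`, 30 working digits,
tolerance 1e−12), well beyond the reported precision; the two-clock `a = 1`
case has an exact telescoping closed form,
`Σ_k 1/((t+k)(t₁+k)) = (H_t − H_{t₁})/(t − t₁)`, which the test-suite uses
as an independent cross-check at 1e−9.

## Numerical choices

- Harmonic numbers go through the digamma identity `H_n = ψ(n+1) + γ`
  (machine precision at any n); generalized power sums are summed
  smallest-term-first. Both are verified against naive term-by-term loops.
- The continuous power-law duration is computed as
  `(expm1(ε·ln t2) − expm1(ε·ln t1))/ε` with `ε = 1 − a`. This form is
  stable for arbitrarily small `ε`, so no branch-switch threshold is
  needed: the only special case is `ε = 0` exactly, where the log form is
  used, and the two branches agree to machine precision at the boundary.
- Hard infinities are counted per zero-age factor within each summed term;
  in every model scenario each singular term has exactly one zero factor,
  so the count equals the number of clock-start years crossed.

## Tunable parameters

- `exponent a` (default 1.0, range [0, 1]): power-law damping of the
  shrinking; 1 is the pure inverse-proportional model, 0.5 the square-root
  variant, 0 no shrinking. One exponent applies to all stacked factors.
- `include_current` (default False): whether a future horizon starts at the
  current year's unit.
- `unit_name` (default "year"): a label only; all arithmetic is in abstract
  objective units.

## Synthetic persons

`FixtureSpec`/`generate_fixtures` draw seeded person timelines for property
testing: births uniform in a calendar window (default 1950–2010), 0–4
social births per person at distinct ages within the first thirty years of
life (the model's framing of ritual socializations: few, and early), and a
fixed exponent of 1.0 unless a range is given. The generator emulates the
*structure* of real timelines (ordering, sparsity, early clustering), not
any empirical distribution of life events — passing property tests shows
the bookkeeping is sound over that structure, not that the model fits
psychological data, which the package makes no claim about.

## Report sizes and precision

Timeline reports carry full double precision internally and print at four
decimals by default. Figure series are regenerated over the ranges the
curves are meant to illustrate (ages 1–30 or 0–50, interval endpoints
2–100); the acceptance script's quantities are desk-scale sums (tens of
terms) and run in well under a second.

## Limitations

- Dates are plain integers in one calendar; no mixed units, fractional
  years in discrete mode, or real calendar arithmetic.
- Per-clock exponents are not supported (one `a` for all factors).
- The "mortal/eternal" language of the stacked-clock result is modeled
  strictly as convergence classification of the unbounded future horizon;
  no claim about longevity or mortality is made.
- The continuous mode is a smooth reading of the same hypothesis; the
  discrete mode is authoritative for all worked numbers.
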