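"""Past/future horizons: finite parts, hard and soft infinities."""

import math

import pytest

from subjective_time import (
    FixtureSpec,
    PersonClock,
    SingularCurrentUnitError,
    classify_infinity,
    future_horizon,
    generate_fixtures,
    harmonic_number,
    past_horizon,
)


class TestPastHorizon:
    def test_twenty_year_old(self):
        """Born 2004, evaluated 2024: H_20 plus the birth singularity."""
        res = past_horizon(PersonClock(2004), 2024)
        assert round(res.value.finite, 3) == 3.598
        assert res.value.hard_infinities == 1
        assert not res.value.divergent
        assert res.value.finite == pytest.approx(harmonic_number(20), rel=1e-12)

    def test_at_birth_only_the_singular_term(self):
        res = past_horizon(PersonClock(1990), 1990)
        assert res.value.finite == 0.0
        assert res.value.hard_infinities == 1

    def test_two_clock_worked_example(self):
        """Born 2004, social birth 2034, evaluated 2044: [3.995 + 0.088 + 2×∞]."""
        res = past_horizon(PersonClock(2004, (2034,)), 2044)
        birth_seg, event_seg = res.segments
        assert round(birth_seg.finite, 3) == 3.995
        assert round(event_seg.finite, 3) == 0.088
        assert birth_seg.hard_infinities == event_seg.hard_infinities == 1
        assert res.value.hard_infinities == 2
        assert res.value.finite == pytest.approx(birth_seg.finite + event_seg.finite)

    def test_two_clock_segment_matches_loop_oracle(self):
        res = past_horizon(PersonClock(2004, (2034,)), 2044)
        oracle = math.fsum(1.0 / (k * (k + 30)) for k in range(1, 11))
        assert res.segments[1].finite == pytest.approx(oracle, rel=1e-12)
        assert res.segments[0].finite == pytest.approx(harmonic_number(30), rel=1e-12)

    def test_eval_before_birth_rejected(self):
        with pytest.raises(ValueError):
            past_horizon(PersonClock(2004), 1999)

    def test_hard_infinity_count_equals_activated_clocks(self):
        clock = PersonClock(2000, (2005, 2010, 2020))
        assert past_horizon(clock, 2002).value.hard_infinities == 1
        assert past_horizon(clock, 2007).value.hard_infinities == 2
        assert past_horizon(clock, 2030).value.hard_infinities == 4


class TestFutureHorizon:
    def test_worked_example_inclusive(self):
        """A 20-year-old looking 10 years ahead, current year included."""
        res = future_horizon(PersonClock(2004), 2024, 10, include_current=True)
        assert round(res.value.finite, 4) == 0.4472

    def test_default_convention_excludes_current(self):
        res = future_horizon(PersonClock(2004), 2024, 10)
        assert res.value.finite == pytest.approx(
            harmonic_number(30) - harmonic_number(20), rel=1e-12
        )
        assert round(res.value.finite, 4) == 0.3972

    def test_single_clock_unbounded_diverges(self):
        res = future_horizon(PersonClock(2004), 2024, "unbounded")
        assert res.value.divergent
        assert res.value.hard_infinities == 0

    def test_two_clock_unbounded_telescopes(self):
        """Sum of 1/((40+k)(10+k)) equals (H_40 - H_10)/30 to 1e-9."""
        res = future_horizon(PersonClock(2004, (2034,)), 2044, "unbounded")
        closed_form = (harmonic_number(40) - harmonic_number(10)) / 30
        assert not res.value.divergent
        assert res.value.finite == pytest.approx(closed_form, abs=1e-9)

    def test_two_clock_unbounded_matches_partial_sums(self):
        res = future_horizon(PersonClock(2004, (2034,)), 2044, "unbounded")
        partial = math.fsum(1.0 / ((40 + k) * (10 + k)) for k in range(1, 200_000))
        assert res.value.finite == pytest.approx(partial, abs=1e-5)
        assert res.value.finite > partial  # tail is positive

    def test_empty_lookahead_is_zero_not_error(self):
        res = future_horizon(PersonClock(2004), 2024, 0)
        assert res.value.finite == 0.0
        assert res.value.is_finite

    def test_singular_current_unit_signalled(self):
        with pytest.raises(SingularCurrentUnitError):
            future_horizon(PersonClock(2004, (2024,)), 2024, 10)

    def test_no_hard_infinities_ever(self):
        for clock, date in [
            (PersonClock(2000), 2030),
            (PersonClock(2000, (2010,)), 2030),
            (PersonClock(2000, (2010, 2020), 0.5), 2030),
        ]:
            res = future_horizon(clock, date, 50, include_current=True)
            assert res.value.hard_infinities == 0

    def test_monotone_assembly(self):
        """Extending the lookahead by one adds exactly the next term."""
        clock = PersonClock(2000, (2010,), 0.7)
        for m in range(0, 12):
            lo = future_horizon(clock, 2025, m).value.finite
            hi = future_horizon(clock, 2025, m + 1).value.finite
            k = m + 1
            term = 1.0 / ((25 + k) * (15 + k)) ** 0.7
            assert hi - lo == pytest.approx(term, rel=1e-12)

    @pytest.mark.parametrize(
        "events, a, divergent",
        [
            ((), 1.0, True),          # one clock, a=1: harmonic, diverges
            ((2010,), 1.0, False),    # two clocks, a=1: terms ~ 1/k^2, converges
            ((2010,), 0.5, True),     # two clocks, a=0.5: boundary case, diverges
        ],
    )
    def test_convergence_threshold(self, events, a, divergent):
        clock = PersonClock(2000, events, a)
        res = future_horizon(clock, 2025, "unbounded")
        assert res.value.divergent is divergent

    def test_social_birth_makes_future_finite(self):
        """The first extra clock turns the endless anticipated future bounded."""
        before = future_horizon(PersonClock(2000), 2025, "unbounded")
        after = future_horizon(PersonClock(2000, (2020,)), 2025, "unbounded")
        assert before.value.divergent
        assert after.value.is_finite
        assert after.value.finite > 0


class TestClassification:
    def test_past_horizon_is_hard(self):
        assert classify_infinity(past_horizon(PersonClock(2004), 2024)) == "hard"

    def test_unbounded_single_clock_future_is_soft(self):
        assert classify_infinity(future_horizon(PersonClock(2004), 2024, "unbounded")) == "soft"

    def test_finite_future_is_none(self):
        assert classify_infinity(future_horizon(PersonClock(2004), 2024, 10)) == "none"

    def test_fixture_population_properties(self):
        """Over seeded synthetic persons: past horizons always hard, a=1
        single-clock unbounded futures always soft."""
        clocks = generate_fixtures(FixtureSpec(count=40, seed=3))
        for clock in clocks:
            eval_date = clock.start_dates[-1] + 5
            past = past_horizon(clock, eval_date)
            assert past.value.hard_infinities >= 1
            assert classify_infinity(past) == "hard"
            solo = PersonClock(clock.birth_date, (), 1.0)
            assert classify_infinity(future_horizon(solo, eval_date, "unbounded")) == "soft"
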