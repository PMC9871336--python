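"""Kinetic-race algebra: probabilities, rate conversions, unit propagation."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from kinrace import (
    DomainError,
    RateEstimate,
    UndefinedRaceError,
    Unit,
    UnitError,
    detach_probability,
    detach_rate_from_affinity,
    fold_change,
    off_rate_from_dwell,
    race_table,
    run_length_in_steps_from_p,
    stepping_rate_from_velocity,
    steps_from_run_length,
    tethered_head_on_rate,
)
from kinrace.race import render_race_table, round_half_up, round_sig

positive_rates = st.floats(min_value=1e-6, max_value=1e6)


class TestDetachProbability:
    @pytest.mark.parametrize(
        "kd, kon, approximate, expected",
        [
            (1.0, 1.0, False, 0.5),
            (0.0, 208.0, False, 0.0),
            (0.56, 208.0, False, 0.56 / 208.56),
            (0.56, 208.0, True, 0.56 / 208.0),
        ],
    )
    def test_examples(self, kd, kon, approximate, expected):
        assert detach_probability(kd, kon, approximate) == pytest.approx(
            expected, rel=1e-12
        )

    def test_both_zero_is_undefined(self):
        with pytest.raises(UndefinedRaceError):
            detach_probability(0.0, 0.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(DomainError):
            detach_probability(-1.0, 5.0)

    @given(kd=positive_rates, kon=positive_rates)
    def test_exact_mode_round_trip(self, kd, kon):
        """1 / p_detach equals (kon + kd)/kd to machine precision."""
        p = detach_probability(kd, kon)
        assert run_length_in_steps_from_p(p) == pytest.approx(
            (kon + kd) / kd, rel=1e-12
        )

    @given(kd=positive_rates, kon=positive_rates)
    def test_approximation_error_bounded_by_p(self, kd, kon):
        """Exact and first-order forms agree to O(p) for rare detachment."""
        p = detach_probability(kd, kon)
        if p < 0.5:
            approx = detach_probability(kd, kon, approximate=True)
            assert abs(p - approx) / approx <= p * (1 + 1e-9)


class TestStepsAndRates:
    @pytest.mark.parametrize("p, expected", [(1.0, 1.0), (0.5, 2.0)])
    def test_steps_from_p(self, p, expected):
        assert run_length_in_steps_from_p(p) == expected

    @pytest.mark.parametrize("bad_p", [0.0, -0.1, 1.5])
    def test_steps_from_p_domain(self, bad_p):
        with pytest.raises(DomainError):
            run_length_in_steps_from_p(bad_p)

    def test_steps_from_run_length(self):
        rl = RateEstimate(3.0, 0.02, Unit.MICROMETER)
        steps = steps_from_run_length(rl)
        assert steps.value == pytest.approx(375.0)
        assert steps.ci95 == pytest.approx(2.5)  # rounds up to the reported 3
        assert steps.unit is Unit.DIMENSIONLESS
        one = steps_from_run_length(RateEstimate(0.008, 0.0, Unit.MICROMETER))
        assert one.value == pytest.approx(1.0)

    def test_off_rate_from_dwell_preserves_relative_ci(self):
        off = off_rate_from_dwell(RateEstimate(1.8, 0.08, Unit.SECOND))
        assert off.value == pytest.approx(1 / 1.8)
        assert off.relative_ci == pytest.approx(0.08 / 1.8)
        assert off.unit is Unit.PER_SECOND
        with pytest.raises(DomainError):
            off_rate_from_dwell(RateEstimate(0.0, 0.0, Unit.SECOND))

    def test_tethered_head_on_rate(self):
        off = RateEstimate(1.0, 0.0, Unit.PER_SECOND)
        steps = RateEstimate(1.0, 0.0, Unit.DIMENSIONLESS)
        assert tethered_head_on_rate(off, steps).value == 1.0
        kon = tethered_head_on_rate(
            RateEstimate(1 / 1.8, 0.08 / 1.8**2, Unit.PER_SECOND),
            RateEstimate(375.0, 2.5, Unit.DIMENSIONLESS),
        )
        assert round_half_up(kon.value) == 208

    def test_detach_rate_from_affinity(self):
        kd18 = detach_rate_from_affinity(
            RateEstimate(1.7, 1.0, Unit.MICROMOLAR),
            RateEstimate(10.6, 0.5, Unit.PER_MICROMOLAR_PER_SECOND),
        )
        assert kd18.value == pytest.approx(18.02)
        assert kd18.unit is Unit.PER_SECOND
        kd66 = detach_rate_from_affinity(
            RateEstimate(7.2, 5.1, Unit.MICROMOLAR),
            RateEstimate(9.1, 2.5, Unit.PER_MICROMOLAR_PER_SECOND),
        )
        assert kd66.value == pytest.approx(65.52)

    @pytest.mark.parametrize(
        "velocity, step, expected", [(1.7, 8, 212.5), (0.0, 8, 0.0), (0.8, 8, 100.0)]
    )
    def test_stepping_rate(self, velocity, step, expected):
        assert stepping_rate_from_velocity(velocity, step) == pytest.approx(expected)

    def test_fold_change(self):
        six = fold_change(
            RateEstimate(3.0, 0.0, Unit.MICROMETER),
            RateEstimate(0.5, 0.0, Unit.MICROMETER),
        )
        assert six.value == pytest.approx(6.0)
        assert six.unit is Unit.DIMENSIONLESS
        x = RateEstimate(2.0, 0.2, Unit.MICROMETER)
        same = fold_change(x, x)
        assert same.value == 1.0
        assert same.relative_ci == pytest.approx(math.sqrt(2) * x.relative_ci)

    def test_fold_change_unit_mismatch(self):
        with pytest.raises(UnitError):
            fold_change(
                RateEstimate(3.0, 0.0, Unit.MICROMETER),
                RateEstimate(0.5, 0.0, Unit.SECOND),
            )


class TestUnitAlgebra:
    def test_concentration_times_bimolecular_rate_is_per_second(self):
        out = RateEstimate(2.0, 0.0, Unit.MICROMOLAR) * RateEstimate(
            3.0, 0.0, Unit.PER_MICROMOLAR_PER_SECOND
        )
        assert out.unit is Unit.PER_SECOND

    def test_unnameable_combination_raises(self):
        with pytest.raises(UnitError):
            _ = RateEstimate(1.0, 0.0, Unit.MICROMETER) * RateEstimate(
                1.0, 0.0, Unit.SECOND
            )

    @given(
        a=positive_rates, b=positive_rates,
        ra=st.floats(min_value=0, max_value=0.5),
        rb=st.floats(min_value=0, max_value=0.5),
    )
    def test_relative_ci_quadrature(self, a, b, ra, rb):
        """Relative CI of products/quotients is the quadrature of the inputs'."""
        x = RateEstimate(a, a * ra, Unit.SECOND)
        y = RateEstimate(b, b * rb, Unit.DIMENSIONLESS)
        expected = math.hypot(ra, rb)
        assert (x * y).relative_ci == pytest.approx(expected, abs=1e-9)
        assert (x / y).relative_ci == pytest.approx(expected, abs=1e-9)

    def test_negative_value_rejected(self):
        with pytest.raises(DomainError):
            RateEstimate(-1.0, 0.0, Unit.SECOND)


class TestRaceTable:
    def _rows(self, frame):
        return [
            {
                "construct": rec["construct"],
                "dwell": RateEstimate(rec["dwell_s"], rec["dwell_ci"], Unit.SECOND),
                "run_length": RateEstimate(
                    rec["run_length_um"], rec["run_length_ci"], Unit.MICROMETER
                ),
            }
            for rec in frame.to_dict("records")
        ]

    def test_reproduces_published_cells(self, construct_table):
        """Off-rates, step counts and k_on_TH match the published table at
        displayed precision for all four constructs."""
        rendered = render_race_table(race_table(self._rows(construct_table)))
        assert list(rendered["off_rate_s"]) == [0.56, 3.3, 0.67, 0.71]
        assert list(rendered["steps"]) == [375, 63, 100, 113]
        assert list(rendered["kon_th_s"]) == [208, 208, 67, 80]
        assert list(rendered["off_rate_ci"]) == [0.02, 0.3, 0.04, 0.05]
        assert list(rendered["steps_ci"]) == [3, 1, 3, 3]

    def test_empty_input(self):
        assert race_table([]) == []

    def test_invalid_row_flagged_not_fatal(self):
        rows = [
            {
                "construct": "bad",
                "dwell": RateEstimate(0.0, 0.0, Unit.SECOND),
                "run_length": RateEstimate(1.0, 0.0, Unit.MICROMETER),
            },
            {
                "construct": "good",
                "dwell": RateEstimate(1.0, 0.0, Unit.SECOND),
                "run_length": RateEstimate(0.8, 0.0, Unit.MICROMETER),
            },
        ]
        results = race_table(rows)
        assert results[0].error is not None and results[0].k_on_TH is None
        assert results[1].error is None
        assert results[1].k_on_TH.value == pytest.approx(100.0)

    def test_order_preserved(self, construct_table):
        results = race_table(self._rows(construct_table))
        assert [r.construct for r in results] == list(construct_table["construct"])


@pytest.mark.parametrize(
    "x, sig, expected",
    [(0.5555, 2, 0.56), (3.3333, 2, 3.3), (0.7142, 2, 0.71), (0.0247, 1, 0.02)],
)
def test_round_sig(x, sig, expected):
    assert round_sig(x, sig) == expected


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(62.5) == 63
    assert round_half_up(112.5) == 113
    assert round_half_up(2.5) == 3
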