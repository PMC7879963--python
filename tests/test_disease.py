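"""Disease model: rate aggregation, attribution, population advancement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvdsim.disease import (
    MEASURES,
    DiseaseModel,
    RiskFactorTable,
    SubpopulationState,
    advance_population,
    attributable_fraction,
    attributed_outcomes,
    AttributionSpec,
    event_rate,
)
from cvdsim.engine import SimulationClock
from cvdsim.errors import DomainError, SpecificationError


def single_factor_table(p, ref, rr, outcome="cvd_event", n=1):
    return RiskFactorTable(
        prevalence={"x": np.full(n, p)},
        reference={"x": np.full(n, ref)},
        rr={("x", outcome): rr},
    )


class TestEventRate:
    def test_null_effect_identity(self):
        table = single_factor_table(0.7, 0.1, rr=1.0)
        assert event_rate(0.02, table, "cvd_event", 0) == pytest.approx(0.02)

    def test_fully_exposed_doubles_rate(self):
        table = single_factor_table(1.0, 0.0, rr=2.0)
        assert event_rate(0.02, table, "cvd_event", 0) == pytest.approx(0.04)

    def test_reference_prevalence_normalization(self):
        table = single_factor_table(0.5, 0.5, rr=3.0)
        assert event_rate(0.02, table, "cvd_event", 0) == pytest.approx(0.02)

    def test_negative_relative_risk_rejected(self):
        table = single_factor_table(0.5, 0.5, rr=-1.0)
        with pytest.raises(DomainError):
            event_rate(0.02, table, "cvd_event", 0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        p1=st.floats(0.0, 1.0),
        p2=st.floats(0.0, 1.0),
        rr=st.floats(1.0, 10.0),
        ref=st.floats(0.0, 1.0),
    )
    def test_monotone_in_prevalence_for_harmful_exposure(self, p1, p2, rr, ref):
        lo, hi = sorted((p1, p2))
        r_lo = event_rate(0.01, single_factor_table(lo, ref, rr), "cvd_event", 0)
        r_hi = event_rate(0.01, single_factor_table(hi, ref, rr), "cvd_event", 0)
        assert r_hi >= r_lo


class TestAttributableFraction:
    def test_no_exposure_gives_zero(self):
        assert attributable_fraction(0.0, 5.0) == 0.0

    def test_full_exposure_closed_form(self):
        assert attributable_fraction(1.0, 2.0) == pytest.approx(0.5)

    def test_hand_arithmetic(self):
        assert attributable_fraction(0.2, 3.0) == pytest.approx(0.4 / 1.4)

    def test_protective_exposure_rejected(self):
        with pytest.raises(DomainError, match="protective"):
            attributable_fraction(0.2, 0.8)

    def test_prevalence_outside_unit_interval_rejected(self):
        with pytest.raises(DomainError):
            attributable_fraction(1.2, 2.0)

    @pytest.mark.parametrize("p", [0.0, 0.1, 0.25, 0.5, 0.9, 1.0])
    @pytest.mark.parametrize("rr", [1.0, 1.3, 2.0, 4.0, 10.0])
    def test_matches_two_group_mixing_oracle(self, p, rr):
        # Oracle: N persons, exposed have incidence rr*r0, unexposed r0.
        # The attributable share is (total - all-unexposed) / total.
        n, r0 = 1_000_000.0, 0.01
        total = n * (p * rr * r0 + (1 - p) * r0)
        attributable = total - n * r0
        assert attributable_fraction(p, rr) == pytest.approx(attributable / total, abs=1e-12)


class TestAttributedOutcomes:
    def test_zero_prevalence_gives_zero_every_year(self):
        table = single_factor_table(0.0, 0.0, rr=3.0, outcome="noncvd_death", n=5)
        spec = AttributionSpec("deaths", "x", rr=3.0, baseline=1000.0)
        np.testing.assert_array_equal(attributed_outcomes(spec, table), np.zeros(5))

    def test_hand_arithmetic(self):
        table = single_factor_table(0.2, 0.0, rr=3.0, n=1)
        spec = AttributionSpec("deaths", "x", rr=3.0, baseline=1000.0)
        assert attributed_outcomes(spec, table, t=0) == pytest.approx(1000 * 0.4 / 1.4)

    def test_linear_in_multiplier(self):
        table = single_factor_table(0.2, 0.0, rr=3.0, n=4)
        spec = AttributionSpec("deaths", "x", rr=3.0, baseline=1000.0)
        once = attributed_outcomes(spec, table, multiplier=1.0)
        twice = attributed_outcomes(spec, table, multiplier=2.0)
        np.testing.assert_allclose(twice, 2.0 * once)

    def test_missing_exposure_factor_is_a_specification_error(self):
        table = single_factor_table(0.2, 0.0, rr=3.0)
        spec = AttributionSpec("deaths", "ghost", rr=3.0, baseline=1000.0)
        with pytest.raises(SpecificationError, match="ghost"):
            attributed_outcomes(spec, table)

    def test_attribution_spec_domain_checks(self):
        with pytest.raises(DomainError):
            AttributionSpec("deaths", "x", rr=0.9, baseline=10.0)
        with pytest.raises(DomainError):
            AttributionSpec("deaths", "x", rr=2.0, baseline=-1.0)


class TestAdvancePopulation:
    def test_zero_rates_leave_state_unchanged(self):
        state = SubpopulationState(non_cvd=1000.0, post_cvd=100.0)
        nxt = advance_population(state, {"population": 1100.0})
        assert nxt.non_cvd == 1000.0 and nxt.post_cvd == 100.0
        assert nxt.deaths_cvd == 0.0 and nxt.deaths_non_cvd == 0.0

    def test_first_event_split_hand_arithmetic(self):
        # 1000 non-CVD, event rate 0.10/yr, case fatality 0.3:
        # 100 events, 30 CVD deaths, 70 enter post-CVD.
        params = {"population": 1000.0, "cvd_event_rate0": 0.10, "cvd_case_fatality": 0.3}
        state = SubpopulationState(non_cvd=1000.0, post_cvd=0.0)
        nxt = advance_population(state, params)
        assert nxt.deaths_cvd == pytest.approx(30.0)
        assert nxt.post_cvd == pytest.approx(70.0)
        assert nxt.non_cvd == pytest.approx(900.0)

    def test_doubling_post_cvd_mortality_never_lowers_cvd_deaths(self, nation):
        params = dict(nation.params)
        base = DiseaseModel(params, clock=nation.clock).run()
        params["post_fatality_ratio"] *= 2.0
        harsher = DiseaseModel(params, clock=nation.clock).run()
        assert harsher.series("cvd_deaths").sum() >= base.series("cvd_deaths").sum()


class TestIntegratedModel:
    def test_persons_conserved_each_year(self, base_traj):
        # Delta(non_cvd + post_cvd) == inflow - all deaths, annually.
        total = base_traj.total_persons()
        deaths = (
            base_traj.flows["first_events_fatal"]
            + base_traj.flows["recurrent_fatal"]
            + base_traj.flows["noncvd_deaths_nc"]
            + base_traj.flows["noncvd_deaths_pc"]
        )
        inflow = base_traj.flows["net_inflow"]
        np.testing.assert_allclose(
            np.diff(total), (inflow - deaths)[:-1], rtol=1e-9, atol=1e-6
        )

    def test_no_clamping_in_the_base_run(self, base_traj):
        assert base_traj.clamp_total() == 0.0

    def test_all_25_measures_are_reported(self, base_traj):
        assert len(MEASURES) == 25
        for measure in MEASURES:
            assert len(base_traj.series(measure)) == 51

    def test_base_run_reproducible_bitwise(self, nation, base_traj):
        again = nation.base_trajectory()
        for measure in MEASURES:
            assert np.array_equal(again.series(measure), base_traj.series(measure))

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(bump=st.floats(0.01, 0.25))
    def test_raising_harmful_prevalence_never_averts_cvd_deaths(self, nation, bump):
        params = dict(nation.params)
        clock = SimulationClock(2010, 2030)
        base = DiseaseModel(params, clock=clock).run()
        params["prev0.current_smoker"] = min(1.0, params["prev0.current_smoker"] + bump)
        raised = DiseaseModel(params, clock=clock).run()
        assert raised.series("cvd_deaths").sum() >= base.series("cvd_deaths").sum()

    def test_multiplier_scales_only_its_own_measure(self, nation, base_traj):
        scaled = nation.run_with_multipliers({"cvd_deaths": 2.0})
        np.testing.assert_allclose(
            scaled.series("cvd_deaths"), 2.0 * base_traj.series("cvd_deaths")
        )
        for measure in MEASURES:
            if measure != "cvd_deaths":
                assert np.array_equal(scaled.series(measure), base_traj.series(measure))
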