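"""Unit and property tests for the cohort-structured labeling simulator."""

import numpy as np
import pytest

from tregmap import (
    ConfigurationError,
    ParameterError,
    PulseDesign,
    divided_recent_fraction,
    evolve_expectation,
    pulse_for_week,
    simulate_mouse,
    tag_probability,
    trapezoid_kernel,
    true_composition,
)

from conftest import make_schedule


def make_pulse(first_dose_day, efficiency=1.0, kernel=None, tissue="toy"):
    return PulseDesign(
        first_dose_day=first_dose_day,
        kernel=trapezoid_kernel() if kernel is None else kernel,
        efficiency_by_tissue={tissue: efficiency},
    )


class TestTagProbability:
    def test_birth_before_window_gets_full_efficiency(self):
        pulse = make_pulse(10, efficiency=0.95)
        assert tag_probability(0, pulse, "toy") == pytest.approx(0.95)
        assert tag_probability(10, pulse, "toy") == pytest.approx(0.95)

    def test_birth_after_window_never_labeled(self):
        pulse = make_pulse(10, efficiency=0.95)
        assert tag_probability(19, pulse, "toy") == 0.0
        assert tag_probability(40, pulse, "toy") == 0.0

    def test_partial_window_is_remaining_kernel_mass(self):
        # birth on kernel day 6: remaining mass 2/3 + 1/3 + 0 = 1 of a total 6
        pulse = make_pulse(10, efficiency=1.0)
        assert tag_probability(16, pulse, "toy") == pytest.approx(1.0 / 6.0)

    def test_truncation_before_window_closes(self):
        # analysis two days in: only kernel days 1-2 of mass have elapsed
        pulse = make_pulse(10, efficiency=1.0)
        assert tag_probability(0, pulse, "toy", at_day=12) == pytest.approx(2.0 / 6.0)

    def test_unknown_tissue_is_configuration_error(self):
        pulse = make_pulse(10)
        with pytest.raises(ConfigurationError):
            tag_probability(0, pulse, "spleen")

    def test_negative_birth_day_rejected(self):
        with pytest.raises(ParameterError):
            tag_probability(-1, make_pulse(10), "toy")


class TestEvolveExpectation:
    def test_conservation_without_dynamics(self, toy_schedule):
        # influx only on day 0, no division, no loss: mass constant forever
        pulse = make_pulse(5, efficiency=1.0)
        for day in (1, 30, 99):
            state = evolve_expectation(toy_schedule, pulse, day)
            assert state.total_mass == pytest.approx(1.0)
        late = evolve_expectation(toy_schedule, pulse, 60)
        assert late.labeled_mass == pytest.approx(1.0)

    def test_balanced_birth_death_keeps_cohort_constant(self):
        sched = make_schedule(division=0.1, loss_resident=0.1, loss_flux=0.1)
        state = evolve_expectation(sched, None, 80)
        assert state.total_mass == pytest.approx(1.0)

    def test_zero_turnover_label_fraction_time_invariant(self):
        # after the window closes with no further influx/loss, the tagged
        # fraction must not drift
        influx = np.zeros(120)
        influx[:30] = 1.0
        sched = make_schedule(horizon=120, influx=influx)
        pulse = make_pulse(40, efficiency=0.9)
        fractions = [
            evolve_expectation(sched, pulse, day).tagged_fraction for day in (50, 80, 119)
        ]
        assert np.allclose(fractions, fractions[0])
        assert fractions[0] == pytest.approx(0.9)

    def test_constant_replacement_matches_exponential_decay(self):
        # pool of size 1 with per-day replacement r: the labeled fraction
        # decays geometrically, which matches exp(-r t) up to discretization
        r = 0.02
        influx = np.full(200, r)
        influx[0] = 1.0
        sched = make_schedule(horizon=200, influx=influx, loss_resident=r, loss_flux=r)
        pulse = make_pulse(50, efficiency=1.0)
        t_ref = 60  # after the window closes
        f_ref = evolve_expectation(sched, pulse, t_ref).tagged_fraction
        for dt in (20, 60, 100):
            frac = evolve_expectation(sched, pulse, t_ref + dt).tagged_fraction
            assert frac / f_ref == pytest.approx((1 - r) ** dt, rel=1e-9)
            assert frac / f_ref == pytest.approx(np.exp(-r * dt), rel=r * 1.1)

    def test_heritable_label_survives_division_and_loss(self):
        # all influx arrives before the window: every later cell descends from
        # labeled cells, so the tagged fraction stays exactly E despite
        # ongoing division and loss
        influx = np.zeros(150)
        influx[:14] = 1.0
        sched = make_schedule(
            horizon=150, influx=influx, division=0.2, loss_resident=0.1, loss_flux=0.1
        )
        pulse = make_pulse(20, efficiency=1.0)
        assert evolve_expectation(sched, pulse, 149).tagged_fraction == pytest.approx(1.0)

    def test_monotone_pulse_ordering(self, scenario):
        sched = scenario.schedule("skin")
        fractions = [
            evolve_expectation(sched, scenario.pulse(week=w), 56).tagged_fraction
            for w in range(1, 7)
        ]
        assert np.all(np.diff(fractions) >= -1e-12)

    def test_analysis_beyond_horizon_rejected(self, toy_schedule):
        with pytest.raises(ParameterError):
            evolve_expectation(toy_schedule, None, 100)


class TestTrueComposition:
    def test_single_cohort_dominates(self, toy_schedule):
        truth = true_composition(toy_schedule, 56)
        assert truth.fractions[0] == pytest.approx(1.0)

    def test_equal_influx_no_turnover_is_uniform(self):
        sched = make_schedule(horizon=100, influx=1.0)
        truth = true_composition(sched, 56)
        assert truth.fractions[:8] == pytest.approx(np.full(8, 1 / 8))

    def test_cumulative_matches_oracle_for_skin_like_schedule(self, scenario):
        # residency-weighted early influx: week 1 dominates the 8-week pool
        sched = scenario.schedule("skin")
        truth = true_composition(sched, 56)
        state = evolve_expectation(sched, None, 56)
        assert truth.fraction_through_week(1) == pytest.approx(
            state.masses[:7].sum() / state.total_mass
        )
        assert truth.fractions[0] == max(truth.fractions)
        assert truth.cumulative()[-1] == pytest.approx(1.0)


class TestDividedRecentFraction:
    @pytest.mark.parametrize(
        "pi,window,expected",
        [(0.0, 4, 0.0), (0.33, 4, 1 - 0.67**4), (0.05, 4, 1 - 0.95**4)],
    )
    def test_mature_pool_closed_form(self, pi, window, expected):
        sched = make_schedule(division=pi)
        assert divided_recent_fraction(sched, 30, window) == pytest.approx(expected)

    def test_newborns_truncate_the_window(self):
        # cells born inside the window have had fewer chances to divide
        sched = make_schedule(horizon=50, influx=1.0, division=0.3)
        young = divided_recent_fraction(sched, 2, 4)
        mature = divided_recent_fraction(sched, 30, 4)
        assert young < mature

    def test_window_must_be_positive(self, toy_schedule):
        with pytest.raises(ParameterError):
            divided_recent_fraction(toy_schedule, 10, 0)


class TestSimulateMouse:
    def test_degenerate_fractions(self, toy_schedule):
        rng = np.random.default_rng(0)
        full = simulate_mouse(toy_schedule, make_pulse(5, efficiency=1.0), 30, rng)
        assert full.n_tagged == full.n_cells
        none = simulate_mouse(toy_schedule, make_pulse(5, efficiency=0.0), 30, rng)
        assert none.n_tagged == 0

    def test_stochastic_mean_matches_expectation_engine(self):
        # cohort mean over many mice within 3 Monte-Carlo SEs of the oracle
        influx = np.zeros(100)
        influx[:40] = 1.0
        sched = make_schedule(horizon=100, influx=influx, kappa=50.0, sampled_cells=2000)
        pulse = make_pulse(20, efficiency=0.95)
        state = evolve_expectation(sched, pulse, 60)
        rng = np.random.default_rng(42)
        n = 3000
        draws = np.array(
            [
                simulate_mouse(sched, pulse, 60, rng, state=state).n_tagged / 2000
                for _ in range(n)
            ]
        )
        se = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - state.tagged_fraction) < 3 * se

    def test_invalid_sampled_cells(self):
        sched = make_schedule(sampled_cells=0)
        with pytest.raises(ParameterError):
            simulate_mouse(sched, make_pulse(5), 30, np.random.default_rng(0))


class TestPulseDesign:
    def test_kernel_validation(self):
        with pytest.raises(ConfigurationError):
            PulseDesign(first_dose_day=0, kernel=np.zeros(8), efficiency_by_tissue={})
        with pytest.raises(ConfigurationError):
            PulseDesign(first_dose_day=0, kernel=-trapezoid_kernel(), efficiency_by_tissue={})

    def test_week_placement(self):
        pulse = pulse_for_week(3, {"toy": 1.0})
        assert pulse.first_dose_day == 15
        with pytest.raises(ConfigurationError):
            pulse_for_week(0, {"toy": 1.0})
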