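"""Tests for the generation-week decomposition pipeline."""

import copy

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from tregmap import (
    ParameterError,
    PoolCompositionModel,
    Scenario,
    ValidationError,
    correct_efficiency,
    decompose,
    isotonic_nondecreasing,
    simulate_cohort,
    stratified_reconstruct,
    summarize_groups,
    waffle_allocate,
)


def tiny_cohort(fractions_by_week, tissue="spleen", n_cells=1000):
    rows = []
    for week, fractions in fractions_by_week.items():
        for i, f in enumerate(fractions):
            rows.append(
                {
                    "mouse_id": f"w{week}m{i}",
                    "tissue": tissue,
                    "pulse_week": week,
                    "pulse_day": 7 * (week - 1) + 1,
                    "analysis_day": 56,
                    "n_cells": n_cells,
                    "n_tagged": int(round(f * n_cells)),
                }
            )
    return pd.DataFrame(rows)


class TestSummarizeGroups:
    def test_median_convention(self):
        cohort = tiny_cohort({1: [0.2, 0.4, 0.6], 2: [0.1, 0.2, 0.3, 0.4]})
        groups = summarize_groups(cohort, "spleen")
        assert groups[0].fraction == pytest.approx(0.4)
        assert groups[1].fraction == pytest.approx(0.25)  # even-n midpoint

    def test_single_mouse(self):
        groups = summarize_groups(tiny_cohort({3: [0.57]}), "spleen")
        assert groups[0].fraction == pytest.approx(0.57)
        assert groups[0].n_mice == 1

    def test_mean_option(self):
        cohort = tiny_cohort({1: [0.2, 0.4, 0.9]})
        assert summarize_groups(cohort, "spleen", stat="mean")[0].fraction == pytest.approx(0.5)

    def test_missing_group_is_explicit(self):
        cohort = tiny_cohort({1: [0.2], 3: [0.4]})
        with pytest.raises(ValidationError, match=r"\[2\]"):
            summarize_groups(cohort, "spleen", pulse_weeks=[1, 2, 3])


class TestCorrectEfficiency:
    @pytest.mark.parametrize(
        "fraction,eff,expected", [(0.57, 0.95, 0.6), (0.99, 0.95, 1.0), (0.0, 0.5, 0.0)]
    )
    def test_values(self, fraction, eff, expected):
        assert correct_efficiency(fraction, eff) == pytest.approx(expected)

    def test_nonpositive_efficiency_rejected(self):
        with pytest.raises(ParameterError):
            correct_efficiency(0.5, 0.0)


def brute_force_monotone_projection(values, weights=None):
    """Independent oracle: constrained weighted least squares via SLSQP."""
    values = np.asarray(values, dtype=float)
    w = np.ones_like(values) if weights is None else np.asarray(weights, float)

    def objective(x):
        return float(np.sum(w * (x - values) ** 2))

    constraints = [
        {"type": "ineq", "fun": (lambda x, i=i: x[i + 1] - x[i])}
        for i in range(len(values) - 1)
    ]
    res = minimize(objective, values, constraints=constraints, method="SLSQP", tol=1e-12)
    assert res.success
    return res.x


class TestIsotonic:
    def test_identity_on_monotone_input(self):
        values = np.array([0.1, 0.2, 0.3])
        assert isotonic_nondecreasing(values) == pytest.approx(values)

    def test_two_point_pooling(self):
        assert isotonic_nondecreasing([0.3, 0.2]) == pytest.approx([0.25, 0.25])

    def test_three_point_projection(self):
        assert isotonic_nondecreasing([0.5, 0.4, 0.6]) == pytest.approx([0.45, 0.45, 0.6])

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_brute_force_projection(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(2, 6))
        values = rng.uniform(0, 1, n)
        weights = rng.uniform(0.5, 3.0, n)
        ours = isotonic_nondecreasing(values, weights)
        oracle = brute_force_monotone_projection(values, weights)
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_weight_validation(self):
        with pytest.raises(ParameterError):
            isotonic_nondecreasing([0.1, 0.2], [1.0])
        with pytest.raises(ParameterError):
            isotonic_nondecreasing([0.1, 0.2], [1.0, 0.0])


class TestDecompose:
    def test_printed_skin_values(self):
        # cumulative 60% by week 1 and 85% by week 2 decompose by difference
        increments, tail = decompose([0.60, 0.85])
        assert increments == pytest.approx([0.60, 0.25])
        assert tail == pytest.approx(0.15)

    def test_saturated_pool(self):
        increments, tail = decompose([1.0, 1.0, 1.0])
        assert increments == pytest.approx([1.0, 0.0, 0.0])
        assert tail == 0.0

    def test_non_monotone_input_rejected(self):
        with pytest.raises(ParameterError):
            decompose([0.5, 0.4])


class TestWaffle:
    def test_degenerate(self):
        assert waffle_allocate([1.0]) == pytest.approx([100])

    def test_tie_goes_to_earlier_week(self):
        # quotas 60.5 / 25 / 14.5: one leftover cell, remainder tie broken in
        # favour of the earlier week
        assert list(waffle_allocate([0.605, 0.25, 0.145])) == [61, 25, 14]

    def test_symmetry(self):
        assert list(waffle_allocate([0.5, 0.5])) == [50, 50]

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            waffle_allocate([-0.1, 1.1])


class TestModelFit:
    def test_bootstrap_determinism_and_degeneracy(self):
        cohort = tiny_cohort({w: [0.1 * w] * 4 for w in range(1, 5)})
        model = PoolCompositionModel(cohort, "spleen", 1.0)
        res1 = model.fit(bootstrap=200, seed=5)
        res2 = model.fit(bootstrap=200, seed=5)
        assert res1.conf_int_.tolist() == res2.conf_int_.tolist()
        # identical mice within groups -> zero-width intervals
        width = res1.conf_int_[:, 1] - res1.conf_int_[:, 0]
        assert np.all(width < 1e-12)

    def test_composition_is_a_distribution(self, ontogeny_cohort, scenario):
        for tissue in ("skin", "LN"):
            res = PoolCompositionModel(
                ontogeny_cohort, tissue, scenario.efficiency
            ).fit(bootstrap=0)
            total = res.increments.sum() + res.tail
            assert total == pytest.approx(1.0)
            assert np.all(res.increments >= 0)
            assert np.all(np.diff(res.cumulative) >= -1e-12)

    def test_small_bootstrap_rejected(self, ontogeny_cohort, scenario):
        model = PoolCompositionModel(ontogeny_cohort, "skin", scenario.efficiency)
        with pytest.raises(ParameterError):
            model.fit(bootstrap=50)

    def test_efficiency_invariance(self, scenario):
        # labeling at E = 0.9 and correcting by 0.9 reproduces the E = 1
        # analysis; noise-free expectation counts isolate the correction step
        from tregmap import evolve_expectation, pulse_for_week

        sched = scenario.schedule("lungs")
        estimates = {}
        for eff in (1.0, 0.9):
            fractions = {}
            for week in range(1, 7):
                pulse = pulse_for_week(week, {"lungs": eff}, scenario.kernel)
                fractions[week] = [evolve_expectation(sched, pulse, 56).tagged_fraction] * 3
            cohort = tiny_cohort(fractions, tissue="lungs", n_cells=100000)
            estimates[eff] = PoolCompositionModel(cohort, "lungs", eff).fit(bootstrap=0).increments
        assert estimates[0.9] == pytest.approx(estimates[1.0], abs=1e-3)

    def test_estimator_consistency_with_sample_size(self, scenario):
        # absolute error of the increments shrinks as mice and cells grow
        truth = np.diff(
            [0.0]
            + [scenario.config["tissues"]["lungs"]["cumulative_targets"][w] for w in range(1, 7)]
        )
        errors = []
        for mice, cells, seed in ((2, 300, 1), (8, 2000, 2), (32, 8000, 3)):
            config = copy.deepcopy(scenario.config)
            config["protocols"]["ontogeny"]["mice_per_group"] = mice
            config["protocols"]["ontogeny"]["include_subsets"] = False
            config["tissues"]["lungs"]["sampled_cells"] = cells
            scn = Scenario(config, source="modified")
            err = []
            for rep in range(3):
                cohort = simulate_cohort(
                    scn, "ontogeny", seed=100 * seed + rep, tissues=["lungs"]
                )
                res = PoolCompositionModel(cohort, "lungs", scenario.efficiency).fit(
                    bootstrap=0
                )
                err.append(np.max(np.abs(res.increments - truth)))
            errors.append(np.mean(err))
        assert errors[2] < errors[0]
        assert errors[2] < 0.05


class TestStratified:
    def test_subset_pipeline_matches_whole_pipeline_shape(self, ontogeny_cohort, scenario):
        results = stratified_reconstruct(
            ontogeny_cohort, "colon", ["GATA3+", "RORgt+", "DN"], scenario.efficiency
        )
        assert set(results) == {"GATA3+", "RORgt+", "DN"}
        for res in results.values():
            assert res.increments.sum() + res.tail == pytest.approx(1.0)
        # the neonatal bias ordering survives estimation noise comfortably
        assert results["GATA3+"].fraction_through_week(2) > results[
            "RORgt+"
        ].fraction_through_week(2)

    def test_absent_subset_is_skipped(self, ontogeny_cohort, scenario, caplog):
        with caplog.at_level("INFO", logger="tregmap.composition"):
            results = stratified_reconstruct(
                ontogeny_cohort, "skin", ["RORgt+"], scenario.efficiency
            )
        assert results == {}
        assert any("skipping" in message for message in caplog.messages)
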