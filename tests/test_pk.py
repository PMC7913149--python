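"""PK engine: covariate models, closed-form solution, periodic steady state."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tamoxsim import (
    Covariates,
    CovariateError,
    DoseEventList,
    IndividualParameters,
    PopulationModel,
    simulate_profile,
    steady_state_min_endx,
)
from tamoxsim.pk import cycle_min_endx_per_mg, endx_concentrations

from conftest import random_individual
from oracle import ode_concentrations

# module-level toy patient for hypothesis-driven properties
_TOY = IndividualParameters(
    ka=0.5, tlag=0.5, v_tam=1000.0, cl23_i=0.2, cl20_i=5.0, v_endx=400.0, cl30=8.0
)


class TestCovariateModels:
    def test_reference_patient_gets_typical_values(self, default_model, reference_covariates):
        cl23, cl20 = default_model.apply_covariates(reference_covariates)
        assert cl23 == pytest.approx(default_model.cl23)
        assert cl20 == pytest.approx(default_model.cl20)

    def test_fractional_change_scales_formation_clearance(self):
        model = PopulationModel(theta_as={0.0: -0.9, 2.0: 0.0})
        cov = Covariates(activity_score=0.0, age=model.age_ref, weight=model.wt_ref)
        cl23, _ = model.apply_covariates(cov)
        assert cl23 == pytest.approx(0.1 * model.cl23)

    def test_age_power_model_on_competing_clearance(self):
        model = PopulationModel(theta_age=0.5)
        cov = Covariates(activity_score=2.0, age=2 * model.age_ref, weight=model.wt_ref)
        _, cl20 = model.apply_covariates(cov)
        assert cl20 == pytest.approx(model.cl20 * np.sqrt(2.0))

    def test_undefined_activity_score_raises(self, default_model):
        model = default_model.model_copy(update={"theta_as": {2.0: 0.0}})
        cov = Covariates(activity_score=0.0, age=55, weight=70)
        with pytest.raises(CovariateError):
            model.apply_covariates(cov)

    @pytest.mark.parametrize(
        "eta23, eta20, factor23, factor20",
        [(0.0, 0.0, 1.0, 1.0), (np.log(2), 0.0, 2.0, 1.0), (0.0, -np.log(2), 1.0, 0.5)],
    )
    def test_lognormal_individualization(
        self, default_model, reference_covariates, eta23, eta20, factor23, factor20
    ):
        ind = default_model.individualize(reference_covariates, eta23, eta20)
        assert ind.cl23_i == pytest.approx(factor23 * default_model.cl23)
        assert ind.cl20_i == pytest.approx(factor20 * default_model.cl20)

    def test_nonfinite_eta_rejected(self, default_model, reference_covariates):
        with pytest.raises(ValueError):
            default_model.individualize(reference_covariates, np.inf, 0.0)


class TestDoseEventList:
    def test_validation(self):
        with pytest.raises(ValueError):
            DoseEventList([0.0, 0.0], [20.0, 20.0])  # not strictly increasing
        with pytest.raises(ValueError):
            DoseEventList([-1.0], [20.0])
        with pytest.raises(ValueError):
            DoseEventList([0.0], [-5.0])

    def test_once_daily_builder(self):
        doses = DoseEventList.once_daily(20.0, 3)
        assert np.array_equal(doses.times, [0.0, 24.0, 48.0])
        assert np.all(doses.amounts == 20.0)


class TestClosedFormSolution:
    def test_empty_dose_list_gives_zero(self, toy_individual):
        prof = simulate_profile(toy_individual, DoseEventList([], []), np.arange(0, 48, 4.0))
        assert np.all(prof.tamoxifen == 0) and np.all(prof.endoxifen == 0)

    def test_zero_before_first_dose_plus_lag(self, toy_individual):
        doses = DoseEventList([10.0], [20.0])
        times = np.array([0.0, 5.0, 10.0, 10.4, 10.5])
        prof = simulate_profile(toy_individual, doses, times)
        assert np.all(prof.tamoxifen == 0) and np.all(prof.endoxifen == 0)

    def test_single_dose_matches_ode_oracle(self, toy_individual):
        times = np.array([24.0, 48.0, 168.0])
        prof = simulate_profile(toy_individual, DoseEventList([0.0], [20.0]), times)
        tam, endx = ode_concentrations(toy_individual, [0.0], [20.0], times)
        np.testing.assert_allclose(prof.tamoxifen, tam, rtol=1e-6)
        np.testing.assert_allclose(prof.endoxifen, endx, rtol=1e-6)

    def test_oracle_equivalence_on_random_draws(self, rng):
        """Closed form vs stiff-safe ODE on 20 seeded parameter/regimen draws."""
        for _ in range(20):
            ind = random_individual(rng)
            n_doses = int(rng.integers(1, 10))
            dose_times = np.sort(rng.choice(np.arange(0, 24 * 14, 12.0), n_doses, replace=False))
            amounts = rng.choice([10.0, 20.0, 40.0], n_doses)
            times = np.sort(dose_times[-1] + ind.tlag + rng.uniform(1.0, 200.0, size=4))
            prof = simulate_profile(ind, DoseEventList(dose_times, amounts), times)
            tam, endx = ode_concentrations(ind, dose_times, amounts, times)
            np.testing.assert_allclose(prof.tamoxifen, tam, rtol=1e-6)
            np.testing.assert_allclose(prof.endoxifen, endx, rtol=1e-6)

    def test_degenerate_rate_constants_stay_finite(self):
        """ka equal to an elimination rate constant must not produce NaN."""
        ind = IndividualParameters(
            ka=8.0 / 400.0,  # equals cl30/v_endx exactly
            tlag=0.5, v_tam=1000.0, cl23_i=0.2, cl20_i=5.0, v_endx=400.0, cl30=8.0,
        )
        times = np.array([24.0, 96.0, 240.0])
        prof = simulate_profile(ind, DoseEventList([0.0], [20.0]), times)
        assert np.all(np.isfinite(prof.endoxifen)) and np.all(prof.endoxifen > 0)
        _, endx = ode_concentrations(ind, [0.0], [20.0], times)
        np.testing.assert_allclose(prof.endoxifen, endx, rtol=1e-6)

    def test_dose_proportionality(self, rng):
        """Linear PK: scaling every dose scales the whole profile."""
        for _ in range(5):
            ind = random_individual(rng)
            doses1 = DoseEventList.once_daily(10.0, 7)
            doses3 = DoseEventList.once_daily(30.0, 7)
            times = np.arange(12.0, 24 * 9, 12.0)
            p1 = simulate_profile(ind, doses1, times)
            p3 = simulate_profile(ind, doses3, times)
            np.testing.assert_allclose(p3.endoxifen, 3.0 * p1.endoxifen, rtol=1e-9)
            np.testing.assert_allclose(p3.tamoxifen, 3.0 * p1.tamoxifen, rtol=1e-9)


class TestPeriodicSteadyState:
    def test_zero_dose_and_empty_pattern(self, toy_individual):
        assert steady_state_min_endx(toy_individual, 0.0) == 0.0
        assert steady_state_min_endx(toy_individual, 20.0, (0,) * 7) == 0.0

    def test_dose_proportionality_of_cycle_minimum(self, toy_individual):
        one = steady_state_min_endx(toy_individual, 20.0, (1, 1, 1, 1, 1, 1, 0))
        two = steady_state_min_endx(toy_individual, 40.0, (1, 1, 1, 1, 1, 1, 0))
        assert two == pytest.approx(2.0 * one, rel=1e-9)

    @pytest.mark.parametrize("pattern", [(1,) * 7, (1, 1, 1, 1, 1, 1, 0), (1, 1, 1, 1, 1, 0, 0)])
    def test_matches_52_week_brute_force(self, toy_individual, pattern):
        """Closed-form periodic steady state vs final cycle of a long simulation."""
        ss = steady_state_min_endx(toy_individual, 20.0, pattern)
        weeks = 52
        days = [7 * w + d for w in range(weeks) for d in range(7) if pattern[d]]
        dose_times = 24.0 * np.asarray(days, dtype=float)
        amounts = np.full(len(days), 20.0)
        grid = np.arange(24.0 * 7 * (weeks - 1), 24.0 * 7 * weeks, 0.25)
        conc = endx_concentrations(
            toy_individual.ka, toy_individual.tlag, toy_individual.v_tam,
            toy_individual.cl20_i, toy_individual.cl23_i,
            toy_individual.v_endx, toy_individual.cl30,
            dose_times, amounts, grid,
        )[0]
        assert ss == pytest.approx(conc.min(), rel=1e-3)

    def test_26_weeks_suffice_for_steady_state(self, rng):
        """Final-cycle minimum after 26 weeks is within 0.5% of the 52-week value."""
        pattern = (1, 1, 1, 1, 1, 0, 0)
        for _ in range(5):
            ind = random_individual(rng)
            mins = {}
            for weeks in (26, 52):
                days = [7 * w + d for w in range(weeks) for d in range(7) if pattern[d]]
                dose_times = 24.0 * np.asarray(days, dtype=float)
                grid = np.arange(24.0 * 7 * (weeks - 1), 24.0 * 7 * weeks, 0.5)
                conc = endx_concentrations(
                    ind.ka, ind.tlag, ind.v_tam, ind.cl20_i, ind.cl23_i, ind.v_endx,
                    ind.cl30, dose_times, np.full(len(days), 20.0), grid,
                )[0]
                mins[weeks] = conc.min()
            assert mins[26] == pytest.approx(mins[52], rel=5e-3)

    def test_missed_doses_strictly_lower_cycle_minimum(self, rng):
        for _ in range(10):
            ind = random_individual(rng)
            full = steady_state_min_endx(ind, 20.0, (1,) * 7)
            miss1 = steady_state_min_endx(ind, 20.0, (1, 1, 1, 1, 1, 1, 0))
            miss2 = steady_state_min_endx(ind, 20.0, (1, 1, 1, 1, 1, 0, 0))
            assert miss2 < miss1 < full

    def test_cycle_minimum_invariant_to_missed_day_placement(self, toy_individual):
        """At periodic steady state the pattern phase cannot matter."""
        a = steady_state_min_endx(toy_individual, 20.0, (1, 1, 1, 1, 1, 0, 0))
        b = steady_state_min_endx(toy_individual, 20.0, (0, 1, 1, 1, 1, 1, 0))
        c = steady_state_min_endx(toy_individual, 20.0, (0, 0, 1, 1, 1, 1, 1))
        assert a == pytest.approx(b, rel=1e-6)
        assert a == pytest.approx(c, rel=1e-6)

    @given(
        dose=st.floats(1.0, 120.0),
        scale=st.floats(0.05, 20.0),
        missed=st.integers(0, 2),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_cycle_minimum_scales_linearly_in_dose(self, dose, scale, missed):
        """Linearity of the PK system: C_SS,min(c*dose) = c*C_SS,min(dose)."""
        ind = _TOY
        pattern = [(1,) * 7, (1, 1, 1, 1, 1, 1, 0), (1, 1, 1, 1, 1, 0, 0)][missed]
        base = steady_state_min_endx(ind, dose, pattern)
        scaled = steady_state_min_endx(ind, dose * scale, pattern)
        assert scaled == pytest.approx(scale * base, rel=1e-9)

    def test_reduced_cyp2d6_activity_lowers_exposure(self, default_model):
        """More negative fractional change on CL23 strictly decreases C_SS,min."""
        troughs = []
        for score in (2.0, 1.5, 1.0, 0.5, 0.0):
            cov = Covariates(activity_score=score, age=55.0, weight=70.0)
            ind = default_model.individualize(cov)
            troughs.append(steady_state_min_endx(ind, 20.0))
        assert all(a > b for a, b in zip(troughs, troughs[1:]))

    def test_batch_agrees_with_scalar_path(self, rng):
        inds = [random_individual(rng) for _ in range(4)]
        ref = inds[0]
        batch = cycle_min_endx_per_mg(
            ref.ka, ref.tlag, ref.v_tam,
            np.array([i.cl20_i for i in inds[:1]] * 1), np.array([i.cl23_i for i in inds[:1]]),
            ref.v_endx, ref.cl30, (1, 1, 1, 1, 1, 1, 0),
        )
        scalar = steady_state_min_endx(ref, 1.0, (1, 1, 1, 1, 1, 1, 0))
        assert batch[0] == pytest.approx(scalar, rel=1e-12)
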