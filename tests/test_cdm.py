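"""Cohort engine: dose-response, conservation, oracle equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hs

from _oracle import brute_force_run
from conftest import make_demography, make_disease, make_pa
from pacea.cdm import (ChronicDiseaseModel, Demography, DiseaseSpec,
                       PADistribution, healthcare_costs, qalys,
                       relative_risk)


class TestRelativeRisk:
    def test_identity_at_reference(self):
        spec = make_disease(beta=-0.01, reference_met=40.0)
        assert relative_risk(40.0, spec) == pytest.approx(1.0)

    def test_null_slope_is_flat(self):
        spec = make_disease(beta=0.0)
        for met in (0.0, 20.0, 100.0):
            assert relative_risk(met, spec) == pytest.approx(1.0)

    def test_log_linear_form(self):
        spec = make_disease(beta=-0.01, reference_met=0.0)
        assert relative_risk(40.0, spec) == pytest.approx(math.exp(-0.4))

    def test_negative_met_rejected(self):
        with pytest.raises(ValueError):
            relative_risk(-1.0, make_disease())

    @given(met=hs.floats(0.0, 200.0))
    def test_positive_and_monotone(self, met):
        spec = make_disease(beta=-0.02, reference_met=40.0)
        rr = relative_risk(met, spec)
        assert rr > 0
        assert relative_risk(met + 1.0, spec) <= rr


class TestValidation:
    def test_occupancy_must_sum_to_one(self):
        with pytest.raises(ValueError):
            make_pa(occupancy=(0.5, 0.4))

    def test_boundaries_strictly_increasing(self):
        with pytest.raises(ValueError):
            PADistribution(np.array([0.0, 10.0, 10.0]),
                           np.array([5.0, 10.0]), np.array([0.5, 0.5]))

    def test_representative_value_inside_class(self):
        with pytest.raises(ValueError):
            PADistribution(np.array([0.0, 10.0, 20.0]),
                           np.array([5.0, 50.0]), np.array([0.5, 0.5]))

    def test_disutility_range(self):
        with pytest.raises(ValueError):
            make_disease(disutility=1.5)

    def test_mortality_probability_range(self):
        with pytest.raises(ValueError):
            make_demography(mortality=1.5)

    def test_onset_probability_above_one_rejected(self):
        model = ChronicDiseaseModel(
            make_demography(), make_pa(),
            [make_disease(incidence=0.9, beta=0.2, reference_met=0.0)])
        with pytest.raises(ValueError, match="exceeds 1"):
            model.run(1)

    def test_horizon_contract(self):
        model = ChronicDiseaseModel(make_demography(), make_pa(),
                                    [make_disease()])
        assert model.run(3).n_cycles == 3
        with pytest.raises(ValueError):
            model.run(0)
        with pytest.raises(ValueError):
            model.run("forever")


class TestClosedForms:
    def test_pure_mortality_matches_geometric_survival(self):
        """1,000 people at mortality 0.1/yr leave 729 alive after 3 cycles."""
        demog = make_demography(n_ages=1, counts=1000.0, mortality=0.1)
        model = ChronicDiseaseModel(demog, make_pa(values=(40.0,),
                                                   occupancy=(1.0,)),
                                    [make_disease(incidence=0.0)])
        traj = model.run(3)
        assert traj.alive_end[-1] == pytest.approx(1000 * 0.9 ** 3)

    def test_constant_mortality_survival_curve(self):
        mu = 0.07
        demog = make_demography(n_ages=1, counts=1.0, mortality=mu)
        model = ChronicDiseaseModel(demog, make_pa(values=(40.0,),
                                                   occupancy=(1.0,)), [])
        traj = model.run(10)
        np.testing.assert_allclose(
            traj.alive_end, (1 - mu) ** np.arange(1, 11), rtol=1e-12)

    def test_no_transitions_preserves_counts(self):
        demog = make_demography(n_ages=3, counts=500.0, mortality=0.0)
        model = ChronicDiseaseModel(demog, make_pa(drift=0.01),
                                    [make_disease(incidence=0.0)])
        traj = model.run(5)
        np.testing.assert_allclose(traj.alive_end, 1500.0)
        np.testing.assert_allclose(traj.deaths, 0.0)


class TestInvariants:
    def make_busy_model(self, drift=0.02):
        demog = Demography(50, np.full((4, 2), 250.0),
                           np.tile(np.array([[0.02, 0.015]]), (4, 1)))
        pa = make_pa(values=(5.0, 25.0, 60.0),
                     occupancy=(0.3, 0.4, 0.3), drift=drift)
        diseases = [
            make_disease("diabetes", incidence=0.05, beta=-0.01, excess=0.03),
            make_disease("breast_cancer", incidence=0.04, beta=-0.005,
                         excess=0.05, female_only=True),
        ]
        return ChronicDiseaseModel(demog, pa, diseases)

    def test_closed_cohort_conservation(self):
        model = self.make_busy_model()
        state = model.initial_state()
        total0 = state.total_alive
        for _ in range(10):
            state, _ = model.step_year(state)
            assert state.total_alive + state.cum_deaths == pytest.approx(
                total0, rel=1e-9)

    def test_bit_identical_reruns(self):
        t1 = self.make_busy_model().run(8)
        t2 = self.make_busy_model().run(8)
        assert t1.to_frame().equals(t2.to_frame())

    def test_zero_shift_reproduces_reference_exactly(self):
        model = self.make_busy_model()
        ref = model.run(8)
        shifted = model.run(8, shift_schedule=lambda t: 0.0)
        assert ref.to_frame().equals(shifted.to_frame())

    def test_pa_upshift_lowers_incidence_and_raises_qalys(self):
        model = self.make_busy_model()
        ref = model.run(10)
        up = model.run(10, shift_schedule=lambda t: 10.0)
        for d in ("diabetes", "breast_cancer"):
            assert all(u <= r + 1e-12 for u, r in
                       zip(up.incidence[d], ref.incidence[d]))
        assert all(u >= r - 1e-12 for u, r in zip(up.qalys, ref.qalys))

    def test_linearity_in_cohort_size(self):
        model = self.make_busy_model()
        demog2 = Demography(50, model.demography.counts * 2,
                            model.demography.mortality)
        model2 = ChronicDiseaseModel(demog2, model.pa, model.diseases)
        t1, t2 = model.run(6), model2.run(6)
        np.testing.assert_allclose(2 * np.asarray(t1.qalys), t2.qalys,
                                   rtol=1e-12)
        np.testing.assert_allclose(2 * np.asarray(t1.costs), t2.costs,
                                   rtol=1e-12)

    def test_lifetime_runs_to_extinction(self):
        demog = make_demography(n_ages=2, counts=100.0, mortality=0.5)
        model = ChronicDiseaseModel(demog, make_pa(), [make_disease()])
        traj = model.run("lifetime")
        assert traj.alive_end[-1] < 1e-9 * 200.0


class TestOracleEquivalence:
    """The engine's marginal recursion must match explicit joint-state
    enumeration on small instances (<= 4 occupied strata, 5 cycles)."""

    def compare(self, model, n_cycles=5, shift=0.0):
        schedule = (lambda t: shift) if shift else None
        traj = model.run(n_cycles, shift_schedule=schedule)
        oracle = brute_force_run(
            model.demography, model.pa, model.diseases, n_cycles,
            shift=shift, other_cost_per_capita=model.other_cost_per_capita)
        for key in ("life_years", "qalys", "deaths", "alive_end", "costs"):
            np.testing.assert_allclose(getattr(traj, key), oracle[key],
                                       rtol=1e-10, err_msg=key)
        for d in model.diseases:
            np.testing.assert_allclose(traj.incidence[d.name],
                                       oracle["incidence"][d.name],
                                       rtol=1e-10)
            np.testing.assert_allclose(traj.prevalence[d.name],
                                       oracle["prevalence"][d.name],
                                       rtol=1e-10)

    def test_single_disease_two_strata(self):
        demog = make_demography(n_ages=2, counts=800.0, mortality=0.05)
        model = ChronicDiseaseModel(
            demog, make_pa(values=(10.0, 50.0), occupancy=(0.6, 0.4)),
            [make_disease(incidence=0.08, beta=-0.01, excess=0.04)])
        self.compare(model)

    def test_two_diseases_with_shift(self):
        # enough age headroom that no strata merge within the horizon: with
        # several diseases the engine's per-disease marginal state space is
        # exact as long as populations with different prevalence never pool
        demog = make_demography(n_ages=7, counts=0.0)
        demog.counts[:2, 1] = 500.0
        pa = make_pa(values=(10.0, 50.0), occupancy=(0.5, 0.5), drift=0.0)
        diseases = [
            make_disease("diabetes", incidence=0.06, beta=-0.008,
                         excess=0.02, disutility=0.15, cost=2000.0),
            make_disease("stroke", incidence=0.04, beta=-0.012, excess=0.06,
                         disutility=0.3, cost=8000.0),
        ]
        model = ChronicDiseaseModel(demog, pa, diseases,
                                    other_cost_per_capita=500.0)
        self.compare(model, shift=5.0)

    def test_single_disease_with_drift_and_merging(self):
        # drift and top-age pooling merge strata; with one disease the
        # marginal state space is still the exact joint one
        demog = make_demography(n_ages=2, counts=500.0, mortality=0.03)
        pa = make_pa(values=(10.0, 50.0), occupancy=(0.5, 0.5), drift=0.05)
        model = ChronicDiseaseModel(
            demog, pa, [make_disease(incidence=0.06, beta=-0.008,
                                     excess=0.04)])
        self.compare(model, shift=5.0)

    def test_multi_disease_merging_projection_error_is_negligible(self):
        """When drift pools strata, the engine's independence projection
        deviates from the exact joint enumeration by < 1e-5 relative."""
        demog = make_demography(n_ages=2, counts=500.0, mortality=0.03)
        pa = make_pa(values=(10.0, 50.0), occupancy=(0.5, 0.5), drift=0.05)
        diseases = [
            make_disease("diabetes", incidence=0.06, excess=0.02),
            make_disease("stroke", incidence=0.04, excess=0.06),
        ]
        model = ChronicDiseaseModel(demog, pa, diseases)
        traj = model.run(5)
        oracle = brute_force_run(demog, pa, diseases, 5)
        for key in ("life_years", "qalys", "deaths", "alive_end"):
            np.testing.assert_allclose(getattr(traj, key), oracle[key],
                                       rtol=1e-5, err_msg=key)

    def test_age_varying_inputs_and_female_only(self):
        demog = Demography(50, np.array([[300.0, 400.0], [200.0, 100.0]]),
                           np.array([[0.02, 0.01], [0.06, 0.05]]))
        pa = make_pa(values=(15.0, 45.0), occupancy=(0.5, 0.5), drift=0.02)
        inc = np.array([[0.05, 0.07], [0.09, 0.11]])
        diseases = [
            DiseaseSpec("breast_cancer", inc, -0.006, 40.0,
                        np.array([[0.0, 0.03], [0.0, 0.05]]), 0.2, 4000.0,
                        female_only=True),
        ]
        model = ChronicDiseaseModel(demog, pa, diseases)
        self.compare(model)


class TestValuation:
    def synth_trajectory(self, py, prev_shares, diseases):
        from pacea.cdm import Trajectory
        traj = Trajectory(tuple(d.name for d in diseases))
        traj.person_years_strata.append(py)
        traj.prevalence_strata.append(prev_shares)
        traj.life_years.append(float(py.sum()))
        for d in diseases:
            traj.prevalence[d.name] = [float((py * prev_shares[d.name]).sum())]
        return traj

    def test_healthy_cohort_full_qalys(self):
        d = make_disease(disutility=0.0)
        py = np.full((1, 2, 1), 500.0)
        traj = self.synth_trajectory(py, {d.name: np.zeros((1, 2, 1))}, [d])
        assert qalys(traj, [d])[0] == pytest.approx(1000.0)

    def test_single_disease_disutility(self):
        d = make_disease(disutility=0.2)
        py = np.full((1, 2, 1), 50.0)
        traj = self.synth_trajectory(py, {d.name: np.ones((1, 2, 1))}, [d])
        assert qalys(traj, [d])[0] == pytest.approx(80.0)

    def test_two_disease_combination_rules(self):
        d1 = make_disease("a", disutility=0.1)
        d2 = make_disease("b", disutility=0.1)
        py = np.full((1, 2, 1), 50.0)
        ones = np.ones((1, 2, 1))
        traj = self.synth_trajectory(py, {"a": ones, "b": ones}, [d1, d2])
        assert qalys(traj, [d1, d2])[0] == pytest.approx(100 * 0.9 * 0.9)
        assert qalys(traj, [d1, d2],
                     rule="additive")[0] == pytest.approx(80.0)

    def test_costs_scale_with_prevalence(self):
        d = make_disease(cost=2000.0)
        py = np.full((1, 2, 1), 50.0)
        traj = self.synth_trajectory(py, {d.name: np.ones((1, 2, 1))}, [d])
        assert healthcare_costs(traj, [d])[0] == pytest.approx(200_000.0)
        zero = self.synth_trajectory(py, {d.name: np.zeros((1, 2, 1))}, [d])
        assert healthcare_costs(zero, [d])[0] == 0.0
        # per-capita cost of being alive adds life-years x rate
        assert healthcare_costs(zero, [d], other_cost_per_capita=10.0)[0] \
            == pytest.approx(1000.0)
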