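"""Energy components: likelihood, Laplace prior, composition, constraints,
grouped Lasso."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptlasso import (
    ConstraintSet,
    EnergyModel,
    Experiment,
    GroupedEnergyModel,
    GroupedSpec,
    HardConstraint,
    LaplacePrior,
    LikelihoodSpec,
    ParameterSpace,
    Trajectory,
    UniformPrior,
    build_complete_unimolecular,
    build_modular_toy,
    check_hard_constraints,
    laplace_log_prior,
    log_likelihood,
)
from ptlasso.errors import InvalidHyperparameterError, SpecificationError
from ptlasso.studies import k3_dataset


def flat_trajectory(times, species, value=1.0):
    values = np.full((len(times), len(species)), value)
    return Trajectory(times=times, values=values, species=species)


class TestLogLikelihood:
    def test_perfect_fit_gives_zero(self):
        t = np.array([1.0, 2.0])
        traj = flat_trajectory(t, ("B",), 5.0)
        lik = LikelihoodSpec(["B", "B"], t, [5.0, 5.0], [1.0, 1.0])
        assert log_likelihood(traj, lik) == 0.0

    def test_one_residual_of_one_sigma(self):
        traj = flat_trajectory(np.array([1.0]), ("B",), 6.0)
        lik = LikelihoodSpec(["B"], [1.0], [5.0], [1.0])
        assert log_likelihood(traj, lik) == pytest.approx(-0.5)

    def test_residuals_sigma_and_two_sigma(self):
        traj = flat_trajectory(np.array([1.0, 2.0]), ("B",), 6.0)
        lik = LikelihoodSpec(["B", "B"], [1.0, 2.0], [5.0, 4.0], [1.0, 1.0])
        # residuals 1*sigma and 2*sigma -> -(1 + 4)/2
        assert log_likelihood(traj, lik) == pytest.approx(-2.5)

    def test_missing_observation_time_is_specification_error(self):
        traj = flat_trajectory(np.array([1.0]), ("B",))
        lik = LikelihoodSpec(["B"], [3.0], [1.0], [1.0])
        with pytest.raises(SpecificationError):
            log_likelihood(traj, lik)

    def test_nonfinite_simulation_gives_minus_inf(self):
        traj = flat_trajectory(np.array([1.0]), ("B",), np.nan)
        lik = LikelihoodSpec(["B"], [1.0], [1.0], [1.0])
        assert log_likelihood(traj, lik) == -np.inf

    def test_sigma_floor_applied_to_zero_sd(self):
        lik = LikelihoodSpec(["B", "B"], [0.0, 1.0], [0.0, 100.0], [0.0, 30.0])
        assert lik.sds[0] == pytest.approx(1.0)  # 1% of max mean


class TestLaplacePrior:
    def test_zero_at_location(self):
        assert laplace_log_prior(-10.0, -10.0, 1.0) == 0.0

    @pytest.mark.parametrize("b,expected", [(1.0, -9.0), (0.5, -18.0)])
    def test_width_scales_penalty(self, b, expected):
        assert laplace_log_prior(-1.0, -10.0, b) == pytest.approx(expected)

    def test_invalid_width_rejected(self):
        with pytest.raises(InvalidHyperparameterError):
            laplace_log_prior(0.0, 0.0, 0.0)

    def test_dropped_constant_bookkeeping_normalizes(self):
        """exp(-|x - mu|/b) / (2b) integrates to 1, so the dropped -log 2b
        term is the only normalization."""
        mu, b = -10.0, 1.0
        grid = np.linspace(mu - 40 * b, mu + 40 * b, 200001)
        density = np.exp(laplace_log_prior(grid, mu, b)) / (2 * b)
        assert np.trapezoid(density, grid) == pytest.approx(1.0, abs=1e-4)


@pytest.fixture(scope="module")
def k3_model():
    net = build_complete_unimolecular(3)
    space = ParameterSpace(net.param_names, -12, 3, priors=[LaplacePrior(-10, 1)] * 6)
    model = EnergyModel(net, space, Experiment(LikelihoodSpec.from_dataset(k3_dataset())))
    return net, space, model


class TestEnergyComposition:
    def test_uniform_priors_give_pure_negative_log_likelihood(self):
        net = build_complete_unimolecular(3)
        space = ParameterSpace(net.param_names, -12, 3)
        model = EnergyModel(net, space, Experiment(LikelihoodSpec.from_dataset(k3_dataset())))
        theta = np.full(6, -2.0)
        assert model(theta) == pytest.approx(-model.log_likelihood(theta), abs=1e-12)

    def test_out_of_bounds_theta_is_infinite(self, k3_model):
        _, space, model = k3_model
        theta = np.full(6, -2.0)
        theta[0] = 4.0  # above upper bound 3
        assert model(theta) == np.inf

    def test_zero_penalty_at_prior_mode(self, k3_model):
        _, _, model = k3_model
        theta = np.full(6, -10.0)
        assert model(theta) == pytest.approx(-model.log_likelihood(theta), abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=-11.9, max_value=2.9), min_size=6, max_size=6))
    def test_energy_decomposes_term_by_term(self, theta_list):
        """Independent oracle: E equals -logL plus the sum of |theta-mu|/b
        recomputed per coordinate, to 1e-12 absolute."""
        net = build_complete_unimolecular(3)
        space = ParameterSpace(net.param_names, -12, 3, priors=[LaplacePrior(-10, 1)] * 6)
        model = EnergyModel(net, space, Experiment(LikelihoodSpec.from_dataset(k3_dataset())))
        theta = np.array(theta_list)
        expected = -model.log_likelihood(theta) + sum(abs(v + 10.0) / 1.0 for v in theta)
        assert model(theta) == pytest.approx(expected, abs=1e-12)


class TestHardConstraints:
    def test_strict_inequality_pass_and_fail(self):
        cs = ConstraintSet(hard=[HardConstraint("k_a > k_b")])
        ok, violated = check_hard_constraints({"k_a": 1.0, "k_b": 0.0}, cs)
        assert ok and not violated
        ok, violated = check_hard_constraints({"k_a": 0.0, "k_b": 0.0}, cs)
        assert not ok and len(violated) == 1  # strict: equality fails

    def test_empty_constraint_set_passes(self):
        ok, violated = check_hard_constraints({"k_a": 0.0}, ConstraintSet())
        assert ok and violated == []

    def test_unresolvable_name_is_specification_error(self):
        cs = ConstraintSet(hard=[HardConstraint("k_a > k_missing")])
        with pytest.raises(SpecificationError):
            check_hard_constraints({"k_a": 0.0}, cs)

    def test_linear_combination_with_offset(self):
        c = HardConstraint("k_a > k_b + 1.5")
        assert c.evaluate({"k_a": 2.0, "k_b": 0.0})
        assert not c.evaluate({"k_a": 1.0, "k_b": 0.0})

    def test_violation_makes_energy_infinite(self, k3_model):
        net, space, _ = k3_model
        cs = ConstraintSet(hard=[HardConstraint("k_AB > k_BC")])
        model = EnergyModel(
            net, space, Experiment(LikelihoodSpec.from_dataset(k3_dataset())), constraints=cs
        )
        theta = np.full(6, -10.0)
        theta[space.index("k_AB")], theta[space.index("k_BC")] = -1.0, 0.0
        assert model(theta) == np.inf
        theta[space.index("k_AB")], theta[space.index("k_BC")] = 0.0, -1.0
        assert np.isfinite(model(theta))


class TestGroupedEnergy:
    @pytest.fixture()
    def toy_grouped(self):
        from ptlasso.studies import toy_dataset

        net = build_modular_toy()
        inputs, ds = toy_dataset("pulse", data_seed=5)
        spec = GroupedSpec(modules=net.modules)
        model = GroupedEnergyModel(
            net, spec, Experiment(LikelihoodSpec.from_dataset(ds), inputs=inputs)
        )
        return net, spec, model

    def test_zero_penalty_at_prior_location(self, toy_grouped):
        _, spec, model = toy_grouped
        lam = np.full(model.n_modules, spec.mu)
        k = np.zeros(len(model.k_names))
        vector = np.concatenate([lam, k])
        assert model.penalty(vector) == 0.0

    def test_boundary_of_open_interval_is_infinite(self, toy_grouped):
        _, spec, model = toy_grouped
        vector = np.concatenate([np.full(model.n_modules, spec.mu), np.zeros(len(model.k_names))])
        vector[model.n_modules] = spec.lb  # k' exactly at the boundary
        assert model(vector) == np.inf

    def test_default_hyperparameters_keep_effective_rates_inert(self, toy_grouped):
        """With lambda' at mu = -25 and k' at its maximum ub = 10, the
        effective log10 rate is -15: far below any dynamically relevant
        value, so a prior-confined module is numerically removed."""
        _, spec, model = toy_grouped
        assert spec.mu == -25.0 and spec.lb == -5.0 and spec.ub == 10.0
        vector = np.concatenate(
            [np.full(model.n_modules, spec.mu), np.full(len(model.k_names), spec.ub - 1e-9)]
        )
        theta_eff = model.effective_theta(vector)
        assert np.all(theta_eff <= -15.0 + 1e-6)

    def test_module_without_members_rejected(self):
        with pytest.raises(SpecificationError):
            GroupedSpec(modules={"empty": []})

    def test_grouped_reduces_to_plain_lasso_for_single_wide_module(self):
        """One module holding one reaction with a wide k' box at k' = 0:
        the grouped energy equals the plain Laplace-penalized energy on the
        effective parameter."""
        from ptlasso import Reaction, ReactionNetwork

        net = ReactionNetwork(
            species=["A", "B"],
            reactions=[Reaction(reactants={"A": 1}, products={"B": 1}, param="k_AB")],
            initial_state={"A": 100.0},
            modules={"only": ["k_AB"]},
        )
        t = np.array([1.0, 2.0])
        lik = LikelihoodSpec(["B", "B"], t, [20.0, 30.0], [2.0, 2.0])
        spec = GroupedSpec(modules=net.modules, mu=-2.0, b=1.0, lb=-50.0, ub=50.0,
                           lambda_bounds=(-60.0, 60.0))
        grouped = GroupedEnergyModel(net, spec, Experiment(lik))
        plain_space = ParameterSpace(["k_AB"], -60, 60, priors=[LaplacePrior(-2.0, 1.0)])
        plain = EnergyModel(net, plain_space, Experiment(lik))
        for theta in (-1.0, 0.5, -3.2):
            vector = np.array([theta, 0.0])  # lambda' = theta, k' = 0
            assert grouped(vector) == pytest.approx(plain(np.array([theta])), abs=1e-10)


class TestParameterSpace:
    def test_bounds_must_be_ordered(self):
        with pytest.raises(SpecificationError):
            ParameterSpace(["a"], [1.0], [0.0])

    def test_truncated_laplace_sampling_stays_in_box_and_near_mode(self):
        space = ParameterSpace(["a"], [-12.0], [3.0], priors=[LaplacePrior(-10, 1)])
        rng = np.random.default_rng(0)
        draws = np.array([space.sample(rng)[0] for _ in range(4000)])
        assert draws.min() >= -12.0 and draws.max() <= 3.0
        inside = np.mean(np.abs(draws + 10.0) <= 3.0)
        # truncated-Laplace mass of [-13,-7] clipped to the box
        assert inside == pytest.approx(0.973, abs=0.02)


class TestSimulationFailureContract:
    def test_failed_integration_maps_to_infinite_energy(self):
        """A diverging model inside the sampling box must yield E = +inf
        (rejected move), never an exception escaping the energy call."""
        from ptlasso import Reaction, ReactionNetwork

        net = ReactionNetwork(
            species=["A"],
            reactions=[Reaction(reactants={"A": 1}, products={"A": 2}, param="k_auto")],
            initial_state={"A": 100.0},
        )
        space = ParameterSpace(["k_auto"], [-12.0], [3.0])
        lik = LikelihoodSpec(["A"], [50.0], [100.0], [10.0])
        model = EnergyModel(net, space, Experiment(lik), sim_method="ode")
        assert model(np.array([2.0])) == np.inf      # blows up -> overflow
        assert np.isfinite(model(np.array([-10.0])))  # inert rate integrates
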