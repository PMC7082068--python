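"""Structural tests for reaction networks and the fixture builders."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptlasso import (
    Reaction,
    ReactionNetwork,
    StimulusSegment,
    build_complete_unimolecular,
    build_dose_response_prior,
    build_modular_toy,
    load_network,
    simulate,
)
from ptlasso.errors import InvalidNetworkError
from ptlasso.simulate import RATE_FLOOR


def floor_params(network, **overrides):
    params = {name: RATE_FLOOR for name in network.param_names}
    params.update(overrides)
    return params


class TestCompleteUnimolecular:
    @settings(max_examples=20, deadline=None)
    @given(n=st.integers(min_value=2, max_value=12))
    def test_reaction_count_is_n_times_n_minus_1(self, n):
        net = build_complete_unimolecular(n)
        assert len(net.reactions) == n * (n - 1)
        assert len(set(net.param_names)) == n * (n - 1)

    def test_three_node_network_has_six_reactions(self):
        assert len(build_complete_unimolecular(3).reactions) == 6

    def test_initial_state_is_100_molecules_of_A(self):
        net = build_complete_unimolecular(4)
        assert net.initial_state["A"] == 100.0
        assert all(net.initial_state[sp] == 0.0 for sp in net.species[1:])

    def test_n_below_two_rejected(self):
        with pytest.raises(InvalidNetworkError):
            build_complete_unimolecular(1)

    def test_two_node_conversion_conserves_mass(self):
        net = build_complete_unimolecular(2)
        traj = simulate(net, floor_params(net, k_AB=0.3, k_BA=0.1), np.linspace(0.5, 30, 40))
        np.testing.assert_allclose(traj.total(), 100.0, rtol=1e-6)


class TestDoseResponsePrior:
    def test_six_parameters(self):
        net = build_dose_response_prior()
        assert len(net.param_names) == 6
        assert set(net.param_names) == {"k_s-rs", "k_r-0", "k_s-xs", "k_x-0", "k_xr-x", "k_0-r"}

    def test_linear_submodel_steady_state_proportional_to_s(self):
        """With only S-driven production and first-order decay active the
        steady state is R* = (k_srs / k_r0) * S, linear in the signal."""
        net = build_dose_response_prior()
        params = floor_params(net, **{"k_s-rs": 10.0, "k_r-0": 0.01})
        states = {}
        for s_val in (1.0, 2.0):
            inputs = [StimulusSegment("S", s_val, 0.0, 2001.0)]
            traj = simulate(net, params, np.linspace(10, 2000, 50), inputs=inputs)
            states[s_val] = traj.series("R")[-1]
        assert states[1.0] == pytest.approx(10.0 / 0.01 * 1.0, rel=1e-3)
        assert states[2.0] == pytest.approx(2 * states[1.0], rel=1e-3)

    def test_adaptive_submodel_steady_state_independent_of_s(self):
        """The sniffer motif adapts perfectly: R* = k_srs*k_x0/(k_xrx*k_sxs)
        regardless of S."""
        net = build_dose_response_prior()
        params = floor_params(
            net, **{"k_s-rs": 10.0, "k_xr-x": 10.0, "k_s-xs": 1.0, "k_x-0": 1.0}
        )
        finals = []
        for s_val in (1.0, 2.0):
            inputs = [StimulusSegment("S", s_val, 0.0, 101.0)]
            traj = simulate(net, params, np.linspace(1, 100, 60), inputs=inputs)
            finals.append(traj.series("R")[-1])
        expect = 10.0 * 1.0 / (10.0 * 1.0)
        assert finals[0] == pytest.approx(expect, rel=1e-3)
        assert abs(finals[1] - finals[0]) / finals[0] < 1e-3

    def test_zero_signal_leaves_state_at_initial_values(self):
        net = build_dose_response_prior()
        params = floor_params(net, **{"k_s-rs": 10.0, "k_s-xs": 1.0})
        traj = simulate(net, params, np.linspace(1, 50, 10))  # no stimulus segments: S = 0
        assert np.all(traj.series("R") < 1e-6)
        assert np.all(traj.series("X") < 1e-6)


class TestModularToy:
    def test_modules_partition_reactions(self):
        net = build_modular_toy()
        assigned = [p for params in net.modules.values() for p in params]
        assert sorted(assigned) == sorted(net.param_names)
        assert len(net.modules) >= 3
        assert len(net.species) <= 8

    def test_feedback_dispensable_under_pulse_required_under_continuous(self):
        """The defining property of the fixture: removing the feedback
        module barely changes the response to a short stimulus pulse, but
        changes it grossly under continuous stimulation."""
        from ptlasso.studies import TOY_TRUTH, toy_protocol

        net = build_modular_toy()
        full = floor_params(net, **TOY_TRUTH)
        nofb = dict(full)
        nofb["k_af"] = nofb["k_fa"] = RATE_FLOOR

        for protocol, dispensable in (("pulse", True), ("continuous", False)):
            inputs, obs = toy_protocol(protocol)
            r_full = simulate(net, full, obs, inputs=inputs).series("R")
            r_nofb = simulate(net, nofb, obs, inputs=inputs).series("R")
            gap = np.max(np.abs(r_full - r_nofb)) / np.max(r_full)
            if dispensable:
                assert gap < 0.10  # within the 10% observation noise
            else:
                assert gap > 0.5


class TestValidationAndIO:
    def test_unknown_species_rejected(self):
        with pytest.raises(InvalidNetworkError):
            ReactionNetwork(
                species=["A"],
                reactions=[Reaction(reactants={"A": 1}, products={"Z": 1}, param="k")],
                initial_state={"A": 1.0},
            )

    def test_duplicate_parameter_rejected(self):
        rxns = [
            Reaction(reactants={"A": 1}, products={"B": 1}, param="k"),
            Reaction(reactants={"B": 1}, products={"A": 1}, param="k"),
        ]
        with pytest.raises(InvalidNetworkError):
            ReactionNetwork(species=["A", "B"], reactions=rxns, initial_state={"A": 1.0})

    def test_negative_initial_abundance_rejected(self):
        with pytest.raises(InvalidNetworkError):
            ReactionNetwork(species=["A"], reactions=[], initial_state={"A": -1.0})

    def test_non_integer_stoichiometry_rejected(self):
        with pytest.raises(InvalidNetworkError):
            Reaction(reactants={"A": 0.5}, products={"B": 1}, param="k")

    def test_units_follow_kinetic_order(self):
        first = Reaction(reactants={"A": 1}, products={"B": 1}, param="k1")
        second = Reaction(reactants={"A": 1}, products={}, modifiers=("B",), param="k2")
        assert first.units == "s^-1"
        assert second.units == "molecule^-1 s^-1"

    @pytest.mark.parametrize("builder", [lambda: build_complete_unimolecular(3),
                                         build_dose_response_prior, build_modular_toy])
    def test_yaml_round_trip(self, builder, tmp_path):
        from ptlasso import save_network

        net = builder()
        path = tmp_path / "net.yaml"
        save_network(net, path)
        loaded = load_network(path)
        assert loaded.to_dict() == net.to_dict()

    @pytest.mark.parametrize(
        "fixture,builder",
        [
            ("k3_network.yaml", lambda: build_complete_unimolecular(3)),
            ("k5_network.yaml", lambda: build_complete_unimolecular(5)),
            ("dose_response_prior.yaml", build_dose_response_prior),
            ("modular_toy.yaml", build_modular_toy),
        ],
    )
    def test_shipped_fixtures_match_builders(self, fixture, builder):
        from pathlib import Path
        import ptlasso

        path = Path(ptlasso.__file__).parent / "fixtures" / fixture
        assert load_network(path).to_dict() == builder().to_dict()
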