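"""Core reaction-network representation and integrator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from apopsynergy.network import (Event, IntegrationError,
                                 NetworkDefinitionError, ReactionNetwork,
                                 assemble_rates, default_grid, integrate,
                                 set_turnover)


def two_species_binding(k_on=1.0, k_off=0.0):
    net = ReactionNetwork("bind")
    net.add_species("A", 2.0).add_species("B", 3.0).add_species("C", 0.0)
    net.add_reaction("on", ("A", "B"), ("C",), k=k_on)
    if k_off:
        net.add_reaction("off", ("C",), ("A", "B"), k=k_off)
    return net


class TestAssembleRates:
    def test_bimolecular_mass_action_derivative(self):
        f = assemble_rates(two_species_binding())
        dy = f(0.0, np.array([2.0, 3.0, 0.0]))
        assert dy == pytest.approx([-6.0, -6.0, 6.0])

    def test_zero_state_zero_derivative(self):
        f = assemble_rates(two_species_binding())
        assert f(0.0, np.zeros(3)) == pytest.approx([0.0, 0.0, 0.0])

    def test_catalyst_has_zero_net_stoichiometry(self):
        net = ReactionNetwork("cat")
        net.add_species("S", 10.0).add_species("P", 0.0)
        net.add_species("E", 5.0)
        net.add_reaction("conv", ("S",), ("P",), modifiers=("E",), k=0.1)
        f = assemble_rates(net)
        dy = f(0.0, np.array([10.0, 0.0, 5.0]))
        assert dy == pytest.approx([-5.0, 5.0, 0.0])

    def test_unknown_species_rejected(self):
        net = ReactionNetwork("bad")
        net.add_species("A", 1.0)
        with pytest.raises(NetworkDefinitionError, match="unknown species"):
            net.add_reaction("r", ("A", "Ghost"), (), k=1.0)

    @pytest.mark.parametrize("kind,reactants,products", [
        ("zeroth_order_synthesis", ("A",), ()),
        ("first_order_degradation", ("A", "A"), ()),
        ("first_order_degradation", ("A",), ("A",)),
    ])
    def test_kind_shape_violations(self, kind, reactants, products):
        net = ReactionNetwork("shape")
        net.add_species("A", 1.0)
        with pytest.raises(NetworkDefinitionError):
            net.add_reaction("r", reactants, products, k=1.0, kind=kind)

    @given(state=st.lists(st.floats(0, 1e6), min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_flux_non_negative_for_non_negative_state(self, state):
        rates = assemble_rates(two_species_binding(k_on=0.5, k_off=2.0))
        assert (rates.fluxes(np.array(state)) >= 0).all()


class TestIntegrate:
    def test_first_order_decay_matches_closed_form(self):
        net = ReactionNetwork("decay")
        net.add_species("A", 100.0)
        net.add_reaction("deg", ("A",), (), k=0.1,
                         kind="first_order_degradation")
        traj = integrate(net, time_grid=default_grid(48.0),
                         rtol=1e-10, atol=1e-10)
        expected = 100.0 * np.exp(-0.1 * traj.times)
        assert np.max(np.abs(traj.get("A") - expected) / 100.0) < 1e-8

    def test_linear_chain_matches_matrix_exponential(self):
        # three first-order reactions: A -> B -> C and A -> 0
        net = ReactionNetwork("chain")
        net.add_species("A", 1000.0).add_species("B", 0.0)
        net.add_species("C", 0.0)
        net.add_reaction("ab", ("A",), ("B",), k=0.7)
        net.add_reaction("bc", ("B",), ("C",), k=0.3)
        net.add_reaction("a0", ("A",), (), k=0.1,
                         kind="first_order_degradation")
        M = np.array([[-0.8, 0.0, 0.0],
                      [0.7, -0.3, 0.0],
                      [0.0, 0.3, 0.0]])
        grid = default_grid(10.0, step=0.5)
        traj = integrate(net, time_grid=grid, rtol=1e-10, atol=1e-12)
        y0 = np.array([1000.0, 0.0, 0.0])
        exact = np.stack([expm(M * t) @ y0 for t in grid], axis=1)
        rel = np.abs(traj.values - exact) / np.maximum(exact, 1e-3)
        assert rel.max() < 1e-6

    def test_reversible_binding_reaches_analytic_equilibrium(self):
        net = ReactionNetwork("rev")
        net.add_species("X", 50.0).add_species("Y", 0.0)
        net.add_reaction("f", ("X",), ("Y",), k=2.0)
        net.add_reaction("b", ("Y",), ("X",), k=1.0)
        traj = integrate(net, time_grid=default_grid(20.0))
        assert traj.get("Y")[-1] / traj.get("X")[-1] == pytest.approx(
            2.0, rel=1e-5)

    def test_event_sets_species_at_its_time(self):
        net = ReactionNetwork("ev")
        net.add_species("TRAIL", 0.0)
        traj = integrate(net, events=[Event(1.0, "TRAIL", 1200.0)],
                         time_grid=default_grid(2.0))
        assert (traj.get("TRAIL")[traj.times < 1.0] == 0).all()
        assert (traj.get("TRAIL")[traj.times >= 1.0] == 1200.0).all()

    def test_no_events_zero_rates_constant_trajectory(self):
        net = two_species_binding(k_on=0.0)
        traj = integrate(net, time_grid=default_grid(5.0))
        assert np.allclose(traj.values, traj.values[:, :1])

    def test_parameter_event_changes_rate(self):
        net = ReactionNetwork("pev")
        net.add_species("A", 100.0)
        net.add_reaction("deg", ("A",), (), k=0.0,
                         kind="first_order_degradation")
        traj = integrate(net, events=[Event(5.0, "k_deg", 1.0)],
                         time_grid=default_grid(10.0))
        assert traj.at("A", 5.0) == pytest.approx(100.0, rel=1e-6)
        assert traj.at("A", 10.0) == pytest.approx(100.0 * np.exp(-5.0),
                                                   rel=1e-4)

    def test_unknown_event_target_raises(self):
        net = two_species_binding()
        with pytest.raises(NetworkDefinitionError, match="unknown"):
            integrate(net, events=[Event(1.0, "nope", 1.0)],
                      time_grid=default_grid(2.0))

    def test_event_before_grid_start_raises(self):
        net = two_species_binding()
        with pytest.raises(ValueError, match="precedes"):
            integrate(net, events=[Event(-2.0, "A", 1.0)],
                      time_grid=default_grid(2.0))


class TestTurnover:
    def make_net(self, k_deg=0.01):
        net = ReactionNetwork("turn")
        net.add_species("C", 10000.0)
        net.add_reaction("deg_C", ("C",), (), k=k_deg,
                         kind="first_order_degradation")
        return net

    def test_synthesis_balances_degradation(self):
        net = set_turnover(self.make_net(), ["C"])
        assert net.parameters["k_synth_C"] == pytest.approx(100.0)

    def test_treatment_free_steady_state_over_48h(self):
        net = set_turnover(self.make_net(), ["C"])
        traj = integrate(net, time_grid=default_grid(48.0))
        assert np.max(np.abs(traj.get("C") / 10000.0 - 1.0)) < 0.01

    def test_zero_degradation_constant_rejected(self):
        with pytest.raises(NetworkDefinitionError, match="> 0"):
            set_turnover(self.make_net(k_deg=0.0), ["C"])

    def test_species_without_degradation_rejected(self):
        net = ReactionNetwork("nodeg")
        net.add_species("C", 100.0)
        with pytest.raises(NetworkDefinitionError, match="degradation"):
            set_turnover(net, ["C"])


class TestSerialization:
    def test_yaml_round_trip_is_lossless(self, tmp_path, combo_variant):
        path = tmp_path / "model.yaml"
        combo_variant.network.to_yaml(path)
        back = ReactionNetwork.from_yaml(path)
        assert back.to_dict() == combo_variant.network.to_dict()

    def test_malformed_config_raises(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("just a string, not a model\n")
        with pytest.raises(NetworkDefinitionError, match="malformed"):
            ReactionNetwork.from_yaml(path)

    def test_missing_fields_raise(self):
        with pytest.raises(NetworkDefinitionError, match="missing"):
            ReactionNetwork.from_dict({"species": [{"name": "A"}]})


def test_conserved_receptor_pool_constant(combo_variant, combo_trajectory):
    """Receptor-containing forms have zero net stoichiometry and no
    turnover, so their sum is constant along any trajectory."""
    total = sum(combo_trajectory.get(s)
                for s in ("R", "R_primed", "DISC", "flip_DISC"))
    assert np.max(np.abs(total - total[0])) / total[0] < 1e-4
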