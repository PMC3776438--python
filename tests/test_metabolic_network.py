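"""Network container invariants, knockouts, community assembly and the LP."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dfba_coculture import (
    MetabolicNetwork,
    PhenotypeCriteria,
    ToyNetworkConfig,
    apply_knockouts,
    bruteforce_lp,
    combine_networks,
    load_sbml,
    make_toy_species,
    screen_respiratory_knockouts,
    solve_community_fba,
    solve_fba,
    write_sbml,
)
from dfba_coculture.metabolic_network import ConfigurationError, ModelError

from conftest import toy_optimum


def tiny_network(**overrides):
    kwargs = dict(
        reaction_ids=["EX_a", "CONV", "BIO"],
        metabolite_ids=["a", "b"],
        stoichiometry=[[-1.0, -1.0, 0.0], [0.0, 1.0, -1.0]],
        lower_bounds=[-10.0, 0.0, 0.0],
        upper_bounds=[0.0, 100.0, 100.0],
        objective_weights=[0.0, 0.0, 1.0],
        exchange_map={"glucose": "EX_a"},
    )
    kwargs.update(overrides)
    return MetabolicNetwork(**kwargs)


class TestNetworkInvariants:
    def test_valid_network_roundtrips_fields(self):
        net = tiny_network()
        assert net.n_reactions == 3 and net.n_metabolites == 2
        assert net.index("CONV") == 1

    @pytest.mark.parametrize(
        "overrides",
        [
            {"stoichiometry": [[-1.0, 0.0], [0.0, 1.0]]},  # wrong shape
            {"lower_bounds": [1.0, 0.0, 0.0]},  # lb > ub on EX_a
            {"objective_weights": [1.0]},  # wrong length
            {"exchange_map": {"glucose": "NOPE"}},
            {"maintenance_reaction_id": "NOPE"},
            {"reaction_ids": ["EX_a", "EX_a", "BIO"]},  # duplicate ids
        ],
    )
    def test_invalid_networks_rejected(self, overrides):
        with pytest.raises(ModelError):
            tiny_network(**overrides)


class TestKnockouts:
    def test_empty_knockout_list_is_identity(self, cerevisiae_model):
        net = cerevisiae_model.network
        assert apply_knockouts(net, []) == net

    def test_knockout_zeroes_bounds_and_preserves_original(self, cerevisiae_model):
        net = cerevisiae_model.network
        ko = apply_knockouts(net, ["RESP"])
        j = ko.index("RESP")
        assert ko.lower_bounds[j] == ko.upper_bounds[j] == 0.0
        assert net.upper_bounds[net.index("RESP")] > 0.0

    def test_unknown_reaction_raises(self, cerevisiae_model):
        with pytest.raises(KeyError, match="NOPE"):
            apply_knockouts(cerevisiae_model.network, ["NOPE"])

    def test_respiration_knockout_drops_to_fermentative_growth(
        self, glucose_cfg, cerevisiae_model
    ):
        """Aerobic growth after the knockout equals the fermentation-only
        optimum computed by hand, and ethanol secretion switches on."""
        caps = {"glucose": 10.0, "oxygen": 60.0}
        ko = apply_knockouts(cerevisiae_model.network, ["RESP"])
        sol = solve_fba(ko, caps)
        expected = toy_optimum(glucose_cfg, caps, resp_ko=True)
        assert sol.objective == pytest.approx(expected["mu"], abs=1e-9)
        assert sol.members["only"].exchange["ethanol"] == pytest.approx(
            expected["ethanol"], abs=1e-9
        )

    def test_knockout_never_improves_growth(self, cerevisiae_model):
        caps = {"glucose": 8.0, "oxygen": 20.0}
        full = solve_fba(cerevisiae_model.network, caps)
        ko = solve_fba(apply_knockouts(cerevisiae_model.network, ["RESP"]), caps)
        assert ko.objective <= full.objective + 1e-12


class TestCommunityAssembly:
    def test_block_diagonal_dimensions_and_zero_off_blocks(
        self, cerevisiae_model, stipitis_model
    ):
        a, b = cerevisiae_model.network, stipitis_model.network
        comm = combine_networks([("c", a), ("s", b)])
        A = comm.combined_stoichiometry()
        assert A.shape == (
            a.n_metabolites + b.n_metabolites,
            a.n_reactions + b.n_reactions,
        )
        assert not A[: a.n_metabolites, a.n_reactions:].any()
        assert not A[a.n_metabolites:, : a.n_reactions].any()
        assert comm.reaction_slices["s"] == slice(
            a.n_reactions, a.n_reactions + b.n_reactions
        )

    def test_duplicate_labels_rejected(self, cerevisiae_model):
        net = cerevisiae_model.network
        with pytest.raises(ConfigurationError, match="duplicate"):
            combine_networks([("c", net), ("c", net)])

    def test_zeroed_member_reduces_to_single_species_optimum(
        self, cerevisiae_model, stipitis_model
    ):
        comm = combine_networks(
            [("c", cerevisiae_model.network), ("s", stipitis_model.network)]
        )
        caps_c = {"glucose": 5.0, "oxygen": 10.0}
        zeroed = {"glucose": 0.0, "xylose": 0.0, "oxygen": 0.0}
        both = solve_community_fba(
            comm,
            {"c": caps_c, "s": zeroed},
            extra_bounds={
                "s": {
                    rid: (0.0, 0.0) for rid in stipitis_model.network.reaction_ids
                }
            },
        )
        alone = solve_fba(cerevisiae_model.network, caps_c)
        assert both.objective == pytest.approx(alone.objective, abs=1e-9)
        assert both.members["c"].mu == pytest.approx(alone.objective, abs=1e-9)

    def test_single_member_community_matches_member(self, stipitis_model):
        caps = {"glucose": 3.0, "xylose": 2.0, "oxygen": 4.0}
        comm = combine_networks([("s", stipitis_model.network)])
        assert solve_community_fba(comm, {"s": caps}).objective == pytest.approx(
            solve_fba(stipitis_model.network, caps).objective, abs=1e-12
        )


class TestCommunityFBA:
    def test_glucose_limited_community_matches_hand_vertex(
        self, glucose_cfg, diauxic_cfg, cerevisiae_model, stipitis_model
    ):
        """Per-member caps decouple the LP, so the community optimum is the
        sum of the members' hand-computed optima."""
        comm = combine_networks(
            [("c", cerevisiae_model.network), ("s", stipitis_model.network)]
        )
        caps = {
            "c": {"glucose": 4.0, "oxygen": 6.0},
            "s": {"glucose": 2.0, "xylose": 1.0, "oxygen": 3.0},
        }
        sol = solve_community_fba(comm, caps)
        mu_c = toy_optimum(glucose_cfg, caps["c"])["mu"]
        mu_s = toy_optimum(diauxic_cfg, caps["s"])["mu"]
        assert sol.members["c"].mu == pytest.approx(mu_c, abs=1e-9)
        assert sol.members["s"].mu == pytest.approx(mu_s, abs=1e-9)
        assert sol.objective == pytest.approx(mu_c + mu_s, abs=1e-9)

    def test_objective_equals_member_mu_sum_and_balances_hold(
        self, cerevisiae_model, stipitis_model
    ):
        comm = combine_networks(
            [("c", cerevisiae_model.network), ("s", stipitis_model.network)]
        )
        sol = solve_community_fba(
            comm,
            {
                "c": {"glucose": 6.0, "oxygen": 2.0},
                "s": {"glucose": 3.0, "xylose": 2.0, "oxygen": 5.0},
            },
        )
        assert sol.optimal
        assert sol.objective == pytest.approx(
            sum(m.mu for m in sol.members.values()), abs=1e-9
        )
        assert sol.residual < 1e-9

    def test_unmeetable_maintenance_is_infeasible(self, cerevisiae_model):
        """Zero substrate cannot cover the nonzero ATP maintenance demand."""
        sol = solve_fba(
            cerevisiae_model.network, {"glucose": 0.0, "oxygen": 10.0}
        )
        assert sol.status == "infeasible"
        assert not sol.optimal

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        g=st.floats(0.5, 20.0),
        o=st.floats(0.0, 30.0),
        bump=st.floats(0.0, 10.0),
    )
    def test_raising_caps_never_decreases_objective(self, g, o, bump):
        net = make_toy_species(ToyNetworkConfig(), "wildtype").network
        lo = solve_fba(net, {"glucose": g, "oxygen": o})
        hi = solve_fba(net, {"glucose": g + bump, "oxygen": o + bump})
        assert lo.optimal and hi.optimal
        assert hi.objective >= lo.objective - 1e-9

    def test_parsimonious_solution_is_reproducible(self, stipitis_model):
        caps = {"glucose": 3.0, "xylose": 2.0, "oxygen": 4.0}
        a = solve_fba(stipitis_model.network, caps)
        b = solve_fba(stipitis_model.network, caps)
        np.testing.assert_array_equal(
            a.members["only"].fluxes, b.members["only"].fluxes
        )

    def test_parsimonious_removes_futile_flux(self):
        """Two parallel identical routes: growth is degenerate but the
        minimum-|v| solution never sends flux through both inefficiently."""
        net = MetabolicNetwork(
            reaction_ids=["EX_a", "P1", "P2", "BIO"],
            metabolite_ids=["a", "b"],
            stoichiometry=[
                [-1.0, -1.0, -1.0, 0.0],
                [0.0, 1.0, 1.0, -1.0],
            ],
            lower_bounds=[-5.0, -100.0, -100.0, 0.0],
            upper_bounds=[0.0, 100.0, 100.0, 100.0],
            objective_weights=[0.0, 0.0, 0.0, 1.0],
            exchange_map={"glucose": "EX_a"},
        )
        sol = solve_fba(net, {"glucose": 5.0})
        v = sol.members["only"].fluxes
        # total |flux| through the parallel pair equals the net requirement
        assert abs(v[1]) + abs(v[2]) == pytest.approx(5.0, abs=1e-9)


class TestKnockoutScreen:
    def _reference(self, net):
        return solve_fba(net, {"glucose": 10.0, "oxygen": 60.0, "ethanol": 0.0})

    def test_screen_finds_electron_transport_pair(self):
        """With an ethanol-respiring wild type, only the double knockout of
        both mitochondrial oxidative routes reproduces the mutant phenotype:
        lower biomass yield, higher ethanol yield, lower oxygen demand and
        no growth on ethanol."""
        cfg = ToyNetworkConfig(substrates=("glucose", "ethanol"))
        net = make_toy_species(cfg, "wildtype").network
        medium = {"glucose": 10.0, "oxygen": 60.0, "ethanol": 0.0}
        nonfermentable = {"glucose": 0.0, "oxygen": 60.0, "ethanol": 20.0}
        accepted = screen_respiratory_knockouts(
            net,
            PhenotypeCriteria(),
            solve_fba(net, medium),
            medium=medium,
            nonfermentable_medium=nonfermentable,
        )
        assert accepted == [("ETOH_RESP", "RESP")]

    def test_single_respiration_knockout_accepted_without_ethanol_route(
        self, cerevisiae_model
    ):
        net = cerevisiae_model.network
        medium = {"glucose": 10.0, "oxygen": 60.0}
        accepted = screen_respiratory_knockouts(
            net,
            PhenotypeCriteria(),
            solve_fba(net, medium),
            medium=medium,
            include_pairs=False,
        )
        assert accepted == [("RESP",)]

    def test_impossible_criteria_give_empty_list(self, cerevisiae_model):
        net = cerevisiae_model.network
        medium = {"glucose": 10.0, "oxygen": 60.0}
        criteria = PhenotypeCriteria(
            biomass_yield_direction="higher",  # a knockout cannot raise it
            ethanol_yield_direction="higher",
            oxygen_demand_direction="lower",
        )
        assert (
            screen_respiratory_knockouts(
                net, criteria, solve_fba(net, medium), medium=medium
            )
            == []
        )

    def test_no_mitochondrial_reactions_is_an_error(self):
        cfg = ToyNetworkConfig(substrates=("xylose",))
        net = make_toy_species(cfg, "fermenter").network
        medium = {"xylose": 5.0, "oxygen": 10.0}
        with pytest.raises(ConfigurationError, match="mitochondrial"):
            screen_respiratory_knockouts(
                net, PhenotypeCriteria(), solve_fba(net, medium), medium=medium
            )


class TestSbmlRoundTrip:
    def test_toy_network_roundtrips_exactly(self, tmp_path, stipitis_model):
        path = tmp_path / "toy.xml"
        write_sbml(stipitis_model.network, str(path), "toy_stipitis")
        reloaded = load_sbml(str(path))
        assert reloaded == stipitis_model.network
        assert reloaded.compartment_of == stipitis_model.network.compartment_of
        assert reloaded.maintenance_reaction_id == "ATPM"

    def test_unreadable_file_raises_model_error(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("this is not SBML")
        with pytest.raises(ModelError):
            load_sbml(str(bad))

    def test_exchange_override_pins_ambiguity(self, tmp_path, stipitis_model):
        path = tmp_path / "toy.xml"
        write_sbml(stipitis_model.network, str(path))
        net = load_sbml(str(path), exchange_overrides={"glucose": "EX_xyl"})
        assert net.exchange_map["glucose"] == "EX_xyl"


class TestBruteforceOracle:
    def test_constructed_infeasible_instance_agrees(self, cerevisiae_model):
        caps = {"glucose": 0.0, "oxygen": 0.0}
        lp = solve_fba(cerevisiae_model.network, caps)
        bf = bruteforce_lp(cerevisiae_model.network, {"only": caps})
        assert lp.status == bf.status == "infeasible"

    def test_oracle_refuses_large_networks(self):
        net = MetabolicNetwork(
            reaction_ids=[f"R{i}" for i in range(13)],
            metabolite_ids=["m"],
            stoichiometry=np.zeros((1, 13)),
            lower_bounds=np.zeros(13),
            upper_bounds=np.ones(13),
            objective_weights=np.ones(13),
        )
        with pytest.raises(ValueError, match="refuses"):
            bruteforce_lp(net)
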