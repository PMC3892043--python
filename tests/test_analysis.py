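"""Attractors, HTGs, pseudo-output reduction, circuits and functionality."""

import networkx as nx
import pytest

from qualm import (
    ALL,
    Circuit,
    GeneratorParams,
    UpdateScheme,
    attractors,
    build_htg,
    build_stg,
    clamp,
    enumerate_circuits,
    functionality_context,
    infer_regulatory_graph,
    random_model,
    reduce_outputs,
    stable_states,
)

from conftest import brute_force_stable_states, reachability_attractors


class TestStableStates:
    def test_toy_has_four_stable_states(self, toy):
        found = [toy.state_tuple(s) for s in stable_states(toy)]
        assert found == [(0, 0, 0), (0, 1, 0), (1, 0, 1), (1, 1, 0)]

    def test_negative_loop_has_none(self, motifs):
        assert stable_states(motifs["negative_2loop"]) == []

    def test_positive_loop_has_both_poles(self, motifs):
        model = motifs["positive_2loop"]
        assert [model.state_tuple(s) for s in stable_states(model)] == [(0, 0), (1, 1)]

    @pytest.mark.parametrize("n_species", [6, 9, 12])
    def test_pruned_search_equals_brute_force(self, n_species, random_models):
        for model in random_models(6, n_species=n_species, max_regulators=3):
            assert stable_states(model) == brute_force_stable_states(model)

    def test_multivalued_search_equals_brute_force(self, random_models):
        for model in random_models(4, n_species=4, max_level=2):
            assert stable_states(model) == brute_force_stable_states(model)


class TestAttractors:
    def test_toy_sync_attractors_are_the_stable_states(self, toy):
        stg = build_stg(toy, ALL, UpdateScheme.synchronous())
        atts = attractors(stg)
        assert all(a.kind == "stable-state" for a in atts)
        assert sorted(min(a.states) for a in atts) == [
            (0, 0, 0), (0, 1, 0), (1, 0, 1), (1, 1, 0),
        ]

    def test_negative_loop_async_single_elementary_cycle(self, motifs):
        stg = build_stg(motifs["negative_2loop"], ALL, UpdateScheme.asynchronous())
        atts = attractors(stg)
        assert len(atts) == 1
        assert atts[0].kind == "cyclic"
        assert atts[0].size == 4
        assert atts[0].elementary is True

    def test_positive_loop_sync_has_stable_pair_and_nonelementary_cycle(self, motifs):
        stg = build_stg(motifs["positive_2loop"], ALL, UpdateScheme.synchronous())
        atts = attractors(stg)
        kinds = sorted(a.kind for a in atts)
        assert kinds == ["cyclic", "stable-state", "stable-state"]
        cyc = next(a for a in atts if a.kind == "cyclic")
        assert sorted(cyc.states) == [(0, 1), (1, 0)]
        assert cyc.elementary is False

    def test_matches_reachability_oracle_on_random_models(self, random_models):
        for model in random_models(10, n_species=6):
            for scheme in (UpdateScheme.synchronous(), UpdateScheme.asynchronous()):
                stg = build_stg(model, ALL, scheme)
                ours = sorted(frozenset(a.states) for a in attractors(stg))
                oracle = sorted(frozenset(s) for s in reachability_attractors(stg.graph))
                assert ours == oracle

    def test_async_attractors_contain_every_stable_state(self, random_models):
        for model in random_models(10, n_species=6):
            stg = build_stg(model, ALL, UpdateScheme.asynchronous())
            stable = {model.state_tuple(s) for s in stable_states(model)}
            att_states = {min(a.states) for a in attractors(stg) if a.kind == "stable-state"}
            assert stable == att_states


class TestHTG:
    def test_toy_sync_htg_has_eight_singleton_nodes(self, toy):
        stg = build_stg(toy, ALL, UpdateScheme.synchronous())
        htg = build_htg(stg)
        assert len(htg) == 8
        assert sum(1 for n in htg.nodes if n.cls == "attractor") == 4
        assert sum(1 for n in htg.nodes if n.cls == "irreversible") == 4
        assert all(n.size == 1 for n in htg.nodes)

    def test_single_cycle_stg_is_one_attractor_node(self, motifs):
        stg = build_stg(
            motifs["negative_2loop"], ALL, UpdateScheme.asynchronous()
        )
        htg = build_htg(stg)
        assert len(htg) == 1
        assert htg.nodes[0].cls == "attractor"
        assert htg.nodes[0].size == 4

    def test_linear_chain_groups_into_one_irreversible_node(self, toy):
        # sync trajectory from (1,0,0) is a 1-state chain into a fixed point
        stg = build_stg(toy, [{"A": 1, "B": 0, "C": 0}], UpdateScheme.synchronous())
        htg = build_htg(stg)
        classes = sorted(n.cls for n in htg.nodes)
        assert classes == ["attractor", "irreversible"]

    def test_partition_and_terminal_nodes_on_random_models(self, random_models):
        for model in random_models(8, n_species=6):
            for scheme in (UpdateScheme.synchronous(), UpdateScheme.asynchronous()):
                stg = build_stg(model, ALL, scheme)
                htg = build_htg(stg)
                all_states = [s for n in htg.nodes for s in n.states]
                assert len(all_states) == len(set(all_states)) == len(stg)
                terminal = {
                    frozenset(htg.nodes[i].states)
                    for i in htg.graph.nodes
                    if htg.graph.out_degree(i) == 0
                }
                att = {frozenset(a.states) for a in attractors(stg)}
                assert terminal == att
                # terminal HTG nodes are labelled as attractors and vice versa
                assert terminal == {
                    frozenset(n.states) for n in htg.nodes if n.cls == "attractor"
                }

    def test_htg_is_acyclic(self, random_models):
        for model in random_models(5, n_species=6):
            stg = build_stg(model, ALL, UpdateScheme.asynchronous())
            htg = build_htg(stg)
            assert nx.is_directed_acyclic_graph(htg.graph)


class TestReduceOutputs:
    def test_toy_removes_the_readout(self, toy):
        reduced, removed = reduce_outputs(toy)
        assert removed == ["C"]
        assert reduced.species_order == ("A", "B")
        assert len(stable_states(reduced)) == 4

    def test_cascade_removes_iterated_sinks(self):
        from qualm import chain

        reduced, removed = reduce_outputs(chain(4))
        assert removed == ["S4", "S3", "S2"]
        assert reduced.species_order == ("S1",)

    def test_loops_remove_nothing(self, motifs):
        for name in ("positive_2loop", "negative_2loop"):
            _, removed = reduce_outputs(motifs[name])
            assert removed == []

    def test_attractors_preserved_and_projected(self, random_models):
        """Pseudo-output removal keeps the number and projected states of attractors."""
        checked = 0
        for model in random_models(40, n_species=7, max_regulators=3):
            reduced, removed = reduce_outputs(model)
            if not removed:
                continue
            checked += 1
            keep = [model.species_order.index(s) for s in reduced.species_order]
            full = attractors(build_stg(model, ALL, UpdateScheme.asynchronous()))
            red = attractors(build_stg(reduced, ALL, UpdateScheme.asynchronous()))
            assert len(full) == len(red)
            projected = {
                frozenset(tuple(st[i] for i in keep) for st in a.states) for a in full
            }
            assert projected == {frozenset(a.states) for a in red}
        assert checked >= 10  # the generator must actually produce sinks


class TestCircuits:
    def test_two_loops_have_expected_signs(self, motifs):
        for name, sign in (("positive_2loop", "+"), ("negative_2loop", "-")):
            graph = infer_regulatory_graph(motifs[name])
            circs = enumerate_circuits(graph)
            assert len(circs) == 1
            assert circs[0].species == ("X", "Y")
            assert circs[0].sign == sign

    def test_toy_graph_is_acyclic(self, toy):
        assert enumerate_circuits(infer_regulatory_graph(toy)) == []

    def test_dual_edges_expand_to_both_signed_variants(self):
        from qualm import RegulatoryGraph

        graph = RegulatoryGraph(("X", "Y"), (("X", "Y", "dual"), ("Y", "X", "+")))
        circs = enumerate_circuits(graph)
        assert sorted(c.sign for c in circs) == ["+", "-"]

    def test_max_len_bound_respected(self):
        from qualm import RegulatoryGraph

        graph = RegulatoryGraph(
            ("A", "B", "C"),
            (("A", "B", "+"), ("B", "C", "+"), ("C", "A", "+"), ("A", "A", "+")),
        )
        short = enumerate_circuits(graph, max_len=1)
        assert [c.species for c in short] == [("A",)]
        full = enumerate_circuits(graph)
        assert sorted(len(c.species) for c in full) == [1, 3]


class TestFunctionalityContext:
    def test_gated_loop_context_is_inhibitor_off(self, motifs):
        model = motifs["gated_loop"]
        circ = enumerate_circuits(infer_regulatory_graph(model))[0]
        assert circ.species == ("X", "Y") and circ.sign == "+"
        ctx = functionality_context(model, circ)
        assert not ctx.empty and ctx.exact
        assert ctx.as_dict() == {"Z": frozenset({0})}

    def test_bare_positive_loop_is_always_functional(self, motifs):
        model = motifs["positive_2loop"]
        circ = enumerate_circuits(infer_regulatory_graph(model))[0]
        ctx = functionality_context(model, circ)
        assert not ctx.empty
        assert ctx.constraints == ()

    def test_nonfunctional_edge_gives_empty_context(self, motifs):
        # claim functionality with the wrong sign: never satisfied
        model = motifs["positive_2loop"]
        wrong = Circuit(("X", "Y"), ("-", "+"))
        assert functionality_context(model, wrong).empty

    def test_functional_positive_context_restores_multistability(self, motifs):
        """Restricting the model to the context yields at least two attractors."""
        model = motifs["gated_loop"]
        circ = enumerate_circuits(infer_regulatory_graph(model))[0]
        ctx = functionality_context(model, circ)
        restricted = clamp(model, {s: min(vals) for s, vals in ctx.constraints})
        stg = build_stg(restricted, ALL, UpdateScheme.asynchronous())
        assert len(attractors(stg)) >= 2
        # outside the context the circuit is broken and multistability is lost
        broken = clamp(model, {"Z": 1})
        assert len(attractors(build_stg(broken, ALL, UpdateScheme.asynchronous()))) == 1
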