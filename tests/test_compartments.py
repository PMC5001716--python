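"""Compartment reconciliation: transport splitting, compartment removal,
boundary repair, unknown-compartment resolution."""

from fractions import Fraction

import pytest

from gsmerge import (Compartment, FixtureSpec, Model, Reversibility,
                     build_compartment_graph, find_alt_compartmentalization,
                     find_alternative_transport, find_invalid_boundary,
                     find_invalid_transport, generate, remove_compartment,
                     repair_boundary, resolve_unknown_compartment,
                     simulate_growth, split_transport, union_models)

from conftest import make_reaction


def three_comp_model() -> Model:
    m = Model(tag="t", biomass_reaction_id="BIO")
    m.add_compartment(Compartment("ext", is_extracellular=True))
    m.add_compartment(Compartment("per"))
    m.add_compartment(Compartment("cyt"))
    m.add_reaction(make_reaction("EX_s", {("s", "ext"): -1},
                                 Reversibility.REVERSIBLE))
    m.add_reaction(make_reaction(
        "UP", {("s", "ext"): -1, ("h", "ext"): -1,
               ("s", "cyt"): 1, ("h", "cyt"): 1}))
    m.add_reaction(make_reaction("BIO", {("s", "cyt"): -1, ("bm", "cyt"): 1}))
    m.add_reaction(make_reaction("TBM", {("bm", "cyt"): -1, ("bm", "ext"): 1}))
    m.add_reaction(make_reaction("EX_bm", {("bm", "ext"): -1}))
    return m


class TestAlternativeTransport:
    def test_different_chemistry_same_membrane_grouped(self):
        m = Model(tag="t")
        m.add_compartment(Compartment("ext", is_extracellular=True))
        m.add_reaction(make_reaction(
            "t1", {("ptrc", "ext"): -1, ("ptrc", "cyt"): 1}, sources={"A"}))
        m.add_reaction(make_reaction(
            "t2", {("ptrc", "ext"): -1, ("h", "ext"): -1,
                   ("ptrc", "cyt"): 1, ("h", "cyt"): 1}, sources={"B"}))
        groups = find_alternative_transport(m)
        assert groups == {("ptrc", frozenset({"ext", "cyt"})): {"t1", "t2"}}

    def test_single_transporter_no_group(self):
        m = Model(tag="t")
        m.add_reaction(make_reaction(
            "t1", {("x", "ext"): -1, ("x", "cyt"): 1}))
        assert find_alternative_transport(m) == {}

    def test_planted_pairs_found(self, planted_pair):
        a, b, truth = planted_pair
        merged = union_models([a, b])
        groups = find_alternative_transport(merged)
        for pair in truth.alt_transport:
            assert any(set(pair) <= g for g in groups.values())


class TestInvalidTransport:
    def test_planted_shortcuts_reported(self, planted_pair):
        a, b, truth = planted_pair
        merged = union_models([a, b])
        graph = build_compartment_graph(merged)
        graph.edges["ext", "cyt"]["valid"] = False
        found = set(find_invalid_transport(merged, graph))
        assert set(truth.invalid_transport) <= found
        # every reported reaction really does span the flagged membrane
        for rid in found:
            assert {"ext", "cyt"} <= merged.reactions[rid].compartments()

    def test_all_edges_valid_yields_empty(self, planted_pair):
        a, _, _ = planted_pair
        graph = build_compartment_graph(a)
        assert find_invalid_transport(a, graph) == []


class TestSplitTransport:
    def test_legs_sum_to_original(self):
        m = three_comp_model()
        original = dict(m.reactions["UP"].stoich)
        l1, l2 = split_transport(m, "UP", via="per")
        total: dict = {}
        for leg in (l1, l2):
            for k, c in m.reactions[leg].stoich.items():
                total[k] = total.get(k, Fraction(0)) + c
        assert {k: c for k, c in total.items() if c != 0} == original

    def test_growth_unchanged_by_splitting(self):
        m = three_comp_model()
        before = simulate_growth(m, {"s": 10.0})
        split_transport(m, "UP", via="per")
        after = simulate_growth(m, {"s": 10.0})
        assert after == pytest.approx(before)

    def test_missing_via_compartment_rejected(self):
        m = three_comp_model()
        with pytest.raises(ValueError):
            split_transport(m, "UP", via="vacuole")


class TestAltCompartmentalization:
    def test_same_conversion_two_compartments_paired(self):
        m = Model(tag="t")
        m.add_reaction(make_reaction("rc", {("A", "cyt"): -1, ("B", "cyt"): 1}))
        m.add_reaction(make_reaction("rm", {("A", "mit"): -1, ("B", "mit"): 1}))
        assert find_alt_compartmentalization(m) == [{"rc", "rm"}]

    def test_transport_reactions_never_appear(self):
        m = Model(tag="t")
        m.add_reaction(make_reaction("t", {("A", "ext"): -1, ("A", "cyt"): 1}))
        m.add_reaction(make_reaction("t2", {("A", "mit"): -1, ("A", "cyt"): 1}))
        assert find_alt_compartmentalization(m) == []


class TestUnknownCompartment:
    def test_cytosolic_twin_proposes_cytosol(self, planted_pair):
        a, b, truth = planted_pair
        merged = union_models([a, b])
        records = resolve_unknown_compartment(merged)
        by_rxn = {r.members[0]: r for r in records}
        for rid, comp in truth.unknown_resolvable:
            assert by_rxn[rid].detail["compartment"] == comp
        for rid in truth.unknown_unresolvable:
            assert by_rxn[rid].resolution == "unresolved"

    def test_mixed_planting_counts(self):
        spec = FixtureSpec(unknown_compartment=3, unknown_unresolvable=1,
                           n_extra_pathways=1, seed=2)
        a, b, truth = generate(spec)
        merged = union_models([a, b])
        records = resolve_unknown_compartment(merged)
        resolved = [r for r in records if r.resolution != "unresolved"]
        unresolved = [r for r in records if r.resolution == "unresolved"]
        assert len(resolved) == 3
        assert len(unresolved) == 1


class TestInvalidBoundary:
    def test_cytosolic_boundary_listed_extracellular_not(self, planted_pair):
        a, b, truth = planted_pair
        merged = union_models([a, b])
        found = find_invalid_boundary(merged)
        assert set(truth.invalid_boundary) <= set(found)
        assert "EX_glc" not in found

    def test_no_extracellular_compartment_is_an_error(self):
        m = Model(tag="t")
        m.add_reaction(make_reaction("ex", {("A", "cyt"): -1}))
        with pytest.raises(ValueError):
            find_invalid_boundary(m)

    def test_repair_preserves_exchange_capability(self):
        m = three_comp_model()
        # the invalid boundary is the sole route feeding s into the cytosol
        del m.reactions["UP"]
        del m.reactions["EX_s"]
        m.add_reaction(make_reaction("EX_bad", {("s", "cyt"): 1},
                                     Reversibility.REVERSIBLE))
        before = simulate_growth(m, {"s": 10.0})
        assert before > 0
        repair_boundary(m, "EX_bad")
        assert find_invalid_boundary(m) == []
        after = simulate_growth(m, {"s": 10.0})
        assert after == pytest.approx(before)


class TestRemoveCompartment:
    def test_diffusion_chain_collapses(self):
        m = Model(tag="t")
        m.add_compartment(Compartment("ext", is_extracellular=True))
        m.add_reaction(make_reaction("l1", {("x", "ext"): -1, ("x", "per"): 1}))
        m.add_reaction(make_reaction("l2", {("x", "per"): -1, ("x", "cyt"): 1}))
        remove_compartment(m, "per", "cyt")
        assert set(m.reactions) == {"l1"}
        assert m.reactions["l1"].stoich == {("x", "ext"): -1, ("x", "cyt"): 1}
        assert "per" not in m.compartments

    def test_conversion_survives_repointed(self):
        # a periplasmic phosphatase: chemistry plus transport in one step
        m = Model(tag="t")
        m.add_reaction(make_reaction(
            "ppase", {("sp", "per"): -1, ("s", "per"): 1, ("pi", "per"): 1}))
        m.add_reaction(make_reaction("upt", {("s", "per"): -1, ("s", "cyt"): 1}))
        remove_compartment(m, "per", "cyt")
        assert set(m.reactions) == {"ppase"}
        assert m.reactions["ppase"].stoich == {
            ("sp", "cyt"): -1, ("s", "cyt"): 1, ("pi", "cyt"): 1}

    def test_growth_preserved_when_collapsing_periplasm(self):
        m = three_comp_model()
        split_transport(m, "UP", via="per")
        before = simulate_growth(m, {"s": 10.0})
        remove_compartment(m, "per", "cyt")
        after = simulate_growth(m, {"s": 10.0})
        assert after == pytest.approx(before)

    def test_exchangeable_metabolites_unchanged(self, planted_pair):
        a, _, _ = planted_pair
        before = {next(iter(a.reactions[r].stoich))[0]
                  for r in a.boundary_reactions()}
        remove_compartment(a, "per", "cyt")
        after = {next(iter(a.reactions[r].stoich))[0]
                 for r in a.boundary_reactions()}
        assert before == after

    def test_split_then_remove_round_trips_net_reaction(self):
        m = three_comp_model()
        original = dict(m.reactions["UP"].stoich)
        split_transport(m, "UP", via="per")
        remove_compartment(m, "per", "cyt")
        survivors = [r for r in m.reactions.values()
                     if set(r.stoich) == set(original)]
        assert any(r.stoich == original for r in survivors)
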