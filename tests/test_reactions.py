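"""Reaction-level detectors against brute-force oracles, and merge policies."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from gsmerge import (MergePolicy, Model, RedoxPairList, Reversibility,
                     find_alt_stoichiometry, find_identical_net, find_lumped,
                     find_nested, find_redox_variants, find_similar, generate,
                     merge_reactions, parse_gpr, suggest_redox_pairs,
                     union_models)
from gsmerge.fixtures import FixtureSpec
from gsmerge.reactions import (DEFAULT_PROTON_WATER_IDS, merge_gprs,
                               resolve_alt_stoichiometry)

from conftest import make_reaction, random_model


# ---------------------------------------------------------------------------
# Brute-force oracles: direct all-pairs definitions, no signatures or
# hashing, re-deriving each detector's output independently.
# ---------------------------------------------------------------------------


def oracle_identical_net(model, ignore=frozenset()):
    def eff(r):
        return {k: c for k, c in r.stoich.items() if k[0] not in ignore}
    rids = sorted(r for r in model.reactions
                  if eff(model.reactions[r]))
    groups = []
    for rid in rids:
        placed = False
        for g in groups:
            other = model.reactions[next(iter(g))]
            s, o = eff(model.reactions[rid]), eff(other)
            if s == o or {k: -c for k, c in s.items()} == o:
                g.add(rid)
                placed = True
                break
        if not placed:
            groups.append({rid})
    return sorted((g for g in groups if len(g) >= 2),
                  key=lambda g: sorted(g)[0])


def oracle_alt_stoich(model):
    rids = sorted(model.reactions)
    groups = {}
    for rid in rids:
        groups.setdefault(frozenset(model.reactions[rid].stoich),
                          set()).add(rid)
    out = []
    for members in groups.values():
        if len(members) < 2:
            continue
        reps = []
        for rid in members:
            s = model.reactions[rid].stoich
            reps.append(min(tuple(sorted(s.items())),
                            tuple(sorted((k, -c) for k, c in s.items()))))
        if len(set(reps)) >= 2:
            out.append(members)
    return sorted(out, key=lambda g: sorted(g)[0])


def oracle_nested(model):
    out = []
    for inner, outer in itertools.permutations(model.reactions.values(), 2):
        si, so = set(inner.stoich), set(outer.stoich)
        if not (si < so) or len(si) < 2:
            continue
        keys = sorted(si)
        iv = [inner.stoich[k] > 0 for k in keys]
        ov = [outer.stoich[k] > 0 for k in keys]
        if iv == ov or iv == [not x for x in ov]:
            out.append((inner.id, outer.id))
    return sorted(out)


def oracle_similar(model, ng=1, ns=1, np_=1):
    out = []
    for r1, r2 in itertools.combinations(
            sorted(model.reactions.values(), key=lambda r: r.id), 2):
        if not r1.sources or not r2.sources or (r1.sources & r2.sources):
            continue
        subs1 = {k for k, c in r1.stoich.items() if c < 0}
        subs2 = {k for k, c in r2.stoich.items() if c < 0}
        prods1 = {k for k, c in r1.stoich.items() if c > 0}
        prods2 = {k for k, c in r2.stoich.items() if c > 0}
        if (len(subs1 & subs2) >= ns and len(prods1 & prods2) >= np_
                and len(r1.gpr.genes() & r2.gpr.genes()) >= ng):
            out.append((r1.id, r2.id))
    return sorted(out)


def oracle_redox(model, pairs):
    sigs = {}
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        for pair in pairs:
            a, b = sorted(pair)
            for comp in {c for (_, c) in rxn.stoich}:
                ca, cb = rxn.stoich.get((a, comp)), rxn.stoich.get((b, comp))
                if ca is None or cb is None or (ca > 0) == (cb > 0):
                    continue
                support = frozenset(k for k in rxn.stoich
                                    if not (k[0] in pair and k[1] == comp))
                sigs.setdefault(support, set()).add(rid)
    out = []
    for members in sigs.values():
        if len(members) < 2:
            continue
        reps = set()
        for rid in members:
            s = model.reactions[rid].stoich
            reps.add(min(tuple(sorted(s.items())),
                         tuple(sorted((k, -c) for k, c in s.items()))))
        if len(reps) >= 2:
            out.append(members)
    return sorted(out, key=lambda g: sorted(g)[0])


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_identical_net_matches_all_pairs_scan(self, seed):
        m = random_model(np.random.default_rng(seed))
        assert (find_identical_net(m, ignore_proton_water=False)
                == oracle_identical_net(m))

    @pytest.mark.parametrize("seed", range(10))
    def test_alt_stoichiometry_matches_all_pairs_scan(self, seed):
        m = random_model(np.random.default_rng(100 + seed))
        assert find_alt_stoichiometry(m) == oracle_alt_stoich(m)

    @pytest.mark.parametrize("seed", range(10))
    def test_nested_matches_subset_scan(self, seed):
        m = random_model(np.random.default_rng(200 + seed))
        assert sorted(find_nested(m)) == oracle_nested(m)

    @pytest.mark.parametrize("seed", range(10))
    def test_similar_matches_triple_intersection(self, seed):
        m = random_model(np.random.default_rng(300 + seed), tag="S")
        assert sorted(find_similar(m)) == oracle_similar(m)


class TestIdenticalNet:
    def test_opposite_directions_grouped(self):
        m = Model(tag="t")
        m.add_reaction(make_reaction("f", {("A", "c"): -1, ("B", "c"): 1}))
        m.add_reaction(make_reaction("b", {("B", "c"): -1, ("A", "c"): 1}))
        assert find_identical_net(m) == [{"f", "b"}]

    def test_redox_direction_variants_grouped(self):
        # the same conversion written NADPH-consuming vs NADPH-producing
        m = Model(tag="t")
        m.add_reaction(make_reaction(
            "v1", {("A", "c"): -1, ("nadph", "c"): -1,
                   ("B", "c"): 1, ("nadp", "c"): 1}))
        m.add_reaction(make_reaction(
            "v2", {("B", "c"): -1, ("nadp", "c"): -1,
                   ("A", "c"): 1, ("nadph", "c"): 1}))
        assert find_identical_net(m) == [{"v1", "v2"}]

    def test_proton_water_ignored_by_default(self):
        m = Model(tag="t")
        m.add_reaction(make_reaction("r1", {("A", "c"): -1, ("B", "c"): 1}))
        m.add_reaction(make_reaction("r2", {("A", "c"): -1, ("B", "c"): 1,
                                            ("h2o", "c"): 1}))
        assert find_identical_net(m) == [{"r1", "r2"}]
        assert find_identical_net(m, ignore_proton_water=False) == []


class TestAltStoichiometry:
    def test_unique_balanced_member_selected(self):
        from gsmerge import Metabolite
        m = Model(tag="t")
        for mid in ("A", "B"):
            m.add_metabolite(Metabolite(mid, "c", {"C": 6}))
        m.add_reaction(make_reaction("good", {("A", "c"): -1, ("B", "c"): 1}))
        m.add_reaction(make_reaction("bad", {("A", "c"): -2, ("B", "c"): 1}))
        groups = find_alt_stoichiometry(m)
        assert groups == [{"good", "bad"}]
        keep, reason = resolve_alt_stoichiometry(m, groups[0])
        assert keep == "good"

    def test_polymer_variants_pend_without_formula(self, planted_pair):
        a, b, truth = planted_pair
        merged = union_models([a, b])
        groups = find_alt_stoichiometry(merged)
        poly_group = next(g for g in groups
                          if set(truth.polymer[0]) <= g)
        keep, reason = resolve_alt_stoichiometry(merged, poly_group)
        assert keep is None


class TestRedox:
    def test_nad_vs_nadp_twins_grouped(self):
        m = Model(tag="t")
        m.add_reaction(make_reaction(
            "r1", {("A", "c"): -1, ("nadh", "c"): -1,
                   ("B", "c"): 1, ("nad", "c"): 1}))
        m.add_reaction(make_reaction(
            "r2", {("A", "c"): -1, ("nadph", "c"): -1,
                   ("B", "c"): 1, ("nadp", "c"): 1}))
        assert find_redox_variants(m) == [{"r1", "r2"}]

    def test_no_redox_metabolites_never_grouped(self):
        m = Model(tag="t")
        m.add_reaction(make_reaction("r1", {("A", "c"): -1, ("B", "c"): 1}))
        m.add_reaction(make_reaction("r2", {("A", "c"): -1, ("B", "c"): 1}))
        assert find_redox_variants(m) == []

    def test_planted_twins_found(self, planted_pair):
        a, b, truth = planted_pair
        merged = union_models([a, b])
        groups = find_redox_variants(merged)
        for pair in truth.redox:
            assert any(set(pair) <= g for g in groups)

    def test_matches_oracle_on_random_models(self):
        pairs = RedoxPairList()
        raw = [set(p) for p in
               (("nad", "nadh"), ("nadp", "nadph"))]
        for seed in range(5):
            rng = np.random.default_rng(400 + seed)
            m = random_model(rng, n_reactions=30)
            # sprinkle redox couples into a few reactions
            for rid in list(sorted(m.reactions))[:6]:
                rxn = m.reactions[rid]
                a, b = sorted(raw[int(rng.integers(0, 2))])
                rxn.stoich[(a, "cyt")] = Fraction(-1)
                rxn.stoich[(b, "cyt")] = Fraction(1)
            assert (find_redox_variants(m, pairs)
                    == oracle_redox(m, [frozenset(p) for p in raw]))


class TestSuggestRedoxPairs:
    def test_always_together_suggested_at_one(self):
        m = Model(tag="t")
        for i in range(4):
            m.add_reaction(make_reaction(
                f"r{i}", {("X", "c"): -1, (f"s{i}", "c"): -1,
                          ("Y", "c"): 1, (f"p{i}", "c"): 1}))
        out = suggest_redox_pairs(m)
        assert ("X", "Y", 1.0) in out

    def test_below_threshold_not_suggested(self):
        m = Model(tag="t")
        for i in range(10):
            stoich = {(f"s{i}", "c"): -1, (f"p{i}", "c"): 1}
            if i < 3:
                stoich.update({("X", "c"): -1, ("Y", "c"): 1})
            else:
                stoich.update({("X", "c"): -1, ("Z", "c"): 1})
            m.add_reaction(make_reaction(f"r{i}", stoich))
        assert not any(p[:2] == ("X", "Y") for p in suggest_redox_pairs(m))

    def test_planted_currency_fraction_exact(self):
        m = Model(tag="t")
        for i in range(20):
            stoich = {(f"s{i}", "c"): -1, (f"p{i}", "c"): 1}
            if i < 16:  # 80% of X's reactions also involve Y, opposite side
                stoich.update({("X", "c"): -1, ("Y", "c"): 1})
            else:
                stoich.update({("X", "c"): -1})
            m.add_reaction(make_reaction(f"r{i}", stoich))
        hit = next(p for p in suggest_redox_pairs(m) if p[:2] == ("X", "Y"))
        assert hit[2] == pytest.approx(0.8)


class TestNested:
    def test_cofactor_variant_confirmed(self):
        m = Model(tag="t")
        m.add_reaction(make_reaction("plain", {("A", "c"): -1, ("B", "c"): 1}))
        m.add_reaction(make_reaction(
            "cof", {("A", "c"): -1, ("nadh", "c"): -1,
                    ("B", "c"): 1, ("nad", "c"): 1}))
        assert find_nested(m) == [("plain", "cof")]

    def test_no_self_pairs(self):
        m = Model(tag="t")
        m.add_reaction(make_reaction("r", {("A", "c"): -1, ("B", "c"): 1}))
        assert find_nested(m) == []


class TestSimilar:
    def test_phosphate_product_variants_pair(self):
        m = Model(tag="t")
        m.add_reaction(make_reaction(
            "tri", {("S", "c"): -1, ("P", "c"): 1, ("ppp", "c"): 1},
            gpr="g1", sources={"A"}))
        m.add_reaction(make_reaction(
            "pyro", {("S", "c"): -1, ("P", "c"): 1, ("ppi", "c"): 1,
                     ("pi", "c"): 1},
            gpr="g1", sources={"B"}))
        assert find_similar(m) == [("pyro", "tri")]

    def test_thresholds_above_overlap_empty(self):
        m = Model(tag="t")
        m.add_reaction(make_reaction("r1", {("S", "c"): -1, ("P", "c"): 1},
                                     gpr="g1", sources={"A"}))
        m.add_reaction(make_reaction("r2", {("S", "c"): -1, ("Q", "c"): 1},
                                     gpr="g1", sources={"B"}))
        assert find_similar(m, min_shared_products=1) == []


class TestLumped:
    def test_two_step_chain_recovered(self):
        m = Model(tag="t")
        m.add_reaction(make_reaction("AB", {("A", "c"): -1, ("B", "c"): 1},
                                     gpr="g1"))
        m.add_reaction(make_reaction("BC", {("B", "c"): -1, ("C", "c"): 1},
                                     gpr="g2"))
        m.add_reaction(make_reaction("LUMP", {("A", "c"): -1, ("C", "c"): 1},
                                     gpr="g1 and g2"))
        sets = find_lumped(m, "LUMP")
        assert [sorted(s.members) for s in sets] == [["AB", "BC"]]
        assert sets[0].exact

    def test_isolated_reaction_yields_nothing(self):
        m = Model(tag="t")
        m.add_reaction(make_reaction("solo", {("A", "c"): -1, ("B", "c"): 1}))
        m.add_reaction(make_reaction("other", {("X", "c"): -1, ("Y", "c"): 1}))
        assert find_lumped(m, "solo") == []

    def test_alternative_chains_found_by_penalty_tripling(self):
        m = Model(tag="t")
        m.add_reaction(make_reaction("AB", {("A", "c"): -1, ("B", "c"): 1},
                                     gpr="g1"))
        m.add_reaction(make_reaction("BC", {("B", "c"): -1, ("C", "c"): 1},
                                     gpr="g1"))
        m.add_reaction(make_reaction("AD", {("A", "c"): -1, ("D", "c"): 1},
                                     gpr="g1"))
        m.add_reaction(make_reaction("DC", {("D", "c"): -1, ("C", "c"): 1},
                                     gpr="g1"))
        m.add_reaction(make_reaction("LUMP", {("A", "c"): -1, ("C", "c"): 1},
                                     gpr="g1"))
        sets = find_lumped(m, "LUMP")
        found = {frozenset(s.members) for s in sets}
        assert found == {frozenset({"AB", "BC"}), frozenset({"AD", "DC"})}
        assert all(s.exact for s in sets)

    def test_bidirectional_chain_against_directed_lump(self):
        # a directed lumped reaction with a reversible non-lumped chain
        m = Model(tag="t")
        m.add_reaction(make_reaction("AB", {("A", "c"): -1, ("B", "c"): 1},
                                     Reversibility.REVERSIBLE, gpr="g1"))
        m.add_reaction(make_reaction("BC", {("B", "c"): -1, ("C", "c"): 1},
                                     Reversibility.REVERSIBLE, gpr="g1"))
        m.add_reaction(make_reaction("LUMP", {("A", "c"): -1, ("C", "c"): 1},
                                     Reversibility.FORWARD, gpr="g1"))
        sets = find_lumped(m, "LUMP")
        assert {frozenset(s.members) for s in sets} == {frozenset({"AB", "BC"})}

    def test_size_cap_respected(self):
        m = Model(tag="t")
        prev = "A"
        for i in range(7):
            nxt = f"x{i}"
            m.add_reaction(make_reaction(
                f"s{i}", {(prev, "c"): -1, (nxt, "c"): 1}, gpr="g1"))
            prev = nxt
        m.add_reaction(make_reaction("LUMP", {("A", "c"): -1, (prev, "c"): 1},
                                     gpr="g1"))
        assert find_lumped(m, "LUMP", max_set_size=5) == []
        assert len(find_lumped(m, "LUMP", max_set_size=10)) == 1

    def test_gene_overlap_filter(self):
        m = Model(tag="t")
        m.add_reaction(make_reaction("AB", {("A", "c"): -1, ("B", "c"): 1},
                                     gpr="g1"))
        m.add_reaction(make_reaction("BC", {("B", "c"): -1, ("C", "c"): 1},
                                     gpr="g2"))
        m.add_reaction(make_reaction("LUMP", {("A", "c"): -1, ("C", "c"): 1},
                                     gpr="g9"))
        assert find_lumped(m, "LUMP") == []
        assert len(find_lumped(m, "LUMP", min_gene_overlap=0)) == 1

    def test_planted_pairs_exactly_recovered(self, planted_pair):
        a, b, truth = planted_pair
        merged = union_models([a, b])
        for candidate, nl in truth.lumped:
            sets = find_lumped(merged, candidate)
            assert [sorted(s.members) for s in sets] == [sorted(nl)]
            assert all(s.exact for s in sets)


class TestMergePolicies:
    def test_identical_forward_members(self):
        m = Model(tag="t")
        m.add_reaction(make_reaction("r1", {("A", "c"): -1, ("B", "c"): 1},
                                     gpr="g1", sources={"A"}))
        m.add_reaction(make_reaction("r2", {("A", "c"): -1, ("B", "c"): 1},
                                     gpr="g1", sources={"B"}))
        merge_reactions(m, {"r1", "r2"}, MergePolicy())
        assert set(m.reactions) == {"r1"}
        kept = m.reactions["r1"]
        assert kept.sources == {"A", "B"}
        assert kept.reversibility is Reversibility.FORWARD

    def test_conflicting_directions_become_reversible(self):
        m = Model(tag="t")
        m.add_reaction(make_reaction("fwd", {("A", "c"): -1, ("B", "c"): 1},
                                     Reversibility.FORWARD, sources={"A"}))
        m.add_reaction(make_reaction("bwd", {("B", "c"): -1, ("A", "c"): 1},
                                     Reversibility.FORWARD, sources={"B"}))
        merge_reactions(m, {"fwd", "bwd"}, MergePolicy())
        assert (m.reactions["bwd"].reversibility is Reversibility.REVERSIBLE)

    def test_predictor_hook_decides_direction(self):
        m = Model(tag="t")
        m.add_reaction(make_reaction("fwd", {("A", "c"): -1, ("B", "c"): 1},
                                     Reversibility.FORWARD, sources={"A"}))
        m.add_reaction(make_reaction("rev", {("A", "c"): -1, ("B", "c"): 1},
                                     Reversibility.REVERSIBLE, sources={"B"}))
        policy = MergePolicy(direction_mode="consensus-then-predictor-hook",
                             direction_predictor=lambda r: "forward")
        merge_reactions(m, {"fwd", "rev"}, policy)
        assert m.reactions["fwd"].reversibility is Reversibility.FORWARD

    @pytest.mark.parametrize("mode,gprs,expected", [
        ("union", ["g1", "g2"], "g1 or g2"),
        ("union", ["g1", "g1"], "g1"),
        ("strict", ["g1", "g1"], "g1"),
        ("strict", ["g1 and g2", "g1"], "g1 and g2"),  # superset kept
    ])
    def test_gpr_merge_table(self, mode, gprs, expected):
        merged, _ = merge_gprs([parse_gpr(g) for g in gprs], mode)
        assert merged.canonical_string() == expected

    def test_strict_disagreement_pends(self):
        merged, note = merge_gprs([parse_gpr("g1 and g2"),
                                   parse_gpr("g1 and g3")], "strict")
        assert merged is None
        m = Model(tag="t")
        m.add_reaction(make_reaction("r1", {("A", "c"): -1, ("B", "c"): 1},
                                     gpr="g1 and g2", sources={"A"}))
        m.add_reaction(make_reaction("r2", {("A", "c"): -1, ("B", "c"): 1},
                                     gpr="g1 and g3", sources={"B"}))
        rec = merge_reactions(m, {"r1", "r2"}, MergePolicy(gpr_mode="strict"))
        assert rec.status == "pending"
        assert set(m.reactions) == {"r1", "r2"}  # nothing merged

    def test_different_net_formula_refused(self):
        m = Model(tag="t")
        m.add_reaction(make_reaction("r1", {("A", "c"): -1, ("B", "c"): 1},
                                     sources={"A"}))
        m.add_reaction(make_reaction("r2", {("A", "c"): -1, ("C", "c"): 1},
                                     sources={"B"}))
        with pytest.raises(ValueError):
            merge_reactions(m, {"r1", "r2"}, MergePolicy())
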