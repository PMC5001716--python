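"""Shared test fixtures: small hand-built models, planted-truth pairs, and
a random-model generator used by the brute-force oracle tests."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest

from gsmerge import (Compartment, FixtureSpec, Metabolite, Model, Reaction,
                     Reversibility, generate, parse_gpr)


def make_reaction(rid: str, stoich: dict, rev=Reversibility.FORWARD,
                  gpr: str = "", sources=None, lb=None, ub=None) -> Reaction:
    return Reaction(rid, {k: Fraction(v) for k, v in stoich.items()}, rev,
                    lb=lb, ub=ub, gpr=parse_gpr(gpr),
                    sources=set(sources or {"M"}))


@pytest.fixture
def linear_toy() -> Model:
    """uptake A (<=10) -> X -> biomass, all 1:1."""
    m = Model(tag="toy", biomass_reaction_id="BIO")
    m.add_compartment(Compartment("ext", is_extracellular=True))
    m.add_compartment(Compartment("cyt"))
    m.add_reaction(make_reaction("EX_A", {("A", "ext"): -1},
                                 Reversibility.REVERSIBLE, lb=-10, ub=1000))
    m.add_reaction(make_reaction("T_A", {("A", "ext"): -1, ("A", "cyt"): 1},
                                 gpr="gT"))
    m.add_reaction(make_reaction("AX", {("A", "cyt"): -1, ("X", "cyt"): 1},
                                 gpr="g1"))
    m.add_reaction(make_reaction("BIO", {("X", "cyt"): -1, ("bio", "cyt"): 1}))
    m.add_reaction(make_reaction("T_bio", {("bio", "cyt"): -1,
                                           ("bio", "ext"): 1}))
    m.add_reaction(make_reaction("EX_bio", {("bio", "ext"): -1}))
    return m


@pytest.fixture
def planted_pair():
    """Fixture pair with a couple of instances of every inconsistency class."""
    spec = FixtureSpec(synonym_mets=2, identical_net_dups=2, alt_stoich=2,
                       polymer_variants=1, redox_twins=2, nested_pairs=2,
                       lumped_pairs=2, alt_transporters=1,
                       invalid_transports=2, transport_splits=1,
                       invalid_boundaries=1, unknown_compartment=1,
                       unknown_unresolvable=1, n_extra_pathways=3, seed=11)
    return generate(spec)


def random_model(rng: np.random.Generator, n_reactions: int = 40,
                 n_metabolites: int = 25, tag: str = "R") -> Model:
    """Random stoichiometries for oracle comparisons; includes planted
    duplicate/reversed/rescaled/cofactor-swapped columns so every detector
    has something to find."""
    m = Model(tag=tag)
    m.add_compartment(Compartment("cyt"))
    mets = [f"m{i}" for i in range(n_metabolites)]
    for mid in mets:
        m.add_metabolite(Metabolite(mid, "cyt", sources={tag}))
    rxns = []
    for j in range(n_reactions):
        size = int(rng.integers(2, 5))
        chosen = rng.choice(n_metabolites, size=size, replace=False)
        stoich = {}
        for pos, i in enumerate(chosen):
            coeff = int(rng.integers(1, 3))
            stoich[(mets[i], "cyt")] = Fraction(coeff if pos % 2 else -coeff)
        rev = [Reversibility.FORWARD, Reversibility.REVERSIBLE][
            int(rng.integers(0, 2))]
        src = tag if rng.random() < 0.5 else tag + "2"
        rxn = make_reaction(f"r{j}", stoich, rev, gpr=f"g{j % 7}",
                            sources={src})
        rxns.append(rxn)
        m.add_reaction(rxn)
    # planted structure: duplicate, reversed, rescaled, subset columns
    for k, base in enumerate(rxns[: max(1, n_reactions // 10)]):
        dup = base.copy()
        dup.id = f"dup{k}"
        dup.sources = {tag + "2"}
        kind = k % 3
        if kind == 1:
            dup.stoich = {key: -c for key, c in dup.stoich.items()}
        elif kind == 2:
            first = sorted(dup.stoich)[0]
            dup.stoich[first] *= 2
        m.add_reaction(dup)
    return m


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
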