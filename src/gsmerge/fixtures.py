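"""Synthetic paired models with planted, labelled inconsistencies.

Real concurrent genome-scale models disagree in a handful of recurring
ways: synonymous metabolite identifiers, duplicate reactions written in
opposite directions or with spurious water/protons, alternative
stoichiometries, polymer granularity, alternative redox pairs, optional
cofactors (nested reactions), lumped pathway representations, alternative
and invalid transporters, different compartment resolution, misplaced
boundary reactions, and species of unknown localisation.

The generator builds a base model — a linear biomass pathway from glucose
uptake through a periplasm, plus random side pathways stitched onto it and
a currency-metabolite layer, so hub effects on the matcher are represented —
copies it, and plants each requested inconsistency class into the copy as
an isolated, ground-truth-labelled perturbation.  Wild-type growth on the
declared medium is guaranteed because plantings never touch the core
pathway.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from pathlib import Path

import numpy as np

from .model import (Compartment, Gene, MetKey, Metabolite, Model, Reaction,
                    Reversibility, UNKNOWN_COMPARTMENT)
from .gpr import parse_gpr
from .namespace import MappingTable

BB_FORMULA = {"C": 6, "H": 12, "O": 6}     # generic backbone unit
NAD = {"C": 21, "H": 26, "N": 7, "O": 14, "P": 2}
NADH = {"C": 21, "H": 27, "N": 7, "O": 14, "P": 2}
NADP = {"C": 21, "H": 25, "N": 7, "O": 17, "P": 3}
NADPH = {"C": 21, "H": 26, "N": 7, "O": 17, "P": 3}


@dataclass
class FixtureSpec:
    """Planting counts and base-network size for a paired-model fixture."""

    chain_len: int = 5
    n_extra_pathways: int = 2
    synonym_mets: int = 0
    identical_net_dups: int = 0
    alt_stoich: int = 0
    polymer_variants: int = 0
    redox_twins: int = 0
    nested_pairs: int = 0
    lumped_pairs: int = 0
    alt_transporters: int = 0
    invalid_transports: int = 0
    transport_splits: int = 0
    invalid_boundaries: int = 0
    unknown_compartment: int = 0
    unknown_unresolvable: int = 0
    collapse_periplasm_b: bool = False
    currency_fraction: float = 0.3
    seed: int = 0

    def pathway_count(self) -> int:
        return (self.synonym_mets + self.identical_net_dups + self.alt_stoich
                + self.redox_twins + self.nested_pairs + self.lumped_pairs
                + self.invalid_boundaries + self.unknown_compartment
                + self.unknown_unresolvable + self.n_extra_pathways)

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if isinstance(value, int) and value < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.chain_len < 2:
            raise ValueError("chain_len must be at least 2")


@dataclass
class FixtureTruth:
    """Ground-truth labels for every planted instance."""

    synonym_pairs: list[tuple[MetKey, MetKey]] = field(default_factory=list)
    identical_net: list[tuple[str, str]] = field(default_factory=list)
    alt_stoich: list[tuple[str, str]] = field(default_factory=list)
    polymer: list[tuple[str, str]] = field(default_factory=list)
    redox: list[tuple[str, str]] = field(default_factory=list)
    nested: list[tuple[str, str]] = field(default_factory=list)
    lumped: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    alt_transport: list[tuple[str, str]] = field(default_factory=list)
    invalid_transport: list[str] = field(default_factory=list)
    transport_split: list[str] = field(default_factory=list)
    invalid_boundary: list[str] = field(default_factory=list)
    unknown_resolvable: list[tuple[str, str]] = field(default_factory=list)
    unknown_unresolvable: list[str] = field(default_factory=list)
    medium: dict[str, float] = field(default_factory=dict)
    biomass_id: str = "BIOMASS"

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=list)

    @staticmethod
    def from_json(text: str) -> "FixtureTruth":
        d = json.loads(text)
        truth = FixtureTruth(medium=d["medium"], biomass_id=d["biomass_id"])
        truth.synonym_pairs = [
            (tuple(a), tuple(b)) for a, b in d["synonym_pairs"]]
        for name in ("identical_net", "alt_stoich", "polymer", "redox",
                     "nested", "alt_transport", "unknown_resolvable"):
            setattr(truth, name, [tuple(x) for x in d[name]])
        truth.lumped = [(c, tuple(nl)) for c, nl in d["lumped"]]
        for name in ("invalid_transport", "transport_split",
                     "invalid_boundary", "unknown_unresolvable"):
            setattr(truth, name, list(d[name]))
        return truth


# ---------------------------------------------------------------------------
# Base model
# ---------------------------------------------------------------------------


def _base_model(spec: FixtureSpec, rng: np.random.Generator) -> Model:
    m = Model(tag="A", biomass_reaction_id="BIOMASS")
    m.add_compartment(Compartment("ext", "extracellular", is_extracellular=True))
    m.add_compartment(Compartment("per", "periplasm"))
    m.add_compartment(Compartment("cyt", "cytosol"))

    def met(mid: str, comp: str, formula=BB_FORMULA) -> Metabolite:
        return m.add_metabolite(Metabolite(
            id=mid, compartment=comp,
            formula=dict(formula) if formula else None, sources={"A"}))

    def rxn(rid: str, stoich: dict[MetKey, int | Fraction],
            gpr: str = "", rev: Reversibility = Reversibility.FORWARD,
            lb=None, ub=None) -> Reaction:
        return m.add_reaction(Reaction(
            rid, {k: Fraction(v) for k, v in stoich.items()}, rev,
            lb=lb, ub=ub, gpr=parse_gpr(gpr), sources={"A"}))

    for comp in ("ext", "per", "cyt"):
        met("glc", comp)
    met("h", "ext", {"H": 1}); met("h", "cyt", {"H": 1})
    met("h2o", "cyt", {"H": 2, "O": 1})
    met("nad", "cyt", NAD); met("nadh", "cyt", NADH)
    met("nadp", "cyt", NADP); met("nadph", "cyt", NADPH)

    rxn("EX_glc", {("glc", "ext"): -1}, rev=Reversibility.REVERSIBLE)
    rxn("TGLC1", {("glc", "ext"): -1, ("glc", "per"): 1}, gpr="gT1")
    rxn("TGLC2", {("glc", "per"): -1, ("glc", "cyt"): 1}, gpr="gT2")
    prev = ("glc", "cyt")
    for i in range(spec.chain_len):
        met(f"core{i}", "cyt")
        rxn(f"C{i}", {prev: -1, (f"core{i}", "cyt"): 1}, gpr=f"gC{i}")
        prev = (f"core{i}", "cyt")
    met("bm", "cyt", None); met("bm", "ext", None)
    rxn("BIOMASS", {prev: -1, ("bm", "cyt"): 1}, gpr="")
    rxn("TBM", {("bm", "cyt"): -1, ("bm", "ext"): 1})
    rxn("EX_bm", {("bm", "ext"): -1})

    n_pathways = spec.pathway_count()
    first_free = n_pathways - spec.n_extra_pathways
    for p in range(n_pathways):
        branch = f"core{int(rng.integers(0, spec.chain_len))}"
        for j in (1, 2, 3):
            met(f"P{p}M{j}", "cyt")
        rxn(f"P{p}R1", {(branch, "cyt"): -1, (f"P{p}M1", "cyt"): 1},
            gpr=f"gP{p}R1")
        mid_stoich = {(f"P{p}M1", "cyt"): -1, (f"P{p}M2", "cyt"): 1}
        # currency layer only on the unreserved pathways, so plantings stay
        # clean, isolated instances of their class
        if p >= first_free and rng.random() < spec.currency_fraction:
            mid_stoich.update({("nadh", "cyt"): -1, ("nad", "cyt"): 1,
                               ("h", "cyt"): 1})
        rxn(f"P{p}R2", mid_stoich, gpr=f"gP{p}R2")
        rxn(f"P{p}R3", {(f"P{p}M2", "cyt"): -1, (f"P{p}M3", "cyt"): 1},
            gpr=f"gP{p}R3")
    return m


def _retag(model: Model, tag: str) -> Model:
    model.tag = tag
    for met in model.metabolites.values():
        met.sources = {tag}
    for rxn in model.reactions.values():
        rxn.sources = {tag}
    for gene in model.genes.values():
        gene.sources = {tag}
    return model


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------


def generate(spec: FixtureSpec) -> tuple[Model, Model, FixtureTruth]:
    """Paired models (A, B) with planted inconsistencies and their truth.

    Deterministic under ``spec.seed``; with all counts zero the two models
    are identical up to provenance tags.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    a = _base_model(spec, rng)
    b = _retag(a.copy(), "B")
    truth = FixtureTruth(medium={"glc": 10.0})

    pathway = iter(range(spec.pathway_count() - spec.n_extra_pathways))

    def b_rxn(rid: str) -> Reaction:
        return b.reactions[rid]

    def replace_b(old: str, new: Reaction) -> None:
        del b.reactions[old]
        new.sources = {"B"}
        b.add_reaction(new)
        b.prune_orphan_metabolites()

    for _ in range(spec.synonym_mets):
        p = next(pathway)
        old, new = (f"P{p}M1", "cyt"), (f"P{p}M1_syn", "cyt")
        met = b.metabolites.pop(old)
        met.id = new[0]
        b.metabolites[new] = met
        for rxn in b.reactions.values():
            if old in rxn.stoich:
                rxn.stoich[new] = rxn.stoich.pop(old)
        truth.synonym_pairs.append((old, new))

    for _ in range(spec.identical_net_dups):
        p = next(pathway)
        rid = f"P{p}R2"
        dup = b_rxn(rid).reversed()
        dup.id = f"{rid}_dup"
        dup.stoich[("h2o", "cyt")] = dup.stoich.get(
            ("h2o", "cyt"), Fraction(0)) + 1
        replace_b(rid, dup)
        truth.identical_net.append((rid, dup.id))

    for _ in range(spec.alt_stoich):
        p = next(pathway)
        rid = f"P{p}R2"
        alt = b_rxn(rid).copy()
        alt.id = f"{rid}_alt"
        alt.stoich[(f"P{p}M1", "cyt")] *= 2
        replace_b(rid, alt)
        truth.alt_stoich.append((rid, alt.id))

    for i in range(spec.polymer_variants):
        sub, poly = f"sub{i}", f"poly{i}"
        for model, tag, n in ((a, "A", 4), (b, "B", 5)):
            model.add_metabolite(Metabolite(sub, "cyt", dict(BB_FORMULA),
                                            sources={tag}))
            model.add_metabolite(Metabolite(poly, "cyt", None, sources={tag}))
            model.add_reaction(Reaction(
                f"SUB{i}", {("core0", "cyt"): Fraction(-1),
                            (sub, "cyt"): Fraction(1)},
                Reversibility.FORWARD, sources={tag}))
            model.add_reaction(Reaction(
                f"POLY{i}" + ("" if tag == "A" else "_b"),
                {(sub, "cyt"): Fraction(-n), (poly, "cyt"): Fraction(1)},
                Reversibility.FORWARD, sources={tag}))
        truth.polymer.append((f"POLY{i}", f"POLY{i}_b"))

    for _ in range(spec.redox_twins):
        p = next(pathway)
        rid = f"P{p}R2"
        a.reactions[rid].stoich.update(
            {("nadh", "cyt"): Fraction(-1), ("nad", "cyt"): Fraction(1),
             ("h", "cyt"): Fraction(1)})
        twin = b_rxn(rid).copy()
        twin.id = f"{rid}_rdx"
        twin.stoich.update({("nadph", "cyt"): Fraction(-1),
                            ("nadp", "cyt"): Fraction(1),
                            ("h", "cyt"): Fraction(1)})
        replace_b(rid, twin)
        truth.redox.append((rid, twin.id))

    for _ in range(spec.nested_pairs):
        p = next(pathway)
        rid = f"P{p}R2"
        outer = b_rxn(rid).copy()
        outer.id = f"{rid}_cof"
        outer.stoich.update({("nadh", "cyt"): Fraction(-1),
                             ("nad", "cyt"): Fraction(1),
                             ("h", "cyt"): Fraction(1)})
        replace_b(rid, outer)
        truth.nested.append((rid, outer.id))

    for _ in range(spec.lumped_pairs):
        p = next(pathway)
        r2, r3 = f"P{p}R2", f"P{p}R3"
        lump = Reaction(
            f"LUMP{p}",
            {(f"P{p}M1", "cyt"): Fraction(-1), (f"P{p}M3", "cyt"): Fraction(1)},
            Reversibility.FORWARD,
            gpr=parse_gpr(f"gP{p}R2 and gP{p}R3"), sources={"B"})
        del b.reactions[r2]
        del b.reactions[r3]
        b.add_reaction(lump)
        b.prune_orphan_metabolites()
        truth.lumped.append((lump.id, (r2, r3)))

    for i in range(spec.alt_transporters):
        amet = f"amet{i}"
        for model, tag in ((a, "A"), (b, "B")):
            model.add_metabolite(Metabolite(amet, "ext", dict(BB_FORMULA),
                                            sources={tag}))
            model.add_metabolite(Metabolite(amet, "cyt", dict(BB_FORMULA),
                                            sources={tag}))
            model.add_reaction(Reaction(
                f"EX_{amet}", {(amet, "ext"): Fraction(-1)},
                Reversibility.REVERSIBLE, sources={tag}))
            model.add_reaction(Reaction(
                f"USE_{amet}", {(amet, "cyt"): Fraction(-1),
                                ("core0", "cyt"): Fraction(1)},
                Reversibility.FORWARD, sources={tag}))
        a.add_reaction(Reaction(
            f"TA{i}", {(amet, "ext"): Fraction(-1), (amet, "cyt"): Fraction(1)},
            Reversibility.FORWARD, sources={"A"}))
        b.add_metabolite(Metabolite("h", "ext", {"H": 1}, sources={"B"}))
        b.add_reaction(Reaction(
            f"TB{i}", {(amet, "ext"): Fraction(-1), ("h", "ext"): Fraction(-1),
                       (amet, "cyt"): Fraction(1), ("h", "cyt"): Fraction(1)},
            Reversibility.FORWARD, sources={"B"}))
        truth.alt_transport.append((f"TA{i}", f"TB{i}"))

    for i in range(spec.invalid_transports):
        imet = f"imet{i}"
        b.add_metabolite(Metabolite(imet, "ext", dict(BB_FORMULA), sources={"B"}))
        b.add_metabolite(Metabolite(imet, "cyt", dict(BB_FORMULA), sources={"B"}))
        b.add_reaction(Reaction(
            f"EX_{imet}", {(imet, "ext"): Fraction(-1)},
            Reversibility.REVERSIBLE, sources={"B"}))
        b.add_reaction(Reaction(
            f"IT{i}", {(imet, "ext"): Fraction(-1), (imet, "cyt"): Fraction(1)},
            Reversibility.FORWARD, sources={"B"}))
        b.add_reaction(Reaction(
            f"USE_{imet}", {(imet, "cyt"): Fraction(-1),
                            ("core0", "cyt"): Fraction(1)},
            Reversibility.FORWARD, sources={"B"}))
        truth.invalid_transport.append(f"IT{i}")

    for i in range(spec.transport_splits):
        smet = f"smet{i}"
        for model, tag in ((a, "A"), (b, "B")):
            model.add_metabolite(Metabolite(smet, "ext", dict(BB_FORMULA),
                                            sources={tag}))
            model.add_metabolite(Metabolite(smet, "cyt", dict(BB_FORMULA),
                                            sources={tag}))
            model.add_reaction(Reaction(
                f"EX_{smet}", {(smet, "ext"): Fraction(-1)},
                Reversibility.REVERSIBLE, sources={tag}))
            model.add_reaction(Reaction(
                f"USE_{smet}", {(smet, "cyt"): Fraction(-1),
                                ("core0", "cyt"): Fraction(1)},
                Reversibility.FORWARD, sources={tag}))
        a.add_metabolite(Metabolite(smet, "per", dict(BB_FORMULA), sources={"A"}))
        a.add_reaction(Reaction(
            f"TS{i}a", {(smet, "ext"): Fraction(-1), (smet, "per"): Fraction(1)},
            Reversibility.FORWARD, sources={"A"}))
        a.add_reaction(Reaction(
            f"TS{i}b", {(smet, "per"): Fraction(-1), (smet, "cyt"): Fraction(1)},
            Reversibility.FORWARD, sources={"A"}))
        b.add_reaction(Reaction(
            f"TSD{i}", {(smet, "ext"): Fraction(-1), (smet, "cyt"): Fraction(1)},
            Reversibility.FORWARD, sources={"B"}))
        truth.transport_split.append(f"TSD{i}")

    for i in range(spec.invalid_boundaries):
        p = next(pathway)
        b.add_reaction(Reaction(
            f"EX_BAD{i}", {(f"P{p}M3", "cyt"): Fraction(-1)},
            Reversibility.FORWARD, sources={"B"}))
        truth.invalid_boundary.append(f"EX_BAD{i}")

    if spec.unknown_compartment or spec.unknown_unresolvable:
        b.add_compartment(Compartment(UNKNOWN_COMPARTMENT, "unknown"))
    for _ in range(spec.unknown_compartment):
        p = next(pathway)
        rid = f"P{p}R2"
        unk = b_rxn(rid).copy()
        unk.id = f"{rid}_unk"
        coeff = unk.stoich.pop((f"P{p}M2", "cyt"))
        unk.stoich[(f"P{p}M2", UNKNOWN_COMPARTMENT)] = coeff
        replace_b(rid, unk)
        # keep the cytosolic instance alive downstream so a twin exists
        truth.unknown_resolvable.append((unk.id, "cyt"))

    for i in range(spec.unknown_unresolvable):
        p = next(pathway)
        b.add_metabolite(Metabolite(f"umet{i}", "cyt", None, sources={"B"}))
        b.add_metabolite(Metabolite(f"vmet{i}", UNKNOWN_COMPARTMENT, None,
                                    sources={"B"}))
        b.add_reaction(Reaction(
            f"UNKX{i}", {(f"P{p}M3", "cyt"): Fraction(-1),
                         (f"vmet{i}", UNKNOWN_COMPARTMENT): Fraction(1)},
            Reversibility.FORWARD, sources={"B"}))
        truth.unknown_unresolvable.append(f"UNKX{i}")

    if spec.collapse_periplasm_b:
        del b.reactions["TGLC1"]
        del b.reactions["TGLC2"]
        b.add_reaction(Reaction(
            "TGLCD", {("glc", "ext"): Fraction(-1), ("glc", "cyt"): Fraction(1)},
            Reversibility.FORWARD, gpr=parse_gpr("gT1"), sources={"B"}))
        for key in [k for k in b.metabolites if k[1] == "per"]:
            del b.metabolites[key]
        del b.compartments["per"]
        truth.transport_split.append("TGLCD")

    a.validate()
    b.validate()
    return a, b, truth


# ---------------------------------------------------------------------------
# Unknown-compartment note: the resolvable planting relies on the matched
# cytosolic twin from model A; model B's own downstream reaction (R3) keeps
# the cytosolic instance in the merged model as well.
# ---------------------------------------------------------------------------


def namespaced_pair(a: Model, b: Model,
                    ) -> tuple[Model, Model, MappingTable]:
    """Prefixed-id variants (FIXA_/FIXB_) of a fixture pair plus the mapping
    table that converts them back to the canonical ids, for exercising the
    namespace-mapping machinery."""
    table = MappingTable()
    out = []
    for model, prefix in ((a, "FIXA_"), (b, "FIXB_")):
        clone = model.copy()
        met_map = {}
        for key in sorted(clone.metabolites):
            met = clone.metabolites.pop(key)
            met.id = prefix + met.id
            met_map[key] = (met.id, key[1])
            clone.metabolites[met.key] = met
            table.rows[(model.tag, met.id)] = key[0]
        for rxn in clone.reactions.values():
            rxn.stoich = {met_map[k]: c for k, c in rxn.stoich.items()}
        out.append(clone)
    return out[0], out[1], table


def write_fixture(directory: str | Path, spec: FixtureSpec) -> None:
    """Materialise a fixture pair: a.xml, b.xml, truth.json, mapping.tsv,
    medium.tsv."""
    from .sbmlio import write_sbml
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    a, b, truth = generate(spec)
    write_sbml(a, directory / "a.xml")
    write_sbml(b, directory / "b.xml")
    (directory / "truth.json").write_text(truth.to_json())
    _, _, table = namespaced_pair(a, b)
    table.to_tsv(directory / "mapping.tsv")
    with open(directory / "medium.tsv", "w") as fh:
        fh.write("boundary_metabolite\tmax_uptake\n")
        for mid, uptake in sorted(truth.medium.items()):
            fh.write(f"{mid}\t{uptake}\n")
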