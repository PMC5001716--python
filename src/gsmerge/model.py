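"""Core domain types for constraint-based metabolic models.

A model is a set of compartments, metabolites (one record per metabolite
*instance*, i.e. per chemical species per compartment), reactions with exact
rational stoichiometries, and genes linked to reactions through boolean
gene-protein-reaction (GPR) rules.  Every entity carries the tags of the
source models it came from, so that provenance survives merging.

Stoichiometric coefficients are stored as :class:`fractions.Fraction`.
Mass-balance checks on polymer-style reactions must be exact; floating point
drift would make "is this reaction elementally balanced" ill-defined.
Coefficients are rendered as decimal floats only on SBML export.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction
from typing import Iterable, Iterator, Mapping

import numpy as np

from .gpr import GprTree

#: id of the canonical "unknown localisation" compartment
UNKNOWN_COMPARTMENT = "UNK_COMP"

#: default flux capacity used when an SBML file specifies no bounds
DEFAULT_FLUX_BOUND = 1000.0

MetKey = tuple[str, str]  # (metabolite id, compartment id)


class Reversibility(str, Enum):
    FORWARD = "forward"
    BACKWARD = "backward"
    REVERSIBLE = "reversible"


@dataclass
class Compartment:
    id: str
    name: str = ""
    is_extracellular: bool = False

    @property
    def is_unknown(self) -> bool:
        return self.id == UNKNOWN_COMPARTMENT


@dataclass
class Metabolite:
    """One metabolite instance: a chemical species in one compartment."""

    id: str
    compartment: str
    formula: dict[str, int] | None = None
    name: str = ""
    sources: set[str] = field(default_factory=set)

    @property
    def key(self) -> MetKey:
        return (self.id, self.compartment)


@dataclass
class Gene:
    id: str
    sources: set[str] = field(default_factory=set)


def _bounds_for(rev: Reversibility) -> tuple[float, float]:
    if rev is Reversibility.REVERSIBLE:
        return (-DEFAULT_FLUX_BOUND, DEFAULT_FLUX_BOUND)
    if rev is Reversibility.FORWARD:
        return (0.0, DEFAULT_FLUX_BOUND)
    return (-DEFAULT_FLUX_BOUND, 0.0)


@dataclass
class Reaction:
    """A reaction with exact stoichiometry.

    ``stoich`` maps metabolite keys to signed rational coefficients; negative
    coefficients are substrates, positive are products.  ``reversibility`` is
    the single source of truth for direction; ``lb``/``ub`` are derived from
    it unless the source file specified tighter bounds.
    """

    id: str
    stoich: dict[MetKey, Fraction]
    reversibility: Reversibility = Reversibility.REVERSIBLE
    lb: float | None = None
    ub: float | None = None
    gpr: GprTree = field(default_factory=GprTree.empty)
    sources: set[str] = field(default_factory=set)
    name: str = ""

    def __post_init__(self) -> None:
        self.stoich = {k: Fraction(v) for k, v in self.stoich.items() if v != 0}
        if self.lb is None or self.ub is None:
            dlb, dub = _bounds_for(self.reversibility)
            if self.lb is None:
                self.lb = dlb
            if self.ub is None:
                self.ub = dub
        if self.lb > self.ub:
            raise ValueError(f"reaction {self.id}: lb {self.lb} > ub {self.ub}")

    @property
    def is_boundary(self) -> bool:
        """Boundary (exchange) reactions have species on one side only."""
        if not self.stoich:
            return False
        signs = {c > 0 for c in self.stoich.values()}
        return len(signs) == 1

    @property
    def substrates(self) -> set[MetKey]:
        return {k for k, c in self.stoich.items() if c < 0}

    @property
    def products(self) -> set[MetKey]:
        return {k for k, c in self.stoich.items() if c > 0}

    @property
    def support(self) -> frozenset[MetKey]:
        return frozenset(self.stoich)

    def compartments(self) -> set[str]:
        return {c for (_, c) in self.stoich}

    def reversed(self) -> "Reaction":
        rev = {
            Reversibility.FORWARD: Reversibility.BACKWARD,
            Reversibility.BACKWARD: Reversibility.FORWARD,
            Reversibility.REVERSIBLE: Reversibility.REVERSIBLE,
        }[self.reversibility]
        return replace(
            self,
            stoich={k: -c for k, c in self.stoich.items()},
            reversibility=rev,
            lb=-self.ub,
            ub=-self.lb,
        )

    def net_signature(self) -> tuple:
        """Canonical, direction-insensitive form of the stoichiometry.

        Two reactions have equal signatures iff their coefficient vectors are
        identical up to an overall sign flip (same metabolites, same ratios
        written in either direction).
        """
        items = tuple(sorted(self.stoich.items()))
        flipped = tuple(sorted((k, -c) for k, c in self.stoich.items()))
        return min(items, flipped)

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoich=dict(self.stoich),
            reversibility=self.reversibility,
            lb=self.lb,
            ub=self.ub,
            gpr=self.gpr.copy(),
            sources=set(self.sources),
            name=self.name,
        )


@dataclass
class Model:
    """A genome-scale constraint-based metabolic model."""

    tag: str
    compartments: dict[str, Compartment] = field(default_factory=dict)
    metabolites: dict[MetKey, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    genes: dict[str, Gene] = field(default_factory=dict)
    biomass_reaction_id: str | None = None

    # -- construction helpers ------------------------------------------------

    def add_compartment(self, comp: Compartment) -> Compartment:
        self.compartments.setdefault(comp.id, comp)
        return self.compartments[comp.id]

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.compartment not in self.compartments:
            self.add_compartment(Compartment(met.compartment))
        existing = self.metabolites.get(met.key)
        if existing is not None:
            existing.sources |= met.sources
            if existing.formula is None:
                existing.formula = met.formula
            return existing
        self.metabolites[met.key] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id}")
        for key in rxn.stoich:
            if key not in self.metabolites:
                self.add_metabolite(Metabolite(id=key[0], compartment=key[1],
                                               sources=set(rxn.sources)))
        for g in rxn.gpr.genes():
            self.genes.setdefault(g, Gene(g, sources=set(rxn.sources)))
        self.reactions[rxn.id] = rxn
        return rxn

    # -- queries -------------------------------------------------------------

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for key in rxn.stoich:
                if key not in self.metabolites:
                    raise ValueError(f"{rxn.id}: unresolved metabolite {key}")
            for g in rxn.gpr.genes():
                if g not in self.genes:
                    raise ValueError(f"{rxn.id}: unresolved gene {g}")
        unknown = [c for c in self.compartments.values() if c.is_unknown]
        if len(unknown) > 1:
            raise ValueError("more than one unknown compartment")

    def reaction_balanced(self, rxn: Reaction) -> bool | None:
        """Exact elemental balance of ``rxn``; None when a formula is absent.

        Boundary reactions are unbalanced by construction and return False.
        """
        totals: dict[str, Fraction] = {}
        for key, coeff in rxn.stoich.items():
            met = self.metabolites[key]
            if met.formula is None:
                return None
            for element, count in met.formula.items():
                totals[element] = totals.get(element, Fraction(0)) + coeff * count
        return all(v == 0 for v in totals.values())

    def boundary_reactions(self) -> list[str]:
        return [r.id for r in self.reactions.values() if r.is_boundary]

    def transport_reactions(self) -> list[str]:
        """Reactions carrying the same metabolite id in >= 2 compartments."""
        out = []
        for rxn in self.reactions.values():
            by_id: dict[str, set[str]] = {}
            for (mid, comp) in rxn.stoich:
                by_id.setdefault(mid, set()).add(comp)
            if any(len(comps) >= 2 for comps in by_id.values()):
                out.append(rxn.id)
        return out

    def extracellular_compartment(self) -> str | None:
        for comp in self.compartments.values():
            if comp.is_extracellular:
                return comp.id
        return None

    def prune_orphan_metabolites(self) -> list[MetKey]:
        """Drop metabolite instances used by no reaction; returns them."""
        used: set[MetKey] = set()
        for rxn in self.reactions.values():
            used |= rxn.support
        orphans = [k for k in self.metabolites if k not in used]
        for k in orphans:
            del self.metabolites[k]
        return orphans

    def copy(self) -> "Model":
        m = Model(tag=self.tag, biomass_reaction_id=self.biomass_reaction_id)
        for comp in self.compartments.values():
            m.add_compartment(replace(comp))
        for met in self.metabolites.values():
            m.metabolites[met.key] = Metabolite(
                id=met.id, compartment=met.compartment,
                formula=dict(met.formula) if met.formula is not None else None,
                name=met.name, sources=set(met.sources))
        for gene in self.genes.values():
            m.genes[gene.id] = Gene(gene.id, sources=set(gene.sources))
        for rxn in self.reactions.values():
            m.reactions[rxn.id] = rxn.copy()
        return m

    def entity_digest(self) -> str:
        """Stable digest of all entity ids, used to guard log replay."""
        payload = json.dumps(
            {
                "tag": self.tag,
                "compartments": sorted(self.compartments),
                "metabolites": sorted(map(list, self.metabolites)),
                "reactions": sorted(self.reactions),
                "genes": sorted(self.genes),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Model):
            return NotImplemented
        return (
            self.tag == other.tag
            and self.biomass_reaction_id == other.biomass_reaction_id
            and {c.id: (c.name, c.is_extracellular)
                 for c in self.compartments.values()}
            == {c.id: (c.name, c.is_extracellular)
                for c in other.compartments.values()}
            and {k: (m.formula, m.sources) for k, m in self.metabolites.items()}
            == {k: (m.formula, m.sources) for k, m in other.metabolites.items()}
            and set(self.genes) == set(other.genes)
            and self._rxn_view() == other._rxn_view()
        )

    def _rxn_view(self) -> dict:
        return {
            r.id: (tuple(sorted(r.stoich.items())), r.reversibility,
                   r.lb, r.ub, r.gpr.canonical_string(),
                   frozenset(r.sources))
            for r in self.reactions.values()
        }


def union_models(models: Iterable[Model], tag: str = "union") -> Model:
    """Naive union of models: all compartments, metabolites (keyed by
    id + compartment), genes and reactions, with provenance unioned.
    Reaction-id collisions between models are resolved by tag-prefixing the
    later duplicate; nothing is merged beyond identical keys."""
    out = Model(tag=tag)
    for m in models:
        for comp in m.compartments.values():
            existing = out.compartments.get(comp.id)
            if existing is None:
                out.add_compartment(replace(comp))
            elif comp.is_extracellular:
                existing.is_extracellular = True
        for met in m.metabolites.values():
            out.add_metabolite(Metabolite(
                id=met.id, compartment=met.compartment,
                formula=dict(met.formula) if met.formula is not None else None,
                name=met.name, sources=set(met.sources) or {m.tag}))
        for gene in m.genes.values():
            g = out.genes.setdefault(gene.id, Gene(gene.id))
            g.sources |= gene.sources or {m.tag}
        for rxn in m.reactions.values():
            new = rxn.copy()
            if not new.sources:
                new.sources = {m.tag}
            if new.id in out.reactions:
                new.id = f"{m.tag}__{new.id}"
            out.add_reaction(new)
        if out.biomass_reaction_id is None:
            out.biomass_reaction_id = m.biomass_reaction_id
    return out


# ---------------------------------------------------------------------------
# Stoichiometric matrix
# ---------------------------------------------------------------------------


@dataclass
class StoichMatrix:
    """Dense m x r matrix of signed stoichiometric coefficients.

    Rows are metabolite instances, columns reactions.  Derived matrices used
    by the reconciliation methods (the doubled matrix for direction-blind
    duplicate detection, the boolean support matrix, the redox-substituted
    matrix, per-compartment matrices, and the all-forward split used by the
    lumped-reaction LP) are built downstream from this one.
    """

    S: np.ndarray
    met_index: list[MetKey]
    rxn_index: list[str]

    @property
    def met_pos(self) -> dict[MetKey, int]:
        return {k: i for i, k in enumerate(self.met_index)}

    @property
    def rxn_pos(self) -> dict[str, int]:
        return {r: j for j, r in enumerate(self.rxn_index)}


def build_stoich_matrix(model: Model) -> StoichMatrix:
    """Assemble S (m x r) with S[i, j] the coefficient of metabolite i in
    reaction j."""
    met_index = sorted(model.metabolites)
    rxn_index = sorted(model.reactions)
    met_pos = {k: i for i, k in enumerate(met_index)}
    S = np.zeros((len(met_index), len(rxn_index)))
    for j, rid in enumerate(rxn_index):
        for key, coeff in model.reactions[rid].stoich.items():
            S[met_pos[key], j] = float(coeff)
    return StoichMatrix(S=S, met_index=met_index, rxn_index=rxn_index)
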