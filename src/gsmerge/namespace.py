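"""Offline canonical-namespace mapping and model overlap statistics.

Models arrive with metabolite and reaction identifiers from whatever
database their authors preferred.  Before anything can be compared, ids are
rewritten into one canonical namespace using a user-supplied mapping table
(the MNXref-style TSV of MetaNetX); ids the table does not know are
prefixed with the model tag so they stay globally unique and become
candidates for network-context matching instead.  Every substitution is
returned for user review; rejected rows revert to the tag-prefixed
original.

Compartment ids are harmonised separately through an alias map, since the
same compartment is spelled differently across models ("c", "Cytoplasm",
"cytosol").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import pandas as pd

from .model import MetKey, Model
from .records import InconsistencyRecord

log = logging.getLogger(__name__)

#: compartment-name harmonisation shipped with the tool; user-extensible
DEFAULT_COMPARTMENT_ALIASES: dict[str, str] = {
    "c": "cyt", "cytoplasm": "cyt", "cytosol": "cyt", "cyt": "cyt",
    "e": "ext", "extracellular": "ext", "extraorganism": "ext",
    "external": "ext", "ext": "ext",
    "p": "per", "periplasm": "per", "periplasmic": "per", "per": "per",
    "m": "mit", "mitochondrion": "mit", "mitochondria": "mit", "mit": "mit",
}


@dataclass
class MappingTable:
    """Rows of (source namespace, source id) -> canonical id."""

    rows: dict[tuple[str, str], str] = field(default_factory=dict)
    descriptions: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not v for v in self.rows.values()):
            raise ValueError("canonical ids must be nonempty")

    @staticmethod
    def from_tsv(path: str | Path) -> "MappingTable":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        rows, desc = {}, {}
        for _, r in df.iterrows():
            key = (r["source_ns"], r["source_id"])
            if key in rows:
                raise ValueError(f"duplicate mapping key {key}")
            rows[key] = r["canonical_id"]
            desc[key] = r.get("description", "")
        return MappingTable(rows=rows, descriptions=desc)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("source_ns\tsource_id\tcanonical_id\tdescription\n")
            for (ns, sid), cid in sorted(self.rows.items()):
                fh.write(f"{ns}\t{sid}\t{cid}\t"
                         f"{self.descriptions.get((ns, sid), '')}\n")

    def lookup(self, namespace: str, source_id: str) -> str | None:
        hit = self.rows.get((namespace, source_id))
        if hit is None:
            hit = self.rows.get(("", source_id))
        return hit

    def canonical_ids(self) -> set[str]:
        return set(self.rows.values())


@dataclass
class ReviewEntry:
    old_id: str
    proposed: str
    status: str = "accepted"   # accepted | rejected | unmapped | conflict


@dataclass
class MappingReview:
    entries: list[ReviewEntry] = field(default_factory=list)

    def rejected_ids(self) -> set[str]:
        return {e.old_id for e in self.entries if e.status == "rejected"}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("old_id\tproposed_canonical_id\tstatus\n")
            for e in self.entries:
                fh.write(f"{e.old_id}\t{e.proposed}\t{e.status}\n")

    @staticmethod
    def from_tsv(path: str | Path) -> "MappingReview":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        return MappingReview([
            ReviewEntry(old_id=r["old_id"],
                        proposed=r["proposed_canonical_id"],
                        status=r["status"] or "accepted")
            for _, r in df.iterrows()])


def harmonize_compartments(model: Model,
                           aliases: dict[str, str] | None = None) -> Model:
    """Rename compartments through the alias map (in place); unknown names
    pass through unchanged."""
    aliases = {**DEFAULT_COMPARTMENT_ALIASES, **(aliases or {})}
    def canon(c: str) -> str:
        return aliases.get(c.lower(), c)
    for old in list(model.compartments):
        new = canon(old)
        if new == old:
            continue
        comp = model.compartments.pop(old)
        comp.id = new
        if new not in model.compartments:
            model.compartments[new] = comp
    for key in list(model.metabolites):
        mid, comp = key
        new = (mid, canon(comp))
        if new != key:
            met = model.metabolites.pop(key)
            met.compartment = new[1]
            model.metabolites[new] = met
    for rxn in model.reactions.values():
        stoich: dict[MetKey, Fraction] = {}
        for (mid, comp), coeff in rxn.stoich.items():
            key = (mid, canon(comp))
            stoich[key] = stoich.get(key, Fraction(0)) + coeff
        rxn.stoich = {k: c for k, c in stoich.items() if c != 0}
    return model


def apply_mapping(model: Model, table: MappingTable,
                  review: MappingReview | None = None,
                  namespace: str | None = None,
                  ) -> tuple[Model, MappingReview]:
    """Rewrite metabolite and reaction ids into the canonical namespace.

    Mapped ids are replaced; ids already canonical are kept; everything
    else is prefixed with the model tag (so it can never silently collide
    with another model's id).  Two same-model metabolites mapping to the
    same canonical id in the same compartment are merged, unless they meet
    inside a single reaction — that conflict is flagged for mandatory
    review instead of auto-merged.  Applying the same table twice is a
    no-op the second time.
    """
    namespace = namespace if namespace is not None else model.tag
    rejected = review.rejected_ids() if review is not None else set()
    out_review = MappingReview()
    canonical = table.canonical_ids()
    prefix = f"{model.tag}_"

    def map_id(old: str) -> tuple[str, str]:
        if old in rejected:
            return (old if old.startswith(prefix) else prefix + old, "rejected")
        hit = table.lookup(namespace, old)
        if hit is not None:
            return hit, "accepted"
        if old in canonical or old.startswith(prefix):
            return old, "already-canonical"
        return prefix + old, "unmapped"

    met_map: dict[MetKey, MetKey] = {}
    for key in sorted(model.metabolites):
        new_id, status = map_id(key[0])
        met_map[key] = (new_id, key[1])
        if status in ("accepted", "unmapped", "rejected"):
            out_review.entries.append(ReviewEntry(
                old_id=key[0], proposed=new_id,
                status="accepted" if status == "accepted" else status))

    # conflict: two distinct metabolites of one reaction collapsing onto one
    # canonical target must not be auto-merged
    conflicts: set[MetKey] = set()
    for rxn in model.reactions.values():
        targets: dict[MetKey, list[MetKey]] = {}
        for key in rxn.stoich:
            targets.setdefault(met_map[key], []).append(key)
        for target, origins in targets.items():
            if len(origins) > 1:
                conflicts.update(origins)
                log.warning("mapping conflict in %s: %s all map to %s; "
                            "left unmapped for review", rxn.id,
                            origins, target)
    for key in conflicts:
        old = key[0]
        fallback = old if old.startswith(prefix) else prefix + old
        met_map[key] = (fallback, key[1])
        for e in out_review.entries:
            if e.old_id == old:
                e.status = "conflict"

    from .model import Metabolite
    new_mets: dict[MetKey, Metabolite] = {}
    for key, met in sorted(model.metabolites.items()):
        target = met_map[key]
        if target in new_mets:
            new_mets[target].sources |= met.sources
            if new_mets[target].formula is None:
                new_mets[target].formula = met.formula
        else:
            met.id, met.compartment = target
            new_mets[target] = met
    model.metabolites = new_mets

    for rxn in model.reactions.values():
        stoich: dict[MetKey, Fraction] = {}
        for key, coeff in rxn.stoich.items():
            target = met_map[key]
            stoich[target] = stoich.get(target, Fraction(0)) + coeff
        rxn.stoich = {k: c for k, c in stoich.items() if c != 0}

    new_rxns = {}
    for rid in sorted(model.reactions):
        new_id, _ = map_id(rid)
        rxn = model.reactions[rid]
        rxn.id = new_id
        new_rxns[new_id] = rxn
    model.reactions = new_rxns
    if model.biomass_reaction_id is not None:
        model.biomass_reaction_id = map_id(model.biomass_reaction_id)[0]
    return model, out_review


# ---------------------------------------------------------------------------
# Overlap statistics
# ---------------------------------------------------------------------------


def _reaction_keys(model: Model) -> set[tuple]:
    keys = set()
    for rxn in model.reactions.values():
        items = tuple(sorted(rxn.stoich.items()))
        flipped = tuple(sorted((k, -c) for k, c in rxn.stoich.items()))
        keys.add(min(items, flipped))
    return keys


def overlap_report(models: list[Model], convention: str = "union",
                   ) -> pd.DataFrame:
    """Shared-entity statistics across two or more models.

    Genes are matched by id, metabolites by (id, compartment) — with a
    compound-level count (id only) emitted alongside — and reactions by
    identical net stoichiometry, direction-insensitive.  The shared
    fraction is |intersection| / |union| by default; ``convention="min"``
    divides by the smaller model instead.
    """
    if len(models) < 2:
        raise ValueError("overlap requires at least two models")
    if convention not in ("union", "min"):
        raise ValueError(f"unknown convention {convention!r}")

    def row(name: str, sets: list[set]) -> dict:
        inter = set.intersection(*sets)
        union = set.union(*sets)
        denom = len(union) if convention == "union" else min(map(len, sets))
        return {"entity": name, "shared": len(inter), "union": len(union),
                "fraction": len(inter) / denom if denom else 0.0}

    return pd.DataFrame([
        row("genes", [set(m.genes) for m in models]),
        row("metabolites", [set(m.metabolites) for m in models]),
        row("metabolite_compounds",
            [{mid for (mid, _) in m.metabolites} for m in models]),
        row("reactions", [_reaction_keys(m) for m in models]),
    ])
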