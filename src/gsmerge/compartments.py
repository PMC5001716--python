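"""Compartment-level reconciliation.

Models of one organism often disagree on subcellular structure: one
resolves a periplasm, the other does not; transporters take different
routes or different co-substrates across the same membrane; boundary
reactions sit on intracellular species.  The operations here detect those
classes and repair them: splitting a direct transporter into two legs via
an intermediate compartment, removing a compartment altogether, re-pointing
invalid boundary reactions, and resolving species parked in the canonical
unknown compartment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import networkx as nx

from .log import DecisionLog, action
from .model import (Compartment, MetKey, Metabolite, Model, Reaction,
                    UNKNOWN_COMPARTMENT)
from .records import InconsistencyRecord

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Compartment connectivity
# ---------------------------------------------------------------------------


def build_compartment_graph(model: Model) -> nx.Graph:
    """Undirected graph of compartments directly connected by at least one
    transport reaction.  Edge attribute ``valid`` defaults to True and is
    meant to be toggled by the user."""
    g = nx.Graph()
    g.add_nodes_from(model.compartments)
    for rid in model.transport_reactions():
        rxn = model.reactions[rid]
        by_id: dict[str, set[str]] = {}
        for (mid, comp) in rxn.stoich:
            by_id.setdefault(mid, set()).add(comp)
        for comps in by_id.values():
            ordered = sorted(comps)
            for i, a in enumerate(ordered):
                for b in ordered[i + 1:]:
                    if not g.has_edge(a, b):
                        g.add_edge(a, b, valid=True, reactions=set())
                    g.edges[a, b]["reactions"].add(rid)
    return g


def graph_from_tsv(model: Model, path) -> nx.Graph:
    """Apply user validity flags (TSV: comp_a, comp_b, valid) to the graph."""
    import pandas as pd
    g = build_compartment_graph(model)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for _, row in df.iterrows():
        a, b = row["comp_a"], row["comp_b"]
        if g.has_edge(a, b):
            g.edges[a, b]["valid"] = str(row["valid"]).lower() in ("1", "true", "yes")
    return g


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def find_alternative_transport(model: Model,
                               ) -> dict[tuple[str, frozenset[str]], set[str]]:
    """Groups of >=2 transport reactions moving the same metabolite between
    the same two compartments, keyed by (metabolite id, compartment pair)."""
    groups: dict[tuple[str, frozenset[str]], set[str]] = {}
    for rid in model.transport_reactions():
        rxn = model.reactions[rid]
        by_id: dict[str, set[str]] = {}
        for (mid, comp) in rxn.stoich:
            by_id.setdefault(mid, set()).add(comp)
        for mid, comps in by_id.items():
            if len(comps) == 2:
                groups.setdefault((mid, frozenset(comps)), set()).add(rid)
    return {k: v for k, v in groups.items() if len(v) >= 2}


def find_invalid_transport(model: Model, graph: nx.Graph) -> list[str]:
    """Reactions containing metabolites from both ends of any user-flagged
    invalid compartment connection."""
    invalid_edges = [frozenset((a, b)) for a, b, d in graph.edges(data=True)
                     if not d.get("valid", True)]
    if not invalid_edges:
        log.info("no compartment connections flagged invalid")
        return []
    out = []
    for rid in sorted(model.reactions):
        comps = model.reactions[rid].compartments()
        if any(edge <= comps for edge in invalid_edges):
            out.append(rid)
    return out


def find_alt_compartmentalization(model: Model) -> list[set[str]]:
    """Groups of single-compartment reactions that are identical once
    compartment tags are stripped — the same conversion placed in different
    compartments.  Transport reactions never qualify."""
    groups: dict[tuple, dict[str, set[str]]] = {}
    for rxn in model.reactions.values():
        comps = rxn.compartments()
        if len(comps) != 1:
            continue
        comp = next(iter(comps))
        stripped = {(mid, ""): c for (mid, _), c in rxn.stoich.items()}
        items = tuple(sorted(stripped.items()))
        flipped = tuple(sorted((k, -c) for k, c in stripped.items()))
        sig = min(items, flipped)
        groups.setdefault(sig, {}).setdefault(comp, set()).add(rxn.id)
    out = []
    for per_comp in groups.values():
        if len(per_comp) >= 2:
            out.append(set().union(*per_comp.values()))
    return sorted(out, key=lambda g: sorted(g)[0])


def resolve_unknown_compartment(model: Model) -> list[InconsistencyRecord]:
    """Placement proposals for reactions touching the unknown compartment.

    A reaction with a species in the unknown compartment is matched against
    reactions that involve the same known-compartment metabolites
    (support match) plus the same metabolite id in a known compartment;
    that compartment is proposed.  Unmatched reactions stay unresolved.
    """
    if UNKNOWN_COMPARTMENT not in model.compartments:
        return []
    out = []
    support_index: dict[frozenset[MetKey], list[str]] = {}
    for rxn in model.reactions.values():
        if UNKNOWN_COMPARTMENT not in rxn.compartments():
            support_index.setdefault(rxn.support, []).append(rxn.id)
    for rxn in sorted(model.reactions.values(), key=lambda r: r.id):
        unk = [(mid, c) for (mid, c) in rxn.stoich if c == UNKNOWN_COMPARTMENT]
        if not unk:
            continue
        known = frozenset(k for k in rxn.stoich if k[1] != UNKNOWN_COMPARTMENT)
        proposals = set()
        for (mid, _) in unk:
            for comp in model.compartments:
                if comp == UNKNOWN_COMPARTMENT:
                    continue
                target = known | {(mid, comp)}
                for rid2 in support_index.get(frozenset(target), []):
                    if rid2 != rxn.id:
                        proposals.add(comp)
        if proposals:
            comp = sorted(proposals)[0]
            out.append(InconsistencyRecord(
                klass="unknown_compartment", members=(rxn.id,),
                status="auto-resolved" if len(proposals) == 1 else "pending",
                resolution=f"propose compartment {comp}",
                detail={"compartment": comp,
                        "alternatives": sorted(proposals)}))
        else:
            out.append(InconsistencyRecord(
                klass="unknown_compartment", members=(rxn.id,),
                status="pending", resolution="unresolved"))
    return out


def find_invalid_boundary(model: Model) -> list[str]:
    """Boundary reactions whose metabolite is not extracellular."""
    ext = model.extracellular_compartment()
    if ext is None:
        raise ValueError("no extracellular compartment designated")
    out = []
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        if rxn.is_boundary and any(c != ext for (_, c) in rxn.stoich):
            out.append(rid)
    return out


# ---------------------------------------------------------------------------
# Repairs (logged actions)
# ---------------------------------------------------------------------------


@action("split_transport")
def _apply_split_transport(model: Model, args: dict) -> None:
    rid, via, move_side = args["reaction"], args["via"], args["move_side"]
    rxn = model.reactions.pop(rid)
    if via not in model.compartments:
        model.reactions[rid] = rxn
        raise ValueError(f"intermediate compartment {via!r} absent from model")
    moved = sorted(k for k in rxn.stoich if k[1] == move_side)
    # diffusion leg: everything on the move side steps into the intermediate
    leg1 = Reaction(
        id=f"{rid}__{move_side}_{via}",
        stoich={**{k: rxn.stoich[k] for k in moved},
                **{(mid, via): -rxn.stoich[(mid, comp)]
                   for (mid, comp) in moved}},
        reversibility=rxn.reversibility,
        lb=rxn.lb, ub=rxn.ub, gpr=rxn.gpr, sources=set(rxn.sources))
    # chemistry leg: the original reaction with move-side species re-pointed
    leg2_stoich: dict[MetKey, Fraction] = {}
    for (mid, comp), coeff in rxn.stoich.items():
        key = (mid, via) if comp == move_side else (mid, comp)
        leg2_stoich[key] = leg2_stoich.get(key, Fraction(0)) + coeff
    leg2_stoich = {k: c for k, c in leg2_stoich.items() if c != 0}
    leg2 = Reaction(
        id=f"{rid}__{via}", stoich=leg2_stoich,
        reversibility=rxn.reversibility,
        lb=rxn.lb, ub=rxn.ub, gpr=rxn.gpr, sources=set(rxn.sources))
    model.add_reaction(leg1)
    model.add_reaction(leg2)


def split_transport(model: Model, reaction: str, via: str,
                    move_side: str | None = None,
                    decision_log: DecisionLog | None = None,
                    origin: str = "auto") -> tuple[str, str]:
    """Split a transporter into two legs through ``via``.

    ``move_side`` names the compartment whose species are re-pointed into
    the intermediate; by default the extracellular side (the chemistry —
    protons, ATP cost — then stays on the membrane-proximal, target-side
    leg, and the outer leg is plain diffusion).  The two legs sum exactly to
    the original reaction.
    """
    rxn = model.reactions[reaction]
    comps = rxn.compartments()
    if move_side is None:
        ext = model.extracellular_compartment()
        move_side = ext if ext in comps else sorted(comps)[0]
    if move_side not in comps:
        raise ValueError(f"{reaction} has no species in {move_side!r}")
    args = {"reaction": reaction, "via": via, "move_side": move_side}
    _apply_split_transport(model, args)
    if decision_log is not None:
        decision_log.record("split_transport", args, origin=origin)
    return (f"{reaction}__{move_side}_{via}", f"{reaction}__{via}")


@action("repair_boundary")
def _apply_repair_boundary(model: Model, args: dict) -> None:
    rid = args["reaction"]
    ext = args["extracellular"]
    rxn = model.reactions[rid]
    (mid, comp), coeff = next(iter(rxn.stoich.items()))
    if comp == ext:
        return
    model.add_metabolite(Metabolite(id=mid, compartment=ext,
                                    sources=set(rxn.sources)))
    rxn.stoich = {(mid, ext): coeff}
    transport_id = f"T_{rid}"
    if transport_id not in model.reactions:
        model.add_reaction(Reaction(
            id=transport_id,
            stoich={(mid, ext): Fraction(-1), (mid, comp): Fraction(1)},
            reversibility=rxn.reversibility,
            lb=rxn.lb, ub=rxn.ub, sources=set(rxn.sources)))


def repair_boundary(model: Model, reaction: str,
                    decision_log: DecisionLog | None = None,
                    origin: str = "auto") -> None:
    """Re-point an invalid boundary reaction to the extracellular instance
    of its metabolite and add the corresponding transport reaction, so the
    net exchange capability is preserved."""
    ext = model.extracellular_compartment()
    if ext is None:
        raise ValueError("no extracellular compartment designated")
    args = {"reaction": reaction, "extracellular": ext}
    _apply_repair_boundary(model, args)
    if decision_log is not None:
        decision_log.record("repair_boundary", args, origin=origin)


@action("remove_compartment")
def _apply_remove_compartment(model: Model, args: dict) -> None:
    rc, tc = args["rc"], args["tc"]
    if rc == tc or rc not in model.compartments or tc not in model.compartments:
        raise ValueError(f"cannot remove compartment {rc!r} into {tc!r}")
    removed: list[str] = []
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        comps = rxn.compartments()
        if rc not in comps:
            continue
        repointed: dict[MetKey, Fraction] = {}
        for (mid, comp), coeff in rxn.stoich.items():
            key = (mid, tc) if comp == rc else (mid, comp)
            repointed[key] = repointed.get(key, Fraction(0)) + coeff
        repointed = {k: c for k, c in repointed.items() if c != 0}
        if not repointed:
            # pure RC<->TC transport: fully cancels, drop it (category ii)
            removed.append(rid)
            continue
        # categories i (RC-only, moved), iii (RC<->TC with chemistry) and
        # iv (RC<->other) all reduce to re-pointing RC species to TC
        for key in repointed:
            if key not in model.metabolites:
                model.add_metabolite(Metabolite(
                    id=key[0], compartment=key[1], sources=set(rxn.sources)))
        rxn.stoich = repointed
    for rid in removed:
        del model.reactions[rid]
    for key in [k for k in model.metabolites if k[1] == rc]:
        del model.metabolites[key]
    del model.compartments[rc]
    orphans = model.prune_orphan_metabolites()
    if removed or orphans:
        log.info("compartment %s removed: %d transport reactions dropped, "
                 "%d orphan metabolites pruned", rc, len(removed), len(orphans))


def remove_compartment(model: Model, rc: str, tc: str,
                       decision_log: DecisionLog | None = None,
                       origin: str = "auto") -> None:
    """Remove compartment ``rc``, moving its chemistry into ``tc``.

    Reactions wholly inside rc move to tc; pure rc<->tc transports vanish;
    rc<->tc reactions with a chemical conversion and rc<->other reactions
    are kept with their rc species re-pointed to tc; orphaned rc species
    are deleted.
    """
    args = {"rc": rc, "tc": tc}
    _apply_remove_compartment(model, args)
    if decision_log is not None:
        decision_log.record("remove_compartment", args, origin=origin)
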