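"""Consensus-model construction.

``build_bcm`` unions the input models into a Basic Consensus Model (BCM)
and immediately merges reactions that are exactly identical.  ``auto_refine``
then runs the four automatic reconciliation steps that turn the BCM into a
Refined Consensus Model (RCM):

1. network-context metabolite matching, and merging of confirmed matches;
2. transport splitting, so models with different compartment resolution
   describe transport the same way;
3. merging of reactions with practically (protons/water ignored) identical
   net formulas, with direction and GPR merge policies;
4. merging of same-metabolite different-stoichiometry groups when exactly
   one member is elementally balanced.

Every mutation is appended to a decision log; replaying the log on the same
inputs reproduces the refined model bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import compartments as comp_mod
from . import matching as match_mod
from . import reactions as rxn_mod
from .log import DecisionLog, action, apply_entry, check_inputs
from .model import Model, union_models
from .records import InconsistencyRecord

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# BCM
# ---------------------------------------------------------------------------


def build_bcm(models: list[Model], decision_log: DecisionLog | None = None,
              tag: str = "bcm") -> Model:
    """Union the inputs and merge exactly identical net reactions.

    Metabolite-id collisions with conflicting formulas are kept (first
    formula wins on the merged record) and reported as conflicts.
    """
    for a in models:
        for b in models:
            if a is not b:
                for key, met in a.metabolites.items():
                    other = b.metabolites.get(key)
                    if (other is not None and met.formula is not None
                            and other.formula is not None
                            and met.formula != other.formula):
                        log.warning("formula conflict for %s: %s vs %s",
                                    key, met.formula, other.formula)
    bcm = union_models(models, tag=tag)
    policy = rxn_mod.MergePolicy(proton_water_ignore=False)
    for group in rxn_mod.find_identical_net(bcm, ignore_proton_water=False):
        present = group & set(bcm.reactions)
        if len(present) >= 2:
            # shortest id survives, so collision-prefixed duplicates vanish
            keep = min(present, key=lambda r: (len(r), r))
            rxn_mod.merge_reactions(bcm, present, policy, keep=keep,
                                    decision_log=decision_log)
    return bcm


def consensus_fraction(model: Model) -> float:
    """Share of reactions carrying provenance from at least two models."""
    if not model.reactions:
        return 0.0
    shared = sum(1 for r in model.reactions.values() if len(r.sources) >= 2)
    return shared / len(model.reactions)


# ---------------------------------------------------------------------------
# Four-step automatic refinement
# ---------------------------------------------------------------------------


@dataclass
class RefineResult:
    model: Model
    decision_log: DecisionLog
    records: list[InconsistencyRecord] = field(default_factory=list)
    proposals: list[match_mod.MatchProposal] = field(default_factory=list)

    @property
    def pending(self) -> list[InconsistencyRecord]:
        return [r for r in self.records if r.status == "pending"]


def auto_refine(bcm: Model, policy: rxn_mod.MergePolicy | None = None,
                tags: tuple[str, str] | None = None,
                confirmed_matches: list[match_mod.MatchProposal] | None = None,
                auto_confirm: bool = False,
                percentile: float = match_mod.DEFAULT_PERCENTILE,
                skip_matching: bool = False,
                decision_log: DecisionLog | None = None) -> RefineResult:
    """Run the four automatic reconciliation steps on a BCM (in place).

    Matching proposals are only acted on when confirmed — either passed in
    as ``confirmed_matches`` (the recommended, reviewed route) or, with
    ``auto_confirm``, taken as scored.  Pending items are carried in the
    result's records, never silently dropped.
    """
    policy = policy or rxn_mod.MergePolicy()
    decision_log = decision_log if decision_log is not None else DecisionLog()
    result = RefineResult(model=bcm, decision_log=decision_log)

    if tags is None:
        tags = _infer_tags(bcm)

    # step 1: metabolite matching
    if not skip_matching and tags is not None:
        confirmed = confirmed_matches
        if confirmed is None:
            ctx = match_mod.build_context(bcm, tags)
            try:
                scores = match_mod.score_matches(ctx, tags)
                proposals = match_mod.threshold_matches(scores, percentile)
            except ValueError as exc:
                log.warning("metabolite matching skipped: %s", exc)
                proposals = []
            result.proposals = proposals
            if auto_confirm:
                confirmed = proposals
            else:
                confirmed = []
                result.records.extend(InconsistencyRecord(
                    klass="met_match",
                    members=(f"{p.met_a[0]}@{p.met_a[1]}",
                             f"{p.met_b[0]}@{p.met_b[1]}"),
                    status="pending",
                    resolution=f"score {p.score:.3f}; awaiting confirmation")
                    for p in proposals)
        result.records.extend(
            match_mod.merge_matched(bcm, confirmed, decision_log))

    # step 2: transport splitting to harmonise compartment resolution
    result.records.extend(_harmonise_transport(bcm, decision_log))

    # step 3: practically identical net reactions
    for group in rxn_mod.find_identical_net(
            bcm, policy.proton_water_ignore, policy.proton_water_ids):
        present = group & set(bcm.reactions)
        if len(present) >= 2:
            result.records.append(rxn_mod.merge_reactions(
                bcm, present, policy, decision_log=decision_log))

    # step 4: alternative stoichiometries, unique balanced member survives
    for group in rxn_mod.find_alt_stoichiometry(bcm):
        present = group & set(bcm.reactions)
        if len(present) < 2:
            continue
        keep, reason = rxn_mod.resolve_alt_stoichiometry(bcm, present)
        if keep is None:
            result.records.append(InconsistencyRecord(
                klass="alt_stoich", members=tuple(sorted(present)),
                status="pending", resolution=reason))
        else:
            rec = rxn_mod.merge_reactions(
                bcm, present, policy, keep=keep, allow_different_net=True,
                decision_log=decision_log)
            rec.klass = "alt_stoich"
            rec.resolution += f"; {reason}"
            result.records.append(rec)
    return result


def _infer_tags(model: Model) -> tuple[str, str] | None:
    tags = sorted({t for r in model.reactions.values() for t in r.sources})
    if len(tags) != 2:
        if len(tags) > 2:
            log.info("model carries %d source tags; automatic pairwise "
                     "matching covers the first two", len(tags))
            return (tags[0], tags[1])
        return None
    return (tags[0], tags[1])


def _harmonise_transport(model: Model, decision_log: DecisionLog,
                         ) -> list[InconsistencyRecord]:
    """Split direct transporters so both models route through the same
    compartments: a reaction from one model moving a metabolite a->c is
    split via b when the other model moves that metabolite a->b and b->c."""
    routes: dict[str, dict[str, set[frozenset[str]]]] = {}
    for rid in model.transport_reactions():
        rxn = model.reactions[rid]
        by_id: dict[str, set[str]] = {}
        for (mid, comp) in rxn.stoich:
            by_id.setdefault(mid, set()).add(comp)
        for mid, comps in by_id.items():
            if len(comps) == 2:
                for tag in rxn.sources:
                    routes.setdefault(mid, {}).setdefault(tag, set()).add(
                        frozenset(comps))
    records = []
    for rid in sorted(model.transport_reactions()):
        rxn = model.reactions.get(rid)
        if rxn is None or len(rxn.sources) != 1:
            continue
        tag = next(iter(rxn.sources))
        by_id: dict[str, set[str]] = {}
        for (mid, comp) in rxn.stoich:
            by_id.setdefault(mid, set()).add(comp)
        for mid, comps in sorted(by_id.items()):
            if len(comps) != 2:
                continue
            a, c = sorted(comps)
            via = None
            for other_tag, pairs in routes.get(mid, {}).items():
                if other_tag == tag:
                    continue
                for b in model.compartments:
                    if b in (a, c):
                        continue
                    if frozenset((a, b)) in pairs and frozenset((b, c)) in pairs:
                        via = b
                        break
                if via:
                    break
            if via is None:
                continue
            ext = model.extracellular_compartment()
            move_side = ext if ext in comps else sorted(comps)[0]
            legs = comp_mod.split_transport(model, rid, via,
                                            move_side=move_side,
                                            decision_log=decision_log)
            records.append(InconsistencyRecord(
                klass="transport_split", members=(rid,),
                status="auto-resolved",
                resolution=f"split via {via} into {legs[0]} + {legs[1]}"))
            break  # reaction replaced; move on
    return records


# ---------------------------------------------------------------------------
# Reaction classification
# ---------------------------------------------------------------------------


@dataclass
class ReactionClassification:
    per_reaction: dict[str, str]
    counts: dict[str, int]

    @property
    def consensus_fraction(self) -> float:
        total = sum(self.counts.values())
        return self.counts["consensus"] / total if total else 0.0


def detect_all(model: Model, pairs: rxn_mod.RedoxPairList | None = None,
               include_lumped: bool = False) -> dict[str, list[set[str]]]:
    """All detector outputs on the current model state, keyed by class."""
    reports: dict[str, list[set[str]]] = {
        "identical_net": rxn_mod.find_identical_net(model),
        "alt_stoich": rxn_mod.find_alt_stoichiometry(model),
        "redox": rxn_mod.find_redox_variants(model, pairs),
        "nested": [set(p) for p in rxn_mod.find_nested(model)],
        "similar": [set(p) for p in rxn_mod.find_similar(model)],
        "alt_transport": [set(g) for g in
                          comp_mod.find_alternative_transport(model).values()],
        "alt_compartment": comp_mod.find_alt_compartmentalization(model),
    }
    if include_lumped:
        lumped = []
        for rid in sorted(model.reactions):
            for ls in rxn_mod.find_lumped(model, rid):
                lumped.append({rid} | set(ls.members))
        reports["lumped"] = lumped
    return reports


def classify_reactions(model: Model,
                       reports: dict[str, list[set[str]]],
                       ) -> ReactionClassification:
    """Consensus vs unique reactions; unique ones binned by how many
    inconsistency classes reference them (classes are not mutually
    exclusive, so one reaction may accumulate several)."""
    classes_per_rxn: dict[str, set[str]] = {r: set() for r in model.reactions}
    for klass, groups in reports.items():
        for group in groups:
            for rid in group:
                if rid in classes_per_rxn:
                    classes_per_rxn[rid].add(klass)
    per_reaction = {}
    counts = {"consensus": 0, "none": 0, "single": 0, "multiple": 0}
    for rid, rxn in model.reactions.items():
        if len(rxn.sources) >= 2:
            cat = "consensus"
        else:
            n = len(classes_per_rxn[rid])
            cat = "none" if n == 0 else ("single" if n == 1 else "multiple")
        per_reaction[rid] = cat
        counts[cat] += 1
    return ReactionClassification(per_reaction=per_reaction, counts=counts)


# ---------------------------------------------------------------------------
# Biomass selection and replay
# ---------------------------------------------------------------------------


@action("select_biomass")
def _apply_select_biomass(model: Model, args: dict) -> None:
    model.biomass_reaction_id = args["keep"]
    for rid in args["disable"]:
        if rid in model.reactions:
            model.reactions[rid].lb = 0.0
            model.reactions[rid].ub = 0.0


def select_biomass(model: Model, keep: str, others: list[str] | None = None,
                   decision_log: DecisionLog | None = None,
                   origin: str = "user") -> None:
    """Designate one input model's biomass reaction; the others stay in the
    model but are disabled (bounds 0)."""
    args = {"keep": keep, "disable": sorted(others or [])}
    _apply_select_biomass(model, args)
    if decision_log is not None:
        decision_log.record("select_biomass", args, origin=origin)


def replay(decision_log: DecisionLog, inputs: list[Model]) -> Model:
    """Re-apply a recorded run to the same inputs.

    The union of the inputs is rebuilt and every logged action re-applied in
    sequence order; an empty log therefore yields the naive union.  Inputs
    are checked against the digests stored in the log.
    """
    if decision_log.input_digests:
        check_inputs(decision_log, inputs)
    model = union_models(inputs, tag="bcm")
    for entry in decision_log.entries:
        apply_entry(model, entry)
    return model


def run_pipeline(models: list[Model], policy: rxn_mod.MergePolicy | None = None,
                 auto_confirm: bool = True, skip_matching: bool = False,
                 percentile: float = match_mod.DEFAULT_PERCENTILE,
                 ) -> RefineResult:
    """BCM construction plus the four automatic steps, fully logged."""
    decision_log = DecisionLog(
        input_digests=[m.entity_digest() for m in models])
    bcm = build_bcm(models, decision_log=decision_log)
    return auto_refine(bcm, policy=policy, auto_confirm=auto_confirm,
                       skip_matching=skip_matching, percentile=percentile,
                       decision_log=decision_log)
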