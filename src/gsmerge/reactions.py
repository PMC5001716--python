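"""Reaction-level inconsistency detection and merging.

Detectors cover the classes that arise when independently built models of
one organism are combined: identical net reactions written in either
direction, same-metabolite reactions with different stoichiometries,
variants differing only in the redox pair used, nested reactions (one
reaction's metabolites a strict subset of another's), partially overlapping
"similar" reactions, and lumped reactions (a single net reaction standing in
for a multi-step pathway), which are found with an iterated linear program.

All detectors work on exact stoichiometries; the LP uses floating point but
every reported lumped set is re-verified in exact rational arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable

import numpy as np
from scipy.optimize import linprog

from .gpr import GprTree, parse_gpr
from .log import DecisionLog, action
from .model import MetKey, Model, Reaction, Reversibility, _bounds_for
from .records import InconsistencyRecord

log = logging.getLogger(__name__)

#: metabolite ids ignored when comparing "practically identical" net formulas
DEFAULT_PROTON_WATER_IDS = frozenset({
    "h", "h+", "proton", "h2o", "water", "oh", "MNXM1", "MNXM2"})

#: commonly used redox pairs (canonical short names)
DEFAULT_REDOX_PAIRS: tuple[tuple[str, str], ...] = (
    ("nad", "nadh"),
    ("nadp", "nadph"),
    ("fad", "fadh2"),
    ("fmn", "fmnh2"),
    ("q8", "q8h2"),
    ("gthox", "gthrd"),
)

LP_FLUX_TOLERANCE = 1e-9


@dataclass
class RedoxPairList:
    pairs: list[frozenset[str]] = field(
        default_factory=lambda: [frozenset(p) for p in DEFAULT_REDOX_PAIRS])

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.pairs:
            if len(p) != 2:
                raise ValueError(f"redox pair must have two members: {set(p)}")
            if p & seen:
                raise ValueError(f"redox pairs overlap in membership: {set(p)}")
            seen |= p

    def add(self, a: str, b: str) -> None:
        self.pairs.append(frozenset({a, b}))
        self.__post_init__()


@dataclass
class MergePolicy:
    """How conflicting attributes are combined when reactions merge.

    ``gpr_mode``: ``union`` ORs the rules of all members; ``strict`` keeps a
    rule only when the members agree (identical rules, or one gene set a
    subset of the other, in which case the superset rule is kept and
    flagged) and otherwise holds the merge for user review.

    ``direction_mode``: when member directions conflict, either fall back to
    reversible, or consult a pluggable predictor (a callable mapping a
    Reaction to forward/backward/reversible/unknown).
    """

    gpr_mode: str = "union"
    direction_mode: str = "consensus-then-reversible"
    proton_water_ignore: bool = True
    proton_water_ids: frozenset[str] = DEFAULT_PROTON_WATER_IDS
    direction_predictor: Callable[[Reaction], str] | None = None

    def __post_init__(self) -> None:
        if self.gpr_mode not in ("union", "strict"):
            raise ValueError(f"unknown gpr_mode {self.gpr_mode!r}")
        if self.direction_mode not in (
                "consensus-then-reversible", "consensus-then-predictor-hook"):
            raise ValueError(f"unknown direction_mode {self.direction_mode!r}")


# ---------------------------------------------------------------------------
# Signatures
# ---------------------------------------------------------------------------


def _effective_stoich(rxn: Reaction, ignore_ids: frozenset[str] | None,
                      ) -> dict[MetKey, Fraction]:
    if not ignore_ids:
        return rxn.stoich
    return {k: c for k, c in rxn.stoich.items() if k[0] not in ignore_ids}


def net_signature(rxn: Reaction, ignore_ids: frozenset[str] | None = None,
                  ) -> tuple:
    """Direction-insensitive canonical stoichiometry (doubled-matrix idea:
    a reaction and its negation share a signature)."""
    stoich = _effective_stoich(rxn, ignore_ids)
    items = tuple(sorted(stoich.items()))
    flipped = tuple(sorted((k, -c) for k, c in stoich.items()))
    return min(items, flipped)


def support_signature(rxn: Reaction, ignore_ids: frozenset[str] | None = None,
                      ) -> frozenset[MetKey]:
    return frozenset(_effective_stoich(rxn, ignore_ids))


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------


def find_identical_net(model: Model, ignore_proton_water: bool = True,
                       proton_water_ids: frozenset[str] = DEFAULT_PROTON_WATER_IDS,
                       ) -> list[set[str]]:
    """Groups of reactions with identical net formula, direction-blind.

    Equivalent to finding identical columns in the doubled matrix [S, -S];
    with ``ignore_proton_water`` the proton and water rows are zeroed first,
    so reactions that differ only in those species still group.
    """
    ignore = proton_water_ids if ignore_proton_water else None
    groups: dict[tuple, set[str]] = {}
    for rxn in model.reactions.values():
        sig = net_signature(rxn, ignore)
        if not sig:
            continue  # reaction vanished entirely under the ignore list
        groups.setdefault(sig, set()).add(rxn.id)
    return sorted((g for g in groups.values() if len(g) >= 2),
                  key=lambda g: sorted(g)[0])


def find_alt_stoichiometry(model: Model) -> list[set[str]]:
    """Groups of reactions with the same metabolites but different
    stoichiometric coefficients (identical boolean-support columns that are
    not identical net reactions)."""
    groups: dict[frozenset[MetKey], set[str]] = {}
    for rxn in model.reactions.values():
        groups.setdefault(support_signature(rxn), set()).add(rxn.id)
    out = []
    for members in groups.values():
        if len(members) < 2:
            continue
        sigs = {net_signature(model.reactions[r], None) for r in members}
        if len(sigs) >= 2:
            out.append(members)
    return sorted(out, key=lambda g: sorted(g)[0])


def resolve_alt_stoichiometry(model: Model, group: set[str],
                              ) -> tuple[str | None, str]:
    """Pick the member to keep: the elementally balanced one, but only when
    exactly one member balances.  Returns (kept id or None, reason)."""
    balance = {rid: model.reaction_balanced(model.reactions[rid])
               for rid in sorted(group)}
    if any(b is None for b in balance.values()):
        return None, "formula missing; balance check skipped"
    balanced = [rid for rid, b in balance.items() if b]
    if len(balanced) == 1:
        return balanced[0], "single elementally balanced member"
    return None, f"{len(balanced)} balanced members; user decision required"


def _redox_pairs_in(rxn: Reaction, pairs: RedoxPairList,
                    ) -> list[tuple[frozenset[str], str]]:
    """Redox pairs applicable to a reaction: both members present in the
    same compartment on opposite sides.  Returns (pair, compartment)."""
    found = []
    for pair in pairs.pairs:
        a, b = sorted(pair)
        for comp in rxn.compartments():
            ca = rxn.stoich.get((a, comp))
            cb = rxn.stoich.get((b, comp))
            if ca is not None and cb is not None and (ca > 0) != (cb > 0):
                found.append((pair, comp))
    return found


def find_redox_variants(model: Model, pairs: RedoxPairList | None = None,
                        ) -> list[set[str]]:
    """Groups of reactions identical up to the redox pair used.

    Each reaction's redox couple is replaced by a unit entry in an
    artificial 'redox pair' row; reactions whose substituted supports match
    (alternative-stoichiometry style) are grouped.  Reactions containing two
    different redox pairs have each substitution tried independently and are
    flagged for review.
    """
    pairs = pairs or RedoxPairList()
    groups: dict[frozenset, set[str]] = {}
    multi: set[str] = set()
    for rxn in model.reactions.values():
        applicable = _redox_pairs_in(rxn, pairs)
        if not applicable:
            continue
        if len({p for p, _ in applicable}) > 1:
            multi.add(rxn.id)
        for pair, comp in applicable:
            support = frozenset(
                k for k in rxn.stoich if not (k[0] in pair and k[1] == comp))
            sig = frozenset({("**redox**", "")}) | support
            groups.setdefault(sig, set()).add(rxn.id)
    out = []
    for members in groups.values():
        if len(members) < 2:
            continue
        sigs = {net_signature(model.reactions[r], None) for r in members}
        if len(sigs) >= 2:
            out.append(members)
    if multi:
        log.info("reactions with multiple redox pairs flagged for review: %s",
                 sorted(multi))
    return sorted(out, key=lambda g: sorted(g)[0])


def suggest_redox_pairs(model: Model, threshold: float = 0.8,
                        ) -> list[tuple[str, str, float]]:
    """Candidate redox/currency couples: metabolite id pairs that co-occur on
    opposite sides in at least ``threshold`` of the reactions of each.

    Returns (id a, id b, min co-occurrence fraction), sorted descending.
    """
    count: dict[str, int] = {}
    both: dict[frozenset[str], int] = {}
    for rxn in model.reactions.values():
        ids = {mid for (mid, _) in rxn.stoich}
        for mid in ids:
            count[mid] = count.get(mid, 0) + 1
        for a in ids:
            for b in ids:
                if a >= b:
                    continue
                opposite = any(
                    (rxn.stoich.get((a, c1), 0) > 0) != (rxn.stoich.get((b, c2), 0) > 0)
                    for (m1, c1) in rxn.stoich if m1 == a
                    for (m2, c2) in rxn.stoich if m2 == b)
                if opposite:
                    both[frozenset({a, b})] = both.get(frozenset({a, b}), 0) + 1
    out = []
    for pair, n in both.items():
        a, b = sorted(pair)
        frac = min(n / count[a], n / count[b])
        if frac >= threshold:
            out.append((a, b, frac))
    return sorted(out, key=lambda t: (-t[2], t[0], t[1]))


def find_nested(model: Model) -> list[tuple[str, str]]:
    """(inner, outer) pairs where inner's metabolite set is a strict subset
    of outer's, confirmed by side agreement: at least two metabolites are
    shared and their substrate/product sidedness in the inner reaction maps
    consistently onto the outer reaction (allowing the outer reaction to be
    written in the opposite direction).  A plain conversion A -> B is thus
    confirmed inside its cofactor-using variant A + NADH -> B + NAD."""
    rxns = sorted(model.reactions.values(), key=lambda r: r.id)
    out = []
    for inner in rxns:
        for outer in rxns:
            if inner.id == outer.id:
                continue
            si, so = inner.support, outer.support
            if not (si < so):
                continue
            if _sides_agree(inner, outer, si):
                out.append((inner.id, outer.id))
    return out


def _sides_agree(inner: Reaction, outer: Reaction,
                 shared: frozenset[MetKey]) -> bool:
    if len(shared) < 2:
        return False
    inner_signs = [inner.stoich[k] > 0 for k in sorted(shared)]
    outer_signs = [outer.stoich[k] > 0 for k in sorted(shared)]
    return (inner_signs == outer_signs
            or inner_signs == [not s for s in outer_signs])


def find_similar(model: Model, min_shared_genes: int = 1,
                 min_shared_substrates: int = 1,
                 min_shared_products: int = 1) -> list[tuple[str, str]]:
    """Cross-model reaction pairs sharing at least the given numbers of
    genes, substrates and products (as written).  Pairs must have disjoint
    source-model sets, so only genuinely unreconciled reactions pair up."""
    rxns = sorted(model.reactions.values(), key=lambda r: r.id)
    out = []
    for i, r1 in enumerate(rxns):
        for r2 in rxns[i + 1:]:
            if not r1.sources or not r2.sources or r1.sources & r2.sources:
                continue
            if len(r1.substrates & r2.substrates) < min_shared_substrates:
                continue
            if len(r1.products & r2.products) < min_shared_products:
                continue
            if len(r1.gpr.genes() & r2.gpr.genes()) < min_shared_genes:
                continue
            out.append((r1.id, r2.id))
    return out


# ---------------------------------------------------------------------------
# Lumped reactions (iterated LP)
# ---------------------------------------------------------------------------


@dataclass
class LumpedSet:
    """One non-lumped representation of a candidate lumped reaction."""

    candidate: str
    members: frozenset[str]
    fluxes: dict[str, Fraction]       # signed net flux per member (and candidate)
    exact: bool = False               # S . x == 0 verified in rationals
    gpr_overlap: int = 0


def _all_forward_columns(model: Model) -> list[tuple[str, int]]:
    """(reaction id, sign) columns: backward reactions reversed, reversible
    reactions split into a forward (+1) and a backward (-1) column; boundary
    reactions dropped."""
    cols: list[tuple[str, int]] = []
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        if rxn.is_boundary:
            continue
        if rxn.reversibility is Reversibility.FORWARD:
            cols.append((rid, +1))
        elif rxn.reversibility is Reversibility.BACKWARD:
            cols.append((rid, -1))
        else:
            cols.append((rid, +1))
            cols.append((rid, -1))
    return cols


def find_lumped(model: Model, candidate: str, max_set_size: int = 5,
                min_gene_overlap: int = 1) -> list[LumpedSet]:
    """Non-lumped representations of ``candidate`` by iterated LP.

    All reactions are made forward-running (reversibles split, backward
    reversed) and boundary columns removed.  The LP maximises c'x subject to
    S x = 0 and 0 <= x <= 1000, with c = -1 everywhere except -1000 for the
    candidate, whose lower bound is opened to -1.  A nonzero optimum runs
    the candidate backwards against a minimal-flux pathway with the same net
    conversion — the non-lumped set NL.  Each found set's objective
    coefficients are tripled and the LP re-run, so alternative pathways
    surface, until the solution is zero, a set recurs, or a set exceeds
    ``max_set_size`` reactions.

    Sets are filtered for gene-association overlap with the candidate
    (``min_gene_overlap`` shared genes; candidates without genes are not
    filtered) and every set is re-verified to satisfy S x = 0 in exact
    rational arithmetic.
    """
    if candidate not in model.reactions:
        raise KeyError(candidate)
    if model.reactions[candidate].is_boundary:
        return []
    cols = _all_forward_columns(model)
    # the reverse column of a reversible candidate would cancel it trivially
    lr_col = (candidate, +1) if (candidate, +1) in cols else (candidate, -1)
    cols = [col for col in cols if col[0] != candidate or col == lr_col]
    i_lr = cols.index(lr_col)

    met_index = sorted(model.metabolites)
    met_pos = {k: i for i, k in enumerate(met_index)}
    S = np.zeros((len(met_index), len(cols)))
    for j, (rid, sign) in enumerate(cols):
        for key, coeff in model.reactions[rid].stoich.items():
            S[met_pos[key], j] = sign * float(coeff)

    c = -np.ones(len(cols))
    c[i_lr] = -1000.0
    lb = np.zeros(len(cols))
    ub = np.full(len(cols), 1000.0)
    lb[i_lr] = -1.0

    lr_genes = model.reactions[candidate].gpr.genes()
    found: list[LumpedSet] = []
    seen: set[frozenset[str]] = set()
    for _ in range(64):  # hard cap; termination normally via the three rules
        res = linprog(-c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                      bounds=list(zip(lb, ub)), method="highs")
        if not res.success:
            raise RuntimeError(
                f"lumped-reaction LP failed for {candidate}: {res.message}")
        x = res.x
        if -res.fun <= 1e-6 or np.all(np.abs(x) < LP_FLUX_TOLERANCE):
            break
        support = [j for j in range(len(cols))
                   if abs(x[j]) > LP_FLUX_TOLERANCE]
        members = frozenset(cols[j][0] for j in support if j != i_lr)
        if not members or members in seen:
            break
        if len(members) > max_set_size:
            break
        seen.add(members)
        net_flux: dict[str, Fraction] = {}
        for j in support:
            rid, sign = cols[j]
            f = Fraction(x[j]).limit_denominator(10 ** 9)
            net_flux[rid] = net_flux.get(rid, Fraction(0)) + sign * f
        exact = _verify_steady_state(model, net_flux)
        overlap = len(lr_genes & set().union(
            *(model.reactions[r].gpr.genes() for r in members)))
        found.append(LumpedSet(candidate=candidate, members=members,
                               fluxes=net_flux, exact=exact,
                               gpr_overlap=overlap))
        for j in support:
            if j != i_lr:
                c[j] *= 3.0
    if lr_genes:
        found = [s for s in found if s.gpr_overlap >= min_gene_overlap]
    return found


def _verify_steady_state(model: Model, net_flux: dict[str, Fraction]) -> bool:
    totals: dict[MetKey, Fraction] = {}
    for rid, flux in net_flux.items():
        for key, coeff in model.reactions[rid].stoich.items():
            totals[key] = totals.get(key, Fraction(0)) + coeff * flux
    return all(v == 0 for v in totals.values())


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


@action("merge_reactions")
def _apply_merge_reactions(model: Model, args: dict) -> None:
    keep = model.reactions[args["keep"]]
    for rid in args["drop"]:
        dropped = model.reactions.pop(rid)
        keep.sources |= dropped.sources
    keep.reversibility = Reversibility(args["reversibility"])
    keep.lb = args["lb"]
    keep.ub = args["ub"]
    keep.gpr = parse_gpr(args["gpr"])
    for g in keep.gpr.genes():
        if g not in model.genes:
            from .model import Gene
            model.genes[g] = Gene(g, sources=set(keep.sources))
    model.prune_orphan_metabolites()


def _aligned_reversibility(member: Reaction, keep: Reaction,
                           ignore: frozenset[str] | None) -> Reversibility:
    """Member's direction expressed in the kept reaction's writing."""
    ks = _effective_stoich(keep, ignore)
    ms = _effective_stoich(member, ignore)
    same = ms == ks
    if not same and {k: -c for k, c in ms.items()} == ks:
        return {
            Reversibility.FORWARD: Reversibility.BACKWARD,
            Reversibility.BACKWARD: Reversibility.FORWARD,
            Reversibility.REVERSIBLE: Reversibility.REVERSIBLE,
        }[member.reversibility]
    return member.reversibility


def merge_gprs(members: list[GprTree], mode: str) -> tuple[GprTree | None, str]:
    """Combine member GPRs; returns (tree or None when pending, note)."""
    nonempty = [g for g in members if not g.is_empty()]
    if not nonempty:
        return GprTree.empty(), "all spontaneous"
    canon = {g.canonical_string() for g in nonempty}
    if len(canon) == 1:
        return nonempty[0], "identical rules"
    if mode == "union":
        return GprTree.any_of(nonempty), "union (OR of member rules)"
    gene_sets = [g.genes() for g in nonempty]
    for i, g in enumerate(nonempty):
        if all(other <= gene_sets[i] for other in gene_sets):
            return g, "superset rule kept (strict mode, flagged)"
    return None, "rules disagree; user review required (strict mode)"


def merge_reactions(model: Model, group: set[str], policy: MergePolicy,
                    keep: str | None = None,
                    allow_different_net: bool = False,
                    decision_log: DecisionLog | None = None,
                    origin: str = "auto",
                    ) -> InconsistencyRecord:
    """Collapse a detected group to one reaction.

    Refuses groups whose net formulas differ (beyond an overall sign and,
    per policy, protons/water) unless ``allow_different_net`` — the caller
    then has chosen which member's stoichiometry survives via ``keep``.
    """
    members = [model.reactions[r] for r in sorted(group)]
    keep_id = keep or sorted(group)[0]
    keep_rxn = model.reactions[keep_id]
    ignore = policy.proton_water_ids if policy.proton_water_ignore else None

    sigs = {net_signature(r, ignore) for r in members}
    if len(sigs) > 1 and not allow_different_net:
        raise ValueError(
            f"group {sorted(group)} has differing net formulas; "
            "explicit override required")

    revs = {_aligned_reversibility(r, keep_rxn, ignore) for r in members}
    if len(revs) == 1:
        resolved = revs.pop()
        dir_note = "member consensus"
    elif (policy.direction_mode == "consensus-then-predictor-hook"
          and policy.direction_predictor is not None):
        verdict = policy.direction_predictor(keep_rxn)
        if verdict in ("forward", "backward", "reversible"):
            resolved = Reversibility(verdict)
            dir_note = "direction predictor"
        else:
            resolved = Reversibility.REVERSIBLE
            dir_note = "predictor undecided; reversible"
    else:
        resolved = Reversibility.REVERSIBLE
        dir_note = "conflicting directions; reversible"

    gpr, gpr_note = merge_gprs([r.gpr for r in members], policy.gpr_mode)
    if gpr is None:
        return InconsistencyRecord(
            klass="merge", members=tuple(sorted(group)), status="pending",
            resolution=f"GPR: {gpr_note}")

    lb, ub = _bounds_for(resolved)
    args = {
        "keep": keep_id,
        "drop": [r.id for r in members if r.id != keep_id],
        "reversibility": resolved.value,
        "lb": lb,
        "ub": ub,
        "gpr": gpr.canonical_string(),
    }
    _apply_merge_reactions(model, args)
    if decision_log is not None:
        decision_log.record("merge_reactions", args, origin=origin)
    return InconsistencyRecord(
        klass="merge", members=tuple(sorted(group)), status=f"{origin}-resolved",
        resolution=f"kept {keep_id}; direction: {dir_note}; GPR: {gpr_note}")
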