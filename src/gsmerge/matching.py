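"""Network-context metabolite matching.

Two models of one organism frequently carry the same chemical compound
under different identifiers, or model it at different granularity
('glucose' vs 'alpha-D-glucose').  Such pairs cannot be found by name, but
they sit in the same place in the network: they neighbour the same
metabolites and are handled by the same genes.

The matcher characterises every metabolite instance by the shared
metabolites and shared genes it co-occurs with in reactions (its *context*),
row-normalises the resulting attribute matrix so that rare — and therefore
defining — connections weigh more than promiscuous hubs, and scores
cross-model candidate pairs by Pearson correlation of their context
columns.  The decision threshold is calibrated on metabolites already known
to be shared: a user-chosen percentile of the score distribution of
shared-metabolite self pairs.

Matching is per compartment; a candidate pair must reside in the same
(harmonised) compartment.  Cross-compartment identity is the business of
the compartment-reconciliation methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .log import DecisionLog, action
from .model import MetKey, Model
from .records import InconsistencyRecord

log = logging.getLogger(__name__)

DEFAULT_PERCENTILE = 5.0

ColKey = tuple[str, MetKey]  # (model tag, metabolite key)


@dataclass
class AttributeMatrix:
    """Row-normalised context matrix.

    Rows are context attributes — metabolite keys and gene ids present in
    both models; columns are per-model metabolite instances.  Entry (i, j)
    is 1/k (before normalisation: 1) when attribute i co-occurs with column
    metabolite j in at least one reaction of j's model, where k is the
    total number of connections of attribute i.  Columns with no context at
    all are excluded and listed in ``no_context``.
    """

    M: np.ndarray
    rows: list[tuple[str, object]]          # ("met", MetKey) | ("gene", id)
    cols: list[ColKey]
    shared_mets: set[MetKey]
    no_context: list[ColKey] = field(default_factory=list)
    raw: np.ndarray | None = None           # pre-normalisation 0/1 matrix

    @property
    def col_pos(self) -> dict[ColKey, int]:
        return {c: j for j, c in enumerate(self.cols)}


def build_context(merged: Model, tags: tuple[str, str]) -> AttributeMatrix:
    """Attribute matrix for a merged pair of models.

    The merged model's provenance tags decide which reactions belong to
    which side; a reaction reconciled earlier (both tags) contributes
    context to both.
    """
    tag_a, tag_b = tags
    per_tag_mets: dict[str, set[MetKey]] = {tag_a: set(), tag_b: set()}
    per_tag_genes: dict[str, set[str]] = {tag_a: set(), tag_b: set()}
    for rxn in merged.reactions.values():
        for tag in (tag_a, tag_b):
            if tag in rxn.sources:
                per_tag_mets[tag] |= set(rxn.stoich)
                per_tag_genes[tag] |= rxn.gpr.genes()
    shared_mets = per_tag_mets[tag_a] & per_tag_mets[tag_b]
    shared_genes = per_tag_genes[tag_a] & per_tag_genes[tag_b]

    rows: list[tuple[str, object]] = (
        [("met", k) for k in sorted(shared_mets)]
        + [("gene", g) for g in sorted(shared_genes)])
    row_pos = {r: i for i, r in enumerate(rows)}

    cols: list[ColKey] = []
    for tag in (tag_a, tag_b):
        cols.extend((tag, k) for k in sorted(per_tag_mets[tag]))
    col_pos = {c: j for j, c in enumerate(cols)}

    M = np.zeros((len(rows), len(cols)))
    for rxn in merged.reactions.values():
        genes = rxn.gpr.genes()
        mets = set(rxn.stoich)
        for tag in (tag_a, tag_b):
            if tag not in rxn.sources:
                continue
            for met in mets:
                j = col_pos[(tag, met)]
                for other in mets:
                    if other != met and ("met", other) in row_pos:
                        M[row_pos[("met", other)], j] = 1.0
                for g in genes:
                    if ("gene", g) in row_pos:
                        M[row_pos[("gene", g)], j] = 1.0

    no_context = [cols[j] for j in range(M.shape[1]) if M[:, j].sum() == 0]
    return AttributeMatrix(M=_normalise_rows(M), rows=rows, cols=cols,
                           shared_mets=shared_mets, no_context=no_context,
                           raw=M)


def _normalise_rows(M: np.ndarray) -> np.ndarray:
    sums = M.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return M / sums


def degrade(matrix: AttributeMatrix, fraction: float,
            rng: np.random.Generator) -> AttributeMatrix:
    """Randomly hide ``fraction`` of the context rows (before
    re-normalisation), emulating incomplete network knowledge."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    n = len(matrix.rows)
    keep_n = n - int(round(fraction * n))
    keep = np.sort(rng.permutation(n)[:keep_n])
    base = matrix.raw if matrix.raw is not None else matrix.M
    M = _normalise_rows(base[keep, :])
    rows = [matrix.rows[i] for i in keep]
    no_context = [matrix.cols[j] for j in range(M.shape[1])
                  if M[:, j].sum() == 0]
    return AttributeMatrix(M=M, rows=rows, cols=matrix.cols,
                           shared_mets=matrix.shared_mets,
                           no_context=no_context)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

#: sentinel for Pearson being undefined (zero-variance context column)
NO_SIGNAL = None


def _pearson(u: np.ndarray, v: np.ndarray) -> float | None:
    du = u - u.mean()
    dv = v - v.mean()
    nu = np.sqrt((du ** 2).sum())
    nv = np.sqrt((dv ** 2).sum())
    if nu == 0 or nv == 0:
        return NO_SIGNAL
    return float(np.clip((du * dv).sum() / (nu * nv), -1.0, 1.0))


@dataclass
class ScoreMatrix:
    scores: dict[tuple[ColKey, ColKey], float]
    no_signal: list[tuple[ColKey, ColKey]]
    shared_scores: list[float]


def candidate_pairs(matrix: AttributeMatrix, tags: tuple[str, str],
                    ) -> list[tuple[ColKey, ColKey]]:
    """Cross-model pairs of non-shared metabolites in the same compartment."""
    tag_a, tag_b = tags
    a_only = [c for c in matrix.cols
              if c[0] == tag_a and c[1] not in matrix.shared_mets]
    b_only = [c for c in matrix.cols
              if c[0] == tag_b and c[1] not in matrix.shared_mets]
    return [(ca, cb) for ca in a_only for cb in b_only
            if ca[1][1] == cb[1][1]]


def score_matches(matrix: AttributeMatrix, tags: tuple[str, str],
                  pairs: list[tuple[ColKey, ColKey]] | None = None,
                  ) -> ScoreMatrix:
    """Pearson correlation of context columns for candidate pairs plus the
    shared-metabolite calibration pairs."""
    tag_a, tag_b = tags
    pos = matrix.col_pos
    if pairs is None:
        pairs = candidate_pairs(matrix, tags)
    scores: dict[tuple[ColKey, ColKey], float] = {}
    no_signal: list[tuple[ColKey, ColKey]] = []
    for ca, cb in pairs:
        s = _pearson(matrix.M[:, pos[ca]], matrix.M[:, pos[cb]])
        if s is NO_SIGNAL:
            no_signal.append((ca, cb))
        else:
            scores[(ca, cb)] = s
    shared_scores = []
    for k in sorted(matrix.shared_mets):
        ca, cb = (tag_a, k), (tag_b, k)
        if ca in pos and cb in pos:
            s = _pearson(matrix.M[:, pos[ca]], matrix.M[:, pos[cb]])
            if s is not NO_SIGNAL:
                shared_scores.append(s)
    return ScoreMatrix(scores=scores, no_signal=no_signal,
                       shared_scores=shared_scores)


@dataclass
class MatchProposal:
    met_a: MetKey
    met_b: MetKey
    score: float
    threshold: float
    status: str = "proposed"   # proposed | confirmed | rejected


def threshold_matches(score_matrix: ScoreMatrix,
                      percentile: float = DEFAULT_PERCENTILE,
                      ) -> list[MatchProposal]:
    """Greedy one-to-one proposals above the calibrated threshold.

    The threshold is the given percentile of the shared-metabolite score
    distribution; candidates scoring at least it are assigned one-to-one in
    descending score order with lexicographic tie-breaking.
    """
    if not score_matrix.shared_scores:
        raise ValueError(
            "no shared metabolites to calibrate the threshold; apply the "
            "namespace mapping first")
    threshold = float(np.percentile(score_matrix.shared_scores, percentile))
    # tolerance so that scores of exactly-matching contexts (1.0 up to
    # floating-point jitter) are never cut by a threshold of 1.0
    ranked = sorted(
        ((s, a, b) for (a, b), s in score_matrix.scores.items()
         if s >= threshold - 1e-12),
        key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[ColKey] = set()
    used_b: set[ColKey] = set()
    out = []
    for s, a, b in ranked:
        if a in used_a or b in used_b:
            continue
        used_a.add(a)
        used_b.add(b)
        out.append(MatchProposal(met_a=a[1], met_b=b[1], score=s,
                                 threshold=threshold))
    return out


# ---------------------------------------------------------------------------
# Merging matched metabolites
# ---------------------------------------------------------------------------


@action("merge_metabolites")
def _apply_merge_metabolites(model: Model, args: dict) -> None:
    keep: MetKey = tuple(args["keep"])  # type: ignore[assignment]
    drop: MetKey = tuple(args["drop"])  # type: ignore[assignment]
    if drop not in model.metabolites:
        return
    kept = model.metabolites.get(keep)
    dropped = model.metabolites.pop(drop)
    if kept is None:
        dropped.id, dropped.compartment = keep
        model.metabolites[keep] = dropped
        kept = dropped
    else:
        kept.sources |= dropped.sources
        if kept.formula is None:
            kept.formula = dropped.formula
    empty = []
    for rxn in model.reactions.values():
        if drop in rxn.stoich:
            coeff = rxn.stoich.pop(drop)
            total = rxn.stoich.get(keep, Fraction(0)) + coeff
            if total == 0:
                rxn.stoich.pop(keep, None)
                log.info("coefficient cancellation in %s after merging "
                         "%s into %s", rxn.id, drop, keep)
            else:
                rxn.stoich[keep] = total
            if not rxn.stoich:
                empty.append(rxn.id)
    for rid in empty:
        log.info("reaction %s fully cancelled by metabolite merge; removed",
                 rid)
        del model.reactions[rid]


def merge_matched(model: Model, confirmed: list[MatchProposal],
                  decision_log: DecisionLog | None = None,
                  origin: str = "auto",
                  ) -> list[InconsistencyRecord]:
    """Collapse confirmed cross-model matches to single metabolites.

    The first member's id survives.  When both formulas are known and
    disagree (granularity/polymer cases) the pair is *not* merged
    automatically; it is returned as pending for user confirmation, since a
    wrong merge can break mass conservation.
    """
    records = []
    for prop in confirmed:
        a, b = prop.met_a, prop.met_b
        met_a = model.metabolites.get(a)
        met_b = model.metabolites.get(b)
        label = (f"{a[0]}@{a[1]}", f"{b[0]}@{b[1]}")
        if met_a is None or met_b is None:
            records.append(InconsistencyRecord(
                klass="met_match", members=label, status="pending",
                resolution="member vanished in an earlier merge"))
            continue
        if (met_a.formula is not None and met_b.formula is not None
                and met_a.formula != met_b.formula and prop.status != "forced"):
            records.append(InconsistencyRecord(
                klass="met_match", members=label, status="pending",
                resolution="formulas differ; mass conservation at risk; "
                           "user confirmation required"))
            continue
        args = {"keep": list(a), "drop": list(b)}
        _apply_merge_metabolites(model, args)
        if decision_log is not None:
            decision_log.record("merge_metabolites", args, origin=origin)
        records.append(InconsistencyRecord(
            klass="met_match", members=label, status=f"{origin}-resolved",
            resolution=f"merged into {a[0]}@{a[1]} (score {prop.score:.3f})"))
    return records


# ---------------------------------------------------------------------------
# Degradation / ROC harness
# ---------------------------------------------------------------------------


def classification_rates(proposals: list[MatchProposal],
                         truth: set[tuple[MetKey, MetKey]],
                         n_candidates: int) -> tuple[float, float]:
    """(sensitivity, specificity) of proposals against ground truth over a
    candidate universe of ``n_candidates`` cross-model pairs."""
    proposed = {(p.met_a, p.met_b) for p in proposals}
    tp = len(proposed & truth)
    fp = len(proposed - truth)
    fn = len(truth - proposed)
    tn = n_candidates - tp - fp - fn
    sens = tp / (tp + fn) if tp + fn else 1.0
    spec = tn / (tn + fp) if tn + fp else 1.0
    return sens, spec


def roc_harness(merged: Model, tags: tuple[str, str],
                truth: set[tuple[MetKey, MetKey]],
                discard_fractions: list[float],
                repeats: int = 20, seed: int = 0,
                percentile: float = DEFAULT_PERCENTILE) -> list[dict]:
    """Matcher robustness under random loss of network information.

    For every discard fraction, that share of the context rows is hidden
    (``repeats`` independent draws from one seeded generator) before
    scoring, and the proposals are classified against the known-identical /
    known-different candidate pairs.  Returns one row per fraction with
    mean and standard deviation of sensitivity and specificity.
    """
    base = build_context(merged, tags)
    pairs = candidate_pairs(base, tags)
    rng = np.random.default_rng(seed)
    table = []
    for fraction in discard_fractions:
        sens_list, spec_list = [], []
        for _ in range(repeats):
            degraded = degrade(base, fraction, rng)
            sm = score_matches(degraded, tags, pairs)
            if sm.shared_scores:
                proposals = threshold_matches(sm, percentile)
            else:
                proposals = []
            sens, spec = classification_rates(proposals, truth, len(pairs))
            sens_list.append(sens)
            spec_list.append(spec)
        table.append({
            "fraction": fraction,
            "sensitivity": float(np.mean(sens_list)),
            "specificity": float(np.mean(spec_list)),
            "sd_sensitivity": float(np.std(sens_list)),
            "sd_specificity": float(np.std(spec_list)),
        })
    return table
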