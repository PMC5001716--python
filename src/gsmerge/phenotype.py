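"""Growth-phenotype prediction by flux balance analysis (FBA).

Growth is the maximal flux through the designated biomass reaction at steady
state (S v = 0) under medium-constrained exchange bounds.  Gene knockouts
disable every reaction whose GPR rule evaluates to false without the deleted
genes.  Predictions are compared against observed growth/no-growth calls,
yielding sensitivity, specificity, accuracy and Matthews correlation
coefficient with growth as the positive class.

Cutoffs: a wild type grows iff its optimum exceeds 1e-6; a mutant grows iff
it retains at least 30% of the wild-type growth rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linprog

from .model import Model, StoichMatrix, build_stoich_matrix

log = logging.getLogger(__name__)

WT_GROWTH_CUTOFF = 1e-6      # absolute wild-type growth threshold
MUTANT_RELATIVE_CUTOFF = 0.30  # minimal relative growth rate of a mutant
FVA_TOLERANCE = 1e-9


@dataclass
class PhenotypeRecord:
    condition: str
    medium: dict[str, float]          # metabolite id -> max uptake
    genotype: set[str] = field(default_factory=set)  # deleted genes
    observed: bool = True             # growth (True) / no-growth (False)


@dataclass
class PhenotypeDataset:
    records: list[PhenotypeRecord] = field(default_factory=list)

    @staticmethod
    def from_tsv(path: str | Path, media: dict[str, dict[str, float]]) -> "PhenotypeDataset":
        """Rows: condition, genotype (semicolon-separated genes, empty for
        wild type), medium name, observed (growth|no-growth)."""
        import pandas as pd
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        records = []
        for _, row in df.iterrows():
            records.append(PhenotypeRecord(
                condition=row["condition"],
                medium=media[row["medium"]],
                genotype=set(filter(None, row["genotype"].split(";"))),
                observed=row["observed"].strip().lower() == "growth",
            ))
        return PhenotypeDataset(records)


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    skipped: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else 0.0

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else 0.0

    @property
    def mcc(self) -> float:
        denom = ((self.tp + self.fp) * (self.tp + self.fn)
                 * (self.tn + self.fp) * (self.tn + self.fn))
        if denom == 0:
            return 0.0
        return (self.tp * self.tn - self.fp * self.fn) / math.sqrt(denom)


# ---------------------------------------------------------------------------
# LP plumbing
# ---------------------------------------------------------------------------


def _medium_bounds(model: Model, medium: dict[str, float] | None,
                   ) -> dict[str, tuple[float, float]]:
    """Exchange bounds under a medium.

    For a boundary reaction written with coefficient c on its metabolite,
    flux with sign(c * v) > 0 produces the metabolite (import).  Metabolites
    listed in the medium may be imported up to their max uptake; everything
    else may only be secreted.
    """
    if medium is None:
        return {}
    out: dict[str, tuple[float, float]] = {}
    for rxn in model.reactions.values():
        if not rxn.is_boundary:
            continue
        mids = {mid for (mid, _) in rxn.stoich}
        uptake = max((medium[m] for m in mids if m in medium), default=None)
        positive = next(iter(rxn.stoich.values())) > 0
        cap = abs(rxn.ub) if rxn.ub else 1000.0
        cap = max(cap, abs(rxn.lb or 0.0), 1000.0)
        if uptake is None:
            out[rxn.id] = (0.0, cap) if not positive else (-cap, 0.0)
        else:
            out[rxn.id] = ((-uptake, cap) if not positive
                           else (-cap, uptake))
    return out


def _solve(model: Model, objective: str, sense: int,
           medium: dict[str, float] | None = None,
           knockouts: set[str] | None = None,
           sm: StoichMatrix | None = None,
           extra_bounds: dict[str, tuple[float, float]] | None = None,
           ) -> tuple[float | None, dict[str, float]]:
    """maximize (sense=+1) or minimize (sense=-1) flux through ``objective``."""
    sm = sm if sm is not None else build_stoich_matrix(model)
    override = _medium_bounds(model, medium)
    if extra_bounds:
        override.update(extra_bounds)
    disabled: set[str] = set()
    if knockouts:
        for rxn in model.reactions.values():
            if not rxn.gpr.is_empty():
                present = set(model.genes) - set(knockouts)
                if not rxn.gpr.evaluate(present):
                    disabled.add(rxn.id)
    bounds = []
    for rid in sm.rxn_index:
        rxn = model.reactions[rid]
        lb, ub = override.get(rid, (rxn.lb, rxn.ub))
        if rid in disabled:
            lb, ub = 0.0, 0.0
        bounds.append((lb, ub))
    c = np.zeros(len(sm.rxn_index))
    c[sm.rxn_pos[objective]] = -float(sense)
    res = linprog(c, A_eq=sm.S, b_eq=np.zeros(sm.S.shape[0]),
                  bounds=bounds, method="highs")
    if not res.success:
        return None, {}
    fluxes = dict(zip(sm.rxn_index, res.x))
    return float(sense) * float(-res.fun), fluxes


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def simulate_growth(model: Model, medium: dict[str, float] | None = None,
                    knockouts: set[str] | None = None) -> float:
    """Maximal biomass flux; 0 when the LP is infeasible (flagged)."""
    if model.biomass_reaction_id is None:
        raise ValueError("no biomass reaction designated")
    value, _ = _solve(model, model.biomass_reaction_id, +1,
                      medium=medium, knockouts=knockouts)
    if value is None:
        log.warning("model %s: infeasible FBA problem; growth reported as 0",
                    model.tag)
        return 0.0
    return value


def call_growth(wildtype_flux: float, mutant_flux: float | None = None) -> bool:
    """Binary growth call.

    Wild type grows iff flux > 1e-6.  A mutant grows iff its flux is at
    least 30% of the wild-type flux; querying a mutant against a non-growing
    wild type yields no-growth (flagged).
    """
    wt_grows = wildtype_flux > WT_GROWTH_CUTOFF
    if mutant_flux is None:
        return wt_grows
    if not wt_grows:
        log.warning("mutant growth queried against non-growing wild type")
        return False
    return mutant_flux >= MUTANT_RELATIVE_CUTOFF * wildtype_flux


def evaluate(model: Model, data: PhenotypeDataset) -> MetricsReport:
    """Confusion matrix and metrics for growth-phenotype predictions."""
    tp = tn = fp = fn = skipped = 0
    wt_cache: dict[frozenset, float] = {}
    for rec in data.records:
        if rec.genotype and not rec.genotype & set(model.genes):
            skipped += 1
            continue
        medium_key = frozenset(rec.medium.items())
        if medium_key not in wt_cache:
            wt_cache[medium_key] = simulate_growth(model, rec.medium)
        wt = wt_cache[medium_key]
        if rec.genotype:
            mut = simulate_growth(model, rec.medium, rec.genotype)
            predicted = call_growth(wt, mut)
        else:
            predicted = call_growth(wt)
        if predicted and rec.observed:
            tp += 1
        elif predicted and not rec.observed:
            fp += 1
        elif not predicted and rec.observed:
            fn += 1
        else:
            tn += 1
    return MetricsReport(tp=tp, tn=tn, fp=fp, fn=fn, skipped=skipped)


def active_reactions(model: Model, medium: dict[str, float] | None = None,
                     ) -> dict[str, bool]:
    """Flux-variability classification: a reaction is active iff some
    steady-state solution gives it |v| > 1e-9 (objective left open)."""
    sm = build_stoich_matrix(model)
    out: dict[str, bool] = {}
    for rid in sm.rxn_index:
        vmax, _ = _solve(model, rid, +1, medium=medium, sm=sm)
        active = vmax is not None and vmax > FVA_TOLERANCE
        if not active:
            vmin, _ = _solve(model, rid, -1, medium=medium, sm=sm)
            active = vmin is not None and vmin < -FVA_TOLERANCE
        out[rid] = bool(active)
    return out
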