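# Methods

This note documents the models and algorithms implemented in `gsmerge`,
the assumptions behind them, the tunable parameters, and what the
synthetic test networks do and do not show about real genome-scale models
(GSMs).

## Model representation

A model is a set of compartments, metabolite instances (one record per
chemical species per compartment), reactions, and genes. Stoichiometric
coefficients are exact rationals (`fractions.Fraction`): elemental-balance
decisions on polymer-style reactions (n vs n+1 subunits) must not depend on
float drift. Coefficients are rendered as decimal doubles only on SBML
export and re-read through their shortest decimal representation, so any
coefficient with a finite decimal expansion round-trips exactly; a
coefficient like 1/3 round-trips to 17 significant digits. Reversibility
(`forward` / `backward` / `reversible`) is the single source of truth for
direction; flux bounds are derived views (±1000 by convention) unless the
source file states tighter ones, which are preserved. A reaction is a
boundary (exchange) reaction iff all its nonzero coefficients share one
sign; SBML species marked `boundaryCondition` are dropped from
stoichiometries, which reduces sink-style writings to the same one-sided
form. Gene-protein-reaction (GPR) rules are boolean trees over gene ids
(AND = complex, OR = isozymes); an empty rule means spontaneous/unknown and
always evaluates true under knockouts. Every entity carries the set of
source-model tags it descends from; the *consensus fraction* of a model is
the share of reactions carrying two or more tags.

SBML I/O targets Level 3 + FBC v2 on write and additionally accepts legacy
Level 2 conventions on read (`GENE_ASSOCIATION` notes, kinetic-law bound
parameters). Both dialects appear among published GSMs, and which one a
given input uses cannot be assumed.

## Namespace mapping and overlap statistics

Identifier canonicalisation is applied offline from a user-supplied
MNXref-style TSV (no web service, no string-similarity guessing): mapped
ids are replaced, ids already canonical are kept, everything else is
prefixed with the model tag so it stays globally unique and falls through
to network-context matching. Two same-model metabolites collapsing onto one
canonical id are merged — unless they meet inside a single reaction, which
is flagged for mandatory review instead (auto-merging would silently change
that reaction's chemistry). The operation is idempotent. Compartment names
are harmonised through an alias map (defaults cover
cytosol/periplasm/extracellular/mitochondrion spellings).

Overlap statistics match genes by id, metabolites by (id, compartment) —
with a compound-level count alongside, since conventions differ on whether
compartment instances count separately — and reactions by identical net
stoichiometry, direction-insensitive. The shared fraction is
|intersection| / |union| by default; a `min` convention
(|intersection| / smaller model) is available as a config switch because
published overlap percentages rarely state their denominator.

## Metabolite matching by network context

Identifiers aside, a compound is characterised by where it sits in the
network. For a merged pair of models with tags (A, B):

- **Rows** of the attribute matrix are the context attributes: metabolite
  instances and genes present in *both* models (entities private to one
  model cannot help identify correspondences).
- **Columns** are per-model metabolite instances (tag, metabolite). Entry
  (i, j) is 1 when attribute i co-occurs with column metabolite j in at
  least one reaction of j's model — metabolite–metabolite co-occurrence is
  boolean, as is gene-to-metabolite incidence.
- Each row is divided by its sum, so an attribute connected to k columns
  contributes 1/k per connection: rare connections define, hubs dilute.
- Candidate pairs (A-only × B-only metabolites, same harmonised
  compartment) are scored by Pearson correlation of their columns.
  Zero-variance columns make the correlation undefined; such metabolites
  are excluded and listed, never scored 0 — a 0 would silently compete
  with genuine negatives.
- The acceptance threshold is a percentile (default 5) of the scores of
  *shared* metabolites, each scored between its own A-column and B-column.
  This calibrates "how similar do contexts of the same compound look in
  these two models" on known ground truth inside the data itself.
  Proposals are assigned one-to-one greedily by descending score with
  lexicographic tie-breaks; a 1e-12 tolerance on the threshold comparison
  keeps exactly-correlated pairs from being cut by a threshold of
  exactly 1.0.

Keeping both per-model columns for shared metabolites (rather than
discarding them after calibration) is what makes the threshold computable
after rows and columns are restricted; the matrix invariant — every
retained row sums to 1 — holds for the matrix actually used for scoring.

Merging a confirmed pair re-points all stoichiometries, cancels
same-metabolite-both-sides coefficients, and removes fully cancelled
reactions. Pairs whose elemental formulas are both known and disagree are
*never* auto-merged (polymer/granularity cases can violate mass
conservation); they pend for user confirmation. Matching is
per-compartment by design; cross-compartment identity is handled by the
compartment methods.

The degradation harness hides a fraction of context rows (the raw 0/1
matrix is re-normalised after the drop) before scoring, repeats under one
seeded generator, and reports mean ± sd sensitivity/specificity against
planted ground truth. Only the *ordering* across discard fractions is
asserted in tests, with a 0.05 sampling-error allowance chosen a priori.

## Reaction-level detectors

All detectors operate on exact stoichiometries via canonical signatures
(equivalent to scanning columns of the corresponding derived matrix):

- **Identical net reactions**: identical columns of the doubled matrix
  [S, −S] — same coefficients up to an overall sign flip. With
  proton/water ignoring (default on, ids configurable) those rows are
  zeroed first, grouping "practically identical" variants.
- **Alternative stoichiometries**: identical boolean-support columns that
  are not identical-net. Auto-resolution keeps a member only when exactly
  one is elementally balanced (exact rational balance); a missing formula
  suspends the check.
- **Redox variants**: for each reaction containing both members of a known
  redox pair in one compartment on opposite sides, the couple is replaced
  by a unit entry in an artificial "redox pair" row; substituted supports
  are grouped as for alternative stoichiometries. Reactions containing two
  different pairs have each substitution tried independently and are
  flagged. Candidate new pairs are suggested when two metabolite ids
  co-occur on opposite sides in ≥ 80% of each one's reactions.
- **Nested reactions**: inner support a strict subset of outer support,
  confirmed when ≥ 2 shared metabolites have consistent sidedness (their
  sign vectors equal up to a global flip — which admits the canonical
  optional-cofactor case A→B inside A+NADH→B+NAD, where the two shared
  metabolites sit on opposite sides).
- **Similar reactions**: cross-model pairs (disjoint source-tag sets; a
  reaction already carrying both tags is reconciled and pairs with
  nothing) sharing at least the configured numbers of genes, substrates
  and products, sides compared as written.

### Lumped reactions (iterated LP)

If a lumped reaction and its multi-step representation carry flux in
opposite directions, they cancel at steady state. All non-boundary
reactions are made forward-running (backward reversed, reversible split
into two columns; the reverse column of the candidate itself is removed,
as it would cancel the candidate trivially). The LP maximises c′x subject
to S·x = 0, 0 ≤ x ≤ 1000, with c = −1 everywhere, c = −1000 at the
candidate and its lower bound opened to −1. A positive optimum runs the
candidate backwards against a minimal-total-flux pathway; its support
(fluxes above 1e-9) minus the candidate is a non-lumped set NL. Tripling
c on each found set and re-solving yields alternative sets until the
solution is zero, a set recurs (canonical sorted-id hashing), or a set
exceeds the size cap (default 5); a hard iteration cap of 64 backstops
termination. Sets are filtered for gene overlap with the candidate
(default ≥ 1 shared gene; candidates without genes pass unfiltered), and
each set's flux vector is rationalised and checked to satisfy S·x = 0
*exactly* before being reported. The LP is solved with HiGHS via
`scipy.optimize.linprog`, which is deterministic under the fixed column
ordering used.

## Compartment-level methods

Transport is operationalised as: the same metabolite id appears in ≥ 2
compartments within one reaction (antiport of two different species with
no shared metabolite is a configurable heuristic, off by default, since no
principled rule exists). Alternative transporters are ≥ 2 reactions moving
one metabolite between the same two compartments. Invalid transporters are
reactions spanning a compartment pair the user has flagged as unconnected
in the compartment graph. Splitting a transporter A→C via B re-points the
A-side species to B in the chemistry leg and adds a plain diffusion leg
A↔B for exactly those species; the legs sum to the original reaction, the
GPR is copied to both, and the chemistry stays on the membrane-proximal
(target-side) leg by default. Removing a compartment RC into TC treats
four reaction categories: RC-only reactions move to TC; pure RC↔TC
transports cancel completely and are removed; RC↔TC reactions with a
chemical conversion, and RC↔other reactions, are kept with RC species
re-pointed (cancellation applied); orphaned metabolites are pruned.
Duplicate reactions created by re-pointing are not auto-merged — they are
picked up by the reaction-level detectors on the next pass. Boundary
reactions on non-extracellular species are listed and repaired by
re-pointing to the extracellular instance plus an added transport
reaction, preserving net exchange capability. Reactions touching the
canonical unknown compartment are matched against reactions agreeing on
all known-compartment metabolites plus the same metabolite in a known
compartment, whose compartment is then proposed; ambiguous or unmatched
cases pend.

## Pipeline, decision log, replay

The BCM is the union of the inputs (metabolites keyed by id+compartment,
reaction-id collisions tag-prefixed) with exactly identical net reactions
merged immediately; the shortest member id survives a merge, so prefixed
duplicates never outlive reconciliation. The four automatic refinement
steps run in the published order (matching → transport splitting →
practically-identical merge → alternative-stoichiometry merge); each step
can uncover work for the next, which is why the order is fixed. Direction
conflicts resolve to the consensus when members agree (member directions
are compared after aligning each member's writing with the kept reaction)
and otherwise fall back to reversible or to a pluggable predictor hook —
the probabilistic direction predictor itself is out of scope, only its
contract (reaction → forward/backward/reversible/unknown) exists. The
`strict` GPR heuristic keeps identical rules, keeps the superset rule
flagged when one gene set contains the other, and otherwise pends; `union`
ORs the rules. `union` is the default for unattended runs because `strict`
deliberately produces pending items.

Every mutation is an *action* — a named operation with JSON-serialisable
arguments — applied through a registry and appended to the decision log
(sequence-numbered, no wall-clock). Replay rebuilds the naive union and
re-applies the entries in order, reproducing the output byte-for-byte; a
digest of the input entity ids guards against replaying a stale log. The
biomass reaction is a user choice among the inputs' biomass reactions; the
others stay in the model with bounds 0.

## Growth-phenotype evaluation

FBA maximises biomass flux subject to S·v = 0 and bounds, with exchange
bounds set from the medium (listed metabolites importable up to their max
uptake, everything else export-only). Knockouts zero the bounds of
reactions whose GPR evaluates false without the deleted genes. Growth
calls: wild type grows iff flux > 1e-6; a mutant grows iff it keeps ≥ 30%
of wild-type flux; a mutant queried against a non-growing wild type is
called no-growth and flagged. Records whose genotype contains no model
gene are skipped and counted. Metrics use growth as the positive class;
MCC is defined 0 when a denominator factor vanishes. Activity of a
reaction is decided by flux variability with the objective left open:
active iff |v| can exceed 1e-9. All LP tolerances are fixed (1e-9) for
reproducibility.

## Synthetic fixtures

The generator builds a three-compartment base model (extracellular →
periplasm → cytosol) with a linear glucose-to-biomass pathway (uptake
bound 10, 1:1 conversions, so wild-type growth is exactly 10), random side
pathways branched off the core, and a currency layer (NAD/NADH with a
balancing proton) on a configurable fraction of unreserved side pathways —
hubs are present, so the matcher's normalisation is actually exercised.
Model B is a retagged copy of A with each requested inconsistency class
planted as an isolated perturbation of its own reserved pathway: renamed
metabolites, reversed duplicates with a spurious water, doubled
coefficients, polymer variants with deliberately unknown polymer formulas
(so they pend, as they should), NADH→NADPH twins, optional-cofactor
outer reactions, two-step chains replaced by their lumped net reaction,
proton-symport alternative transporters, direct-uptake shortcuts (both the
splittable kind, where A routes through the periplasm, and the invalid
kind with no parallel route), boundary reactions on cytosolic species, and
reactions with a species parked in the unknown compartment (with and
without a resolvable twin). Generation is deterministic under the seed —
identical seeds give byte-identical SBML.

What the fixtures do **not** emulate: real organism stoichiometry, mass-
imbalanced legacy reactions, GPRs with hundreds of genes, thermodynamic
infeasibilities, or the sheer scale (thousands of reactions) of genome-
scale models. Passing tests therefore demonstrate algorithmic correctness
on every inconsistency class, not end-to-end curation quality on a real
model pair; the published-model overlap check runs only when those models
are supplied locally.

## Numerical and design choices

- Exact rational stoichiometry everywhere a *decision* depends on
  equality or balance; floats only inside LPs, whose outputs are
  re-verified exactly where exactness is claimed.
- LP flux support cutoff 1e-9; FVA/optimality tolerances 1e-9; matching
  threshold comparison tolerance 1e-12.
- Greedy one-to-one match assignment with lexicographic tie-breaks;
  deterministic iteration (sorted ids) throughout, so identical inputs
  give identical outputs and logs.
- Problem sizes in the shipped acceptance run (≈ 75-reaction inputs,
  20-repeat degradation protocol, 200 random oracle models of ≤ 100
  reactions) were chosen as the smallest networks that exercise every
  class with non-trivial topology; all quantities are recomputed from
  scratch at run time.

## Known limitations

- Biomass reactions are not reconciled (user choice among inputs), as
  their composition is modelled too differently across GSMs for network
  context to match.
- The directionality predictor is a hook, not an implementation; without
  it, direction conflicts become reversible, which can overestimate
  metabolic capability.
- Lumped/non-lumped pairs with *different* net reactions (partially
  overlapping side products) are only caught by the similar-reaction
  detector, with its attendant sensitivity/specificity trade-off.
- Cross-compartment metabolite matching is deferred to the compartment
  methods; the matcher itself is per-compartment.
- Round-trip exactness of coefficients is limited to finite decimal
  expansions (a consequence of SBML's double-typed stoichiometries).
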