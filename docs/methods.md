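# Methods

This note documents the models, procedures, parameters and design choices
behind gsmcompare, in the order the pipeline applies them.

## Networks and pre-processing

A network is a set of genes, compartmented metabolites and stoichiometric
reactions with flux bounds and boolean gene-reaction rules (GPRs). SBML
Level 3 with FBC v2 is the native interchange format; Level 2 files with
`GENE_ASSOCIATION:` notes and kinetic-law bound parameters are read for
compatibility with older exporters. Species flagged `boundaryCondition` or
living in a compartment named `b` are treated as outside the system and
removed from metabolite sets and stoichiometries, matching the exchange-
reaction convention. GPRs are normalised to canonical AND/OR trees
(flattened, deduplicated, operands sorted) so that rules written in
different orders compare equal and OR-merges are order-independent.

Metabolite identifiers carry a compartment suffix: the substring after the
final underscore when it is a known single-letter token, optionally
followed by digits that normalisation strips (`glc__D_c` and `cpd00002_c0`
both yield compartment `c`). This covers both the plain-letter and the
numbered dialects found in practice. Identifiers without a recognisable
suffix keep their full id as core and receive the default compartment
(`c`), logged once per identifier.

Before comparison, networks are pre-processed: reactions with empty
stoichiometry are removed, and duplicate reactions are merged — by
identical equation for equation-level comparison, or by shared mapped
identifier for identifier-level comparison. The surviving reaction is the
one with the lexicographically smallest id (a deterministic choice,
producing reproducible merge logs), and the gene rules of removed
duplicates are OR-merged into it.

Every reaction receives exactly one class with precedence
`exchange > demand > sink > biomass > transport > internal`:
single-metabolite reactions are boundary reactions (exchange when
reversible, demand when irreversibly consuming, sink when irreversibly
producing); a configurable id pattern (default: contains `biomass`,
case-insensitive) marks biomass reactions; reactions moving an identical
core id between compartments with opposite signs are transporters.

## Namespace mapping

Synonym tables are 3-column TSVs (source id, target id, provenance) and
layer cross-reference data with a custom dictionary and discovered
synonyms; lookups are case-sensitive and single-hop (no transitive
chaining through a hub namespace — multi-hop chains multiply mapping
errors and the single-hop table already encodes the useful closure).
Metabolite translation strips the compartment token, looks up synonyms of
the core id, re-appends the original token and accepts the first candidate
present in the reference. Cross-compartment matches are never attempted.
When several synonyms are reference members the lexicographically smallest
is returned and the match is flagged as multiple.

## Set comparison

Gene sets are compared by case-sensitive string equality — gene
identifiers are locus tags shared by all tools, so no mapping is involved.
Metabolite sets are compared on full compartmented identifiers after
translation. For each class the report carries coverage, additional
percentage, Jaccard distance and the coverage/additional ratio; undefined
ratios (empty reference, empty union) are reported as NaN with a warning
rather than raising.

Reaction equations match in one of three categories: `equation_exact`
(identical translated stoichiometries), `reversed` (identical after
negating one side — only the written direction matters, bounds are
ignored), and `proton_partial` (identical, directly or after negation,
once all proton species are deleted from both sides, reflecting
charge-state disagreements between databases). Proton species are
recognised by core id, default `{h, H, cpd00067, PROTON}` in any
compartment, configurable per call. Coefficients are compared at relative
tolerance 1e-6 with no rescaling: two reactions differing by a common
factor are genuinely different reactions. Draft reactions containing any
untranslatable metabolite cannot match. Assignment is greedy one-to-one in
category priority with sorted-id iteration, making results independent of
input order; an indexed implementation (hash of the canonical
stoichiometry key) keeps it linear in practice and is verified against a
brute-force nested-loop oracle in the test suite.

Proton-partial matches are tallied separately and excluded from the
Jaccard/ratio intersection: they indicate recoverable database
disagreement, not identity, and folding them into the intersection would
silently inflate similarity. Reaction coverage and additional percentages
use the corrected reference size — total reference reactions minus
biomass-class reactions, whose presence is a curation artefact rather than
predictable content. Exchange reactions are included by default (some
tools generate them, and excluding them would hide that difference); a
flag removes them for secondary analyses. Metabolite Jaccard distances are
computed on compartmented identifiers, so the same compound in two
compartments counts twice — consistent with how the networks themselves
treat the two species.

## Synonym discovery

Cross-reference tables are incomplete; near-matching equations reveal the
missing entries. For every unmatched draft/reference reaction pair whose
translated, proton-stripped equations agree at every shared position, the
leftover positions are paired one-to-one by equal coefficient and
identical compartment (an ambiguous pairing rejects the pair). Position
pairs collapse to (draft core, reference core) candidates — the same
unknown species seen in two compartments of one transporter is a single
mismatched metabolite — and at most `max_unmatched` (default 1) distinct
core pairs are allowed per reaction pair.

Candidates are aggregated with a support count (number of independent
reaction pairs proposing them). A candidate is auto-accepted when its
support is at least 2, at least one witness is *anchored* (the reaction
pair shares at least one agreeing metabolite position — a bare coefficient
pattern such as a lone exchange `{X_e: −1}` or a generic transporter is
interchangeable between unrelated species and carries no identifying
evidence), and no credible competitor (another candidate with
auto-acceptable support sharing its draft or reference core) exists.
Everything else is emitted to a review TSV for human decision. Accepted
synonyms enter the mapping table with provenance `discovered` and the
propose/accept loop repeats until a round accepts nothing; termination is
guaranteed because each round strictly grows the table or stops. Reaction
synonyms are not discovered directly: they fall out of re-running the
identifier comparison after the metabolite table improves.

## Topology diagnostics

Dead-end metabolites are species only produced or only consumed across all
reactions. A reversible reaction counts as producer and consumer of every
participant; an exchange reaction counts as both for its metabolite
regardless of bounds, because the boundary supplies the missing side — an
extracellular species served only by its exchange is not a dead end.
Demand and sink reactions count per their effective direction. Orphan
reactions are reactions with empty gene rules, excluding
exchange/demand/sink classes, which never carry genes by construction.
Unconnected reactions share no metabolite with any other reaction. All
three are pure structural diagnostics — no LP-based flux-consistency
analysis is attempted.

## Flux balance analysis and omission experiments

FBA maximises the objective flux subject to steady-state mass balance
`S·v = 0` and flux bounds, solved with the HiGHS LP backend. Only the
objective value is contract-bound; flux vectors are reported but LP
degeneracy makes them non-unique. Infeasible problems report growth 0;
unbounded objectives raise, naming the objective.

A medium is a list of (compound, exchange id, maximum uptake) rows;
applying it opens the uptake side of listed exchanges to the stated rate
(default 10 flux units when a file omits one — media tables specify
compositions, not rates) and closes the uptake side of every other
exchange, leaving secretion untouched. Single-omission evaluation drops
one component at a time, re-runs FBA, and calls no growth below 10% of the
basal rate (growth below 1e-9 is treated as exactly zero first). Crossing
the in-silico call with the in-vivo phenotype labels each experiment
TP/TN/FP/FN, from which sensitivity `TP/(TP+FN)`, specificity
`TN/(TN+FP)`, precision `TP/(TP+FP)`, NPV `TN/(TN+FN)`, accuracy and the F
score (harmonic mean of precision and sensitivity) follow; zero
denominators give NaN. Evaluation aborts when the basal medium itself
supports no growth, since the threshold is then undefined.

## Synthetic scenarios

The generator emulates the statistical structure of draft-versus-curated
comparisons with fully known ground truth. The reference is built around a
deterministic growth core: four essential nutrients and one redundant
nutrient pair, each with an exchange, a transporter and a conversion step
to a biomass precursor; a mass-balanced biomass assembly producing an
explicit biomass species; a demand drain for it; and a proton exchange and
transporter. The core guarantees FBA growth on the bundled medium (rate 10
— the uptake cap of each limiting nutrient at 1:1 yield) and gives the
omission panel known answers: essential nutrients abolish growth when
omitted, either redundant nutrient does not.

Padding reactions are mass-balanced by integer pseudo-formula bookkeeping:
every species carries an integer mass, reactions conserve total mass
exactly, and a dedicated proton species of mass 1 absorbs decomposition
remainders — which also gives proton perturbations realistic targets.
Padding never produces nutrients, precursors or biomass (that would break
planted essentiality), and reference equations are kept unique even modulo
direction and proton stripping, so every planted perturbation has exactly
one possible partner and greedy matching cannot be ambiguous. GPRs are
drawn over the configured gene pool with mixed single/OR/AND/nested
patterns, dealing genes out so every gene is used; a configured fraction
of non-boundary reactions is left ruleless (planted orphans). The biomass
assembly reaction carries a rule so that an orphan fraction of zero plants
zero orphans.

The draft derives from the reference by: gene subsampling at
`gene_recall` plus novel extra genes; reaction dropout; proton-coefficient
perturbation (±1 on a proton-containing kept reaction — all-proton
reactions are ineligible, stripping them leaves nothing to match);
direction reversal (stoichiometry negated, bounds mirrored); duplicate
injection (same equation, different id and rule, exercising the merge
logic); and renaming of metabolite cores and reaction ids into a synthetic
`synX_`/`synr_` namespace. The truth object records every decision:
shared/extra/missed genes, a fate per reference reaction
(kept_exact / kept_proton_perturbed / kept_reversed / dropped /
duplicated), and the rename bijections. The mapping generator emits the
rename tables at a chosen completeness, recording withheld entries so
synonym-discovery recovery can be scored.

Defaults (200 reactions, 150 metabolites, 120 genes, 8% exchanges, 10%
orphans, gene recall 0.8, 10% extra genes, 20% dropout, 5% proton
perturbation, 3% reversal, 5% duplicates, 30% renaming) sit in the middle
of the ranges observed across reconstruction tools: gene coverages of
roughly 50–88%, additional-gene fractions from a few percent to
two-thirds, and visible proton-mismatch bars for database-backed tools.
What the generator does **not** emulate: biologically meaningful pathway
content, database-specific error profiles, unbalanced or lumped curated
reactions, and subsystem annotations — so passing tests demonstrate
correctness of the comparison machinery under controlled divergence, not
performance claims about any particular reconstruction tool on real
genomes.

## Numerical and procedural choices

- Stoichiometric equality: relative tolerance 1e-6, no rescaling.
- Growth epsilon 1e-9 before the 10% no-growth rule.
- All iteration orders are sorted; all randomness flows from a single
  integer seed per scenario, and the same configuration reproduces
  byte-identical SBML.
- Ties in synonym lookup resolve to the lexicographically smallest member
  with a multiplicity flag.
- Degenerate inputs (empty reference sets, both-empty Jaccard, zero
  confusion-matrix denominators) produce NaN plus a warning, never an
  exception, so batch comparisons keep running.

## Problem sizes

The test battery uses 200-reaction scenarios for ground-truth recovery
(20 configurations spanning gene recall 0.6–0.95 and dropout 0.1–0.4),
networks of 60–100 reactions for the matcher-versus-oracle equivalence
check (100 random pairs), and 20 seeds for synonym-recovery measurement.
These sizes give exact, fully enumerable ground truth while keeping the
whole suite and the acceptance script in the seconds range.

## Known limitations

- Identifier mapping is single-hop; genuinely transitive synonym chains
  are only found if the equation-based discovery proposes them.
- Equation matching requires exact coefficient agreement (modulo protons);
  lumped or rescaled reactions in real curated models will not match.
- The dead-end and unconnected-reaction definitions are the declared ones
  above; other toolchains draw slightly different boundaries (e.g. around
  irreversible exchanges), so absolute counts are comparable only within
  one convention.
- GPR-aware reaction matching, EC-number matching and pathway-level
  attribution are out of scope.
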