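# Methods

## The problem

Genome-scale metabolic models (GSMs) for non-model organisms are rarely
produced by a single platform. A typical reconstruction merges an
annotation-derived draft with one or more orthology-transferred networks,
patches the holes with gap-filling against a reference reaction database,
and finishes with expert curation. Each of those steps is run by a
different tool, and once the result is flattened to SBML the *process*
metadata — which step, which tool, which source introduced each reaction,
and why — is gone. `gsmtrace` is a workspace that keeps that metadata
first-class: every model element carries source tags, every pipeline run
leaves a replayable log, and every manual edit is a stored, re-applicable
form.

## Data model

A model is a typed entity store (reactions, compounds, genes, pathways,
proteins, ontology classes) with typed relations (`consumes`/`produces`
with positive stoichiometric coefficients, `is_linked_to` for
gene–reaction links, `is_in_pathway`, `catalyzes`, `is_a` for
instance→class edges, `has_xref`) and a set of *source tags*
`(entity, category, tool, source, comment, step)`, where category is one of
`annotation`, `orthology`, `gap-filling`, `manual`. Tag identity excludes
the comment, so re-recording the same evidence never duplicates it, and no
core operation ever deletes a tag.

Merging is union by id. Attribute conflicts are resolved by *union of
value lists, never overwrite*: if two sources disagree about a reaction's
direction, both values coexist and the disagreement is visible in diffs
and reports. This is a deliberate design choice — the store is a record of
evidence, not an arbiter — and it makes merge idempotent and
inclusion–exclusion exact on entity counts.

Identifiers are stored verbatim (MetaCyc ids legitimately contain dots and
slashes, e.g. instantiated reaction ids like
`...-RXN-THF/NADP//DIHYDROFOLATE/NADPH/PROTON.37.`). Escaping to SBML SIds
(`__<ord>__` per forbidden character, with `M_`/`R_`/`G_` type prefixes)
happens only at the SBML boundary and is exactly inverted on import.

## Topological producibility (network expansion)

The analysis layer treats the model as a bipartite reaction/compound graph
and ignores stoichiometric coefficients. Given a seed set S (the growth
medium), producibility is the least fixpoint of

    a reaction fires iff all of its reactants are already producible;
    its products then become producible,

iterated from S. Reversible reactions contribute two directed copies;
firing one direction never grants the other, and a compound appearing on
both sides of one reaction cannot bootstrap itself (least-fixpoint
semantics). The scope computation records, per compound, the first
expansion layer that produced it; it terminates in at most one iteration
per compound and is independent of iteration order (verified against a
naive iterate-until-stable oracle on hundreds of random networks).

On top of the scope primitive:

- **Unproducible targets** — targets outside the scope of the seeds.
- **Unblocking compounds** — all subset-minimal sets of non-seed compounds
  (size ≤ a bound, default 3) whose addition to the medium restores every
  target, enumerated by increasing cardinality with superset pruning.
- **Production paths** — one witness reaction sequence per target, ordered
  by the expansion layer of the compound each reaction provides
  (lexicographic tie-break), so that sequential replay never lacks a
  reactant.
- **Gap-filling** — cardinality-minimal subsets of database reactions
  whose addition to the draft restores all targets. Candidates are pruned
  to reactions on some backward path from a target; search is iterative
  deepening over cardinality and exhaustive while the pruned pool holds at
  most 20 candidates (configurable). Larger pools fall back to a greedy
  set cover trimmed to single-removal minimality and explicitly flagged
  `heuristic`. With enumeration on, all minimal-cardinality solutions plus
  their union and intersection are returned — which of the three a user
  should trust is genuinely situational, so all are exposed. Every
  returned completion can be re-verified post hoc (`verify_completion`):
  targets restored, and no single removal preserves that.

This deliberately diverges from flux-based validation: a topologically
producible target can still be stoichiometrically infeasible. The
topological criteria are cheap enough to drive combinatorial searches and
are the intended first-pass curation instrument; flux analysis is out of
scope here and delegated to constraint-based tools via the SBML export.

Ignoring compartments is likewise deliberate: the operators treat
identically-named compounds as one node unless ids already encode the
compartment.

An Answer Set Programming backend would be a drop-in alternative for the
combinatorial searches; the native iterative-deepening search is the only
backend provided, and its results are checked against exhaustive
enumeration in the test suite.

## Class/instance instantiation

Reference databases write some reactions against compound *classes* of an
ontology (a generic polyglutamylated folate) while pathway neighbours
produce concrete *instances* — topologically this disconnects the pathway
even though the chemistry is fine. `instantiate_class_reactions` expands
every reaction with class-typed participants into variants over the
cartesian product of direct instances (capped at 64 variants per reaction
by default; capped reactions are skipped and reported). Variants record
their parent in an `instance-of` attribute, are tagged
`gap-filling`/`class-instantiation`, and count toward their parent in
pathway-completeness scoring.

## The packaged folate scenario

The fixture encodes tetrahydrofolate biosynthesis: pathways PWY-6147
(five reactions, GTP → 6-hydroxymethyl-dihydropterin diphosphate) and
PWY-6614 (three reactions, → dihydrofolate → tetrahydrofolate), eight
reactions in total. The draft holds seven of them — three tagged
annotation, five orthology, one by both — and stops at DIHYDROFOLATE: the
reductase step exists in the database only in its class-written form,
consuming the DIHYDROFOLATE-GLU-N class that nothing produces. The
instantiated variant
`DIHYDROFOLATEREDUCT-RXN-THF/NADP//DIHYDROFOLATE/NADPH/PROTON.37.`
consumes the concrete DIHYDROFOLATE and is the unique size-1 completion;
adding it brings both pathways to completeness 1.0. The five cofactor
compounds (water, ATP, p-aminobenzoate, glutamate, NADPH) are given
neutral ids and included as seeds alongside GTP, so producibility hinges
exactly on the class/instance mismatch; the fixture makes no attempt to
reproduce the true MetaCyc stoichiometry of the two pathways.

## Synthetic network generator

`random_network` draws connected-by-construction networks: each
reaction's reactants come from the seeds or earlier products, except that
with a configurable *leak probability* a reactant is drawn from orphan
(never-produced) compounds. Leak 0 therefore guarantees every target
producible; positive leaks create genuinely blocked targets for the
gap-filling and unblocking oracles. Defaults: 20 compounds, 15 reactions,
≤2 reactants/products per reaction, 20 % reversible, 3 seeds, 2 targets,
annotation/orthology tags at 60/40. The generator emulates the
*topological* shape of draft networks only — it has no meaningful
stoichiometry, formulas, compartments or gene rules — so passing oracle
suites demonstrates algorithmic correctness, not biological realism.

## Reports

- **Pathway completeness** — fraction of a reference pathway's member
  reactions present in the model (variants count for their parent),
  sorted descending; zero-member pathways are excluded and reported.
- **Provenance breakdown** — exact set algebra over tag groups by
  category/tool/source: marginal counts, pairwise overlaps, exclusive
  counts. Overlaps are always published explicitly because reconstruction
  categories are not disjoint; marginal counts do not sum to the union.
- **Quality** — percentage of non-exchange reactions with ≥1 gene link
  (exchange reactions have no enzyme; the exclusion is configurable);
  mass balance as the per-element signed sum of coefficient×formula
  counts (Hill-notation parser; polymer/R-group formulas make a reaction
  *undetermined*, never balanced); charge balance analogously.

## Interchange conventions

SBML (L3+fbc by default, L2 on request) carries provenance as note lines
(`CATEGORY:`/`TOOL:`/`SOURCE:`/`STEP:`/`COMMENT:`, one group per tag),
pathway membership as BiGG-style `SUBSYSTEM:` notes, class membership as
`IS_A:` notes and class-typed species as `OBJECT_TYPE: class`; gene
associations use fbc gene products (L3) or `GENE_ASSOCIATION` notes (L2),
both accepted on import. These keys are this package's documented
convention. The flat tab-separated dialect
(`[entities]`/`[relations]`/`[tags]` sections) is the full-fidelity
format: write∘read is the identity and a second write is byte-stable.
RDF export (Turtle) emits one triple per relation, one per attribute
value and exactly five predicates per tag, so the graph size is the
closed form `|relations| + Σ attribute values + 5·|tags|`.

Identifier mapping against a MetaNetX-style two-column dictionary is
single-pass and scope-separated; transitive chains in the dictionary are
rejected as input errors, which makes mapping idempotent. Compatible
collisions (two foreign reactions onto one reference id) merge with both
tag sets; incompatible ones (type clash) are errors.

## Pipeline and curation

A pipeline is a YAML list of steps over registered operations (read,
merge, map, instantiate, gap-fill, curate, exports, reports, wiki). The
runner stamps every model-mutating step's tags with the step index and
logs per-step parameter sets, input digests (SHA-256) and entity-count
deltas; deltas telescope to the final counts, and identical configs on
identical inputs reproduce identical models (timestamps aside). External
reconstruction tools are never invoked — their outputs are consumed as
declared inputs, which is what keeps a run reproducible from its inputs.

Curation forms (add/modify/delete with mandatory justification and
source) are flat text blocks, applied in order and appended to a log.
Replaying the log on the original base reproduces the curated model
exactly; on a regenerated base, forms whose target vanished are skipped
and reported rather than failing. Deleted entities leave no tombstone in
the model — their history lives in the log.

## Problem sizes and determinism

The oracle suites run on 200 random networks of up to 50 compounds for
scope and 12 instances with ≤12 candidate reactions for gap-filling —
small enough for the exhaustive oracles to stay exact, large and varied
enough to exercise reversibility, leaks and dead ends; the whole suite
runs in a few seconds. All enumeration orders and tie-breaks are
lexicographic by id, and every randomized component takes an explicit
seed, so all outputs (including the generated wiki) are byte-reproducible.

## Known limitations

- Topological producibility ignores stoichiometry, compartments and
  thermodynamics; it bounds, but does not establish, flux feasibility.
- Cardinality-minimal completions above the exhaustive threshold come
  from a greedy cover and may be non-minimal (flagged).
- SBML round-trips preserve the reaction/compound/gene graph, pathway
  membership, attributes and tags; protein entities and `catalyzes`/
  `has_xref` relations travel only through the flat format.
- A stoichiometric coefficient of exactly 1 is not re-emitted as an
  explicit attribute on SBML import.
- The wiki is static hypertext with no search; semantic queries are the
  RDF export's job.
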