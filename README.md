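# gsmtrace

Traceable, reproducible "à-la-carte" reconstruction of genome-scale
metabolic models (GSMs).

Modern GSMs for non-model organisms are assembled by personalized
pipelines: an annotation-derived draft is merged with orthology-transferred
networks, gap-filled against a reference database (MetaCyc-, BiGG- or
SEED-style), and hand-curated. Once exported to SBML, the *process*
metadata — which step, tool and source introduced each reaction, and why —
is usually lost. `gsmtrace` is a library + CLI that keeps that metadata
first-class throughout:

- a **provenance-tracked model store** (entities, relations, source tags)
  with a byte-stable flat format and SBML L2/L3(+fbc) interop;
- **topological producibility analysis** over the bipartite
  reaction/compound graph: scope (network expansion from a seed set /
  growth medium), unproducible-target detection, minimal unblocking
  compound sets, production paths, and cardinality-minimal **gap-filling**
  with class/instance reaction instantiation;
- **merging and identifier mapping** (MetaNetX-style dictionary) across
  reference namespaces;
- **replayable manual curation** via justification-bearing forms, and
  model **diffing** across versions;
- **reports** (pathway completeness rates, provenance breakdowns with
  explicit overlaps, gene-association ratio, mass/charge balance) plus a
  deterministic **static wiki** and **RDF/Turtle** export;
- a **config-driven pipeline runner** with a replayable log of parameters,
  input digests and entity-count deltas.

The producibility semantics is network expansion: starting from seeds S,
a reaction fires iff all its reactants are producible and its products
become producible; the scope Σ(S) is the least fixpoint. Stoichiometry is
deliberately ignored (graph-based, not flux-based, analysis); reversible
reactions act as two directed reactions. Gap-filling returns minimal
X ⊆ database∖draft with targets ⊆ Σ_draft∪X(S). See `docs/methods.md`.

## Worked example: completing tetrahydrofolate biosynthesis

The packaged fixture encodes a draft network holding 7 of the 8 reactions
of the pathways PWY-6147 + PWY-6614 (GTP → tetrahydrofolate). The draft is
blocked by a class/instance mismatch: the reductase step in the database
consumes the compound *class* DIHYDROFOLATE-GLU-N, while the upstream
synthase produces the concrete *instance* DIHYDROFOLATE.

```python
from gsmtrace import (make_folate_fixture, unproducible_targets,
                      gapfill, pathway_completeness)

fx = make_folate_fixture()
print(unproducible_targets(fx.draft, fx.seeds, fx.targets))
# {'THF-GLU-N'}

sols = gapfill(fx.draft, fx.database, fx.seeds, fx.targets,
               max_size=3, enumerate_all=True)
print([(s.flag, sorted(s.reactions)) for s in sols][0])
# ('one-minimal-solution',
#  ['DIHYDROFOLATEREDUCT-RXN-THF/NADP//DIHYDROFOLATE/NADPH/PROTON.37.'])
```

The unique size-1 completion is the instantiated reductase variant that
consumes the instance; adding it restores target producibility and brings
both pathways to completion rate 1.0:

```python
filled = fx.draft.copy()
rid = next(iter(sols[0].reactions))
filled.add_entity(fx.database.entities[rid])
for rel in fx.database.relations_from(rid):
    if rel.object not in filled.entities:
        filled.add_entity(fx.database.entities[rel.object])
    filled.add_relation(rel)
print([(r.pathway, r.ratio) for r in
       pathway_completeness(filled, fx.pathway_defs).rows])
# [('PWY-6147', 1.0), ('PWY-6614', 1.0)]
```

The same run from the shell:

```
gsmtrace fixtures folate --out fx/
gsmtrace check   --model fx/draft.sbml --seeds fx/seeds.tsv --targets fx/targets.tsv
gsmtrace gapfill --model fx/draft.sbml --db fx/database.sbml \
                 --seeds fx/seeds.tsv --targets fx/targets.tsv --max-size 2
gsmtrace wiki    --model fx/draft.sbml --out site/
```

Pipelines are YAML files (`gsmtrace run --config wf.yaml`); each step
stamps the provenance tags it creates with its step index and appends a
log record, so re-running a config on the same inputs reproduces the same
model byte-for-byte.

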