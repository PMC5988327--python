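"""Deterministic synthetic networks for testing and demonstration.

Two generators:

- :func:`make_folate_fixture` encodes the tetrahydrofolate biosynthesis
  scenario — two MetaCyc pathways (6-hydroxymethyl-dihydropterin diphosphate
  biosynthesis I, PWY-6147, and tetrahydrofolate biosynthesis, PWY-6614)
  jointly spanning eight reactions from GTP to tetrahydrofolate, where the
  draft model is blocked by a class/instance mismatch that only an
  instantiated database variant of the dihydrofolate reductase step can
  resolve. The pathway connectivity and the key identifiers are real
  MetaCyc ids; the cofactor stoichiometry is simplified (five cofactor
  compounds, all seeds) so that producibility hinges exactly on the
  class/instance mismatch — this fixture makes no attempt to reproduce the
  true stoichiometry of the two pathways.

- :func:`random_network` draws connected-by-construction reaction networks
  of configurable size: each reaction's reactants come from the seeds or
  from earlier products, except that with a configurable *leak* probability
  a reactant is drawn from never-produced orphan compounds, creating
  genuinely blocked targets for the gap-filling and unblocking oracles.
  Identical seeds give identical networks.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import NamedTuple

from .model import Entity, GsmtraceError, Model, Relation, SourceTag, LEFT_TO_RIGHT

# -------------------------------------------------------------- folate

#: the instantiated reductase variant retrieved by gap-filling
REDUCTASE_VARIANT = (
    "DIHYDROFOLATEREDUCT-RXN-THF/NADP//DIHYDROFOLATE/NADPH/PROTON.37."
)
REDUCTASE_CLASS_RXN = "DIHYDROFOLATEREDUCT-RXN"

#: (reaction id, pathway, reactants, products); cofactors are seeds
_FOLATE_STEPS = [
    ("GTP-CYCLOHYDRO-I-RXN", "PWY-6147",
     ["GTP", "WATER"], ["DIHYDRONEOPTERIN-P3"]),
    ("H2NEOPTERINP3PYROPHOSPHOHYDRO-RXN", "PWY-6147",
     ["DIHYDRONEOPTERIN-P3", "WATER"], ["DIHYDRONEOPTERIN-P"]),
    ("DIHYDRONEOPTERIN-MONO-P-DEPHOS-RXN", "PWY-6147",
     ["DIHYDRONEOPTERIN-P", "WATER"], ["DIHYDRONEOPTERIN"]),
    ("H2NEOPTERINALDOL-RXN", "PWY-6147",
     ["DIHYDRONEOPTERIN"], ["AMINO-OH-HYDROXYMETHYL-DIHYDROPTERIDINE"]),
    ("H2PTERIDINEPYROPHOSPHOKIN-RXN", "PWY-6147",
     ["AMINO-OH-HYDROXYMETHYL-DIHYDROPTERIDINE", "ATP"],
     ["DIHYDROPTERIN-CH2OH-PP"]),
    ("H2PTEROATESYNTH-RXN", "PWY-6614",
     ["DIHYDROPTERIN-CH2OH-PP", "P-AMINO-BENZOATE"], ["7-8-DIHYDROPTEROATE"]),
    ("DIHYDROFOLATESYNTH-RXN", "PWY-6614",
     ["7-8-DIHYDROPTEROATE", "GLT", "ATP"], ["DIHYDROFOLATE"]),
    # the class-written reductase: consumes the ontology class, which no
    # upstream reaction produces -- the topological block of the scenario
    (REDUCTASE_CLASS_RXN, "PWY-6614",
     ["DIHYDROFOLATE-GLU-N", "NADPH"], ["THF-GLU-N"]),
]

FOLATE_SEEDS = ["GTP", "WATER", "ATP", "P-AMINO-BENZOATE", "GLT", "NADPH"]
FOLATE_TARGETS = ["THF-GLU-N"]

#: draft membership with the reconstruction-category evidence per reaction
_DRAFT_ANNOTATION = {
    "GTP-CYCLOHYDRO-I-RXN",
    "H2NEOPTERINP3PYROPHOSPHOHYDRO-RXN",
    "DIHYDRONEOPTERIN-MONO-P-DEPHOS-RXN",
}
_DRAFT_ORTHOLOGY = {
    "DIHYDRONEOPTERIN-MONO-P-DEPHOS-RXN",  # also found by annotation
    "H2NEOPTERINALDOL-RXN",
    "H2PTERIDINEPYROPHOSPHOKIN-RXN",
    "H2PTEROATESYNTH-RXN",
    "DIHYDROFOLATESYNTH-RXN",
}

#: decoy database reactions that never help produce the target
_DECOYS = [
    ("RXN-DECOY-1", ["THF-GLU-N"], ["FORMYL-THF"]),
    ("RXN-DECOY-2", ["GTP"], ["GDP"]),
]


class FolateFixture(NamedTuple):
    draft: Model
    database: Model
    seeds: list[str]
    targets: list[str]
    pathway_defs: Model


def _add_reaction(model: Model, rid: str, reactants: list[str],
                  products: list[str], pathway: str = "") -> None:
    model.add_entity(Entity(rid, "reaction", {"direction": [LEFT_TO_RIGHT]}))
    for cid in reactants + products:
        if cid not in model.entities:
            etype = "class" if cid.endswith("-GLU-N") else "compound"
            model.add_entity(Entity(cid, etype))
    for cid in reactants:
        model.add_relation(Relation(rid, "consumes", cid))
    for cid in products:
        model.add_relation(Relation(rid, "produces", cid))
    if pathway:
        if pathway not in model.entities:
            model.add_entity(Entity(pathway, "pathway"))
        model.add_relation(Relation(rid, "is_in_pathway", pathway))


def make_folate_fixture() -> FolateFixture:
    """Build the tetrahydrofolate gap-filling scenario.

    The draft holds seven of the eight pathway reactions (three tagged
    annotation, five orthology, one reaction carrying both tags) and stops
    at dihydrofolate: the missing reductase step exists in the database only
    in its class-written form, which consumes the DIHYDROFOLATE-GLU-N
    ontology class rather than the DIHYDROFOLATE instance the pathway
    produces. The database also holds the instantiated variant (the unique
    useful completion) and decoys. The target THF-GLU-N is therefore
    unproducible from the draft and producible after adding exactly the
    variant, which also completes both pathways.
    """
    target_class = "THF-GLU-N"

    database = Model(model_id="folate-database", ref_db="metacyc",
                     ref_db_version="20.0")
    for rid, pathway, reactants, products in _FOLATE_STEPS:
        _add_reaction(database, rid, reactants, products, pathway)
    database.entities["PWY-6147"].add_attribute(
        "common-name", "6-hydroxymethyl-dihydropterin diphosphate biosynthesis I")
    database.entities["PWY-6614"].add_attribute(
        "common-name", "tetrahydrofolate biosynthesis")
    # ontology: the concrete monoglutamate is an instance of the class
    database.add_relation(Relation("DIHYDROFOLATE", "is_a", "DIHYDROFOLATE-GLU-N"))
    # the instantiated variant consumes the instance; unique useful completion
    _add_reaction(database, REDUCTASE_VARIANT,
                  ["DIHYDROFOLATE", "NADPH"], [target_class])
    database.entities[REDUCTASE_VARIANT].add_attribute(
        "instance-of", REDUCTASE_CLASS_RXN)
    for rid, reactants, products in _DECOYS:
        _add_reaction(database, rid, reactants, products)

    draft = Model(model_id="esiliculosus-folate-draft", ref_db="metacyc",
                  ref_db_version="20.0")
    for rid, pathway, reactants, products in _FOLATE_STEPS:
        if rid == REDUCTASE_CLASS_RXN:
            continue
        _add_reaction(draft, rid, reactants, products, pathway)
        if rid in _DRAFT_ANNOTATION:
            draft.add_tag(SourceTag(rid, "annotation", "pathway-tools",
                                    "genome-annotation", "", 0))
        if rid in _DRAFT_ORTHOLOGY:
            draft.add_tag(SourceTag(rid, "orthology", "pantograph",
                                    "a-thaliana", "", 1))

    pathway_defs = Model(model_id="folate-pathway-defs", ref_db="metacyc")
    for rid, pathway, reactants, products in _FOLATE_STEPS:
        _add_reaction(pathway_defs, rid, reactants, products, pathway)

    return FolateFixture(draft, database, list(FOLATE_SEEDS),
                         list(FOLATE_TARGETS), pathway_defs)


# ------------------------------------------------------------- random


@dataclass
class GeneratorSpec:
    """Knobs of the random network generator; same seed, same output."""

    n_compounds: int = 20
    n_reactions: int = 15
    max_reactants: int = 2
    max_products: int = 2
    reversible_fraction: float = 0.2
    leak_probability: float = 0.0
    n_seeds: int = 3
    n_targets: int = 2
    tag_categories: dict[str, float] = field(
        default_factory=lambda: {"annotation": 0.6, "orthology": 0.4}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_compounds <= 0 or self.n_reactions <= 0:
            raise GsmtraceError("compound and reaction counts must be positive")
        for name, value in (
            ("reversible_fraction", self.reversible_fraction),
            ("leak_probability", self.leak_probability),
        ):
            if not 0.0 <= value <= 1.0:
                raise GsmtraceError(f"{name} must be in [0, 1]")
        if self.n_seeds + self.max_reactants > self.n_compounds:
            raise GsmtraceError(
                "infeasible spec: reactions need more compounds than exist"
            )


class RandomNetwork(NamedTuple):
    model: Model
    seeds: list[str]
    targets: list[str]


def random_network(spec: GeneratorSpec) -> RandomNetwork:
    """Draw a random reaction network following the generator settings.

    With ``leak_probability`` 0 every generated compound is producible from
    the seeds; leaks introduce orphan reactants, hence blocked reactions and
    possibly unproducible targets.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    width = len(str(spec.n_compounds - 1))
    compounds = [f"C{str(i).zfill(width)}" for i in range(spec.n_compounds)]
    model = Model(model_id=f"random-{spec.seed}")
    for cid in compounds:
        model.add_entity(Entity(cid, "compound"))
    seeds = compounds[: spec.n_seeds]
    available = list(seeds)
    produced: list[str] = []
    categories = sorted(spec.tag_categories)
    weights = [spec.tag_categories[c] for c in categories]

    for i in range(spec.n_reactions):
        rid = f"R{str(i).zfill(len(str(spec.n_reactions - 1)))}"
        n_reactants = rng.randint(1, spec.max_reactants)
        n_products = rng.randint(1, spec.max_products)
        reactants = set()
        for _ in range(n_reactants):
            orphans = [c for c in compounds if c not in available]
            if orphans and rng.random() < spec.leak_probability:
                reactants.add(rng.choice(orphans))
            else:
                reactants.add(rng.choice(available))
        candidates = [c for c in compounds if c not in reactants]
        products = set(rng.sample(candidates, min(n_products, len(candidates))))
        reversible = rng.random() < spec.reversible_fraction
        attributes = {} if reversible else {"direction": [LEFT_TO_RIGHT]}
        model.add_entity(Entity(rid, "reaction", attributes))
        for cid in sorted(reactants):
            model.add_relation(Relation(rid, "consumes", cid))
        for cid in sorted(products):
            model.add_relation(Relation(rid, "produces", cid))
        if categories:
            category = rng.choices(categories, weights=weights)[0]
            model.add_tag(SourceTag(rid, category, "generator", "synthetic", "", 0))
        for cid in sorted(products):
            if cid not in available:
                available.append(cid)
                produced.append(cid)

    pool = produced or seeds
    targets = sorted(rng.sample(pool, min(spec.n_targets, len(pool))))
    return RandomNetwork(model, list(seeds), targets)
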