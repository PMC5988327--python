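"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import random

import pytest

from gsmtrace import (
    Entity,
    GeneratorSpec,
    Model,
    Relation,
    SourceTag,
    make_folate_fixture,
    random_network,
    REVERSIBLE,
)


@pytest.fixture()
def folate():
    return make_folate_fixture()


@pytest.fixture()
def chain_model():
    """Linear chain A -> B -> C (irreversible)."""
    model = Model(model_id="chain")
    for cid in "ABC":
        model.add_entity(Entity(cid, "compound"))
    for rid, (src, dst) in (("r1", "AB"), ("r2", "BC")):
        model.add_entity(Entity(rid, "reaction", {"direction": ["LEFT-TO-RIGHT"]}))
        model.add_relation(Relation(rid, "consumes", src))
        model.add_relation(Relation(rid, "produces", dst))
    return model


def naive_scope(model: Model, seeds) -> set:
    """Independent fixpoint oracle: iterate over directed reactions until
    no new compound appears, with no layer/firing bookkeeping."""
    directed = []
    for reaction in model.reactions():
        reactants = frozenset(model.reactants_of(reaction.id))
        products = frozenset(model.products_of(reaction.id))
        directed.append((reactants, products))
        if model.direction(reaction.id) == REVERSIBLE:
            directed.append((products, reactants))
    producible = {s for s in seeds if s in model.entities}
    changed = True
    while changed:
        changed = False
        for reactants, products in directed:
            if reactants <= producible and not products <= producible:
                producible |= products
                changed = True
    return producible


def brute_force_completions(draft, database, seeds, targets, max_size):
    """Exhaustive oracle: all cardinality-minimal candidate subsets whose
    addition makes every target producible."""
    from gsmtrace.topology import _add_reactions

    candidates = sorted(
        rid for rid in (e.id for e in database.reactions())
        if rid not in draft.entities
    )
    targets = set(targets)
    for size in range(0, max_size + 1):
        hits = []
        for combo in itertools.combinations(candidates, size):
            extended = _add_reactions(draft, database, combo)
            if targets <= naive_scope(extended, seeds):
                hits.append(frozenset(combo))
        if hits:
            return hits
    return []


def brute_force_unblocking(model, seeds, targets, max_size):
    """Exhaustive oracle over non-seed compound subsets (subset-minimal)."""
    seeds, targets = set(seeds), set(targets)
    candidates = sorted(
        eid for eid, e in model.entities.items()
        if e.etype in ("compound", "class") and eid not in seeds
    )
    solutions = []
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(candidates, size):
            subset = frozenset(combo)
            if any(sol <= subset for sol in solutions):
                continue
            if targets <= naive_scope(model, seeds | subset):
                solutions.append(subset)
    return sorted(solutions, key=lambda s: (len(s), sorted(s)))


def replay_path(model: Model, seeds, path) -> set:
    """Replay simulator: fire the path's reactions in order, failing if any
    reaction's reactants (in either legal direction) are unavailable."""
    available = {s for s in seeds if s in model.entities}
    for rid in path:
        reactants = set(model.reactants_of(rid))
        products = set(model.products_of(rid))
        if reactants <= available:
            available |= products
        elif model.direction(rid) == REVERSIBLE and products <= available:
            available |= reactants
        else:
            raise AssertionError(
                f"replay of {rid} requires unavailable reactants "
                f"{sorted((reactants - available))}"
            )
    return available


def random_models_pair(seed: int):
    """Two small random models with overlapping reaction ids, for merge laws."""
    rng = random.Random(seed)
    a = random_network(GeneratorSpec(
        n_compounds=rng.randint(6, 12), n_reactions=rng.randint(3, 8),
        seed=rng.randint(0, 10_000),
    )).model
    b = random_network(GeneratorSpec(
        n_compounds=rng.randint(6, 12), n_reactions=rng.randint(3, 8),
        seed=rng.randint(0, 10_000),
    )).model
    return a, b
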