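"""Topological producibility analysis and gap-filling.

The model is viewed as a bipartite reaction/compound graph and analysed with
network-expansion semantics: starting from a set of *seed* compounds (the
growth medium), a reaction fires as soon as **all** of its reactants are
producible, and its products become producible in turn; iterating to the
least fixpoint yields the *scope* of the seeds. Stoichiometric coefficients
are deliberately ignored (presence/absence semantics) — this is the
graph-based counterpart to flux-based analysis, cheap enough to drive
combinatorial searches.

On top of the scope primitive the module provides:

- :func:`unproducible_targets` — which asserted targets the network cannot
  reach from the medium;
- :func:`unblocking_compounds` — minimal sets of compounds whose addition to
  the medium would restore all targets;
- :func:`production_path` — an ordered witness sequence of reactions
  producing a target;
- :func:`gapfill` — cardinality-minimal sets of database reactions whose
  addition to a draft restores target producibility;
- :func:`instantiate_class_reactions` — expansion of class-written database
  reactions into concrete variants over an instance ontology, the step that
  resolves class/instance mismatches between annotation-derived reactions
  and pathway neighbours.

Reversible reactions are treated as two directed reactions; firing one
direction never grants the other, and a compound appearing on both sides of
one reaction does not bootstrap itself (least-fixpoint semantics). All
enumeration and tie-breaking is lexicographic by id for reproducibility.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .model import (
    Entity,
    GsmtraceError,
    Model,
    Relation,
    SourceTag,
    REVERSIBLE,
)


class NotProducibleError(GsmtraceError):
    """A production path was requested for a target outside the scope."""


class InfeasibleCompletionError(GsmtraceError):
    """Targets stay unproducible even with the full database added."""

    def __init__(self, unproducible: Iterable[str]):
        self.unproducible = sorted(unproducible)
        super().__init__(
            "targets unproducible even with the full database: "
            + ", ".join(self.unproducible)
        )


class OntologyCycleError(GsmtraceError):
    """The is_a ontology contains a cycle."""


@dataclass
class ScopeResult:
    """Least fixpoint of network expansion from a seed set.

    ``layer`` maps each producible compound to the first expansion iteration
    that produced it (seeds are layer 0); ``fired`` holds every reaction that
    activated in at least one direction, ``reaction_layer`` the iteration at
    which it first did. ``unknown_seeds`` lists seed ids absent from the
    network — they are excluded with a warning rather than failing the run.
    """

    producible: frozenset[str]
    layer: dict[str, int]
    fired: frozenset[str]
    reaction_layer: dict[str, int]
    unknown_seeds: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class CompletionSet:
    """A set of database reactions restoring target producibility.

    ``flag`` qualifies the set: ``one-minimal-solution`` for a single
    cardinality-minimal completion, ``union-of-minimal`` /
    ``intersection-of-minimal`` for the aggregates over all minimal
    solutions, and ``heuristic`` when a greedy cover produced it and
    minimality is not guaranteed.
    """

    reactions: frozenset[str]
    flag: str = "one-minimal-solution"

    def __len__(self) -> int:
        return len(self.reactions)


class CompletionList(list):
    """List of :class:`CompletionSet` with search-outcome annotations."""

    exhausted_bound: bool = False
    heuristic: bool = False


@dataclass
class UnblockingResult:
    """Minimal compound sets restoring producibility, or an exhausted bound."""

    sets: list[frozenset[str]]
    exhausted_bound: bool = False


def _directed_reactions(model: Model) -> list[tuple[str, frozenset[str], frozenset[str]]]:
    """Expand reactions into directed (id, reactants, products) triples."""
    directed = []
    for reaction in sorted(model.reactions(), key=lambda e: e.id):
        reactants = frozenset(model.reactants_of(reaction.id))
        products = frozenset(model.products_of(reaction.id))
        directed.append((reaction.id, reactants, products))
        if model.direction(reaction.id) == REVERSIBLE:
            directed.append((reaction.id, products, reactants))
    return directed


def compute_scope(model: Model, seeds: Iterable[str]) -> ScopeResult:
    """Network expansion to the least fixpoint.

    Independent of iteration order and terminates in at most one iteration
    per compound; unknown seed ids are excluded and reported in the result.
    """
    known = set()
    unknown = []
    for seed in seeds:
        if seed in model.entities:
            known.add(seed)
        else:
            unknown.append(seed)
    directed = _directed_reactions(model)
    producible = set(known)
    layer = {seed: 0 for seed in sorted(known)}
    fired: set[str] = set()
    reaction_layer: dict[str, int] = {}
    pending = list(range(len(directed)))
    iteration = 0
    while True:
        iteration += 1
        newly: set[str] = set()
        still_pending = []
        for idx in pending:
            rid, reactants, products = directed[idx]
            if reactants <= producible:
                if rid not in reaction_layer:
                    reaction_layer[rid] = iteration
                fired.add(rid)
                newly.update(products - producible)
            else:
                still_pending.append(idx)
        if not newly:
            break
        for compound in sorted(newly):
            layer[compound] = iteration
        producible |= newly
        pending = still_pending
    return ScopeResult(
        producible=frozenset(producible),
        layer=layer,
        fired=frozenset(fired),
        reaction_layer=reaction_layer,
        unknown_seeds=sorted(unknown),
    )


def unproducible_targets(
    model: Model, seeds: Iterable[str], targets: Iterable[str]
) -> set[str]:
    """Targets outside the scope of the seeds (unknown ids count as absent)."""
    scope = compute_scope(model, seeds)
    return {t for t in targets if t not in scope.producible}


def unblocking_compounds(
    model: Model,
    seeds: Iterable[str],
    targets: Iterable[str],
    max_size: int = 3,
) -> UnblockingResult:
    """Subset-minimal non-seed compound sets whose addition unblocks all targets.

    Enumerates by increasing cardinality up to ``max_size`` (supersets of a
    found solution are pruned, so every returned set is subset-minimal),
    sorted by cardinality then lexicographically. When nothing is found
    within the bound the result carries ``exhausted_bound=True``.
    """
    seeds = set(seeds)
    targets = set(targets)
    if not unproducible_targets(model, seeds, targets):
        return UnblockingResult(sets=[])
    candidates = sorted(
        eid for eid, e in model.entities.items()
        if e.etype in ("compound", "class") and eid not in seeds
    )
    solutions: list[frozenset[str]] = []
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(candidates, size):
            subset = frozenset(combo)
            if any(found <= subset for found in solutions):
                continue
            if not unproducible_targets(model, seeds | subset, targets):
                solutions.append(subset)
    solutions.sort(key=lambda s: (len(s), sorted(s)))
    return UnblockingResult(sets=solutions, exhausted_bound=not solutions)


def production_path(
    model: Model, seeds: Iterable[str], target: str
) -> list[str]:
    """One witness reaction sequence producing ``target`` from the seeds.

    Reactions are returned ordered by scope layer (lexicographic within a
    layer); replaying them in order never requires an unavailable reactant.
    A seed target needs no reactions (empty path). A target outside the
    scope raises :class:`NotProducibleError` naming its missing precursors.
    """
    seeds = set(seeds)
    scope = compute_scope(model, seeds)
    if target not in scope.producible:
        missing = _first_missing_precursors(model, scope, target)
        raise NotProducibleError(
            f"target {target!r} is not producible from the seeds; "
            f"first missing precursors: {', '.join(missing) or '(absent from model)'}"
        )
    chosen: dict[str, int] = {}
    stack = [target]
    resolved: set[str] = set()
    while stack:
        compound = stack.pop()
        if compound in resolved or scope.layer.get(compound, 0) == 0:
            continue
        resolved.add(compound)
        producer = _best_producer(model, scope, compound)
        if producer is None:
            continue
        rid, reactants = producer
        # replay position = layer of the compound this firing provides
        chosen[rid] = max(chosen.get(rid, 0), scope.layer[compound])
        stack.extend(sorted(reactants, reverse=True))
    return sorted(chosen, key=lambda rid: (chosen[rid], rid))


def _best_producer(
    model: Model, scope: ScopeResult, compound: str
) -> Optional[tuple[str, frozenset[str]]]:
    """Earliest-layer (lexicographic tie-break) fired reaction producing compound."""
    best = None
    for rid, reactants, products in _directed_reactions(model):
        if rid not in scope.fired or compound not in products:
            continue
        if not reactants <= scope.producible:
            continue
        # producer must strictly precede the compound's own layer
        if max((scope.layer[r] for r in reactants), default=0) >= scope.layer[compound]:
            continue
        key = (scope.reaction_layer[rid], rid)
        if best is None or key < best[0]:
            best = (key, rid, reactants)
    if best is None:
        return None
    return best[1], best[2]


def _first_missing_precursors(model: Model, scope: ScopeResult, target: str) -> list[str]:
    if target not in model.entities:
        return []
    missing = set()
    for rid, reactants, products in _directed_reactions(model):
        if target in products:
            missing.update(r for r in reactants if r not in scope.producible)
    return sorted(missing)


def _relevant_candidates(
    combined: Model, targets: set[str], candidates: Sequence[str]
) -> list[str]:
    """Keep candidates lying on some backward path from a target."""
    relevant_compounds = set(targets)
    directed = _directed_reactions(combined)
    changed = True
    relevant_reactions: set[str] = set()
    while changed:
        changed = False
        for rid, reactants, products in directed:
            if rid in relevant_reactions:
                continue
            if products & relevant_compounds:
                relevant_reactions.add(rid)
                new = reactants - relevant_compounds
                if new:
                    relevant_compounds |= new
                changed = True
    return [c for c in candidates if c in relevant_reactions]


def _add_reactions(base: Model, database: Model, reaction_ids: Iterable[str]) -> Model:
    extended = base.copy()
    for rid in reaction_ids:
        extended.add_entity(database.entities[rid])
        for relation in database.relations_from(rid):
            if relation.object not in extended.entities:
                extended.add_entity(database.entities[relation.object])
            extended.add_relation(relation)
    return extended


def gapfill(
    draft: Model,
    database: Model,
    seeds: Iterable[str],
    targets: Iterable[str],
    max_size: int = 4,
    enumerate_all: bool = False,
    exhaustive_threshold: int = 20,
) -> CompletionList:
    """Cardinality-minimal database completions restoring target producibility.

    Candidates are the database reactions absent from the draft, pruned to
    those on some backward path from a target. The search is iterative
    deepening over cardinality (lexicographic enumeration, exhaustive while
    the candidate pool is at most ``exhaustive_threshold``); larger pools
    fall back to a greedy set cover whose result is trimmed to
    single-removal minimality and flagged ``heuristic``.

    With ``enumerate_all`` every minimal-cardinality solution is returned,
    followed by their union and intersection. Already-producible targets
    yield the empty completion; targets unreachable even with the whole
    database raise :class:`InfeasibleCompletionError`.
    """
    seeds = set(seeds)
    targets = set(targets)
    candidates = sorted(
        rid for rid in (e.id for e in database.reactions())
        if rid not in draft.entities
    )
    result = CompletionList()
    if not unproducible_targets(draft, seeds, targets):
        result.append(CompletionSet(frozenset(), "one-minimal-solution"))
        return result
    full = _add_reactions(draft, database, candidates)
    still = unproducible_targets(full, seeds, targets)
    if still:
        raise InfeasibleCompletionError(still)
    pruned = _relevant_candidates(full, targets, candidates)

    if len(pruned) > exhaustive_threshold:
        solution = _greedy_cover(draft, database, pruned, seeds, targets, max_size)
        result.heuristic = True
        if solution is None:
            result.exhausted_bound = True
        else:
            result.append(CompletionSet(frozenset(solution), "heuristic"))
        return result

    for size in range(1, max_size + 1):
        hits = []
        for combo in itertools.combinations(pruned, size):
            extended = _add_reactions(draft, database, combo)
            if not unproducible_targets(extended, seeds, targets):
                hits.append(frozenset(combo))
                if not enumerate_all:
                    break
        if hits:
            if enumerate_all:
                for hit in sorted(hits, key=sorted):
                    result.append(CompletionSet(hit, "one-minimal-solution"))
                union = frozenset().union(*hits)
                inter = frozenset.intersection(*hits)
                result.append(CompletionSet(union, "union-of-minimal"))
                result.append(CompletionSet(inter, "intersection-of-minimal"))
            else:
                result.append(CompletionSet(hits[0], "one-minimal-solution"))
            return result
    result.exhausted_bound = True
    return result


def _greedy_cover(
    draft: Model,
    database: Model,
    candidates: Sequence[str],
    seeds: set[str],
    targets: set[str],
    max_size: int,
) -> Optional[list[str]]:
    """Greedy completion: repeatedly add the reaction maximizing scope gain
    toward the targets, then trim to single-removal minimality."""
    chosen: list[str] = []
    remaining = list(candidates)
    while unproducible_targets(_add_reactions(draft, database, chosen), seeds, targets):
        if len(chosen) >= max_size or not remaining:
            return None
        best_rid, best_score = None, None
        base_scope = compute_scope(
            _add_reactions(draft, database, chosen), seeds
        ).producible
        for rid in remaining:
            scope = compute_scope(
                _add_reactions(draft, database, chosen + [rid]), seeds
            ).producible
            score = (len(scope & targets), len(scope - base_scope))
            if best_score is None or score > best_score:
                best_rid, best_score = rid, score
        chosen.append(best_rid)
        remaining.remove(best_rid)
    # single-removal trim keeps the result irredundant
    for rid in list(chosen):
        trial = [r for r in chosen if r != rid]
        if not unproducible_targets(_add_reactions(draft, database, trial), seeds, targets):
            chosen = trial
    return chosen


def verify_completion(
    draft: Model,
    database: Model,
    seeds: Iterable[str],
    targets: Iterable[str],
    completion: CompletionSet,
) -> bool:
    """Post-hoc check: completion restores all targets and is single-removal minimal."""
    seeds, targets = set(seeds), set(targets)
    extended = _add_reactions(draft, database, completion.reactions)
    if unproducible_targets(extended, seeds, targets):
        return False
    for rid in completion.reactions:
        trial = _add_reactions(
            draft, database, completion.reactions - {rid}
        )
        if not unproducible_targets(trial, seeds, targets):
            return False
    return True


def instantiate_class_reactions(
    database: Model,
    ontology: Optional[Iterable[Relation]] = None,
    max_variants: int = 64,
) -> tuple[Model, list[str]]:
    """Expand class-written reactions into per-instance variants.

    Reaction databases write some reactions against compound *classes* of an
    ontology tree (e.g. a generic polyglutamylated folate) while neighbouring
    pathway reactions produce concrete *instances*; topologically this
    disconnects the pathway. For every reaction with at least one class-typed
    participant, a variant is added for each combination of direct instances
    substituted into the class slots (cartesian across slots, capped at
    ``max_variants`` per reaction — capped reactions are skipped and
    returned in the report list). Variant ids are
    ``parent-id + "/" + "/".join(instance ids)``; the parent id is kept in an
    ``instance-of`` attribute and originals are retained. Variants are
    tagged category ``gap-filling`` / tool ``class-instantiation`` so their
    synthetic origin stays visible.

    ``ontology`` defaults to the database's own ``is_a`` relations; a cyclic
    ontology raises :class:`OntologyCycleError`.
    """
    if ontology is None:
        ontology = [r for r in database.relations.values() if r.rtype == "is_a"]
    else:
        ontology = list(ontology)
    parents: dict[str, set[str]] = {}
    instances: dict[str, list[str]] = {}
    for relation in ontology:
        parents.setdefault(relation.subject, set()).add(relation.object)
        instances.setdefault(relation.object, []).append(relation.subject)
    _check_acyclic(parents)
    for members in instances.values():
        members.sort()

    extended = database.copy()
    skipped: list[str] = []
    for reaction in sorted(database.reactions(), key=lambda e: e.id):
        participants = database.relations_from(reaction.id, "consumes") + \
            database.relations_from(reaction.id, "produces")
        class_slots = sorted(
            {
                rel.object
                for rel in participants
                if database.entities[rel.object].etype == "class"
                and instances.get(rel.object)
            }
        )
        if not class_slots:
            continue
        combos = list(itertools.product(*(instances[c] for c in class_slots)))
        if len(combos) > max_variants:
            skipped.append(reaction.id)
            continue
        for combo in combos:
            substitution = dict(zip(class_slots, combo))
            variant_id = reaction.id + "/" + "/".join(combo)
            variant = reaction.copy()
            variant.id = variant_id
            variant.attributes["instance-of"] = [reaction.id]
            extended.add_entity(
                variant,
                SourceTag(variant_id, "gap-filling", "class-instantiation",
                          database.meta.get("ref_db", "")),
            )
            for rel in participants:
                target_id = substitution.get(rel.object, rel.object)
                if target_id not in extended.entities:
                    extended.add_entity(database.entities[target_id])
                extended.add_relation(
                    Relation(variant_id, rel.rtype, target_id,
                             {k: list(v) for k, v in rel.attributes.items()})
                )
    return extended, skipped


def _check_acyclic(parents: dict[str, set[str]]) -> None:
    state: dict[str, int] = {}

    def visit(node: str, trail: list[str]) -> None:
        state[node] = 1
        for parent in parents.get(node, ()):  # walk instance -> class edges
            if state.get(parent) == 1:
                raise OntologyCycleError(
                    "is_a cycle through " + " -> ".join(trail + [node, parent])
                )
            if state.get(parent, 0) == 0:
                visit(parent, trail + [node])
        state[node] = 2

    for node in sorted(parents):
        if state.get(node, 0) == 0:
            visit(node, [])


def read_compound_list(path: Union[str, os.PathLike]) -> list[str]:
    """Read a seeds/targets TSV: one compound id per line, ``#`` comments."""
    ids = []
    with open(path, "r", encoding="utf-8") as handle:
        for raw in handle:
            line = raw.split("#", 1)[0].strip()
            if line:
                ids.append(line.split("\t")[0])
    return ids
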