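"""Provenance-tracked metabolic model store.

A :class:`Model` is a typed entity/relation store with per-entity process
metadata (:class:`SourceTag`). Entities are reactions, compounds, genes,
pathways, proteins or ontology classes; relations connect them (a reaction
``consumes``/``produces`` compounds, a gene ``is_linked_to`` a reaction, a
reaction ``is_in_pathway`` a pathway, an instance compound ``is_a`` a class,
...). Every modification records *which* reconstruction step introduced an
element, so that the final model can be audited reaction by reaction:
at which step, by which tool, from which source each piece of knowledge
entered the network.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

ENTITY_TYPES = frozenset(
    {"reaction", "compound", "gene", "pathway", "protein", "class"}
)
RELATION_TYPES = frozenset(
    {
        "consumes",
        "produces",
        "is_in_pathway",
        "is_linked_to",
        "catalyzes",
        "has_xref",
        "is_a",
    }
)
TAG_CATEGORIES = frozenset({"annotation", "orthology", "gap-filling", "manual"})

#: direction attribute values understood by the topological operators
LEFT_TO_RIGHT = "LEFT-TO-RIGHT"
REVERSIBLE = "REVERSIBLE"


class GsmtraceError(Exception):
    """Base class for all errors raised by this package."""


class EntityTypeConflictError(GsmtraceError):
    """An id was re-added with a different entity type."""

    def __init__(self, entity_id: str, existing: str, new: str):
        self.entity_id, self.existing, self.new = entity_id, existing, new
        super().__init__(
            f"entity {entity_id!r} already present with type {existing!r}, "
            f"cannot re-add as {new!r}"
        )


class IntegrityError(GsmtraceError):
    """A relation or tag references an id absent from the model."""


class ValidationError(GsmtraceError):
    """A value violates a field-level invariant."""


class NamespaceMismatchError(GsmtraceError):
    """Two models declare different reference databases.

    Raised by :func:`merge_models` when both operands declare a reference
    namespace and they disagree; run identifier mapping on one side first.
    """


def _norm_key(key: str) -> str:
    return key.strip().lower()


@dataclass
class Entity:
    """A typed node of the model: reaction, compound, gene, pathway, protein
    or ontology class.

    ``attributes`` is an ordered multimap (key -> list of string values);
    keys are case-insensitive and normalized to lower case, value order is
    preserved and significant for round-tripping.
    """

    id: str
    etype: str
    attributes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id or not self.id.strip():
            raise ValidationError("entity id must be non-empty")
        if self.etype not in ENTITY_TYPES:
            raise ValidationError(
                f"unknown entity type {self.etype!r} for {self.id!r} "
                f"(expected one of {sorted(ENTITY_TYPES)})"
            )
        self.attributes = {
            _norm_key(k): list(v) for k, v in self.attributes.items()
        }

    def add_attribute(self, key: str, value: str) -> None:
        self.attributes.setdefault(_norm_key(key), []).append(value)

    def get_attribute(self, key: str) -> list[str]:
        return self.attributes.get(_norm_key(key), [])

    def first_attribute(self, key: str, default: Optional[str] = None) -> Optional[str]:
        values = self.get_attribute(key)
        return values[0] if values else default

    def copy(self) -> "Entity":
        return Entity(self.id, self.etype, {k: list(v) for k, v in self.attributes.items()})


@dataclass
class Relation:
    """A typed edge between two entities, identified by (subject, rtype, object).

    Stoichiometric links (``consumes``/``produces``) carry a positive
    ``coefficient`` attribute; ``compartment`` is carried the same way.
    """

    subject: str
    rtype: str
    object: str
    attributes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rtype not in RELATION_TYPES:
            raise ValidationError(
                f"unknown relation type {self.rtype!r} "
                f"({self.subject!r} -> {self.object!r})"
            )
        self.attributes = {
            _norm_key(k): list(v) for k, v in self.attributes.items()
        }
        if self.rtype in ("consumes", "produces"):
            coeff = self.coefficient
            if coeff <= 0:
                raise ValidationError(
                    f"stoichiometric coefficient must be > 0 on "
                    f"{self.subject} {self.rtype} {self.object}"
                )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject, self.rtype, self.object)

    @property
    def coefficient(self) -> float:
        values = self.attributes.get("coefficient")
        if not values:
            return 1.0
        return float(values[0])

    def copy(self) -> "Relation":
        return Relation(
            self.subject, self.rtype, self.object,
            {k: list(v) for k, v in self.attributes.items()},
        )


@dataclass(frozen=True)
class SourceTag:
    """Process metadata: why/when an entity entered the model.

    ``category`` is the reconstruction step family (annotation, orthology,
    gap-filling, manual); ``tool`` the program or form that produced it;
    ``source`` the data source (template species, database, literature ref);
    ``step`` the pipeline step index. The identity of a tag is
    (entity, category, tool, source, step): re-recording it with a different
    comment does not create a duplicate.
    """

    entity: str
    category: str
    tool: str = ""
    source: str = ""
    comment: str = ""
    step: int = 0

    def __post_init__(self) -> None:
        if self.category not in TAG_CATEGORIES:
            raise ValidationError(
                f"unknown tag category {self.category!r} "
                f"(expected one of {sorted(TAG_CATEGORIES)})"
            )
        if self.step < 0:
            raise ValidationError("tag step index must be >= 0")

    @property
    def key(self) -> tuple[str, str, str, str, int]:
        return (self.entity, self.category, self.tool, self.source, self.step)


class Model:
    """An id-indexed entity store with relations and provenance tags.

    Invariants maintained by every mutator: all relation endpoints and tag
    entities resolve; no two entities share an id; tags are never deleted by
    core operations (only explicit curation deletes remove an entity and its
    incident relations/tags together).
    """

    def __init__(
        self,
        model_id: str = "model",
        ref_db: str = "",
        ref_db_version: str = "",
    ):
        self.entities: dict[str, Entity] = {}
        self.relations: dict[tuple[str, str, str], Relation] = {}
        self.tags: dict[tuple[str, str, str, str, int], SourceTag] = {}
        self.meta: dict[str, str] = {
            "model_id": model_id,
            "ref_db": ref_db,
            "ref_db_version": ref_db_version,
        }

    # -- construction -------------------------------------------------

    def add_entity(self, entity: Entity, tag: Optional[SourceTag] = None) -> Entity:
        """Insert or extend an entity; optionally record a provenance tag.

        Re-adding an existing id with the same type unions the attribute
        value lists (new values appended, duplicates skipped), so repeated
        evidence accumulates tags without duplicating the entity.
        """
        existing = self.entities.get(entity.id)
        if existing is None:
            self.entities[entity.id] = entity.copy()
        else:
            if existing.etype != entity.etype:
                raise EntityTypeConflictError(entity.id, existing.etype, entity.etype)
            _union_attributes(existing.attributes, entity.attributes)
        if tag is not None:
            if tag.entity != entity.id:
                tag = SourceTag(entity.id, tag.category, tag.tool,
                                tag.source, tag.comment, tag.step)
            self.add_tag(tag)
        return self.entities[entity.id]

    def add_relation(self, relation: Relation) -> Relation:
        for endpoint in (relation.subject, relation.object):
            if endpoint not in self.entities:
                raise IntegrityError(
                    f"relation {relation.subject} {relation.rtype} "
                    f"{relation.object} references unknown id {endpoint!r}"
                )
        existing = self.relations.get(relation.key)
        if existing is None:
            self.relations[relation.key] = relation.copy()
        else:
            _union_attributes(existing.attributes, relation.attributes)
        return self.relations[relation.key]

    def add_tag(self, tag: SourceTag) -> SourceTag:
        if tag.entity not in self.entities:
            raise IntegrityError(f"tag references unknown entity {tag.entity!r}")
        return self.tags.setdefault(tag.key, tag)

    def remove_entity(self, entity_id: str) -> None:
        """Delete an entity with its incident relations and tags.

        Reserved for curation deletes; ordinary reconstruction steps only add.
        """
        if entity_id not in self.entities:
            raise IntegrityError(f"cannot remove unknown entity {entity_id!r}")
        del self.entities[entity_id]
        self.relations = {
            k: r for k, r in self.relations.items()
            if r.subject != entity_id and r.object != entity_id
        }
        self.tags = {k: t for k, t in self.tags.items() if t.entity != entity_id}

    # -- queries ------------------------------------------------------

    def entities_of_type(self, etype: str) -> Iterator[Entity]:
        return (e for e in self.entities.values() if e.etype == etype)

    def reactions(self) -> Iterator[Entity]:
        return self.entities_of_type("reaction")

    def compounds(self) -> Iterator[Entity]:
        return self.entities_of_type("compound")

    def relations_from(self, subject: str, rtype: Optional[str] = None) -> list[Relation]:
        return [
            r for r in self.relations.values()
            if r.subject == subject and (rtype is None or r.rtype == rtype)
        ]

    def relations_to(self, obj: str, rtype: Optional[str] = None) -> list[Relation]:
        return [
            r for r in self.relations.values()
            if r.object == obj and (rtype is None or r.rtype == rtype)
        ]

    def reactants_of(self, reaction_id: str) -> list[str]:
        return sorted(r.object for r in self.relations_from(reaction_id, "consumes"))

    def products_of(self, reaction_id: str) -> list[str]:
        return sorted(r.object for r in self.relations_from(reaction_id, "produces"))

    def genes_of(self, reaction_id: str) -> list[str]:
        return sorted(r.subject for r in self.relations_to(reaction_id, "is_linked_to"))

    def direction(self, reaction_id: str) -> str:
        """Reaction direction attribute; SBML-style default is REVERSIBLE."""
        return self.entities[reaction_id].first_attribute("direction", REVERSIBLE)

    def tags_of(self, entity_id: str) -> list[SourceTag]:
        return sorted(
            (t for t in self.tags.values() if t.entity == entity_id),
            key=lambda t: t.key,
        )

    def entity_counts(self) -> dict[str, int]:
        counts = {etype: 0 for etype in sorted(ENTITY_TYPES)}
        for entity in self.entities.values():
            counts[entity.etype] += 1
        return counts

    # -- invariants ---------------------------------------------------

    def validate(self) -> None:
        """Raise IntegrityError on any dangling reference."""
        for relation in self.relations.values():
            for endpoint in (relation.subject, relation.object):
                if endpoint not in self.entities:
                    raise IntegrityError(
                        f"dangling relation endpoint {endpoint!r} in "
                        f"{relation.subject} {relation.rtype} {relation.object}"
                    )
        for tag in self.tags.values():
            if tag.entity not in self.entities:
                raise IntegrityError(f"dangling tag entity {tag.entity!r}")

    # -- copy / equality ----------------------------------------------

    def copy(self) -> "Model":
        clone = Model()
        clone.entities = {eid: e.copy() for eid, e in self.entities.items()}
        clone.relations = {k: r.copy() for k, r in self.relations.items()}
        clone.tags = dict(self.tags)
        clone.meta = dict(self.meta)
        return clone

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Model):
            return NotImplemented
        return (
            self.entities == other.entities
            and self.relations == other.relations
            and self.tags == other.tags
        )

    def __repr__(self) -> str:
        counts = self.entity_counts()
        short = ", ".join(f"{n} {t}s" for t, n in counts.items() if n)
        return f"<Model {self.meta.get('model_id', '?')}: {short or 'empty'}>"


def _union_attributes(
    target: dict[str, list[str]], extra: dict[str, list[str]]
) -> None:
    """Union value lists in place, preserving target order, never overwriting."""
    for key, values in extra.items():
        bucket = target.setdefault(_norm_key(key), [])
        for value in values:
            if value not in bucket:
                bucket.append(value)


def add_entity(model: Model, entity: Entity, tag: Optional[SourceTag] = None) -> Model:
    """Functional-style wrapper over :meth:`Model.add_entity` (mutates in place)."""
    model.add_entity(entity, tag)
    return model


def merge_models(
    base: Model,
    addition: Model,
    category: str,
    tool: str = "",
    source: str = "",
    step: int = 0,
) -> Model:
    """Union two models, stamping every entity of ``addition`` with provenance.

    Entities are unioned by id (attribute value lists unioned, never
    overwritten — disagreeing values coexist and are surfaced by the diff
    and report modules), relations deduplicated by (subject, rtype, object),
    and all tags of both operands are kept. Each entity contributed by
    ``addition`` additionally gains a tag with the given
    category/tool/source/step, so the merged model records which merge step
    brought it in.

    Both operands must live in the same reference namespace; if both declare
    a reference database in ``meta`` and they differ, the merge refuses and
    asks for identifier mapping first.
    """
    ref_a = base.meta.get("ref_db", "")
    ref_b = addition.meta.get("ref_db", "")
    if ref_a and ref_b and ref_a != ref_b:
        raise NamespaceMismatchError(
            f"reference databases differ ({ref_a!r} vs {ref_b!r}); "
            "run map_identifiers on one model before merging"
        )
    merged = base.copy()
    for entity in addition.entities.values():
        merged.add_entity(
            entity,
            SourceTag(entity.id, category, tool, source, "", step),
        )
    for relation in addition.relations.values():
        merged.add_relation(relation)
    for tag in addition.tags.values():
        merged.add_tag(tag)
    if not ref_a and ref_b:
        merged.meta["ref_db"] = ref_b
        merged.meta["ref_db_version"] = addition.meta.get("ref_db_version", "")
    return merged
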