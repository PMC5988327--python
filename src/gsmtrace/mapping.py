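"""Identifier mapping against a MetaNetX-style translation dictionary.

A reconstruction keeps a single reference namespace; reactions and
compounds imported from models built on another database (BiGG ids in a
MetaCyc workspace, say) are rewritten through a two-column dictionary before
merging. Mapping is single-pass and scope-separated (reaction vs compound);
transitive chains in the dictionary are an input error, which keeps the
operation deterministic and idempotent.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Union

from .model import Entity, GsmtraceError, Model, Relation, SourceTag, ValidationError

SCOPES = ("reaction", "compound")


class MappingCollisionError(GsmtraceError):
    """Two entities of incompatible types would land on one reference id."""


@dataclass
class MappingTable:
    """Rows of (foreign id -> reference id) per scope.

    Invariants enforced on construction: reference ids non-empty, no foreign
    id maps to two reference ids within a scope, and no reference id is
    itself a foreign id of the same scope (no transitive chains).
    """

    rows: dict[str, dict[str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for scope in SCOPES:
            table = self.rows.setdefault(scope, {})
            for foreign, reference in table.items():
                if not reference:
                    raise ValidationError(
                        f"empty reference id for {foreign!r} ({scope})"
                    )
                if reference in table and reference != foreign:
                    raise ValidationError(
                        f"transitive mapping chain: {foreign!r} -> {reference!r} "
                        f"-> {table[reference]!r} ({scope})"
                    )

    def get(self, scope: str, foreign: str) -> Union[str, None]:
        return self.rows.get(scope, {}).get(foreign)


@dataclass
class MappingReport:
    """Outcome of one mapping pass; mapped + unmapped = ids encountered."""

    mapped: dict[str, int] = field(default_factory=lambda: {s: 0 for s in SCOPES})
    unmapped: list[str] = field(default_factory=list)
    collisions: list[str] = field(default_factory=list)


def read_mapping_table(path: Union[str, os.PathLike], provenance: str = "") -> MappingTable:
    """Read a TSV dictionary with header ``foreign_id  reference_id  scope``."""
    rows: dict[str, dict[str, str]] = {s: {} for s in SCOPES}
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "foreign_id":
                continue
            if len(fields) != 3:
                raise ValidationError(
                    f"{path} line {lineno}: expected 3 columns, got {len(fields)}"
                )
            foreign, reference, scope = fields
            if scope not in SCOPES:
                raise ValidationError(
                    f"{path} line {lineno}: unknown scope {scope!r}"
                )
            existing = rows[scope].get(foreign)
            if existing is not None and existing != reference:
                raise ValidationError(
                    f"{path} line {lineno}: {foreign!r} maps to both "
                    f"{existing!r} and {reference!r}"
                )
            rows[scope][foreign] = reference
    return MappingTable(rows, provenance=provenance or str(path))


def map_identifiers(model: Model, table: MappingTable) -> tuple[Model, MappingReport]:
    """Rewrite foreign reaction/compound ids to the reference namespace.

    Every id with a dictionary entry is rewritten across entities, relation
    endpoints and tags; the rewritten entity records its foreign id in an
    ``xrefs`` attribute. Ids without an entry are left untouched and listed
    in the report. When two distinct entities map onto one reference id they
    are merged if their types agree (attributes and tags unioned, recorded
    in the report's collision list) and raise
    :class:`MappingCollisionError` otherwise.
    """
    report = MappingReport()
    rename: dict[str, str] = {}
    for entity in model.entities.values():
        scope = "reaction" if entity.etype == "reaction" else (
            "compound" if entity.etype in ("compound", "class") else None
        )
        if scope is None:
            continue
        reference = table.get(scope, entity.id)
        if reference is None:
            report.unmapped.append(entity.id)
        elif reference != entity.id:
            rename[entity.id] = reference
            report.mapped[scope] += 1
        else:
            report.unmapped.append(entity.id)
    report.unmapped.sort()

    mapped = Model()
    mapped.meta = dict(model.meta)
    if table.provenance:
        mapped.meta["mapping_dictionary"] = table.provenance

    for old_id in sorted(model.entities):
        entity = model.entities[old_id]
        new_id = rename.get(old_id, old_id)
        existing = mapped.entities.get(new_id)
        if existing is not None and existing.etype != entity.etype:
            raise MappingCollisionError(
                f"{old_id!r} ({entity.etype}) and a {existing.etype} entity "
                f"collide on reference id {new_id!r}"
            )
        if existing is not None:
            report.collisions.append(f"{old_id} -> {new_id}")
        clone = entity.copy()
        clone.id = new_id
        mapped.add_entity(clone)
        if old_id != new_id:
            mapped.entities[new_id].add_attribute("xrefs", old_id)

    for relation in model.relations.values():
        mapped.add_relation(
            Relation(
                rename.get(relation.subject, relation.subject),
                relation.rtype,
                rename.get(relation.object, relation.object),
                {k: list(v) for k, v in relation.attributes.items()},
            )
        )
    for tag in model.tags.values():
        mapped.add_tag(
            SourceTag(
                rename.get(tag.entity, tag.entity),
                tag.category,
                tag.tool,
                tag.source,
                tag.comment,
                tag.step,
            )
        )
    mapped.validate()
    return mapped, report
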