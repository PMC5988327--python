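"""Assisted, replayable manual curation and model comparison.

Manual edits are expressed as *forms* — flat, diffable text blocks with a
mandatory justification and source — rather than interactive edits, so that
expert interventions can be re-applied verbatim when an upstream step is
re-run (new genome assembly, new database release). Every applied form
stamps the touched entities with a ``manual`` provenance tag and is appended
to a :class:`CurationLog`. Replaying a log on a drifted base skips forms
whose target vanished (a warning, not an error) and reports the skips.

:func:`diff_models` reports the differences between two model versions per
entity category (genes, reactions, compounds, pathways) with attribute- and
relation-level deltas for ids present in both.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Union

from .model import (
    Entity,
    GsmtraceError,
    Model,
    Relation,
    SourceTag,
    ValidationError,
)

FORM_OPS = ("add_reaction", "add_compound", "modify_entity", "delete_entity")


class FormError(GsmtraceError):
    """A curation form fails validation or names an unknown target."""


@dataclass
class CurationForm:
    """One manual edit: operation, payload, and its mandatory justification."""

    op: str
    payload: dict[str, str]
    justification: str
    source: str
    author: str = ""
    timestamp: str = ""

    def validate(self) -> None:
        if self.op not in FORM_OPS:
            raise FormError(f"unknown curation op {self.op!r}")
        if not self.justification.strip():
            raise FormError(f"{self.op}: justification is mandatory")
        if not self.source.strip():
            raise FormError(f"{self.op}: source is mandatory")
        if not self.payload.get("id", "").strip():
            raise FormError(f"{self.op}: payload needs an 'id'")
        if self.op == "add_reaction":
            if not _parse_participants(self.payload.get("reactants", "")):
                raise FormError("add_reaction needs at least one reactant")
            if not _parse_participants(self.payload.get("products", "")):
                raise FormError("add_reaction needs at least one product")


@dataclass
class CurationLog:
    """Append-only ordered record of applied forms."""

    forms: list[CurationForm] = field(default_factory=list)

    def append(self, form: CurationForm) -> None:
        self.forms.append(form)

    def __len__(self) -> int:
        return len(self.forms)


def _parse_participants(text: str) -> list[tuple[str, float]]:
    """Parse ``id:coefficient,id:coefficient`` lists (coefficient optional)."""
    participants = []
    for chunk in text.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        cid, _, coeff = chunk.partition(":")
        participants.append((cid.strip(), float(coeff) if coeff else 1.0))
    return participants


def apply_form(
    model: Model,
    form: CurationForm,
    log: Optional[CurationLog] = None,
    step: int = 0,
) -> Model:
    """Apply one validated form in place; tag touched entities ``manual``.

    delete/modify targets must exist (:class:`FormError` otherwise).
    """
    form.validate()
    target = form.payload["id"].strip()

    def manual_tag(entity_id: str) -> SourceTag:
        return SourceTag(
            entity_id, "manual", "curation-form", form.source,
            form.justification, step,
        )

    if form.op == "add_compound":
        entity = Entity(target, "compound")
        for key, value in form.payload.items():
            if key not in ("id",):
                entity.add_attribute(key, value)
        model.add_entity(entity, manual_tag(target))

    elif form.op == "add_reaction":
        entity = Entity(target, "reaction")
        if form.payload.get("direction"):
            entity.add_attribute("direction", form.payload["direction"])
        for key, value in form.payload.items():
            if key not in ("id", "reactants", "products", "direction", "genes"):
                entity.add_attribute(key, value)
        model.add_entity(entity, manual_tag(target))
        for rtype, key in (("consumes", "reactants"), ("produces", "products")):
            for cid, coeff in _parse_participants(form.payload.get(key, "")):
                if cid not in model.entities:
                    model.add_entity(Entity(cid, "compound"), manual_tag(cid))
                attributes = {} if coeff == 1.0 else {"coefficient": ["%g" % coeff]}
                model.add_relation(Relation(target, rtype, cid, attributes))
        for gene in form.payload.get("genes", "").split(","):
            gene = gene.strip()
            if gene:
                if gene not in model.entities:
                    model.add_entity(Entity(gene, "gene"), manual_tag(gene))
                model.add_relation(Relation(gene, "is_linked_to", target))

    elif form.op == "modify_entity":
        if target not in model.entities:
            raise FormError(f"modify_entity: unknown target {target!r}")
        entity = model.entities[target]
        for key, value in form.payload.items():
            if key != "id":
                entity.attributes[key.strip().lower()] = [value]
        model.add_tag(manual_tag(target))

    elif form.op == "delete_entity":
        if target not in model.entities:
            raise FormError(f"delete_entity: unknown target {target!r}")
        model.remove_entity(target)

    if log is not None:
        log.append(form)
    return model


@dataclass
class ReplayReport:
    """Forms skipped during a replay, with the reason for each."""

    skipped: list[tuple[CurationForm, str]] = field(default_factory=list)


def replay_log(model: Model, log: CurationLog) -> tuple[Model, ReplayReport]:
    """Re-apply a curation log in order on a (possibly regenerated) base.

    Forms whose delete/modify target no longer exists are skipped and
    reported rather than failing: upstream regeneration legitimately changes
    the base. The result is deterministic for a given base and log.
    """
    report = ReplayReport()
    for index, form in enumerate(log.forms):
        try:
            apply_form(model, form, step=index)
        except FormError as exc:
            if form.op in ("modify_entity", "delete_entity"):
                report.skipped.append((form, str(exc)))
            else:
                raise
    return model, report


# ----------------------------------------------------------- form files


def parse_forms(path: Union[str, os.PathLike]) -> list[CurationForm]:
    """Parse a form file: blank-line-separated blocks of

    ``op:<TAB or space>name`` followed by ``key<TAB>value`` lines
    (``reactants``/``products`` as ``id:coefficient`` comma lists).
    """
    forms: list[CurationForm] = []
    block: dict[str, str] = {}

    def flush() -> None:
        if not block:
            return
        op = block.pop("op", "")
        forms.append(
            CurationForm(
                op=op.strip(),
                justification=block.pop("justification", ""),
                source=block.pop("source", ""),
                author=block.pop("author", ""),
                timestamp=block.pop("timestamp", ""),
                payload=dict(block),
            )
        )
        block.clear()

    with open(path, "r", encoding="utf-8") as handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if line.startswith("#"):
                continue
            if line.startswith("op:"):
                flush()
                block["op"] = line[3:].strip()
                continue
            key, sep, value = line.partition("\t")
            if not sep:
                key, sep, value = line.partition(" ")
            block[key.strip()] = value.strip()
    flush()
    for form in forms:
        form.validate()
    return forms


# ----------------------------------------------------------------- diff


DIFF_CATEGORIES = ("gene", "reaction", "compound", "pathway")


@dataclass
class CategoryDiff:
    added: list[str] = field(default_factory=list)
    removed: list[str] = field(default_factory=list)
    changed: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class DiffReport:
    """Per-category id partition between two model versions."""

    categories: dict[str, CategoryDiff] = field(default_factory=dict)

    def summary(self) -> dict[str, dict[str, int]]:
        return {
            name: {
                "added": len(diff.added),
                "removed": len(diff.removed),
                "changed": len(diff.changed),
            }
            for name, diff in self.categories.items()
        }

    def is_empty(self) -> bool:
        return all(
            not d.added and not d.removed and not d.changed
            for d in self.categories.values()
        )

    def to_tsv(self, path: Union[str, os.PathLike]) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as handle:
            handle.write("category\tchange\tid\tdetail\n")
            for name in DIFF_CATEGORIES:
                diff = self.categories[name]
                for eid in diff.added:
                    handle.write(f"{name}\tadded\t{eid}\t\n")
                for eid in diff.removed:
                    handle.write(f"{name}\tremoved\t{eid}\t\n")
                for eid, deltas in sorted(diff.changed.items()):
                    handle.write(f"{name}\tchanged\t{eid}\t{'; '.join(deltas)}\n")


def _entity_fingerprint(model: Model, entity_id: str) -> dict[str, object]:
    entity = model.entities[entity_id]
    incident = sorted(
        (r.rtype, r.object) for r in model.relations_from(entity_id)
    ) + sorted((r.rtype, r.subject) for r in model.relations_to(entity_id))
    return {"attributes": entity.attributes, "relations": incident}


def diff_models(a: Model, b: Model) -> DiffReport:
    """Compare two models per entity category.

    Ids are partitioned into added (in ``b`` only), removed (in ``a`` only)
    and common; common ids whose attributes or incident relations differ are
    listed as changed with field-level deltas.
    """
    report = DiffReport()
    for etype in DIFF_CATEGORIES:
        ids_a = {e.id for e in a.entities_of_type(etype)}
        ids_b = {e.id for e in b.entities_of_type(etype)}
        diff = CategoryDiff(
            added=sorted(ids_b - ids_a),
            removed=sorted(ids_a - ids_b),
        )
        for eid in sorted(ids_a & ids_b):
            deltas = []
            fp_a = _entity_fingerprint(a, eid)
            fp_b = _entity_fingerprint(b, eid)
            attrs_a, attrs_b = fp_a["attributes"], fp_b["attributes"]
            for key in sorted(set(attrs_a) | set(attrs_b)):
                if attrs_a.get(key) != attrs_b.get(key):
                    deltas.append(
                        f"attribute {key}: {attrs_a.get(key)} -> {attrs_b.get(key)}"
                    )
            if fp_a["relations"] != fp_b["relations"]:
                gone = set(fp_a["relations"]) - set(fp_b["relations"])
                new = set(fp_b["relations"]) - set(fp_a["relations"])
                if gone:
                    deltas.append(f"relations removed: {sorted(gone)}")
                if new:
                    deltas.append(f"relations added: {sorted(new)}")
            if deltas:
                diff.changed[eid] = deltas
        report.categories[etype] = diff
    return report
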