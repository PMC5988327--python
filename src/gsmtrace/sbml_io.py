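"""SBML import/export (Level 2 and Level 3 core, fbc where available).

Identifier convention: SBML SIds only allow ``[A-Za-z_][A-Za-z0-9_]*`` while
reaction databases use ids containing dots, dashes and slashes (MetaCyc
instantiated reaction ids being the worst offenders). Ids are therefore
escaped only at the SBML boundary — never inside the store — with a
type prefix (``M_`` species, ``R_`` reactions, ``G_`` genes, BiGG style)
followed by an ASCII escape of every forbidden character as ``__<ord>__``
(e.g. ``.`` becomes ``__46__``). Import reverses the convention.

Process metadata travels in notes: each provenance tag is a group of
``CATEGORY:`` / ``TOOL:`` / ``SOURCE:`` / ``STEP:`` / ``COMMENT:`` lines
(a ``CATEGORY:`` line starts a new tag). Pathway membership is written as a
BiGG-style ``SUBSYSTEM:`` reaction note, compound class membership as an
``IS_A:`` species note, class-typed species as ``OBJECT_TYPE: class``, and
attributes with no native SBML slot as ``ATTRIBUTE key: value`` lines.
Gene associations use fbc gene products on Level 3 and ``GENE_ASSOCIATION``
notes on Level 2 (both accepted on import). These note keys are this
package's documented convention; full-fidelity storage (proteins, arbitrary
relations) is the job of the flat format.
"""

from __future__ import annotations

import os
import re
from typing import Optional, Union

import libsbml

from .model import (
    Entity,
    GsmtraceError,
    Model,
    Relation,
    SourceTag,
    LEFT_TO_RIGHT,
    REVERSIBLE,
)


class SBMLError(GsmtraceError):
    """SBML parse or serialization failure."""


class UnsupportedLevelError(SBMLError):
    """Only SBML Level 2 and Level 3 core are supported."""


_PREFIXES = {"compound": "M_", "class": "M_", "reaction": "R_", "gene": "G_"}
_SID_OK = re.compile(r"[A-Za-z0-9_]")
_UNESCAPE = re.compile(r"__(\d+)__")
_NOTE_KEYS = ("CATEGORY", "TOOL", "SOURCE", "STEP", "COMMENT")

# escapes for values embedded in note lines (adds ',' to the flat set)
_NOTE_ESCAPES = [("%", "%25"), (",", "%2C"), (";", "%3B"), ("\n", "%0A")]


def escape_id(raw: str, etype: str = "compound") -> str:
    """Escape a store id into a legal SBML SId with a type prefix."""
    body = "".join(
        c if _SID_OK.fullmatch(c) else f"__{ord(c)}__" for c in raw
    )
    return _PREFIXES.get(etype, "X_") + body


def unescape_id(sid: str) -> str:
    """Reverse :func:`escape_id`; unknown prefixes are kept verbatim."""
    body = sid
    for prefix in ("M_", "R_", "G_", "X_"):
        if sid.startswith(prefix):
            body = sid[len(prefix):]
            break
    return _UNESCAPE.sub(lambda m: chr(int(m.group(1))), body)


def _esc_note(value: str) -> str:
    for char, code in _NOTE_ESCAPES:
        value = value.replace(char, code)
    return value


def _unesc_note(value: str) -> str:
    for char, code in reversed(_NOTE_ESCAPES):
        value = value.replace(code, char)
    return value


# ---------------------------------------------------------------- writing


def _notes_xml(lines: list[str]) -> str:
    body = "".join(f"<p>{line}</p>" for line in lines)
    return (
        '<notes><body xmlns="http://www.w3.org/1999/xhtml">'
        + body
        + "</body></notes>"
    )


def _tag_lines(model: Model, entity_id: str) -> list[str]:
    lines = []
    for tag in model.tags_of(entity_id):
        lines.append(f"CATEGORY:{_esc_note(tag.category)}")
        if tag.tool:
            lines.append(f"TOOL:{_esc_note(tag.tool)}")
        if tag.source:
            lines.append(f"SOURCE:{_esc_note(tag.source)}")
        if tag.step:
            lines.append(f"STEP:{tag.step}")
        if tag.comment:
            lines.append(f"COMMENT:{_esc_note(tag.comment)}")
    return lines


_NATIVE_ATTRS = {"direction", "common-name", "formula", "charge",
                 "compartment", "boundary"}


def _attribute_lines(entity: Entity) -> list[str]:
    lines = []
    for key in sorted(entity.attributes):
        if key in _NATIVE_ATTRS:
            continue
        for value in entity.attributes[key]:
            lines.append(f"ATTRIBUTE {_esc_note(key)}: {_esc_note(value)}")
    return lines


def write_sbml(model: Model, path: Union[str, os.PathLike], level: int = 3) -> None:
    """Export a model to SBML Level 3 (fbc) or Level 2.

    Raises :class:`UnsupportedLevelError` for other levels. Compartments
    default to ``c`` when compounds carry no ``compartment`` attribute.
    """
    model.validate()
    if level == 3:
        ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
        document = libsbml.SBMLDocument(ns)
        document.setPackageRequired("fbc", False)
    elif level == 2:
        document = libsbml.SBMLDocument(2, 4)
    else:
        raise UnsupportedLevelError(f"cannot write SBML level {level}")
    sbml_model = document.createModel()
    sbml_model.setId(escape_id(model.meta.get("model_id", "model"), "gene")[2:] or "model")
    use_fbc = level == 3
    fbc = sbml_model.getPlugin("fbc") if use_fbc else None
    if fbc is not None:
        fbc.setStrict(False)

    compartments = {"c"}
    for compound in model.entities.values():
        if compound.etype in ("compound", "class"):
            compartments.add(compound.first_attribute("compartment", "c"))
    for cid in sorted(compartments):
        compartment = sbml_model.createCompartment()
        compartment.setId(cid)
        compartment.setConstant(True)

    # model-level notes: pathway and reference-database bookkeeping
    model_lines = []
    if model.meta.get("ref_db"):
        model_lines.append(f"REF_DB: {_esc_note(model.meta['ref_db'])}")
    if model.meta.get("ref_db_version"):
        model_lines.append(f"REF_DB_VERSION: {_esc_note(model.meta['ref_db_version'])}")
    for pathway in sorted(model.entities_of_type("pathway"), key=lambda e: e.id):
        attrs = ";".join(
            f"{_esc_note(k)}={_esc_note(v)}"
            for k in sorted(pathway.attributes)
            for v in pathway.attributes[k]
        )
        model_lines.append(f"PATHWAY: {_esc_note(pathway.id)}|{attrs}")
    if model_lines:
        sbml_model.setNotes(_notes_xml(model_lines))

    for entity in sorted(model.entities.values(), key=lambda e: e.id):
        if entity.etype not in ("compound", "class"):
            continue
        species = sbml_model.createSpecies()
        species.setId(escape_id(entity.id, entity.etype))
        name = entity.first_attribute("common-name")
        if name:
            species.setName(name)
        species.setCompartment(entity.first_attribute("compartment", "c"))
        species.setBoundaryCondition(
            entity.first_attribute("boundary", "false") == "true"
        )
        species.setHasOnlySubstanceUnits(True)
        species.setConstant(False)
        formula = entity.first_attribute("formula")
        charge = entity.first_attribute("charge")
        lines = []
        if use_fbc:
            splug = species.getPlugin("fbc")
            if formula:
                splug.setChemicalFormula(formula)
            if charge is not None:
                splug.setCharge(int(float(charge)))
        else:
            if formula:
                lines.append(f"FORMULA: {_esc_note(formula)}")
            if charge is not None:
                lines.append(f"CHARGE: {_esc_note(charge)}")
        if entity.etype == "class":
            lines.append("OBJECT_TYPE: class")
        for rel in model.relations_from(entity.id, "is_a"):
            lines.append(f"IS_A: {_esc_note(rel.object)}")
        lines.extend(_attribute_lines(entity))
        lines.extend(_tag_lines(model, entity.id))
        if lines:
            species.setNotes(_notes_xml(lines))

    if use_fbc:
        for gene in sorted(model.entities_of_type("gene"), key=lambda e: e.id):
            product = fbc.createGeneProduct()
            product.setId(escape_id(gene.id, "gene"))
            product.setLabel(gene.id)

    for reaction in sorted(model.reactions(), key=lambda e: e.id):
        sbml_reaction = sbml_model.createReaction()
        sbml_reaction.setId(escape_id(reaction.id, "reaction"))
        name = reaction.first_attribute("common-name")
        if name:
            sbml_reaction.setName(name)
        sbml_reaction.setReversible(model.direction(reaction.id) == REVERSIBLE)
        sbml_reaction.setFast(False)
        for rel in model.relations_from(reaction.id, "consumes"):
            ref = sbml_reaction.createReactant()
            ref.setSpecies(escape_id(rel.object, model.entities[rel.object].etype))
            ref.setStoichiometry(rel.coefficient)
            ref.setConstant(True)
        for rel in model.relations_from(reaction.id, "produces"):
            ref = sbml_reaction.createProduct()
            ref.setSpecies(escape_id(rel.object, model.entities[rel.object].etype))
            ref.setStoichiometry(rel.coefficient)
            ref.setConstant(True)
        genes = model.genes_of(reaction.id)
        rule = reaction.first_attribute("gene-rule") or " or ".join(genes)
        lines = []
        if rule:
            lines.append(f"GENE_ASSOCIATION: {_esc_note(rule)}")
            if use_fbc and genes:
                rplug = sbml_reaction.getPlugin("fbc")
                assoc = rplug.createGeneProductAssociation()
                infix = " or ".join(escape_id(g, "gene") for g in genes)
                # usingId=True, addMissingGeneProducts=False: tokens are the
                # ids of the gene products created above
                assoc.setAssociation(infix, True, False)
        pathways = sorted(
            r.object for r in model.relations_from(reaction.id, "is_in_pathway")
        )
        if pathways:
            lines.append(
                "SUBSYSTEM: " + "; ".join(_esc_note(p) for p in pathways)
            )
        lines.extend(_attribute_lines(reaction))
        lines.extend(_tag_lines(model, reaction.id))
        if lines:
            sbml_reaction.setNotes(_notes_xml(lines))

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(document, str(path)):
        raise SBMLError(f"could not write SBML to {path}")


# ---------------------------------------------------------------- reading


def _note_lines(sbase) -> list[str]:
    notes = sbase.getNotesString() if sbase.isSetNotes() else ""
    if not notes:
        return []
    lines = re.findall(r"<p[^>]*>(.*?)</p>", notes, flags=re.S)
    return [re.sub(r"<[^>]+>", "", line).strip() for line in lines]


def _parse_tags(lines: list[str], entity_id: str) -> list[SourceTag]:
    tags = []
    current: Optional[dict] = None
    for line in lines:
        for key, value in re.findall(
            r"(CATEGORY|TOOL|SOURCE|STEP|COMMENT)\s*:\s*([^,]*)", line
        ):
            value = _unesc_note(value.strip())
            if key == "CATEGORY":
                if current:
                    tags.append(current)
                current = {"category": value}
            elif current is not None:
                current[key.lower()] = value
    if current:
        tags.append(current)
    return [
        SourceTag(
            entity_id,
            t["category"],
            t.get("tool", ""),
            t.get("source", ""),
            t.get("comment", ""),
            int(t.get("step", 0)),
        )
        for t in tags
    ]


def _gene_refs(association) -> list[str]:
    """Flatten an fbc association tree into gene-product SIds."""
    refs = []
    if association is None:
        return refs
    if association.isGeneProductRef():
        refs.append(association.getGeneProduct())
    else:
        for i in range(association.getNumAssociations()):
            refs.extend(_gene_refs(association.getAssociation(i)))
    return refs


_GENE_TOKEN = re.compile(r"[^\s()]+")


def _rule_genes(rule: str) -> list[str]:
    return sorted(
        {
            token
            for token in _GENE_TOKEN.findall(rule)
            if token.lower() not in ("and", "or", "not")
        }
    )


def read_sbml(path: Union[str, os.PathLike]) -> Model:
    """Import an SBML Level 2 / Level 3 core (+fbc) file.

    Species become compounds (or classes when flagged), reactions carry
    stoichiometry/reversibility/compartments, gene associations come from
    fbc or ``GENE_ASSOCIATION`` notes, and provenance note lines become
    source tags. Invalid XML raises :class:`SBMLError`; other levels raise
    :class:`UnsupportedLevelError`.
    """
    reader = libsbml.SBMLReader()
    document = reader.readSBMLFromFile(str(path))
    if document.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        first = document.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLError(f"invalid SBML in {path}: {first.getMessage().strip()}")
    if document.getLevel() not in (2, 3):
        raise UnsupportedLevelError(
            f"unsupported SBML level {document.getLevel()} in {path}"
        )
    sbml_model = document.getModel()
    if sbml_model is None:
        raise SBMLError(f"no <model> element in {path}")

    model = Model(model_id=unescape_id("G_" + sbml_model.getId())
                  if sbml_model.getId() else "model")
    pending_tags: list[SourceTag] = []
    is_a_links: list[tuple[str, str]] = []

    for line in _note_lines(sbml_model):
        if line.startswith("REF_DB_VERSION:"):
            model.meta["ref_db_version"] = _unesc_note(line.split(":", 1)[1].strip())
        elif line.startswith("REF_DB:"):
            model.meta["ref_db"] = _unesc_note(line.split(":", 1)[1].strip())
        elif line.startswith("PATHWAY:"):
            payload = line.split(":", 1)[1].strip()
            pid, _, attrs = payload.partition("|")
            entity = Entity(_unesc_note(pid), "pathway")
            for part in attrs.split(";"):
                if "=" in part:
                    key, value = part.split("=", 1)
                    entity.add_attribute(_unesc_note(key), _unesc_note(value))
            model.add_entity(entity)

    for i in range(sbml_model.getNumSpecies()):
        species = sbml_model.getSpecies(i)
        lines = _note_lines(species)
        etype = "class" if any(
            l.replace(" ", "") == "OBJECT_TYPE:class" for l in lines
        ) else "compound"
        entity = Entity(unescape_id(species.getId()), etype)
        if species.isSetName() and species.getName():
            entity.add_attribute("common-name", species.getName())
        if species.isSetCompartment() and species.getCompartment() != "c":
            entity.add_attribute("compartment", species.getCompartment())
        if species.getBoundaryCondition():
            entity.add_attribute("boundary", "true")
        splug = species.getPlugin("fbc")
        if splug is not None and splug.isSetChemicalFormula():
            entity.add_attribute("formula", splug.getChemicalFormula())
        if splug is not None and splug.isSetCharge():
            entity.add_attribute("charge", str(splug.getCharge()))
        for line in lines:
            if line.startswith("FORMULA:"):
                entity.add_attribute("formula", _unesc_note(line.split(":", 1)[1].strip()))
            elif line.startswith("CHARGE:"):
                entity.add_attribute("charge", _unesc_note(line.split(":", 1)[1].strip()))
            elif line.startswith("ATTRIBUTE "):
                key, _, value = line[len("ATTRIBUTE "):].partition(":")
                entity.add_attribute(_unesc_note(key.strip()), _unesc_note(value.strip()))
            elif line.startswith("IS_A:"):
                is_a_links.append(
                    (entity.id, _unesc_note(line.split(":", 1)[1].strip()))
                )
        model.add_entity(entity)
        pending_tags.extend(_parse_tags(lines, entity.id))

    for subject, obj in is_a_links:
        if obj not in model.entities:
            model.add_entity(Entity(obj, "class"))
        model.add_relation(Relation(subject, "is_a", obj))

    fbc = sbml_model.getPlugin("fbc")
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            product = fbc.getGeneProduct(i)
            gene_id = product.getLabel() or unescape_id(product.getId())
            model.add_entity(Entity(gene_id, "gene"))

    for i in range(sbml_model.getNumReactions()):
        sbml_reaction = sbml_model.getReaction(i)
        rid = unescape_id(sbml_reaction.getId())
        entity = Entity(rid, "reaction")
        if sbml_reaction.isSetName() and sbml_reaction.getName():
            entity.add_attribute("common-name", sbml_reaction.getName())
        if not sbml_reaction.getReversible():
            entity.add_attribute("direction", LEFT_TO_RIGHT)
        lines = _note_lines(sbml_reaction)
        rule = ""
        pathways: list[str] = []
        for line in lines:
            if line.startswith("GENE_ASSOCIATION:"):
                rule = _unesc_note(line.split(":", 1)[1].strip())
            elif line.startswith("SUBSYSTEM:"):
                pathways = [
                    _unesc_note(p.strip())
                    for p in line.split(":", 1)[1].split(";")
                    if p.strip()
                ]
            elif line.startswith("ATTRIBUTE "):
                key, _, value = line[len("ATTRIBUTE "):].partition(":")
                entity.add_attribute(_unesc_note(key.strip()), _unesc_note(value.strip()))
        model.add_entity(entity)
        pending_tags.extend(_parse_tags(lines, rid))

        for j in range(sbml_reaction.getNumReactants()):
            ref = sbml_reaction.getReactant(j)
            _add_participant(model, rid, "consumes", ref)
        for j in range(sbml_reaction.getNumProducts()):
            ref = sbml_reaction.getProduct(j)
            _add_participant(model, rid, "produces", ref)

        genes: list[str] = []
        rplug = sbml_reaction.getPlugin("fbc")
        if rplug is not None and rplug.isSetGeneProductAssociation():
            sids = _gene_refs(rplug.getGeneProductAssociation().getAssociation())
            for sid in sids:
                product = fbc.getGeneProduct(sid)
                genes.append(
                    product.getLabel() if product is not None and product.getLabel()
                    else unescape_id(sid)
                )
        elif rule:
            genes = _rule_genes(rule)
        if rule:
            model.entities[rid].add_attribute("gene-rule", rule)
        for gene in sorted(set(genes)):
            model.add_entity(Entity(gene, "gene"))
            model.add_relation(Relation(gene, "is_linked_to", rid))

        for pathway in pathways:
            if pathway not in model.entities:
                model.add_entity(Entity(pathway, "pathway"))
            model.add_relation(Relation(rid, "is_in_pathway", pathway))

    for tag in pending_tags:
        model.add_tag(tag)
    model.validate()
    return model


def _add_participant(model: Model, rid: str, rtype: str, ref) -> None:
    species_id = unescape_id(ref.getSpecies())
    if species_id not in model.entities:
        model.add_entity(Entity(species_id, "compound"))
    attributes = {}
    stoich = ref.getStoichiometry()
    if stoich != 1.0 and stoich == stoich:  # NaN-safe
        attributes["coefficient"] = ["%g" % stoich]
    model.add_relation(Relation(rid, rtype, species_id, attributes))
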