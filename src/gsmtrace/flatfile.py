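"""Tab-separated flat dialect for the model store.

Three sections introduced by ``[entities]``, ``[relations]`` and ``[tags]``
header lines; UTF-8, LF line endings. Attribute multimaps are serialized as
``key=value;key=value`` with a repeated key per extra value, preserving the
in-memory value order, so a write/read cycle is the identity and a second
write is byte-stable. Model metadata (model id, reference database) rides in
``#! key<TAB>value`` comment lines so the body stays within the three-section
dialect. ``%``-escapes protect the separator characters inside values.
"""

from __future__ import annotations

import io
import os
from typing import Union

from .model import Entity, GsmtraceError, IntegrityError, Model, Relation, SourceTag

_ESCAPES = [("%", "%25"), ("\t", "%09"), ("\n", "%0A"), (";", "%3B"), ("=", "%3D")]


class FlatParseError(GsmtraceError):
    """Malformed flat-file line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


def _escape(value: str) -> str:
    for char, code in _ESCAPES:
        value = value.replace(char, code)
    return value


def _unescape(value: str) -> str:
    for char, code in reversed(_ESCAPES):
        value = value.replace(code, char)
    return value


def _format_attributes(attributes: dict[str, list[str]]) -> str:
    parts = []
    for key in sorted(attributes):
        for value in attributes[key]:
            parts.append(f"{_escape(key)}={_escape(value)}")
    return ";".join(parts)


def _parse_attributes(text: str, lineno: int) -> dict[str, list[str]]:
    attributes: dict[str, list[str]] = {}
    if not text:
        return attributes
    for part in text.split(";"):
        if "=" not in part:
            raise FlatParseError(lineno, f"attribute {part!r} lacks '='")
        key, value = part.split("=", 1)
        attributes.setdefault(_unescape(key), []).append(_unescape(value))
    return attributes


def write_flat(model: Model, path: Union[str, os.PathLike]) -> None:
    """Serialize a model; deterministic (sorted) ordering within sections."""
    model.validate()
    buffer = io.StringIO()
    for key in ("model_id", "ref_db", "ref_db_version"):
        value = model.meta.get(key, "")
        if value:
            buffer.write(f"#! {key}\t{_escape(value)}\n")
    buffer.write("[entities]\n")
    for eid in sorted(model.entities):
        entity = model.entities[eid]
        buffer.write(
            f"{_escape(eid)}\t{entity.etype}\t{_format_attributes(entity.attributes)}\n"
        )
    buffer.write("[relations]\n")
    for key in sorted(model.relations):
        relation = model.relations[key]
        buffer.write(
            f"{_escape(relation.subject)}\t{relation.rtype}\t{_escape(relation.object)}"
            f"\t{_format_attributes(relation.attributes)}\n"
        )
    buffer.write("[tags]\n")
    for key in sorted(model.tags):
        tag = model.tags[key]
        buffer.write(
            f"{_escape(tag.entity)}\t{tag.category}\t{_escape(tag.tool)}"
            f"\t{_escape(tag.source)}\t{tag.step}\t{_escape(tag.comment)}\n"
        )
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write(buffer.getvalue())


def read_flat(path: Union[str, os.PathLike]) -> Model:
    """Parse the flat dialect back into a model.

    Malformed lines raise :class:`FlatParseError` with the line number;
    a relation or tag naming an unknown id raises :class:`IntegrityError`
    listing the id.
    """
    model = Model()
    section = None
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#!"):
                fields = line[2:].strip().split("\t")
                if len(fields) == 2:
                    model.meta[fields[0]] = _unescape(fields[1])
                continue
            if line.startswith("#"):
                continue
            if line in ("[entities]", "[relations]", "[tags]"):
                section = line[1:-1]
                continue
            fields = line.split("\t")
            try:
                if section == "entities":
                    if len(fields) != 3:
                        raise FlatParseError(
                            lineno, f"entity line needs 3 fields, got {len(fields)}"
                        )
                    model.add_entity(
                        Entity(
                            _unescape(fields[0]),
                            fields[1],
                            _parse_attributes(fields[2], lineno),
                        )
                    )
                elif section == "relations":
                    if len(fields) != 4:
                        raise FlatParseError(
                            lineno, f"relation line needs 4 fields, got {len(fields)}"
                        )
                    model.add_relation(
                        Relation(
                            _unescape(fields[0]),
                            fields[1],
                            _unescape(fields[2]),
                            _parse_attributes(fields[3], lineno),
                        )
                    )
                elif section == "tags":
                    if len(fields) != 6:
                        raise FlatParseError(
                            lineno, f"tag line needs 6 fields, got {len(fields)}"
                        )
                    model.add_tag(
                        SourceTag(
                            _unescape(fields[0]),
                            fields[1],
                            _unescape(fields[2]),
                            _unescape(fields[3]),
                            _unescape(fields[5]),
                            int(fields[4]),
                        )
                    )
                else:
                    raise FlatParseError(lineno, "content before any section header")
            except IntegrityError:
                raise
            except FlatParseError:
                raise
            except GsmtraceError as exc:
                raise FlatParseError(lineno, str(exc)) from exc
            except ValueError as exc:
                raise FlatParseError(lineno, str(exc)) from exc
    model.validate()
    return model
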