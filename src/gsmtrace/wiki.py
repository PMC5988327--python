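"""Static wiki export: one browsable page per model entity.

The wiki is a local, regenerable view of the model and its process
metadata: per-entity pages (a reaction page lists reactants/products with
coefficients, genes, pathways and provenance badges), per-type index pages,
per-category/tool/source provenance pages, and a pathway index sortable by
completion rate. It is plain static hypertext — it is not meant to be
edited, only re-generated after each pipeline step, so output is
deterministic (byte-identical for an identical model) and all internal
links resolve by construction.

External database links are URL templates keyed by the reference-database
name; they are emitted even when unverifiable offline.
"""

from __future__ import annotations

import os
import re
from pathlib import Path
from typing import Optional, Union

from jinja2 import Environment, BaseLoader, select_autoescape

from .model import Model
from .report import CompletenessReport, pathway_completeness

#: default external hyperlink templates per reference database
LINK_TEMPLATES = {
    "metacyc": "https://metacyc.org/META/NEW-IMAGE?object={id}",
    "bigg": "http://bigg.ucsd.edu/search?query={id}",
    "seed": "https://modelseed.org/biochem/reactions/{id}",
}

ETYPES = ("reaction", "compound", "gene", "pathway", "protein", "class")

_SAFE = re.compile(r"[A-Za-z0-9_-]")


def _page_name(entity_id: str) -> str:
    body = "".join(c if _SAFE.fullmatch(c) else f"__{ord(c)}__" for c in entity_id)
    return f"e_{body}.html"


_BASE = """<!DOCTYPE html>
<html lang="en"><head><meta charset="utf-8">
<title>{{ title }}</title>
<link rel="stylesheet" href="style.css">
</head><body>
<nav>
<a href="index.html">model</a>
{% for etype in etypes %} | <a href="type_{{ etype }}.html">{{ etype }}s</a>{% endfor %}
 | <a href="provenance.html">provenance</a>
</nav>
<h1>{{ title }}</h1>
{% block content %}{% endblock %}
</body></html>
"""

_INDEX = """{% extends "base" %}{% block content %}
<table><tr><th>entity type</th><th>count</th></tr>
{% for etype, n in counts %}<tr><td><a href="type_{{ etype }}.html">{{ etype }}</a></td><td>{{ n }}</td></tr>
{% endfor %}</table>
<p>{{ n_relations }} relations, {{ n_tags }} provenance tags.</p>
{% endblock %}
"""

_TYPE_INDEX = """{% extends "base" %}{% block content %}
{% if rows %}<table><tr><th>id</th>{% if with_ratio %}<th>completion rate</th>{% endif %}</tr>
{% for row in rows %}<tr><td><a href="{{ row.page }}">{{ row.id }}</a></td>{% if with_ratio %}<td>{{ row.ratio }}</td>{% endif %}</tr>
{% endfor %}</table>{% else %}<p>none</p>{% endif %}
{% endblock %}
"""

_ENTITY = """{% extends "base" %}{% block content %}
<p>type: {{ entity.etype }}</p>
{% if external %}<p>external: <a href="{{ external }}">{{ entity.id }}</a></p>{% endif %}
{% if attributes %}<h2>Attributes</h2><table>
{% for key, value in attributes %}<tr><th>{{ key }}</th><td>{{ value }}</td></tr>
{% endfor %}</table>{% endif %}
{% for section, rows in sections %}{% if rows %}<h2>{{ section }}</h2><ul>
{% for row in rows %}<li><a href="{{ row.page }}">{{ row.id }}</a>{% if row.extra %} ({{ row.extra }}){% endif %}</li>
{% endfor %}</ul>{% endif %}{% endfor %}
{% if tags %}<h2>Provenance</h2><table>
<tr><th>category</th><th>tool</th><th>source</th><th>step</th><th>comment</th></tr>
{% for tag in tags %}<tr><td><span class="badge {{ tag.category }}">{{ tag.category }}</span></td>
<td><a href="{{ tag.tool_page }}">{{ tag.tool }}</a></td>
<td><a href="{{ tag.source_page }}">{{ tag.source }}</a></td>
<td>{{ tag.step }}</td><td>{{ tag.comment }}</td></tr>
{% endfor %}</table>{% endif %}
{% endblock %}
"""

_PROVENANCE = """{% extends "base" %}{% block content %}
{% for kind, groups in sections %}<h2>by {{ kind }}</h2><ul>
{% for group in groups %}<li><a href="{{ group.page }}">{{ group.name }}</a> ({{ group.n }} entities)</li>
{% endfor %}</ul>{% endfor %}
{% endblock %}
"""

_GROUP = """{% extends "base" %}{% block content %}
<ul>{% for row in rows %}<li><a href="{{ row.page }}">{{ row.id }}</a></li>
{% endfor %}</ul>
{% endblock %}
"""

_STYLE = """body { font-family: sans-serif; margin: 2em; }
nav { border-bottom: 1px solid #999; padding-bottom: 0.5em; }
table { border-collapse: collapse; }
td, th { border: 1px solid #ccc; padding: 0.2em 0.6em; text-align: left; }
.badge { padding: 0.1em 0.4em; border-radius: 0.3em; color: #000; }
.badge.annotation { background: #f5d76e; }
.badge.orthology { background: #7fd17f; }
.badge.gap-filling { background: #7fb3e8; }
.badge.manual { background: #e8a8d8; }
"""


def _environment() -> Environment:
    templates = {
        "base": _BASE, "index": _INDEX, "type_index": _TYPE_INDEX,
        "entity": _ENTITY, "provenance": _PROVENANCE, "group": _GROUP,
    }

    class DictLoader(BaseLoader):
        def get_source(self, environment, name):
            return templates[name], name, lambda: True

    return Environment(loader=DictLoader(), autoescape=select_autoescape(default=True))


def _group_page(kind: str, value: str) -> str:
    return _page_name(f"{kind}@{value}").replace("e_", "prov_", 1)


def generate_wiki(
    model: Model,
    outdir: Union[str, os.PathLike],
    pathway_defs: Optional[Model] = None,
    link_templates: Optional[dict[str, str]] = None,
) -> list[str]:
    """Render the static site into ``outdir``; returns the page list.

    ``pathway_defs`` enables completion rates on the pathway index; the
    reference database named in ``model.meta`` selects the external link
    template (override with ``link_templates``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    env = _environment()
    templates = dict(link_templates or LINK_TEMPLATES)
    ref_db = model.meta.get("ref_db", "").lower()
    external_template = templates.get(ref_db)
    pages: list[str] = []

    completeness: Optional[CompletenessReport] = None
    if pathway_defs is not None:
        completeness = pathway_completeness(model, pathway_defs)

    def write(name: str, template: str, **context) -> None:
        html = env.get_template(template).render(etypes=ETYPES, **context)
        (outdir / name).write_text(html, encoding="utf-8", newline="\n")
        pages.append(name)

    (outdir / "style.css").write_text(_STYLE, encoding="utf-8", newline="\n")
    pages.append("style.css")

    counts = model.entity_counts()
    write(
        "index.html", "index",
        title=f"Model {model.meta.get('model_id', '')}",
        counts=[(etype, counts[etype]) for etype in ETYPES],
        n_relations=len(model.relations),
        n_tags=len(model.tags),
    )

    for etype in ETYPES:
        entities = sorted(model.entities_of_type(etype), key=lambda e: e.id)
        if etype == "pathway" and completeness is not None:
            ratios = {row.pathway: f"{row.ratio:.2f}" for row in completeness.rows}
            rows = [
                {"id": e.id, "page": _page_name(e.id), "ratio": ratios.get(e.id, "-")}
                for e in entities
            ]
            rows.sort(key=lambda r: (
                r["ratio"] == "-",
                -(float(r["ratio"]) if r["ratio"] != "-" else 0.0),
                r["id"],
            ))
            write(f"type_{etype}.html", "type_index",
                  title=f"{etype}s", rows=rows, with_ratio=True)
        else:
            rows = [{"id": e.id, "page": _page_name(e.id)} for e in entities]
            write(f"type_{etype}.html", "type_index",
                  title=f"{etype}s", rows=rows, with_ratio=False)

    # provenance navigation: one page per category/tool/source value
    groups: dict[str, dict[str, set[str]]] = {
        "category": {}, "tool": {}, "source": {},
    }
    for tag in model.tags.values():
        for kind in groups:
            value = getattr(tag, kind)
            if value:
                groups[kind].setdefault(value, set()).add(tag.entity)
    write(
        "provenance.html", "provenance",
        title="Reconstruction provenance",
        sections=[
            (
                kind,
                [
                    {"name": value, "page": _group_page(kind, value), "n": len(ids)}
                    for value, ids in sorted(groups[kind].items())
                ],
            )
            for kind in ("category", "tool", "source")
        ],
    )
    for kind, values in groups.items():
        for value, ids in sorted(values.items()):
            write(
                _group_page(kind, value), "group",
                title=f"{kind}: {value}",
                rows=[{"id": eid, "page": _page_name(eid)} for eid in sorted(ids)],
            )

    for entity in sorted(model.entities.values(), key=lambda e: e.id):
        sections = []
        if entity.etype == "reaction":
            sections = [
                ("Reactants", _participants(model, entity.id, "consumes")),
                ("Products", _participants(model, entity.id, "produces")),
                ("Genes", [
                    {"id": g, "page": _page_name(g), "extra": ""}
                    for g in model.genes_of(entity.id)
                ]),
                ("Pathways", [
                    {"id": r.object, "page": _page_name(r.object), "extra": ""}
                    for r in sorted(model.relations_from(entity.id, "is_in_pathway"),
                                    key=lambda r: r.object)
                ]),
            ]
        elif entity.etype == "pathway":
            sections = [(
                "Member reactions",
                [
                    {"id": r.subject, "page": _page_name(r.subject),
                     "extra": ", ".join(
                         f"{t.category}" for t in model.tags_of(r.subject))}
                    for r in sorted(model.relations_to(entity.id, "is_in_pathway"),
                                    key=lambda r: r.subject)
                ],
            )]
        elif entity.etype in ("compound", "class"):
            sections = [
                ("Consumed by", [
                    {"id": r.subject, "page": _page_name(r.subject), "extra": ""}
                    for r in sorted(model.relations_to(entity.id, "consumes"),
                                    key=lambda r: r.subject)
                ]),
                ("Produced by", [
                    {"id": r.subject, "page": _page_name(r.subject), "extra": ""}
                    for r in sorted(model.relations_to(entity.id, "produces"),
                                    key=lambda r: r.subject)
                ]),
                ("Classes", [
                    {"id": r.object, "page": _page_name(r.object), "extra": ""}
                    for r in sorted(model.relations_from(entity.id, "is_a"),
                                    key=lambda r: r.object)
                ]),
            ]
        elif entity.etype == "gene":
            sections = [(
                "Catalysed reactions",
                [
                    {"id": r.object, "page": _page_name(r.object), "extra": ""}
                    for r in sorted(model.relations_from(entity.id, "is_linked_to"),
                                    key=lambda r: r.object)
                ],
            )]
        write(
            _page_name(entity.id), "entity",
            title=entity.id,
            entity=entity,
            external=(
                external_template.format(id=entity.id)
                if external_template and entity.etype in ("reaction", "compound", "pathway")
                else None
            ),
            attributes=[
                (key, "; ".join(values))
                for key, values in sorted(entity.attributes.items())
            ],
            sections=sections,
            tags=[
                {
                    "category": tag.category,
                    "tool": tag.tool or "-",
                    "source": tag.source or "-",
                    "step": tag.step,
                    "comment": tag.comment,
                    "tool_page": _group_page("tool", tag.tool) if tag.tool
                    else "provenance.html",
                    "source_page": _group_page("source", tag.source) if tag.source
                    else "provenance.html",
                }
                for tag in model.tags_of(entity.id)
            ],
        )
    return pages


def _participants(model: Model, reaction_id: str, rtype: str) -> list[dict]:
    rows = []
    for relation in sorted(model.relations_from(reaction_id, rtype),
                           key=lambda r: r.object):
        coeff = relation.coefficient
        rows.append({
            "id": relation.object,
            "page": _page_name(relation.object),
            "extra": "" if coeff == 1.0 else "%g" % coeff,
        })
    return rows
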