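"""Model analyses: pathway completeness, provenance breakdown, quality checks.

These are the reports a curator watches while a reconstruction progresses:
which reference pathways are nearly complete (good gap-filling candidates),
how the reconstruction categories overlap (what annotation found that
orthology did not, and vice versa), and basic structural quality (fraction
of reactions with a gene association, mass/charge balance of reactions
whose participants carry formulas).
"""

from __future__ import annotations

import os
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Union

from .model import GsmtraceError, Model


# ------------------------------------------------------ pathway completeness


@dataclass
class PathwayCompleteness:
    pathway: str
    total: int
    present: int
    missing: list[str]

    @property
    def ratio(self) -> float:
        return self.present / self.total


@dataclass
class CompletenessReport:
    """Per-pathway completion rates, sorted descending by ratio then id."""

    rows: list[PathwayCompleteness] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)  # pathways defining 0 reactions

    def for_pathway(self, pathway_id: str) -> Optional[PathwayCompleteness]:
        for row in self.rows:
            if row.pathway == pathway_id:
                return row
        return None

    def to_tsv(self, path: Union[str, os.PathLike]) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as handle:
            handle.write("pathway\ttotal\tpresent\tratio\tmissing\n")
            for row in self.rows:
                handle.write(
                    f"{row.pathway}\t{row.total}\t{row.present}"
                    f"\t{row.ratio:.3f}\t{','.join(row.missing)}\n"
                )


def pathway_completeness(model: Model, pathway_defs: Model) -> CompletenessReport:
    """Fraction of each reference pathway's reactions present in the model.

    ``pathway_defs`` lists member reactions through ``is_in_pathway``
    relations (typically the reference database itself). A defined member
    counts as present when the model contains it directly or contains an
    instantiated variant of it (a reaction whose ``instance-of`` attribute
    names the member) — class-written database reactions are routinely
    replaced by concrete variants during gap-filling. Pathways defining no
    reactions are excluded and reported.
    """
    variants_of: dict[str, list[str]] = {}
    for reaction in model.reactions():
        for parent in reaction.get_attribute("instance-of"):
            variants_of.setdefault(parent, []).append(reaction.id)

    report = CompletenessReport()
    for pathway in sorted(pathway_defs.entities_of_type("pathway"), key=lambda e: e.id):
        members = sorted(
            r.subject for r in pathway_defs.relations_to(pathway.id, "is_in_pathway")
        )
        if not members:
            report.excluded.append(pathway.id)
            continue
        missing = [
            m for m in members
            if m not in model.entities and m not in variants_of
        ]
        report.rows.append(
            PathwayCompleteness(
                pathway=pathway.id,
                total=len(members),
                present=len(members) - len(missing),
                missing=missing,
            )
        )
    report.rows.sort(key=lambda row: (-row.ratio, row.pathway))
    return report


# ------------------------------------------------------ provenance breakdown


@dataclass
class ProvenanceBreakdown:
    """Set algebra over provenance tag groups.

    ``groups`` maps each value of the grouping key (category, tool or
    source) to the set of tagged entity ids; ``overlap`` holds the pairwise
    intersection sizes and ``exclusive`` the count of entities tagged in
    exactly one group. The counts always publish overlaps explicitly —
    reconstruction categories are not disjoint (a reaction can be found by
    annotation *and* orthology) so marginal counts never sum to the union.
    """

    key: str
    groups: dict[str, set[str]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {name: len(ids) for name, ids in sorted(self.groups.items())}

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for ids in self.groups.values():
            out |= ids
        return out

    @property
    def overlap(self) -> dict[tuple[str, str], int]:
        names = sorted(self.groups)
        return {
            (a, b): len(self.groups[a] & self.groups[b])
            for i, a in enumerate(names)
            for b in names[i + 1:]
        }

    @property
    def exclusive(self) -> dict[str, int]:
        out = {}
        for name, ids in sorted(self.groups.items()):
            others: set[str] = set()
            for other, other_ids in self.groups.items():
                if other != name:
                    others |= other_ids
            out[name] = len(ids - others)
        return out


def provenance_breakdown(
    model: Model, key: str = "category", etype: Optional[str] = None
) -> ProvenanceBreakdown:
    """Group tagged entities by a tag field and count exactly.

    ``key`` is one of ``category``, ``tool``, ``source``; ``etype``
    optionally restricts the counted entities to one type.
    """
    if key not in ("category", "tool", "source"):
        raise GsmtraceError(f"breakdown key must be category/tool/source, not {key!r}")
    breakdown = ProvenanceBreakdown(key=key)
    for tag in model.tags.values():
        if etype is not None:
            entity = model.entities.get(tag.entity)
            if entity is None or entity.etype != etype:
                continue
        value = getattr(tag, key)
        breakdown.groups.setdefault(value, set()).add(tag.entity)
    return breakdown


# ------------------------------------------------------------- quality


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Counter:
    """Parse a Hill-notation chemical formula into element counts.

    Polymer and R-group formulas (anything with characters outside element
    symbols and digits, e.g. ``(C5H8)n`` or ``CHR``-style generics with an
    unknown rest) raise ValueError and make the reaction *undetermined*.
    """
    counts: Counter = Counter()
    position = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != position:
            raise ValueError(f"unparsable formula {formula!r}")
        counts[match.group(1)] += int(match.group(2) or 1)
        position = match.end()
    if position != len(formula) or not counts:
        raise ValueError(f"unparsable formula {formula!r}")
    return counts


@dataclass
class QualityReport:
    gene_association_ratio: float  # percentage over non-exchange reactions
    mass_unbalanced: dict[str, dict[str, float]]  # reaction -> element deltas
    charge_unbalanced: dict[str, float]  # reaction -> charge delta
    undetermined: dict[str, str]  # reaction -> offending formula / reason
    counts: dict[str, int]


def _is_exchange(model: Model, reaction_id: str) -> bool:
    entity = model.entities[reaction_id]
    if entity.first_attribute("exchange", "false") == "true":
        return True
    return not model.reactants_of(reaction_id) or not model.products_of(reaction_id)


def quality_report(model: Model, exclude_exchange: bool = True) -> QualityReport:
    """Structural quality checks.

    The gene-association ratio is the percentage of reactions with at least
    one gene link, computed over non-exchange reactions by default
    (boundary/exchange reactions have no enzyme and would dilute the ratio;
    set ``exclude_exchange=False`` to count them). Mass balance is the
    per-element signed sum of coefficient x formula counts over products
    minus reactants; charge balance is the analogous scalar. A reaction with
    any participant lacking a parsable formula is reported *undetermined*,
    never balanced.
    """
    reactions = sorted(e.id for e in model.reactions())
    denominator = [
        rid for rid in reactions
        if not (exclude_exchange and _is_exchange(model, rid))
    ]
    with_genes = sum(1 for rid in denominator if model.genes_of(rid))
    ratio = round(100.0 * with_genes / len(denominator), 1) if denominator else 0.0

    mass_unbalanced: dict[str, dict[str, float]] = {}
    charge_unbalanced: dict[str, float] = {}
    undetermined: dict[str, str] = {}
    for rid in reactions:
        participants = (
            [(r, -r.coefficient) for r in model.relations_from(rid, "consumes")]
            + [(r, r.coefficient) for r in model.relations_from(rid, "produces")]
        )
        if not participants:
            continue
        element_delta: Counter = Counter()
        charge_delta = 0.0
        determinable = True
        for relation, signed_coeff in participants:
            compound = model.entities[relation.object]
            formula = compound.first_attribute("formula")
            if formula is None:
                undetermined[rid] = f"{relation.object}: no formula"
                determinable = False
                break
            try:
                counts = parse_formula(formula)
            except ValueError:
                undetermined[rid] = f"{relation.object}: {formula}"
                determinable = False
                break
            for element, n in counts.items():
                element_delta[element] += signed_coeff * n
            charge_delta += signed_coeff * float(
                compound.first_attribute("charge", "0")
            )
        if not determinable:
            continue
        deltas = {el: d for el, d in sorted(element_delta.items()) if d != 0}
        if deltas:
            mass_unbalanced[rid] = deltas
        if charge_delta != 0:
            charge_unbalanced[rid] = charge_delta

    counts = model.entity_counts()
    return QualityReport(
        gene_association_ratio=ratio,
        mass_unbalanced=mass_unbalanced,
        charge_unbalanced=charge_unbalanced,
        undetermined=undetermined,
        counts={
            "reactions": counts["reaction"],
            "compounds": counts["compound"],
            "genes": counts["gene"],
            "pathways": counts["pathway"],
        },
    )
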