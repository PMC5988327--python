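"""Completeness, provenance-breakdown and quality reports."""

import random

import pytest

from gsmtrace import (
    Entity,
    Model,
    Relation,
    SourceTag,
    gapfill,
    merge_models,
    parse_formula,
    pathway_completeness,
    provenance_breakdown,
    quality_report,
)


def pathway_defs_model(n_reactions=8, pathway="PWY-X"):
    model = Model()
    model.add_entity(Entity(pathway, "pathway"))
    for i in range(n_reactions):
        rid = f"r{i}"
        model.add_entity(Entity(rid, "reaction"))
        model.add_relation(Relation(rid, "is_in_pathway", pathway))
    return model


class TestCompleteness:
    def test_direct_ratio_and_missing_ids(self):
        defs = pathway_defs_model(8)
        model = Model()
        for i in range(6):
            model.add_entity(Entity(f"r{i}", "reaction"))
        report = pathway_completeness(model, defs)
        row = report.for_pathway("PWY-X")
        assert row.present == 6 and row.total == 8
        assert row.ratio == 0.75
        assert row.missing == ["r6", "r7"]

    def test_absent_pathway_scores_zero(self):
        report = pathway_completeness(Model(), pathway_defs_model(4))
        assert report.for_pathway("PWY-X").ratio == 0.0

    def test_zero_reaction_pathway_excluded(self):
        defs = Model()
        defs.add_entity(Entity("PWY-EMPTY", "pathway"))
        report = pathway_completeness(Model(), defs)
        assert report.rows == []
        assert report.excluded == ["PWY-EMPTY"]

    def test_folate_completion_reaches_one_after_gapfill(self, folate):
        before = pathway_completeness(folate.draft, folate.pathway_defs)
        assert before.for_pathway("PWY-6614").ratio < 1.0
        completions = gapfill(folate.draft, folate.database, folate.seeds,
                              folate.targets, max_size=2)
        filled = folate.draft.copy()
        for rid in completions[0].reactions:
            filled.add_entity(folate.database.entities[rid])
            for relation in folate.database.relations_from(rid):
                if relation.object not in filled.entities:
                    filled.add_entity(folate.database.entities[relation.object])
                filled.add_relation(relation)
        after = pathway_completeness(filled, folate.pathway_defs)
        assert after.for_pathway("PWY-6147").ratio == 1.0
        assert after.for_pathway("PWY-6614").ratio == 1.0

    def test_invariant_under_consistent_renaming(self):
        defs = pathway_defs_model(5)
        model = Model()
        for i in range(3):
            model.add_entity(Entity(f"r{i}", "reaction"))
        before = pathway_completeness(model, defs).for_pathway("PWY-X").ratio

        def rename(m):
            out = Model()
            for entity in m.entities.values():
                clone = entity.copy()
                clone.id = "zz-" + clone.id if entity.etype == "reaction" else clone.id
                out.add_entity(clone)
            for relation in m.relations.values():
                subject = ("zz-" + relation.subject
                           if m.entities[relation.subject].etype == "reaction"
                           else relation.subject)
                out.add_relation(Relation(subject, relation.rtype, relation.object))
            return out

        after = pathway_completeness(
            rename(model), rename(defs)).for_pathway("PWY-X").ratio
        assert before == after

    def test_sorted_descending_by_ratio(self, folate):
        report = pathway_completeness(folate.draft, folate.pathway_defs)
        ratios = [row.ratio for row in report.rows]
        assert ratios == sorted(ratios, reverse=True)


def two_category_model(n_a, n_b, n_both):
    """Protein entities tagged annotation (n_a total) / orthology (n_b total)
    with n_both tagged by both, built through a real merge."""
    base = Model()
    for i in range(n_a):
        base.add_entity(Entity(f"E{i:04d}", "protein"),
                        SourceTag(f"E{i:04d}", "annotation", "pathway-tools"))
    addition = Model()
    start = n_a - n_both
    for i in range(start, start + n_b):
        addition.add_entity(Entity(f"E{i:04d}", "protein"))
    return merge_models(base, addition, "orthology", "pantograph")


class TestProvenanceBreakdown:
    def test_annotation_orthology_overlap_arithmetic(self):
        # 898 annotation, 790 orthology, 524 found by both
        model = two_category_model(898, 790, 524)
        breakdown = provenance_breakdown(model, "category", etype="protein")
        assert breakdown.counts == {"annotation": 898, "orthology": 790}
        assert len(breakdown.union) == 1164
        assert breakdown.overlap[("annotation", "orthology")] == 524
        assert breakdown.exclusive == {"annotation": 374, "orthology": 266}

    def test_single_category_has_no_overlap(self):
        model = Model()
        for i in range(5):
            model.add_entity(Entity(f"r{i}", "reaction"),
                             SourceTag(f"r{i}", "annotation"))
        breakdown = provenance_breakdown(model)
        assert breakdown.overlap == {}
        assert breakdown.exclusive == {"annotation": 5}

    @pytest.mark.parametrize("seed", range(6))
    def test_inclusion_exclusion_on_random_assignments(self, seed):
        rng = random.Random(seed)
        model = Model()
        categories = ["annotation", "orthology", "gap-filling", "manual"]
        assigned = {}
        for i in range(40):
            rid = f"r{i}"
            model.add_entity(Entity(rid, "reaction"))
            mine = rng.sample(categories, rng.randint(1, 3))
            assigned[rid] = set(mine)
            for category in mine:
                model.add_tag(SourceTag(rid, category))
        breakdown = provenance_breakdown(model)
        # brute-force recount
        for name, ids in breakdown.groups.items():
            assert ids == {r for r, cats in assigned.items() if name in cats}
        for (a, b), n in breakdown.overlap.items():
            only_a = len(breakdown.groups[a] - breakdown.groups[b])
            only_b = len(breakdown.groups[b] - breakdown.groups[a])
            assert only_a + only_b + n == len(breakdown.groups[a] | breakdown.groups[b])

    def test_breakdown_by_tool_and_source(self):
        model = Model()
        model.add_entity(Entity("r", "reaction"))
        model.add_tag(SourceTag("r", "orthology", "pantograph", "a-thaliana"))
        by_tool = provenance_breakdown(model, "tool")
        by_source = provenance_breakdown(model, "source")
        assert by_tool.counts == {"pantograph": 1}
        assert by_source.counts == {"a-thaliana": 1}


class TestQuality:
    def _reaction(self, model, rid, reactants, products, coeffs=None):
        model.add_entity(Entity(rid, "reaction"))
        for cid in reactants:
            model.add_relation(Relation(
                rid, "consumes", cid,
                {"coefficient": [str((coeffs or {}).get(cid, 1))]}))
        for cid in products:
            model.add_relation(Relation(
                rid, "produces", cid,
                {"coefficient": [str((coeffs or {}).get(cid, 1))]}))

    def test_glycolysis_style_split_is_balanced(self):
        model = Model()
        model.add_entity(Entity("GLC", "compound", {"formula": ["C6H12O6"]}))
        model.add_entity(Entity("LAC", "compound", {"formula": ["C3H6O3"]}))
        self._reaction(model, "split", ["GLC"], ["LAC"], {"LAC": 2})
        report = quality_report(model)
        assert report.mass_unbalanced == {}
        assert report.charge_unbalanced == {}
        assert report.undetermined == {}

    def test_unbalanced_deltas_reported(self):
        model = Model()
        model.add_entity(Entity("A", "compound",
                                {"formula": ["CH4"], "charge": ["0"]}))
        model.add_entity(Entity("B", "compound",
                                {"formula": ["CH3"], "charge": ["-1"]}))
        self._reaction(model, "r", ["A"], ["B"])
        report = quality_report(model)
        assert report.mass_unbalanced["r"] == {"H": -1}
        assert report.charge_unbalanced["r"] == -1

    def test_missing_formula_is_undetermined_never_balanced(self):
        model = Model()
        model.add_entity(Entity("A", "compound", {"formula": ["CH4"]}))
        model.add_entity(Entity("B", "compound"))
        self._reaction(model, "r", ["A"], ["B"])
        report = quality_report(model)
        assert "r" in report.undetermined
        assert "r" not in report.mass_unbalanced

    def test_polymer_formula_is_undetermined(self):
        model = Model()
        model.add_entity(Entity("A", "compound", {"formula": ["(C5H8)n"]}))
        model.add_entity(Entity("B", "compound", {"formula": ["C5H8"]}))
        self._reaction(model, "r", ["A"], ["B"])
        assert "r" in quality_report(model).undetermined

    def test_gene_ratio_five_of_seven(self):
        model = Model()
        model.add_entity(Entity("X", "compound"))
        model.add_entity(Entity("Y", "compound"))
        for i in range(7):
            self._reaction(model, f"r{i}", ["X"], ["Y"])
        for i in range(5):
            model.add_entity(Entity(f"g{i}", "gene"))
            model.add_relation(Relation(f"g{i}", "is_linked_to", f"r{i}"))
        assert quality_report(model).gene_association_ratio == 71.4

    def test_exchange_reactions_excluded_from_ratio(self):
        model = Model()
        model.add_entity(Entity("X", "compound"))
        model.add_entity(Entity("Y", "compound"))
        self._reaction(model, "core", ["X"], ["Y"])
        model.add_entity(Entity("g", "gene"))
        model.add_relation(Relation("g", "is_linked_to", "core"))
        # exchange: product-only pseudo reaction
        model.add_entity(Entity("EX_x", "reaction"))
        model.add_relation(Relation("EX_x", "produces", "X"))
        assert quality_report(model).gene_association_ratio == 100.0
        assert quality_report(model, exclude_exchange=False
                              ).gene_association_ratio == 50.0


class TestFormulaParser:
    @pytest.mark.parametrize("formula,expected", [
        ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
        ("H2O", {"H": 2, "O": 1}),
        ("Fe2S3", {"Fe": 2, "S": 3}),
        ("C", {"C": 1}),
    ])
    def test_hill_notation(self, formula, expected):
        assert dict(parse_formula(formula)) == expected

    @pytest.mark.parametrize("bad", ["(C5H8)n", "CHR-rest", "", "c6h12"])
    def test_rejects_non_hill(self, bad):
        with pytest.raises(ValueError):
            parse_formula(bad)
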