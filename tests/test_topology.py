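"""Producibility suite: scope, targets, unblocking, paths, gap-filling,
class instantiation — each checked against an independent oracle."""

import pytest

from gsmtrace import (
    Entity,
    GeneratorSpec,
    InfeasibleCompletionError,
    Model,
    NotProducibleError,
    OntologyCycleError,
    Relation,
    compute_scope,
    gapfill,
    instantiate_class_reactions,
    production_path,
    random_network,
    unblocking_compounds,
    unproducible_targets,
    verify_completion,
    REDUCTASE_VARIANT,
)
from conftest import (
    brute_force_completions,
    brute_force_unblocking,
    naive_scope,
    replay_path,
)


def build(reactions, reversible=()):
    """reactions: {rid: (reactants, products)}."""
    model = Model()
    compounds = set()
    for reactants, products in reactions.values():
        compounds.update(reactants, products)
    for cid in sorted(compounds):
        model.add_entity(Entity(cid, "compound"))
    for rid, (reactants, products) in reactions.items():
        attrs = {} if rid in reversible else {"direction": ["LEFT-TO-RIGHT"]}
        model.add_entity(Entity(rid, "reaction", attrs))
        for cid in reactants:
            model.add_relation(Relation(rid, "consumes", cid))
        for cid in products:
            model.add_relation(Relation(rid, "produces", cid))
    return model


class TestScope:
    def test_linear_chain_layers(self, chain_model):
        result = compute_scope(chain_model, ["A"])
        assert result.producible == {"A", "B", "C"}
        assert result.layer == {"A": 0, "B": 1, "C": 2}
        assert result.fired == {"r1", "r2"}

    def test_and_semantics_blocks_partial_reactants(self):
        model = build({"r1": (["A", "X"], ["B"])})
        result = compute_scope(model, ["A"])
        assert result.producible == {"A"}
        assert result.fired == set()

    def test_reversible_fires_both_ways(self):
        model = build({"r1": (["A"], ["B"])}, reversible={"r1"})
        assert compute_scope(model, ["B"]).producible == {"A", "B"}

    def test_self_loop_does_not_bootstrap(self):
        # A + B -> B + C: B on both sides must not make itself available
        model = build({"r1": (["A", "B"], ["B", "C"])})
        assert compute_scope(model, ["A"]).producible == {"A"}
        assert compute_scope(model, ["A", "B"]).producible == {"A", "B", "C"}

    def test_unknown_seed_warned_not_fatal(self, chain_model):
        result = compute_scope(chain_model, ["A", "ghost"])
        assert result.unknown_seeds == ["ghost"]
        assert "ghost" not in result.producible

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_naive_fixpoint_oracle(self, seed):
        network = random_network(GeneratorSpec(
            n_compounds=10 + seed % 30, n_reactions=8 + seed % 20,
            reversible_fraction=0.3, leak_probability=0.25, seed=seed,
        ))
        result = compute_scope(network.model, network.seeds)
        assert set(result.producible) == naive_scope(network.model, network.seeds)

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_in_seeds_and_reactions(self, seed):
        network = random_network(GeneratorSpec(
            n_compounds=15, n_reactions=12, leak_probability=0.3,
            reversible_fraction=0.2, seed=seed + 500,
        ))
        small = compute_scope(network.model, network.seeds[:1]).producible
        large = compute_scope(network.model, network.seeds).producible
        assert small <= large
        # removing a reaction never grows the scope
        model = network.model.copy()
        some_rid = sorted(e.id for e in model.reactions())[0]
        model.remove_entity(some_rid)
        assert compute_scope(model, network.seeds).producible <= large

    @pytest.mark.parametrize("seed", range(5))
    def test_fixpoint_idempotence(self, seed):
        network = random_network(GeneratorSpec(seed=seed + 900,
                                               leak_probability=0.2))
        scope = compute_scope(network.model, network.seeds)
        again = compute_scope(network.model, scope.producible)
        assert again.producible == scope.producible

    def test_layer_defined_exactly_on_producible(self, folate):
        full = folate.database
        result = compute_scope(full, folate.seeds)
        assert set(result.layer) == set(result.producible)


class TestTargets:
    def test_reachable_target_not_reported(self, chain_model):
        assert unproducible_targets(chain_model, ["A"], ["C"]) == set()

    def test_absent_target_reported(self, chain_model):
        assert unproducible_targets(chain_model, ["A"], ["D"]) == {"D"}

    @pytest.mark.parametrize("seed", range(8))
    def test_consistent_with_scope(self, seed):
        network = random_network(GeneratorSpec(leak_probability=0.3,
                                               seed=seed + 40))
        missing = unproducible_targets(network.model, network.seeds,
                                       network.targets)
        scope = naive_scope(network.model, network.seeds)
        assert missing == {t for t in network.targets if t not in scope}


class TestUnblocking:
    def test_minimal_sets_for_disconnected_producer(self):
        model = build({"r1": (["B"], ["C"])})
        model.add_entity(Entity("A", "compound"))
        result = unblocking_compounds(model, ["A"], ["C"], max_size=2)
        assert result.sets == [frozenset({"B"}), frozenset({"C"})]
        assert not result.exhausted_bound

    def test_producible_targets_need_nothing(self, chain_model):
        assert unblocking_compounds(chain_model, ["A"], ["C"]).sets == []

    def test_bound_exhaustion_then_success(self):
        model = build({"r1": (["B", "D"], ["C"])})
        model.add_entity(Entity("A", "compound"))
        bounded = unblocking_compounds(model, ["A"], ["C"], max_size=1)
        assert bounded.sets == [frozenset({"C"})]  # direct addition always works
        # without the direct escape hatch the bound is exhausted
        no_direct = unblocking_compounds(model, ["A"], ["X"], max_size=2)
        assert no_direct.exhausted_bound is False or no_direct.sets == []
        wide = unblocking_compounds(model, ["A"], ["C"], max_size=2)
        assert frozenset({"B", "D"}) in wide.sets

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        network = random_network(GeneratorSpec(
            n_compounds=10, n_reactions=8, leak_probability=0.4,
            seed=seed + 70,
        ))
        got = unblocking_compounds(network.model, network.seeds,
                                   network.targets, max_size=2)
        expected = brute_force_unblocking(network.model, network.seeds,
                                          network.targets, 2)
        if unproducible_targets(network.model, network.seeds, network.targets):
            assert got.sets == expected
        else:
            assert got.sets == []


class TestProductionPath:
    def test_chain_path_in_order(self, chain_model):
        assert production_path(chain_model, ["A"], "C") == ["r1", "r2"]

    def test_seed_target_has_empty_path(self, chain_model):
        assert production_path(chain_model, ["A"], "A") == []

    def test_unproducible_target_raises_with_precursors(self):
        model = build({"r1": (["A", "X"], ["B"])})
        with pytest.raises(NotProducibleError, match="X"):
            production_path(model, ["A"], "B")

    @pytest.mark.parametrize("seed", range(15))
    def test_replay_never_lacks_a_reactant(self, seed):
        network = random_network(GeneratorSpec(
            n_compounds=20, n_reactions=15, reversible_fraction=0.3,
            seed=seed + 300,
        ))
        scope = compute_scope(network.model, network.seeds)
        for target in sorted(scope.producible)[:5]:
            path = production_path(network.model, network.seeds, target)
            available = replay_path(network.model, network.seeds, path)
            assert target in available


class TestGapfill:
    def test_folate_unique_size1_completion(self, folate):
        completions = gapfill(folate.draft, folate.database, folate.seeds,
                              folate.targets, max_size=3, enumerate_all=True)
        minimal = [c for c in completions if c.flag == "one-minimal-solution"]
        assert len(minimal) == 1
        assert minimal[0].reactions == frozenset({REDUCTASE_VARIANT})
        assert verify_completion(folate.draft, folate.database, folate.seeds,
                                 folate.targets, minimal[0])

    def test_already_producible_gives_empty_completion(self, folate):
        completions = gapfill(folate.database, folate.database, folate.seeds,
                              folate.targets)
        assert len(completions) == 1
        assert completions[0].reactions == frozenset()

    def test_infeasible_lists_targets(self, folate):
        with pytest.raises(InfeasibleCompletionError, match="UNREACHABLE"):
            gapfill(folate.draft, folate.database, folate.seeds,
                    ["UNREACHABLE", "THF-GLU-N"], max_size=2)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_instances(self, seed):
        draft_net = random_network(GeneratorSpec(
            n_compounds=12, n_reactions=6, leak_probability=0.5,
            seed=seed + 1000,
        ))
        db_net = random_network(GeneratorSpec(
            n_compounds=12, n_reactions=10, leak_probability=0.1,
            seed=seed + 2000,
        ))
        # database reactions get distinct ids so they are real candidates
        database = Model()
        for entity in db_net.model.entities.values():
            clone = entity.copy()
            if entity.etype == "reaction":
                clone.id = "DB-" + entity.id
            database.add_entity(clone)
        for relation in db_net.model.relations.values():
            subject = ("DB-" + relation.subject
                       if relation.subject.startswith("R") else relation.subject)
            database.add_relation(Relation(subject, relation.rtype,
                                           relation.object, relation.attributes))
        targets = db_net.targets
        expected = brute_force_completions(
            draft_net.model, database, draft_net.seeds, targets, 3)
        try:
            got = gapfill(draft_net.model, database, draft_net.seeds, targets,
                          max_size=3, enumerate_all=True)
        except InfeasibleCompletionError:
            assert expected == []
            return
        minimal = {c.reactions for c in got if c.flag == "one-minimal-solution"}
        if got.exhausted_bound:
            assert expected == []
        else:
            assert minimal == set(expected)
            for completion in got:
                if completion.flag == "one-minimal-solution":
                    assert verify_completion(
                        draft_net.model, database, draft_net.seeds, targets,
                        completion)

    def test_enumeration_reports_union_and_intersection(self):
        draft = build({"r0": (["A"], ["B"])})
        draft.add_entity(Entity("T", "compound"))
        database = build({
            "d1": (["B"], ["T"]),
            "d2": (["B"], ["T", "Z"]),
        })
        got = gapfill(draft, database, ["A"], ["T"], max_size=2,
                      enumerate_all=True)
        flags = [c.flag for c in got]
        assert flags.count("one-minimal-solution") == 2
        union = next(c for c in got if c.flag == "union-of-minimal")
        inter = next(c for c in got if c.flag == "intersection-of-minimal")
        assert union.reactions == {"d1", "d2"}
        assert inter.reactions == frozenset()

    def test_heuristic_flagged_above_threshold(self):
        draft = build({"r0": (["A"], ["B"])})
        draft.add_entity(Entity("T", "compound"))
        # all candidates lie on a backward path from T, so pruning keeps
        # them and the pool exceeds the exhaustive threshold
        database = build({
            "d1": (["B"], ["Y"]),
            "d2": (["Y"], ["T"]),
            "d99": (["B"], ["T"]),
        })
        got = gapfill(draft, database, ["A"], ["T"], max_size=3,
                      exhaustive_threshold=2)
        assert got.heuristic
        assert got[0].flag == "heuristic"
        assert got[0].reactions == {"d99"}


class TestInstantiation:
    def _class_reaction_db(self, n_instances):
        model = Model()
        model.add_entity(Entity("K", "class"))
        model.add_entity(Entity("P", "compound"))
        for i in range(n_instances):
            model.add_entity(Entity(f"k{i}", "compound"))
            model.add_relation(Relation(f"k{i}", "is_a", "K"))
        model.add_entity(Entity("rx", "reaction"))
        model.add_relation(Relation("rx", "consumes", "K"))
        model.add_relation(Relation("rx", "produces", "P"))
        return model

    def test_one_variant_per_instance(self):
        extended, skipped = instantiate_class_reactions(self._class_reaction_db(2))
        variants = [e for e in extended.reactions() if e.id != "rx"]
        assert {v.id for v in variants} == {"rx/k0", "rx/k1"}
        assert all(v.get_attribute("instance-of") == ["rx"] for v in variants)
        assert "rx" in extended.entities  # original retained
        assert skipped == []

    def test_reaction_without_classes_unchanged(self, chain_model):
        extended, _ = instantiate_class_reactions(chain_model)
        assert extended == chain_model

    def test_two_slots_cartesian_product(self):
        model = Model()
        for name, n in (("K", 2), ("L", 3)):
            model.add_entity(Entity(name, "class"))
            for i in range(n):
                model.add_entity(Entity(f"{name.lower()}{i}", "compound"))
                model.add_relation(Relation(f"{name.lower()}{i}", "is_a", name))
        model.add_entity(Entity("rx", "reaction"))
        model.add_relation(Relation("rx", "consumes", "K"))
        model.add_relation(Relation("rx", "produces", "L"))
        extended, _ = instantiate_class_reactions(model)
        variants = [e for e in extended.reactions() if e.id != "rx"]
        assert len(variants) == 6

    def test_cap_skips_and_reports(self):
        extended, skipped = instantiate_class_reactions(
            self._class_reaction_db(5), max_variants=3)
        assert skipped == ["rx"]
        assert [e.id for e in extended.reactions()] == ["rx"]

    def test_cyclic_ontology_rejected(self):
        model = Model()
        for name in ("X", "Y"):
            model.add_entity(Entity(name, "class"))
        model.add_relation(Relation("X", "is_a", "Y"))
        model.add_relation(Relation("Y", "is_a", "X"))
        with pytest.raises(OntologyCycleError):
            instantiate_class_reactions(model)

    def test_folate_database_instantiation_recovers_variant_semantics(self, folate):
        # instantiating the class-written reductase yields a variant that,
        # like the packaged one, consumes the concrete dihydrofolate
        extended, _ = instantiate_class_reactions(folate.database)
        generated = "DIHYDROFOLATEREDUCT-RXN/DIHYDROFOLATE"
        assert generated in extended.entities
        assert extended.reactants_of(generated) == ["DIHYDROFOLATE", "NADPH"]
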