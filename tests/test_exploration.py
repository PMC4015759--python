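import json

import numpy as np
import pytest

from federank import (
    ExplorationError,
    WeightConfig,
    atom_view,
    back,
    expand,
    forward,
    load_history,
    load_pax_fixture,
    make_synthetic_world,
    reweight_node,
    start,
)
from federank.exploration import history_to_json, serialize_history
from federank.scoring import COMPLEMENT, NEGLOG, reweight as score_reweight

BLAST_INPUTS = {
    "SearchedDB": "UniProtKB/Swiss-Prot",
    "QueryUniprotProteinID": "P26367",
    "TopAlignment": "100",
    "SubstitutionMatrix": "BLOSUM62",
    "ExpectationUpper": "10.0",
    "SearchFilter": "none",
    "GapOpenCost": "11",
    "GapExtensionCost": "1",
}


def start_pax(**kwargs):
    registry, adapters = load_pax_fixture()
    tree, node = start(registry, adapters, "ncbi_blast", BLAST_INPUTS, **kwargs)
    return tree, node


def expand_genes(tree):
    return expand(tree, None, "ProteinCodingGene", "gpdw_protein_coding_gene")


def expand_expression(tree):
    return expand(
        tree, None, "GeneExpressionOfGene", "array_express_gene_expression",
        extra_inputs={"BiologicalCondition": "tumor", "RegulationType": "up"},
    )


def expand_disorder(tree):
    return expand(tree, None, "ExistsProteinGeneticDisorder", "gpdw_protein_genetic_disorder")


def expand_function(tree):
    return expand(
        tree, None, "ExistsGeneBiologicalFunctionFeature", "gpdw_gene_biological_function",
        extra_inputs={"BiologicalFunctionFeatureName": "regulation of apoptotic process"},
    )


class TestStart:
    def test_alignment_search_returns_ranked_hits(self):
        tree, node = start_pax()
        assert node.action == "start"
        assert len(node.result.tuples) == 5
        scores = [t.global_score for t in node.result.tuples]
        assert scores == sorted(scores, reverse=True)
        assert node.result.tuples[0].records["ncbi_blast"]["FoundSequenceID"] == "P26367"

    def test_zero_hit_start_is_empty_but_not_an_error(self):
        registry, adapters = load_pax_fixture()
        tree, node = start(
            registry, adapters, "ncbi_blast", BLAST_INPUTS | {"QueryUniprotProteinID": "QXXXXX"}
        )
        assert node.result.tuples == []

    def test_missing_required_input_named_in_error(self):
        registry, adapters = load_pax_fixture()
        inputs = dict(BLAST_INPUTS)
        del inputs["QueryUniprotProteinID"]
        with pytest.raises(ExplorationError, match="QueryUniprotProteinID"):
            start(registry, adapters, "ncbi_blast", inputs)


class TestExpand:
    def test_expansion_joins_coding_genes(self):
        tree, _ = start_pax()
        node = expand_genes(tree)
        assert len(node.result.tuples) == 5
        assert "gpdw_protein_coding_gene" in node.result.tuples[0].records

    def test_full_pax_chain_keeps_four_genes(self):
        tree, _ = start_pax()
        expand_genes(tree)
        expand_expression(tree)
        node = expand_function(tree)
        genes = [t.records["gpdw_protein_coding_gene"]["GeneSymbol"] for t in node.result.tuples]
        assert len(genes) == 4
        assert "PAX6" not in genes  # the query protein's own gene drops out

    def test_selection_limits_downstream_bindings(self):
        tree, root = start_pax()
        picked = [t.row_id for t in root.result.tuples[:2]]
        counters_before = tree.adapter_calls()["gpdw_protein_coding_gene"]
        node = expand(tree, None, "ProteinCodingGene", "gpdw_protein_coding_gene",
                      selection=picked)
        assert len(node.result.tuples) == 2
        assert tree.adapter_calls()["gpdw_protein_coding_gene"] - counters_before == 2

    def test_empty_selection_warns_and_yields_empty_result(self):
        tree, _ = start_pax()
        with pytest.warns(UserWarning, match="empty selection"):
            node = expand(tree, None, "ProteinCodingGene", "gpdw_protein_coding_gene",
                          selection=[])
        assert node.result.tuples == []

    def test_inapplicable_connection_rejected(self):
        tree, _ = start_pax()
        with pytest.raises(ExplorationError, match="not applicable"):
            # the Gene mart is not in the chain yet
            expand(tree, None, "GeneExpressionOfGene", "array_express_gene_expression",
                   extra_inputs={"BiologicalCondition": "tumor", "RegulationType": "up"})

    def test_unknown_selection_row_rejected(self):
        tree, _ = start_pax()
        with pytest.raises(ExplorationError, match="unknown row id"):
            expand(tree, None, "ProteinCodingGene", "gpdw_protein_coding_gene",
                   selection=["ghost:0"])

    def test_expansion_reuses_cached_upstream_responses(self):
        tree, _ = start_pax()
        expand_genes(tree)
        calls_after_first = dict(tree.adapter_calls())
        back(tree)
        expand_genes(tree)  # same sub-queries: must come from the cache
        assert tree.adapter_calls() == calls_after_first


class TestNavigation:
    def test_back_then_forward_restores_same_node(self):
        tree, _ = start_pax()
        child = expand_genes(tree)
        parent = back(tree)
        assert parent.node_id == child.parent_id
        again = forward(tree, child.node_id)
        assert again.node_id == child.node_id

    def test_back_at_initial_query_rejected(self):
        tree, _ = start_pax()
        with pytest.raises(ExplorationError, match="cannot move back"):
            back(tree)

    def test_forward_to_unknown_child_rejected(self):
        tree, _ = start_pax()
        with pytest.raises(ExplorationError, match="no child"):
            forward(tree, "n99")

    def test_navigation_performs_zero_invocations(self):
        tree, _ = start_pax()
        child = expand_genes(tree)
        before = dict(tree.adapter_calls())
        back(tree)
        forward(tree, child.node_id)
        assert tree.adapter_calls() == before

    def test_branching_scenario_builds_six_node_tree(self):
        """Start, three expansions, one back, one different expansion."""
        tree, _ = start_pax()
        expand_genes(tree)
        n_expr = expand_expression(tree)
        expand_disorder(tree)
        back(tree)
        expand_function(tree)
        assert len(tree.nodes) == 6
        assert len(tree.nodes[n_expr.node_id].children) == 2  # the branch point
        branch_actions = {tree.nodes[c].action for c in tree.nodes[n_expr.node_id].children}
        assert branch_actions == {"expand"}


class TestReweight:
    def test_degenerate_weights_follow_first_service(self):
        # neglog keeps the e-value partials distinct (complement would
        # collapse them all to 1.0 in double precision)
        tree, _ = start_pax(strategy=NEGLOG)
        expand_genes(tree)
        node = expand_expression(tree)
        w = WeightConfig(
            {"ncbi_blast": NEGLOG, "array_express_gene_expression": NEGLOG},
            {"ncbi_blast": 1.0, "array_express_gene_expression": 0.0},
        )
        child = reweight_node(tree, None, w)
        evalues = [float(t.records["ncbi_blast"]["BestAlignmentExpectation"])
                   for t in child.result.tuples]
        assert evalues == sorted(evalues)

    def test_reweight_round_trip_restores_order(self):
        tree, _ = start_pax()
        expand_genes(tree)
        node = expand_expression(tree)
        equal = node.state.weights
        skew = WeightConfig(
            dict(equal.strategies), {"ncbi_blast": 0.9, "array_express_gene_expression": 0.1}
        )
        twice = reweight_node(tree, reweight_node(tree, node, skew), equal)
        assert [t.provenance for t in twice.result.tuples] == [
            t.provenance for t in node.result.tuples
        ]

    def test_reweight_matches_scoring_oracle_and_invokes_nothing(self):
        tree, _ = start_pax()
        expand_genes(tree)
        node = expand_expression(tree)
        rng = np.random.default_rng(3)
        before = dict(tree.adapter_calls())
        for _ in range(5):
            wa = float(rng.uniform(0.05, 0.95))
            w = WeightConfig(
                dict(node.state.weights.strategies),
                {"ncbi_blast": wa, "array_express_gene_expression": 1.0 - wa},
            )
            child = reweight_node(tree, node, w)
            expected = score_reweight(node.result.tuples, w)
            assert [t.provenance for t in child.result.tuples] == [
                t.provenance for t in expected
            ]
        assert tree.adapter_calls() == before


class TestAtomView:
    def test_top_tuple_group_carries_rank_one(self):
        tree, _ = start_pax()
        expand_genes(tree)
        expand_expression(tree)
        node = expand_function(tree)
        view = atom_view(node)
        top_gene = node.result.tuples[0].records["gpdw_protein_coding_gene"]
        gene_groups = view.groups["gpdw_protein_coding_gene"]
        (top_group,) = [g for g in gene_groups if g.values == dict(top_gene)]
        assert 1 in top_group.ranks

    def test_single_tuple_result_has_one_rank_one_group_per_interface(self):
        tree, root = start_pax()
        node = expand(tree, None, "ProteinCodingGene", "gpdw_protein_coding_gene",
                      selection=[root.result.tuples[0].row_id])
        view = atom_view(node)
        for iface, groups in view.groups.items():
            assert len(groups) == 1
            assert groups[0].ranks == [1]

    def test_each_tuple_in_exactly_one_group_per_interface(self):
        tree, _ = start_pax()
        expand_genes(tree)
        node = expand_expression(tree)
        view = atom_view(node)
        for iface, groups in view.groups.items():
            seen = [tid for g in groups for tid in g.tuple_ids]
            assert sorted(seen) == sorted(t.row_id for t in node.result.tuples)
            assert len(seen) == len(set(seen))


class TestHistorySerialization:
    def test_round_trip_is_structural_identity(self):
        registry, adapters = load_pax_fixture()
        tree, _ = start(registry, adapters, "ncbi_blast", BLAST_INPUTS)
        expand_genes(tree)
        expand_expression(tree)
        expand_disorder(tree)
        back(tree)
        expand_function(tree)
        doc = history_to_json(tree)
        reloaded = load_history(doc, registry, adapters)
        assert history_to_json(reloaded) == doc

    def test_root_only_tree_round_trips(self):
        from federank.exploration import HistoryTree
        registry, adapters = load_pax_fixture()
        tree = HistoryTree(registry, adapters)
        reloaded = load_history(history_to_json(tree), registry, adapters)
        assert history_to_json(reloaded) == history_to_json(tree)

    def test_empty_document_rejected(self):
        registry, adapters = load_pax_fixture()
        with pytest.raises(ExplorationError, match="no nodes"):
            load_history({"format": "federank-history", "nodes": []}, registry, adapters)

    def test_ancestor_subtree_unchanged_by_descendant_creation(self):
        tree, _ = start_pax()
        node = expand_genes(tree)
        def subtree(t, nid):
            doc = serialize_history(t)
            nodes = {n["id"]: n for n in doc["nodes"]}
            keep = {nid}
            frontier = [nid]
            while frontier:
                cur = nodes[frontier.pop()]
                parent = cur["parent"]
                if parent is not None and parent not in keep:
                    keep.add(parent)
                    frontier.append(parent)
            snap = []
            for k in sorted(keep):
                n = dict(nodes[k])
                n.pop("children")  # append-only by design
                snap.append(n)
            return json.dumps(snap, sort_keys=True)
        before = subtree(tree, node.node_id)
        expand_expression(tree)
        assert subtree(tree, node.node_id) == before


def random_walk(tree, rng, steps=6):
    """Random expand/reweight/back walk over the PAX world; returns actions."""
    expansions = [expand_genes, expand_expression, expand_disorder, expand_function]
    done = 0
    while done < steps:
        choice = rng.integers(0, 3)
        try:
            if choice == 0:
                expansions[int(rng.integers(0, len(expansions)))](tree)
            elif choice == 1:
                cur = tree.current
                ranked = sorted(cur.state.weights.weights)
                if not ranked:
                    continue
                raw = rng.uniform(0.05, 1.0, size=len(ranked))
                w = WeightConfig(
                    dict(cur.state.weights.strategies),
                    {n: float(v / raw.sum()) for n, v in zip(ranked, raw)},
                )
                reweight_node(tree, None, w)
            else:
                back(tree)
        except ExplorationError:
            continue
        done += 1


class TestUndoIdentityProperty:
    @pytest.mark.parametrize("seed", range(50))
    def test_back_after_any_action_restores_parent_state(self, seed):
        rng = np.random.default_rng(seed)
        tree, _ = start_pax()
        random_walk(tree, rng, steps=5)
        anchor = tree.current
        snapshot = json.dumps(
            {
                "steps": [s.interface for s in anchor.state.steps],
                "rows": [t.row_id for t in anchor.result.tuples],
                "scores": [t.global_score for t in anchor.result.tuples],
            },
            sort_keys=True,
        )
        # one more action, then undo
        before_calls = dict(tree.adapter_calls())
        try:
            expand_genes(tree)
        except ExplorationError:
            reweight_node(tree, None, anchor.state.weights)
        restored = back(tree)
        assert restored.node_id == anchor.node_id
        again = json.dumps(
            {
                "steps": [s.interface for s in restored.state.steps],
                "rows": [t.row_id for t in restored.result.tuples],
                "scores": [t.global_score for t in restored.result.tuples],
            },
            sort_keys=True,
        )
        assert again == snapshot

    def test_invocations_bounded_by_distinct_subqueries(self):
        """Along any navigation pattern, each distinct sub-query runs once."""
        tree, _ = start_pax()
        expand_genes(tree)
        back(tree)
        expand_genes(tree)
        back(tree)
        expand_genes(tree)
        # 1 start + 5 distinct coding-gene bindings, regardless of replays
        assert tree.adapter_calls()["ncbi_blast"] == 1
        assert tree.adapter_calls()["gpdw_protein_coding_gene"] == 5
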