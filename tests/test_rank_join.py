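import itertools

import numpy as np
import pytest

from federank import (
    COMPLEMENT,
    JoinError,
    JoinSpec,
    RankedStream,
    WeightConfig,
    bind_subquery,
    full_join_oracle,
    load_pax_fixture,
    multiway_rank_join,
    rank_join_topk,
)
from federank.service_model import AttributeSpec, Direction, Registry
from federank.synthetic import make_random_join_instance

from conftest import assert_same_ranking, cartesian_join


def _simple_connection():
    reg = Registry()
    reg.register_mart("A", [AttributeSpec("k"), AttributeSpec("v")])
    reg.register_mart("B", [AttributeSpec("k"), AttributeSpec("v")])
    return reg.register_connection_pattern("link", "A", "B", [{"source": "k", "target": "k"}])


def _stream(iface, rows, ranked="v", random_access=True, truncation=None):
    return RankedStream(
        iface,
        [{"k": k, "v": f"{v}"} for k, v in rows],
        ranked_attribute=ranked,
        direction=Direction.ASCENDING_BETTER,
        truncation=truncation,
        supports_random_access=random_access,
    )


EQUAL_AB = WeightConfig.equal(["a", "b"])


class TestFullJoinOracle:
    def test_single_matching_key(self):
        cp = _simple_connection()
        a = _stream("a", [("g1", 0.1), ("g2", 0.5), ("g3", 0.9)])
        b = _stream("b", [("g2", 0.2), ("g4", 0.3), ("g5", 0.4)])
        out = full_join_oracle([a, b], [[JoinSpec(cp, "a")]], EQUAL_AB)
        assert len(out) == 1
        assert out[0].records["a"]["k"] == "g2"
        assert out[0].global_score == pytest.approx(0.5 * 0.5 + 0.5 * 0.8)

    def test_disjoint_keys_empty(self):
        cp = _simple_connection()
        a = _stream("a", [("g1", 0.1)])
        b = _stream("b", [("g9", 0.2)])
        assert full_join_oracle([a, b], [[JoinSpec(cp, "a")]], EQUAL_AB) == []

    def test_count_matches_independent_hash_join(self):
        cp = _simple_connection()
        rng = np.random.default_rng(11)
        a = _stream("a", [(f"g{rng.integers(8)}", float(rng.uniform())) for _ in range(50)])
        b = _stream("b", [(f"g{rng.integers(8)}", float(rng.uniform())) for _ in range(50)])
        out = full_join_oracle([a, b], [[JoinSpec(cp, "a")]], EQUAL_AB)
        from collections import Counter
        ca = Counter(r["k"] for r in a.records)
        cb = Counter(r["k"] for r in b.records)
        assert len(out) == sum(ca[k] * cb[k] for k in ca)

    def test_matches_cartesian_enumeration_on_tiny_instances(self):
        for seed in range(20):
            streams, joins, weights = make_random_join_instance(seed, n_streams=2, max_n=8)
            assert_same_ranking(
                full_join_oracle(streams, joins, weights),
                cartesian_join(streams, joins, weights),
            )


class TestRankJoinTopK:
    def test_empty_side_short_circuits(self):
        cp = _simple_connection()
        a = _stream("a", [("g1", 0.1)])
        b = _stream("b", [])
        res = rank_join_topk(a, b, cp, EQUAL_AB, k=5)
        assert res.tuples == []
        assert res.exhausted["b"] is True

    def test_k_below_one_rejected(self):
        cp = _simple_connection()
        a = _stream("a", [("g1", 0.1)])
        with pytest.raises(JoinError):
            rank_join_topk(a, a, cp, EQUAL_AB, k=0)

    def test_unbound_join_attribute_rejected(self):
        cp = _simple_connection()
        a = RankedStream("a", [{"v": "0.1"}], "v")
        b = _stream("b", [("g1", 0.2)])
        with pytest.raises(JoinError, match="join attribute"):
            rank_join_topk(a, b, cp, EQUAL_AB, k=1)

    @pytest.mark.parametrize(
        "shape",
        [
            dict(n_streams=2),
            dict(n_streams=2, tie_heavy=True),
            dict(n_streams=2, truncated=True),
            dict(n_streams=2, tie_heavy=True, truncated=True),
        ],
        ids=["plain", "ties", "truncated", "ties+truncated"],
    )
    def test_equals_oracle_topk_on_random_instances(self, shape):
        for seed in range(100):
            streams, joins, weights = make_random_join_instance(seed, max_n=60, **shape)
            rng = np.random.default_rng(seed + 10_000)
            k = int(rng.integers(1, 21))
            res = rank_join_topk(streams[0], streams[1], joins[0], weights, k)
            oracle = full_join_oracle(streams, joins, weights)[:k]
            assert_same_ranking(res.tuples, oracle)

    def test_every_emitted_tuple_satisfies_the_predicate(self):
        for seed in range(20):
            streams, joins, weights = make_random_join_instance(seed, tie_heavy=True)
            res = rank_join_topk(streams[0], streams[1], joins[0], weights, k=10)
            for t in res.tuples:
                for spec in joins[0]:
                    for c in spec.connection.clauses:
                        assert (
                            t.records[spec.source_interface][c.source]
                            == t.records[streams[1].interface][c.target]
                        )

    def test_rerun_is_bit_identical(self):
        streams, joins, weights = make_random_join_instance(3, tie_heavy=True)
        r1 = rank_join_topk(streams[0], streams[1], joins[0], weights, k=10)
        r2 = rank_join_topk(streams[0], streams[1], joins[0], weights, k=10)
        assert [t.provenance for t in r1.tuples] == [t.provenance for t in r2.tuples]
        assert [t.global_score for t in r1.tuples] == [t.global_score for t in r2.tuples]

    def test_scores_nonincreasing(self):
        for seed in range(20):
            streams, joins, weights = make_random_join_instance(seed)
            res = rank_join_topk(streams[0], streams[1], joins[0], weights, k=15)
            scores = [t.global_score for t in res.tuples]
            assert scores == sorted(scores, reverse=True)

    def test_truncated_records_never_join(self):
        cp = _simple_connection()
        a = _stream("a", [("g1", 0.1), ("g2", 0.2), ("g3", 0.3)], truncation=2)
        b = _stream("b", [("g1", 0.1), ("g2", 0.2), ("g3", 0.3)])
        res = rank_join_topk(a, b, cp, EQUAL_AB, k=10)
        assert {t.records["a"]["k"] for t in res.tuples} == {"g1", "g2"}

    def test_matching_heads_terminate_early(self):
        """Planted matching heads: top-1 costs a handful of sorted accesses."""
        cp = _simple_connection()
        n = 1000
        pad_a = [(f"x{i}", 0.001 + i / n) for i in range(n)]
        pad_b = [(f"y{i}", 0.001 + i / n) for i in range(n)]
        a = _stream("a", [("G1", 1e-9)] + pad_a)
        b = _stream("b", [("G1", 1e-9)] + pad_b)
        res = rank_join_topk(a, b, cp, EQUAL_AB, k=1)
        assert len(res.tuples) == 1
        assert res.tuples[0].records["a"]["k"] == "G1"
        for iface in ("a", "b"):
            assert res.access_stats[iface]["sorted"] <= 10
            assert res.access_stats[iface]["sorted"] < n

    def test_two_by_two_heads_cost_at_most_two_accesses_per_stream(self):
        cp = _simple_connection()
        a = _stream("a", [("G1", 0.1), ("x", 0.9)])
        b = _stream("b", [("G1", 0.2), ("y", 0.8)])
        res = rank_join_topk(a, b, cp, EQUAL_AB, k=1)
        assert res.tuples[0].records["a"]["k"] == "G1"
        assert res.access_stats["a"]["sorted"] <= 2
        assert res.access_stats["b"]["sorted"] <= 2


class TestMultiwayRankJoin:
    def test_pax_three_stage_chain_yields_four_tuples(self, pax_world):
        registry, adapters = pax_world
        blast = adapters["ncbi_blast"].stream(
            {a: "x" for a in registry.access_patterns["NCBI-BLAST"].input_attributes}
            | {"QueryUniprotProteinID": "P26367"},
            k=50,
        )
        # unranked lookup: the full gene table as a match-all stream
        genes = RankedStream("gpdw_protein_coding_gene", adapters["gpdw_protein_coding_gene"].rows)
        expr = RankedStream(
            "array_express_gene_expression",
            [r for r in adapters["array_express_gene_expression"].rows
             if r["BiologicalCondition"] == "tumor"],
            "ExpressionPValue",
            Direction.ASCENDING_BETTER,
        )
        cps = registry.connection_patterns
        joins = [
            [JoinSpec(cps["ProteinCodingGene"], "ncbi_blast")],
            [JoinSpec(cps["GeneExpressionOfGene"], "gpdw_protein_coding_gene")],
        ]
        weights = WeightConfig.equal(["ncbi_blast", "array_express_gene_expression"])
        res = multiway_rank_join([blast, genes, expr], joins, weights, k=50)
        assert len(res.tuples) == 4
        oracle = full_join_oracle([blast, genes, expr], joins, weights)
        assert_same_ranking(res.tuples, oracle)

    def test_single_stream_plan_is_scored_passthrough(self):
        a = _stream("a", [("g1", 0.2), ("g2", 0.6)])
        res = multiway_rank_join([a], [], WeightConfig.equal(["a"]), k=10)
        assert [t.global_score for t in res.tuples] == pytest.approx([0.8, 0.4])

    def test_equals_oracle_on_random_three_way_chains(self):
        for seed in range(100):
            streams, joins, weights = make_random_join_instance(seed, n_streams=3, max_n=40)
            rng = np.random.default_rng(seed + 20_000)
            k = int(rng.integers(1, 21))
            res = multiway_rank_join(streams, joins, weights, k)
            oracle = full_join_oracle(streams, joins, weights)[:k]
            assert_same_ranking(res.tuples, oracle)


class TestBindSubquery:
    def test_alignment_hits_bind_annotation_inputs(self, pax_world):
        registry, adapters = pax_world
        cp = registry.connection_patterns["ExistsProteinBiologicalFunctionFeature"]
        hits = adapters["ncbi_blast"].rows
        bindings = bind_subquery(cp, hits)
        assert bindings[0] == {"ProteinID": "P26367", "ProteinIDName": "UniProt"}
        assert len(bindings) == len(hits)

    def test_duplicate_upstream_keys_deduplicated(self):
        cp = _simple_connection()
        records = [{"k": "g1"}, {"k": "g1"}, {"k": "g2"}]
        assert bind_subquery(cp, records) == [{"k": "g1"}, {"k": "g2"}]

    def test_empty_upstream_yields_no_bindings(self):
        cp = _simple_connection()
        assert bind_subquery(cp, []) == []

    def test_missing_attribute_rejected(self):
        cp = _simple_connection()
        with pytest.raises(JoinError, match="join attribute"):
            bind_subquery(cp, [{"other": "1"}])
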