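"""Seeded synthetic worlds and random problem instances.

``make_synthetic_world`` emulates the five-topic service landscape with
generated tables: an alignment service whose hits carry e-values drawn
log-uniformly over [1e-180, 1] (mimicking BLAST's dynamic range, with a
configurable tie mass), a protein-to-gene lookup, a gene-expression service
with uniform p-values and a planted co-expressed gene subset under the
queried condition, a gene-to-biological-function lookup and a
protein-to-genetic-disorder lookup.  The same seed always yields a
bit-identical world.

The module also generates random registries and random ranked-join
instances used by the verification suites (oracle-equivalence and
plan-optimality checks).
"""

from __future__ import annotations

import numpy as np

from .adapters import TableService
from .rank_join import JoinSpec, RankedStream
from .scoring import (
    COMPLEMENT,
    NEGLOG,
    RANK_BASED,
    NormalizationStrategy,
    WeightConfig,
)
from .service_model import (
    AdapterDescriptor,
    AttributeSpec,
    ConnectionPattern,
    Direction,
    Registry,
    Role,
)
from .fixtures import fig1_registry
from .errors import FederankError

__all__ = [
    "make_synthetic_world",
    "make_random_registry",
    "make_random_join_instance",
]

QUERY_PROTEIN = "P26367"


def make_synthetic_world(
    seed: int,
    n_proteins: int = 20,
    genes_per_protein: int = 1,
    terms_per_gene: int = 2,
    n_coexpressed: int = 5,
    tie_mass: float = 0.0,
) -> tuple[Registry, dict[str, TableService]]:
    """Five-topic world with generated tables behind the shipped registry.

    ``n_coexpressed`` genes are planted with tumor/up expression records
    (small p-values); the remaining genes are expressed only under a
    control condition, so a tumor-filtered chain query retains exactly the
    planted subset.  ``tie_mass`` is the fraction of alignment hits whose
    e-value is duplicated from another hit (exercises ties).
    """
    if n_proteins < 1 or genes_per_protein < 1 or terms_per_gene < 1:
        raise FederankError("synthetic world sizes must be >= 1")
    if not (0.0 <= tie_mass <= 1.0):
        raise FederankError("tie_mass must be in [0, 1]")
    n_coexpressed = min(n_coexpressed, n_proteins * genes_per_protein)
    rng = np.random.default_rng(seed)
    registry = fig1_registry()

    # alignment hits: e-values log-uniform over [1e-180, 1]
    exponents = rng.uniform(-180.0, 0.0, size=n_proteins)
    n_tied = int(round(tie_mass * n_proteins))
    if n_tied and n_proteins > 1:
        donors = rng.integers(0, n_proteins, size=n_tied)
        receivers = rng.integers(0, n_proteins, size=n_tied)
        exponents[receivers] = exponents[donors]
    blast_rows = []
    for i in range(n_proteins):
        pid = f"PRT{i + 1:05d}"
        blast_rows.append(
            {
                "QueryUniprotProteinID": QUERY_PROTEIN,
                "FoundSequenceID": pid,
                "FoundSequenceIDName": "UniProt",
                "FoundSequenceSymbol": f"SYM{i + 1}",
                "FoundSequenceDescription": f"synthetic protein {i + 1}",
                "FoundSequenceLength": str(int(rng.integers(100, 2000))),
                "BestAlignmentExpectation": f"{10.0 ** exponents[i]:.6E}",
            }
        )

    gene_rows = []
    genes = []
    for i in range(n_proteins):
        for g in range(genes_per_protein):
            gid = f"G{i * genes_per_protein + g + 1:05d}"
            genes.append(gid)
            gene_rows.append(
                {
                    "ProteinID": f"PRT{i + 1:05d}",
                    "ProteinIDName": "UniProt",
                    "GeneID": gid,
                    "GeneIDName": "Entrez",
                    "GeneSymbol": f"GENE{gid[1:]}",
                    "TaxonomyName": "Homo sapiens",
                }
            )

    planted = list(rng.choice(len(genes), size=n_coexpressed, replace=False))
    planted_set = {genes[int(i)] for i in planted}
    expr_rows = []
    for j, gid in enumerate(genes):
        if gid in planted_set:
            condition, reg, p = "tumor", "up", 10.0 ** float(rng.uniform(-12.0, -2.0))
        else:
            condition, reg, p = "control", "up", float(rng.uniform(0.0, 1.0))
        expr_rows.append(
            {
                "GeneID": gid,
                "GeneIDName": "Entrez",
                "BiologicalCondition": condition,
                "RegulationType": reg,
                "ExperimentID": f"E-SYN-{j + 1:04d}",
                "ExpressionPValue": f"{p:.6E}",
            }
        )

    function_rows = []
    terms = ["regulation of apoptotic process", "cell differentiation", "signal transduction",
             "kidney development", "eye development", "cell cycle"]
    for gid in genes:
        picked = rng.choice(len(terms), size=min(terms_per_gene, len(terms)), replace=False)
        extra = terms_per_gene - len(picked)
        term_ids = list(picked) + list(rng.integers(0, len(terms), size=max(0, extra)))
        for t in term_ids:
            function_rows.append(
                {
                    "GeneID": gid,
                    "GeneIDName": "Entrez",
                    "BiologicalFunctionFeatureName": terms[int(t)],
                    "BiologicalFunctionFeatureID": f"GO:{int(t) + 1:07d}",
                    "BiologicalFunctionFeatureIDName": "GO",
                    "BiologicalFunctionFeatureDefinition": f"synthetic definition of {terms[int(t)]}",
                }
            )

    disorder_rows = []
    for i in range(n_proteins):
        if rng.uniform() < 0.5:
            disorder_rows.append(
                {
                    "ProteinID": f"PRT{i + 1:05d}",
                    "ProteinIDName": "UniProt",
                    "GeneticDisorderID": f"OMIM:{int(rng.integers(100000, 700000))}",
                    "GeneticDisorderName": f"synthetic disorder {i + 1}",
                    "GeneticDisorderDescription": "generated for testing",
                }
            )

    protein_function_rows = [
        {
            "ProteinID": g["ProteinID"],
            "ProteinIDName": "UniProt",
            "BiologicalFunctionFeatureName": f["BiologicalFunctionFeatureName"],
            "BiologicalFunctionFeatureID": f["BiologicalFunctionFeatureID"],
            "BiologicalFunctionFeatureIDName": "GO",
            "BiologicalFunctionFeatureDefinition": f["BiologicalFunctionFeatureDefinition"],
        }
        for g in gene_rows
        for f in function_rows
        if f["GeneID"] == g["GeneID"]
    ]

    tables = {
        "ncbi_blast": blast_rows,
        "gpdw_protein_coding_gene": gene_rows,
        "array_express_gene_expression": expr_rows,
        "gpdw_gene_biological_function": function_rows,
        "gpdw_protein_biological_function": protein_function_rows,
        "gpdw_protein_genetic_disorder": disorder_rows,
    }
    adapters = {}
    for name, rows in tables.items():
        iface = registry.interfaces[name]
        adapters[name] = TableService(iface, registry.access_patterns[iface.access_pattern], rows)
    return registry, adapters


# ---------------------------------------------------------------------------
# random registries (for derivation-equivalence checks)


def make_random_registry(seed: int, n_marts: int = 4, n_interfaces: int = 6, n_patterns: int = 5) -> Registry:
    """A random but always-valid registry with varied roles and predicates."""
    rng = np.random.default_rng(seed)
    reg = Registry()
    for m in range(n_marts):
        n_attr = int(rng.integers(2, 6))
        reg.register_mart(
            f"M{m}", [AttributeSpec(f"a{m}_{i}", "identifier") for i in range(n_attr)]
        )
    mart_names = list(reg.marts)
    pattern_names = []
    for p in range(int(rng.integers(n_marts, n_marts + 4))):
        mart = mart_names[int(rng.integers(0, n_marts))]
        attrs = list(reg.marts[mart].attribute_names)
        roles = {}
        for a in attrs:
            roles[a] = ["input", "output", "input_output"][int(rng.integers(0, 3))]
        # guarantee at least one output
        roles[attrs[int(rng.integers(0, len(attrs)))]] = "output"
        if rng.uniform() < 0.5:
            # promote one plain output to ranked
            outs = [a for a, r in roles.items() if r == "output"]
            roles[outs[int(rng.integers(0, len(outs)))]] = "output_ranked"
        name = f"AP{p}"
        reg.register_access_pattern(name, mart, roles, "ascending_better")
        pattern_names.append(name)
    for i in range(n_interfaces):
        ap = pattern_names[int(rng.integers(0, len(pattern_names)))]
        reg.register_interface(
            f"iface{i}", ap, AdapterDescriptor(f"table:iface{i}", True, bool(rng.uniform() < 0.5))
        )
    for c in range(n_patterns):
        src = mart_names[int(rng.integers(0, n_marts))]
        tgt = mart_names[int(rng.integers(0, n_marts))]
        src_attrs = list(reg.marts[src].attribute_names)
        tgt_attrs = list(reg.marts[tgt].attribute_names)
        n_clauses = int(rng.integers(1, 3))
        predicate = [
            {
                "source": src_attrs[int(rng.integers(0, len(src_attrs)))],
                "target": tgt_attrs[int(rng.integers(0, len(tgt_attrs)))],
            }
            for _ in range(n_clauses)
        ]
        reg.register_connection_pattern(f"CP{c}", src, tgt, predicate)
    return reg


# ---------------------------------------------------------------------------
# random join instances (for oracle-equivalence checks)


def _random_strategy(rng) -> NormalizationStrategy:
    return [COMPLEMENT, NEGLOG, RANK_BASED][int(rng.integers(0, 3))]


def make_random_join_instance(
    seed: int,
    n_streams: int = 2,
    max_n: int = 60,
    tie_heavy: bool = False,
    truncated: bool = False,
    key_space: int = 12,
):
    """A random chain-join instance: streams, join specs and weights.

    Keys are drawn from a small alphabet so matches are frequent;
    ``tie_heavy`` draws ranked values from a handful of discrete levels so
    ties dominate; ``truncated`` applies a random service-side top-k to
    each stream.  Returns ``(streams, joins, weights)`` directly consumable
    by :func:`federank.rank_join.multiway_rank_join` and
    :func:`federank.rank_join.full_join_oracle`.
    """
    rng = np.random.default_rng(seed)
    registry = Registry()
    streams = []
    joins = []
    strategies = {}
    raw_weights = {}
    for s in range(n_streams):
        mart = f"T{s}"
        registry.register_mart(
            mart,
            [AttributeSpec("key", "identifier"), AttributeSpec("val", "number"),
             AttributeSpec("payload", "text")],
        )
        n = int(rng.integers(2, max_n + 1))
        ranked = rng.uniform() < 0.85 or s == 0
        if tie_heavy:
            levels = rng.uniform(0.0, 1.0, size=int(rng.integers(2, 5)))
            values = levels[rng.integers(0, len(levels), size=n)]
        else:
            values = rng.uniform(0.0, 1.0, size=n)
        direction = (
            Direction.ASCENDING_BETTER if rng.uniform() < 0.7 else Direction.DESCENDING_BETTER
        )
        records = [
            {
                "key": f"K{int(rng.integers(0, key_space))}",
                "val": f"{values[i]:.6f}",
                "payload": f"s{s}r{i}",
            }
            for i in range(n)
        ]
        iface = f"svc{s}"
        stream = RankedStream(
            iface,
            records,
            ranked_attribute="val" if ranked else None,
            direction=direction if ranked else None,
            truncation=int(rng.integers(1, n + 1)) if truncated else None,
            supports_random_access=bool(rng.uniform() < 0.5),
        )
        streams.append(stream)
        if ranked:
            strategies[iface] = _random_strategy(rng)
            raw_weights[iface] = float(rng.uniform(0.05, 1.0))
        if s > 0:
            source = f"svc{int(rng.integers(0, s))}"
            cp = registry.register_connection_pattern(
                f"CPjoin{s}", f"T{int(source[3:])}", mart, [{"source": "key", "target": "key"}]
            )
            joins.append([JoinSpec(cp, source)])
    total = sum(raw_weights.values())
    weights = WeightConfig(strategies, {n_: w / total for n_, w in raw_weights.items()})
    return streams, joins, weights
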