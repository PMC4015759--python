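# federank

Ranking-aware federated search over registered bio-data services: a service
registry (marts, access patterns, connection patterns), Fagin-style top-k
rank joins over partially ranked result streams, a weighted [0, 1] global
score, cost-based invocation planning, and liquid-query exploration with a
navigable history tree. All services are table-backed mocks, so every
behavior runs and is tested offline.

## Who this is for

Complex biomedical questions — *which genes encode proteins similar to X,
are over-expressed in condition Y, and participate in process Z?* — span
several search services at once, each returning *ranked* answers: BLAST
hits ordered by expectation value, expression records ordered by p-value,
plain annotation lookups with no ranking at all. federank is for anyone who
wants to join such streams without discarding the rankings: results are
combined under conjunctive attribute-equality predicates and ordered by a
global score that blends the partial rankings.

## The model in brief

Each ranked service contributes a partial score per record by normalizing
its ranked attribute into [0, 1] (1 best); the default `complement`
strategy maps an ascending-better value v to `1 − clamp(v, 0, 1)`, with
`neglog` (`min(1, −log10 v / C)`) and midrank-based alternatives. A joined
tuple scores

    g = Σ_i  w_i · s_i        with  w_i ≥ 0,  Σ w_i = 1,

so `g ∈ [0, 1]` and `g = 1` only when every partial is perfect. The top-k
join is a threshold algorithm: streams are read in rank order, new records
are probed against seen (and, with random access, unseen) partners by join
key, and the join stops as soon as the k-th best discovered score strictly
beats an optimistic bound on anything undiscovered. Results equal the
exhaustive join's top-k exactly — set and order — under a deterministic
tie-break; an exhaustive oracle in the package is the reference the
threshold path is verified against.

## Worked example

The shipped fixture replays a canonical exploration: a similarity
search for the human Pax-6 protein (UniProt P26367), expanded to the
coding genes, to tumor up-regulation evidence, and to genes annotated with
*regulation of apoptotic process*:

```sh
federank explore run "$(python -c 'from federank.fixtures import pax_session_path; print(pax_session_path())')" --out-dir out/
```

`out/pax_results.tsv` then starts (columns truncated for width):

```
global_score  ncbi_blast.BestAlignmentExpectation  array_express_gene_expression.ExpressionPValue  gene
1.00000       1.73781E-70                          1.0E-11                                          PAX2 (Homo sapiens)
1.00000       1.17479E-67                          1.0E-11                                          PAX8 (Homo sapiens)
0.99850       1.3658E-76                           0.0030                                           PAX7 (Homo sapiens)
0.97950       3.2506E-69                           0.041                                            Pax8 (Mus musculus)
```

Four genes survive the whole chain. PAX6 itself is absent: its gene lacks
the apoptosis-regulation annotation (and the tumor expression record) in
the fixture tables. PAX7 encodes the protein *most* similar to the query,
yet ranks below PAX2 and PAX8 — its weaker expression evidence (p = 0.0030
versus 1.0E-11) outweighs the alignment advantage under equal weights,
which is precisely the ranking-aware behavior a plain intersection would
lose. Reweighting (e.g. alignment 0.9 / expression 0.1) re-ranks the same
tuples without re-invoking any service.

The same session is available programmatically:

```python
from federank import load_pax_fixture, start, expand

registry, adapters = load_pax_fixture()
tree, node = start(registry, adapters, "ncbi_blast", {...inputs...})
expand(tree, None, "ProteinCodingGene", "gpdw_protein_coding_gene")
...
```

Other CLI entry points: `federank registry validate <file>`,
`federank registry graph <file>` (topic graph as TSV), `federank plan
explain <query.yaml>` (chosen invocation order with its cost arithmetic),
`federank export <history.json>`.

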