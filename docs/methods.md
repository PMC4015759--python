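# Methods

## Problem setting

Bioinformatics web services answer narrow questions well — "which proteins
are similar to this sequence?", "which genes are up-regulated in tumor?" —
but complex biomedical questions span several such topics at once, and many
services return *ranked* answers (BLAST expectation values, expression
p-values) that naive intersection would throw away. federank is an engine
for this setting: heterogeneous search services are described in a registry,
their partially ranked result streams are joined under conjunctive
attribute-equality predicates, and joined tuples are ordered by a weighted
global score in [0, 1]. Queries are built exploratively — start with one
service, inspect, select, expand onto a connected service, reweight, undo —
with every state kept in a navigable history tree. Everything runs against
table-backed mock services, so the whole behavior is testable offline.

## Service model

A **service mart** is the normalized conceptual description of a topic
(Protein, Gene, Gene Expression, Biological Function, Genetic Disorder in
the shipped registry), carrying normalized attribute names. An **access
pattern** is a signature of a mart assigning each attribute a role: `input`,
`output`, `output_ranked` (at most one per pattern; with a declared
direction, ascending-better for e-values/p-values) or `input_output`. The
fourth role exists because real annotation services take a term filter that
is also echoed as an output column; a single-valued role map cannot express
that otherwise. A **service interface** binds a pattern to an adapter with
declared capabilities (sorted access, random access by key, an optional
hard top-k). **Connection patterns** couple two marts pair-wise with a
conjunction of attribute-equality clauses; only the equality comparator is
implemented (the clause model reserves a comparator slot). Patterns are
stored directed — derivation feeds *outputs* of a source-mart interface
into *inputs* of a target-mart interface — while the topic graph treats
edges as undirected for neighbourhood navigation. Interface-level
connections are derived mechanically: a (pattern, source interface, target
interface) triple qualifies iff every clause's source attribute is an
output and its target attribute an input of the respective signatures.
Attribute values join by exact normalized name and case-sensitive
comparison after trimming surrounding whitespace (UniProt-style accessions
are case-significant; trimming guards hand-edited tables).

## Scoring

Each ranked service contributes a partial score per record by normalizing
the raw ranked value into [0, 1] (1 best); the global score of a joined
tuple is `g = Σ_i w_i · s_i` with user-settable relative weights `w_i ≥ 0`,
`Σ w_i = 1` (tolerance 1e-9; configs merely summing to something positive
are rescaled with a warning). Unranked services (plain lookups) contribute
no term and their weight mass is redistributed proportionally among the
ranked services present, so removing a lookup never changes `g`.

The normalization ("service-specific weight") is a pluggable strategy:

| strategy | formula (ascending-better) | default use |
| --- | --- | --- |
| `complement` | `1 − clamp(v, 0, 1)` | default for [0,1]-valued e-values/p-values |
| `neglog` | `min(1, −log10(max(v, ε)) / C)`, `C = 100`, `ε = 1e-300` | spreads 180 orders of magnitude |
| `rank_based` | `1 − (r − 1)/(n − 1)`, midrank `r` over the cohort | position-only, tie-respecting |

Descending-better attributes use the mirrored form (`1 − s`). e-values above
1 clamp to score 0 under `complement`. `rank_based` scores a single-record
or all-tied cohort 1.0 throughout: such a cohort carries no ranking
information, and penalizing it would make a lone perfect hit score 0.
`complement` is the default because e-values and p-values are dimensionless
values on the same [0, 1] scale, making the complement the minimal faithful
choice; nothing is claimed about reproducing any particular system's
absolute scores, which depend on normalization details no fixture can pin
down (the replay fixtures assert ordering, never score values).

Ties in the global score are broken deterministically: (1) higher partial
score of the earlier interface in plan order, (2) lexicographic join key,
(3) provenance record indices. This makes every ranking total and re-runs
bit-identical. Note that under `complement` e-values below ~1e-16 all
normalize to exactly 1.0 in double precision, so alignment partials for
strong hits tie and the later tie-break terms decide — an intended
consequence of the scale, not an implementation accident.

## Top-k rank join

`rank_join_topk` is a threshold-style aggregation in the Fagin family
(TA with optional random access). Both streams are consumed by alternating
sorted accesses; each newly seen record is probed against already-seen
partners (hash on the canonicalized join key) and, when the opposite side
supports random access, against its unseen partners by key. The optimistic
bound on any undiscovered combination is `T = nl + nr` (next-unseen score
contribution per side) plus, for a side without random access, the
seen-max-plus-frontier terms that such pairs can still reach. The join
stops when the k-th best discovered score strictly exceeds the bound;
strictness matters because an undiscovered tuple with a tied score could
still win on the tie-break. Without random access the engine simply keeps
buffering (NRA-style): correctness is identical, only access counts grow.
A join with an unranked side degenerates to a driven lookup (the unranked
side contributes a constant 0 to the bound), which is why stopping after k
matches is then exact.

Multiway joins are left-deep: intermediate joins run to exhaustion (so the
composition equals the definitional full join over the whole conjunctive
predicate) and only the final join exploits k. A connection may attach the
new stream to *any* earlier interface in the chain, not just the terminal
one — the disorder-after-expression expansion in the replay scenario
requires exactly that. Many downstream records matching one upstream
record each yield a distinct tuple (no per-entity deduplication at the
join layer; the atom view groups them later, and collapsing earlier would
lose provenance). `full_join_oracle` provides the definitional semantics
(hash joins, everything materialized, sorted with the same tie-break) and
is the reference the threshold path is verified against on hundreds of
seeded random instances; a cartesian-product enumeration in the test suite
independently checks the oracle itself at tiny sizes.

## Planner

Invocation orders are left-deep only (exploration adds one service at a
time, so bushy plans never arise). An order is feasible when every step is
either user-bound or reachable as the target of a connection from an
already-placed step; the lexicographically first usable connection is
recorded as the step's binding. The expected cost is a multiplicative
cascade — step 1 runs once; step *i* runs
`Π_{j<i} size_j × Π_{2≤j≤i} sel_j` times (selectivity 1 for a user-bound
step); total cost sums invocations × unit cost. The functional form is a
declared design choice, not an empirically fitted model. Defaults when statistics
are absent: size = the adapter's `max_k` or 10, selectivity = 0.5, unit
cost = 1 — overridable in the query/stats config. `choose_plan` is the
exhaustive argmin with lexicographic tie-break, verified against an
independent permutation search for queries of up to 4 services.

## Exploration and history

The history is a tree, not a stack: `back` moves a pointer, and a
subsequent different expansion creates a sibling branch. Nodes are
immutable snapshots (query steps, weights, selection, cached result);
`reweight` creates a child node rather than mutating, so weight changes are
as navigable as expansions. The tree has a pristine root node (no state,
no result) above the first `start` node; this supports multiple independent
start branches in one session and makes the canonical replay — start,
three expansions, one back, one different expansion — a 6-node tree with
branching factor 2 at the third action node. `back` at a start node is an
error; the pristine root is not navigable.

Service responses are cached per tree under the key (interface,
canonicalized sorted bindings, k); expansion invokes the downstream
service once per distinct deduplicated join-key binding of the *selected*
upstream rows, and navigation or reweighting never invokes anything — the
adapter call counters make this observable and tested. Per-tree (rather
than global) cache scope keeps tests hermetic. The default k per expansion
is 50, overridable per step. The atom view projects a node's result into
distinct attribute-value groups per interface, each cross-linked to its
tuples and their 1-based global-rank positions. Histories serialize to
JSON (nodes, results, cache, pointer) and round-trip byte-identically.

## Synthetic worlds and fixtures

`make_synthetic_world(seed, ...)` generates the five-topic landscape behind
the shipped registry: alignment hits with e-values drawn log-uniformly over
[1e-180, 1] (BLAST's dynamic range; a configurable tie mass duplicates
values), a protein→gene lookup, a gene-expression service with uniform
p-values in which a planted subset of genes (default 5) is co-expressed
under the queried tumor/up condition while the rest are expressed only
under a control condition, gene→function and protein→disorder lookups.
Same seed ⇒ bit-identical tables. The generator emulates the *structure*
of real service answers (ranked streams, ties, truncation, key joins), not
their content: no sequence model, no real expression data, no ontology
structure — so passing tests demonstrate the engine's join/score/explore
semantics, not biological validity of any particular ranking.

The PAX fixture embeds the reference values of the worked use case (see
the package README): four alignment expectations, two tied 1e-11 p-values
plus 0.0030 and 0.041, apoptosis-regulation annotations for the four
genes, and a PAX6 distractor whose gene deliberately lacks both the tumor
expression record and the annotation. Only those known rows are included —
the live services' full answer sets are not reproducible — so replay
assertions are about counts and ordering, never about absolute scores.
Under `complement` with equal weights the engine yields the reference
relative order (PAX2, PAX8 above PAX7 above mouse Pax8); under `neglog`
(C=100) PAX7's much stronger alignment outweighs PAX8's stronger
expression and the order changes — a worked illustration that the choice
of normalization, not just the weights, shapes the global ranking.

## Numerical and scale choices

Verification suites run at desk scale: random join instances use streams of
up to 60 records with keys from a 12-symbol alphabet (frequent matches),
100 seeded instances per shape; planted-head early-termination instances
use 1000 padding records per stream; planner checks cover all queries of
up to 4 services over 100 random stat sets; exploration invariants run 50
random action walks. Score comparisons in tests use absolute tolerance
1e-12; weight-sum validation uses 1e-9. All randomness flows from explicit
seeds (numpy `default_rng`); hypothesis-based property tests run
derandomized.

## Known limitations

- Live adapters are an interface only; no network code is exercised.
- The threshold join materializes streams (access counts are semantic
  instrumentation, not I/O savings against a remote service).
- Only equality predicates; no ontology-aware attribute matching.
- Consensus/median ranking across sources is out of scope by design.
- The planner's cost model is uncalibrated; it orders plans plausibly but
  its absolute numbers are unit-free.
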