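"""Ranking-aware top-k joins over ranked service result streams.

The engine combines partially ranked streams (each ordered by a service's
ranked attribute, possibly with ties and possibly truncated to a service-side
top k) under conjunctive attribute-equality predicates, and returns the k
joined tuples with the highest weighted global score.

The algorithm is a threshold-style aggregation in the Fagin family: both
sides of a binary join are consumed by alternating *sorted accesses*; every
newly seen record is probed against the partners seen so far (hash on the
join key) and — when the opposite side supports *random access* by key —
against its not-yet-seen partners as well.  An optimistic bound on the score
of any still-undiscovered combination is maintained from the score frontier
of each stream, and the join stops as soon as the k-th best discovered score
strictly exceeds that bound.  Without random access the engine keeps
buffering seen records (NRA-style); correctness is unchanged, only the
access counts grow.

Multiway joins are executed as left-deep compositions of binary joins with
intermediate results fully materialized, which keeps the semantics equal to
the definitional full join over the whole conjunctive predicate
(intersection semantics: a tuple survives only if present in every stream).

``full_join_oracle`` provides those definitional semantics directly (hash
joins, every combination materialized and sorted) and is the reference the
threshold join is verified against.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

from .errors import JoinError
from .scoring import (
    PartialScore,
    WeightConfig,
    normalize,
    rank_normalize,
    ranking_sort_key,
    sort_ranked,
)
from .service_model import (
    Clause,
    ConnectionPattern,
    Direction,
    ServiceInterface,
    canonical_value,
)

__all__ = [
    "RankedStream",
    "CombinedTuple",
    "TopKResult",
    "JoinSpec",
    "full_join_oracle",
    "rank_join_topk",
    "multiway_rank_join",
    "bind_subquery",
    "passthrough_tuples",
    "stream_scores",
]


@dataclass
class RankedStream:
    """An ordered, possibly tied, possibly truncated sequence of records.

    ``records`` are attribute-value maps (string values as delivered by the
    adapter).  Construction sorts stably by the ranked attribute under its
    direction, so tied raw values stay adjacent in delivery order, then
    truncates to ``truncation`` records.  An unranked stream keeps its
    deterministic delivery order and scores a constant 1.0.
    """

    interface: str
    records: list[dict]
    ranked_attribute: Optional[str] = None
    direction: Optional[Direction] = None
    truncation: Optional[int] = None
    supports_random_access: bool = False

    def __post_init__(self):
        if self.ranked_attribute is not None:
            if self.direction is None:
                self.direction = Direction.ASCENDING_BETTER
            try:
                keyed = [float(r[self.ranked_attribute]) for r in self.records]
            except KeyError:
                raise JoinError(
                    f"stream {self.interface!r}: record missing ranked attribute "
                    f"{self.ranked_attribute!r}"
                ) from None
            reverse = self.direction is Direction.DESCENDING_BETTER
            order = sorted(range(len(self.records)), key=lambda i: (-keyed[i] if reverse else keyed[i]))
            self.records = [self.records[i] for i in order]
        if self.truncation is not None:
            if self.truncation < 0:
                raise JoinError("stream truncation must be >= 0")
            self.records = self.records[: self.truncation]

    def __len__(self):
        return len(self.records)


def stream_scores(stream: RankedStream, weights: WeightConfig) -> list[float]:
    """Normalized partial score of every visible record of a stream."""
    if stream.ranked_attribute is None:
        return [1.0] * len(stream.records)
    strategy = weights.strategy(stream.interface)
    raws = [float(r[stream.ranked_attribute]) for r in stream.records]
    if strategy.kind == "rank_based":
        return rank_normalize(raws, stream.direction)
    return [normalize(v, stream.direction, strategy) for v in raws]


@dataclass(frozen=True)
class CombinedTuple:
    """A joined multi-service result.

    ``records`` maps interface name to the contributing record; ``partials``
    carries the normalized partial score of every ranked interface;
    ``global_score`` is always recomputable from the partials and the weight
    configuration.  ``provenance`` lists (interface, record index within its
    stream) in plan order; ``key`` accumulates the canonical join-key values
    of every join the tuple went through (used in the deterministic
    tie-break).
    """

    records: Mapping[str, Mapping[str, str]]
    partials: Mapping[str, PartialScore]
    global_score: float
    provenance: tuple[tuple[str, int], ...]
    key: tuple[str, ...] = ()

    def with_global_score(self, g: float) -> "CombinedTuple":
        return replace(self, global_score=g)

    @property
    def row_id(self) -> str:
        return "|".join(f"{i}:{idx}" for i, idx in self.provenance)


@dataclass
class TopKResult:
    """Ordered join output plus per-stream access instrumentation."""

    tuples: list[CombinedTuple]
    access_stats: dict[str, dict[str, int]] = field(default_factory=dict)
    exhausted: dict[str, bool] = field(default_factory=dict)

    def __len__(self):
        return len(self.tuples)


@dataclass(frozen=True)
class JoinSpec:
    """One predicate application: which earlier interface feeds which clauses."""

    connection: ConnectionPattern
    source_interface: str


def _clause_key_source(record: Mapping, clauses: Sequence[Clause], iface: str) -> tuple[str, ...]:
    try:
        return tuple(canonical_value(record[c.source]) for c in clauses)
    except KeyError as exc:
        raise JoinError(f"record of {iface!r} missing join attribute {exc.args[0]!r}") from None


def _clause_key_target(record: Mapping, clauses: Sequence[Clause], iface: str) -> tuple[str, ...]:
    try:
        return tuple(canonical_value(record[c.target]) for c in clauses)
    except KeyError as exc:
        raise JoinError(f"record of {iface!r} missing join attribute {exc.args[0]!r}") from None


def _left_key(t: CombinedTuple, joins: Sequence[JoinSpec]) -> tuple[str, ...]:
    key: tuple[str, ...] = ()
    for j in joins:
        if j.source_interface not in t.records:
            raise JoinError(
                f"join source interface {j.source_interface!r} not present in left tuple"
            )
        key += _clause_key_source(t.records[j.source_interface], j.connection.clauses, j.source_interface)
    return key


def _right_key(record: Mapping, joins: Sequence[JoinSpec], iface: str) -> tuple[str, ...]:
    key: tuple[str, ...] = ()
    for j in joins:
        key += _clause_key_target(record, j.connection.clauses, iface)
    return key


def passthrough_tuples(
    stream: RankedStream,
    weights: WeightConfig,
    eff: Optional[Mapping[str, float]] = None,
    constant_unranked_score: float = 0.0,
) -> list[CombinedTuple]:
    """One CombinedTuple per stream record, in stream order.

    ``eff`` are the effective weights of the enclosing join (the stream's
    contribution is ``eff[iface] * normalized``).  For a stand-alone
    single-service result pass ``eff={iface: 1.0}`` so the global score is
    the normalized score itself; unranked streams then score
    ``constant_unranked_score`` (1.0 for user-facing passthrough, 0.0 as a
    join contribution).
    """
    iface = stream.interface
    out = []
    if stream.ranked_attribute is None:
        for idx, rec in enumerate(stream.records):
            out.append(
                CombinedTuple({iface: rec}, {}, constant_unranked_score, ((iface, idx),))
            )
        return out
    w = (eff or {}).get(iface, 0.0)
    norms = stream_scores(stream, weights)
    for idx, (rec, s) in enumerate(zip(stream.records, norms)):
        raw = float(rec[stream.ranked_attribute])
        out.append(
            CombinedTuple(
                {iface: rec},
                {iface: PartialScore(iface, raw, s)},
                w * s,
                ((iface, idx),),
            )
        )
    return out


# ---------------------------------------------------------------------------
# reference semantics


def full_join_oracle(
    streams: Sequence[RankedStream],
    joins: Sequence[Sequence[JoinSpec]],
    weights: WeightConfig,
) -> list[CombinedTuple]:
    """Materialize every predicate-satisfying combination, score and sort.

    ``joins[i]`` holds the predicate applications that attach
    ``streams[i+1]`` to earlier streams (conjunction over all specs).  This
    is the definitional join semantics the threshold algorithm is verified
    against.
    """
    if not streams:
        return []
    if len(joins) != len(streams) - 1:
        raise JoinError("need exactly one join spec group per stream after the first")
    ranked = [s.interface for s in streams if s.ranked_attribute is not None]
    eff = weights.effective_weights([n for n in ranked if n in weights.weights])
    current = passthrough_tuples(streams[0], weights, eff)
    for stream, specs in zip(streams[1:], joins):
        if not specs:
            raise JoinError(f"stream {stream.interface!r} attached without a join predicate")
        right = passthrough_tuples(stream, weights, eff)
        index: dict[tuple, list[CombinedTuple]] = defaultdict(list)
        for rt in right:
            index[_right_key(rt.records[stream.interface], specs, stream.interface)].append(rt)
        merged = []
        for lt in current:
            key = _left_key(lt, specs)
            for rt in index.get(key, []):
                merged.append(_merge(lt, rt, key))
        current = merged
    return sort_ranked(current)


def _merge(lt: CombinedTuple, rt: CombinedTuple, key: tuple[str, ...]) -> CombinedTuple:
    return CombinedTuple(
        {**lt.records, **rt.records},
        {**lt.partials, **rt.partials},
        lt.global_score + rt.global_score,
        lt.provenance + rt.provenance,
        lt.key + key,
    )


# ---------------------------------------------------------------------------
# threshold algorithm


class _Side:
    """One side of a binary threshold join: scored, key-addressable entries."""

    def __init__(self, tuples: Sequence[CombinedTuple], keys: Sequence[tuple], random_access: bool):
        self.tuples = list(tuples)
        self.keys = list(keys)
        self.random_access = random_access
        self.pos = 0
        self.sorted_count = 0
        self.random_count = 0
        self.max_seen: Optional[float] = None
        self.seen_by_key: dict[tuple, list[int]] = defaultdict(list)
        self.key_index: dict[tuple, list[int]] = defaultdict(list)
        for i, k in enumerate(self.keys):
            self.key_index[k].append(i)
        self.probed: set[tuple] = set()

    def __len__(self):
        return len(self.tuples)

    @property
    def exhausted(self) -> bool:
        return self.pos >= len(self.tuples)

    def next_unseen_bound(self) -> Optional[float]:
        if self.exhausted:
            return None
        return self.tuples[self.pos].global_score

    def pop(self) -> int:
        i = self.pos
        self.pos += 1
        self.sorted_count += 1
        k = self.keys[i]
        self.seen_by_key[k].append(i)
        s = self.tuples[i].global_score
        self.max_seen = s if self.max_seen is None else max(self.max_seen, s)
        return i

    def partners(self, key: tuple) -> list[int]:
        """Indices joinable with ``key``: all of them under random access
        (counted once per distinct probed key), else only those already seen."""
        if self.random_access:
            if key not in self.probed:
                self.probed.add(key)
                self.random_count += 1
            return self.key_index.get(key, [])
        return self.seen_by_key.get(key, [])


def _ta_join(
    left: _Side, right: _Side, k: Optional[int]
) -> list[CombinedTuple]:
    """Core alternating threshold join of two pre-scored sides."""
    if not left.tuples or not right.tuples:
        return []
    results: list[CombinedTuple] = []
    scores: list[float] = []
    found: set[tuple[int, int]] = set()
    sides = (left, right)

    def discover(li: int, ri: int):
        if (li, ri) in found:
            return
        found.add((li, ri))
        lt, rt = left.tuples[li], right.tuples[ri]
        merged = _merge(lt, rt, left.keys[li])
        results.append(merged)
        scores.append(merged.global_score)

    def bound() -> float:
        nl = left.next_unseen_bound()
        nr = right.next_unseen_bound()
        cands = []
        if nl is not None and nr is not None:
            cands.append(nl + nr)
        # (seen left, unseen right) pairs are impossible when the right side
        # is random-accessible: each seen left key was probed exhaustively.
        if nr is not None and not right.random_access and left.max_seen is not None:
            cands.append(left.max_seen + nr)
        if nl is not None and not left.random_access and right.max_seen is not None:
            cands.append(right.max_seen + nl)
        return max(cands) if cands else -math.inf

    turn = 0
    while not (left.exhausted and right.exhausted):
        side = sides[turn] if not sides[turn].exhausted else sides[1 - turn]
        other = sides[1] if side is left else sides[0]
        i = side.pop()
        key = side.keys[i]
        for j in other.partners(key):
            discover(i, j) if side is left else discover(j, i)
        turn = 1 - turn
        if k is not None and len(results) >= k:
            kth = sorted(scores, reverse=True)[k - 1]
            if kth > bound():
                break
    return results


def _side_from_tuples(
    tuples: Sequence[CombinedTuple], joins: Sequence[JoinSpec], random_access: bool
) -> _Side:
    ordered = sort_ranked(tuples)
    keys = [_left_key(t, joins) for t in ordered]
    return _Side(ordered, keys, random_access)


def _side_from_stream(
    stream: RankedStream, joins: Sequence[JoinSpec], weights: WeightConfig, eff: Mapping[str, float]
) -> _Side:
    tuples = passthrough_tuples(stream, weights, eff)
    keys = [_right_key(t.records[stream.interface], joins, stream.interface) for t in tuples]
    return _Side(tuples, keys, stream.supports_random_access)


def rank_join_topk(
    stream_a: RankedStream,
    stream_b: RankedStream,
    connection: Union[ConnectionPattern, JoinSpec, Sequence[JoinSpec]],
    weights: WeightConfig,
    k: Optional[int] = None,
) -> TopKResult:
    """Top-k threshold join of two ranked streams under one connection.

    Returns exactly the k best tuples of :func:`full_join_oracle` (same set,
    same order under the deterministic tie-break), with per-stream counts of
    sorted and random accesses and exhaustion flags.  ``k=None`` joins to
    exhaustion.
    """
    if k is not None and k < 1:
        raise JoinError("k must be >= 1")
    specs = _as_specs(connection, stream_a.interface)
    ranked = [s.interface for s in (stream_a, stream_b) if s.ranked_attribute is not None]
    eff = weights.effective_weights([n for n in ranked if n in weights.weights])
    left = _side_from_tuples(
        passthrough_tuples(stream_a, weights, eff), specs, stream_a.supports_random_access
    )
    right = _side_from_stream(stream_b, specs, weights, eff)
    tuples = sort_ranked(_ta_join(left, right, k))
    if k is not None:
        tuples = tuples[:k]
    return TopKResult(
        tuples,
        {
            stream_a.interface: {"sorted": left.sorted_count, "random": left.random_count},
            stream_b.interface: {"sorted": right.sorted_count, "random": right.random_count},
        },
        {stream_a.interface: left.exhausted, stream_b.interface: right.exhausted},
    )


def _as_specs(connection, default_source: str) -> list[JoinSpec]:
    if isinstance(connection, ConnectionPattern):
        return [JoinSpec(connection, default_source)]
    if isinstance(connection, JoinSpec):
        return [connection]
    specs = list(connection)
    if not specs or not all(isinstance(s, JoinSpec) for s in specs):
        raise JoinError("connection must be a ConnectionPattern or JoinSpec(s)")
    return specs


def multiway_rank_join(
    streams: Sequence[RankedStream],
    joins: Sequence[Sequence[JoinSpec]],
    weights: WeightConfig,
    k: Optional[int] = None,
) -> TopKResult:
    """Left-deep composition of binary threshold joins.

    ``joins[i]`` attaches ``streams[i+1]`` to any earlier interface(s);
    intermediate joins run to exhaustion so the result equals the oracle
    over the full multiway predicate, and only the final join applies ``k``.
    A single-stream plan is a scored passthrough.
    """
    if not streams:
        raise JoinError("multiway join needs at least one stream")
    if k is not None and k < 1:
        raise JoinError("k must be >= 1")
    if len(joins) != len(streams) - 1:
        raise JoinError("need exactly one join spec group per stream after the first")
    ranked = [s.interface for s in streams if s.ranked_attribute is not None]
    eff = weights.effective_weights([n for n in ranked if n in weights.weights])

    stats: dict[str, dict[str, int]] = {}
    exhausted: dict[str, bool] = {}

    if len(streams) == 1:
        s = streams[0]
        single_eff = {s.interface: 1.0} if s.ranked_attribute is not None else {}
        tuples = sort_ranked(
            passthrough_tuples(s, weights, single_eff, constant_unranked_score=1.0)
        )
        if k is not None:
            tuples = tuples[:k]
        stats[s.interface] = {"sorted": len(tuples), "random": 0}
        exhausted[s.interface] = len(tuples) == len(s.records)
        return TopKResult(tuples, stats, exhausted)

    current = passthrough_tuples(streams[0], weights, eff)
    first = True
    for step, (stream, specs) in enumerate(zip(streams[1:], joins)):
        if not specs:
            raise JoinError(f"stream {stream.interface!r} attached without a join predicate")
        last = step == len(streams) - 2
        left = _side_from_tuples(current, specs, random_access=True)
        right = _side_from_stream(stream, specs, weights, eff)
        current = _ta_join(left, right, k if last else None)
        if first:
            stats[streams[0].interface] = {
                "sorted": left.sorted_count,
                "random": left.random_count,
            }
            exhausted[streams[0].interface] = left.exhausted
            first = False
        stats[stream.interface] = {"sorted": right.sorted_count, "random": right.random_count}
        exhausted[stream.interface] = right.exhausted
    tuples = sort_ranked(current)
    if k is not None:
        tuples = tuples[:k]
    return TopKResult(tuples, stats, exhausted)


def bind_subquery(
    connection: Union[ConnectionPattern, JoinSpec],
    upstream: Sequence[Union[CombinedTuple, Mapping]],
    extra_inputs: Optional[Mapping[str, str]] = None,
) -> list[dict]:
    """Input bindings for the downstream service of a connection.

    One deduplicated binding per distinct join key, preserving upstream
    order of first appearance; each binding maps the connection's target
    input attributes to the upstream output values, merged with any
    user-supplied ``extra_inputs``.
    """
    if isinstance(connection, JoinSpec):
        clauses = connection.connection.clauses
        source_iface = connection.source_interface
    else:
        clauses = connection.clauses
        source_iface = None
    seen = set()
    out = []
    for item in upstream:
        if isinstance(item, CombinedTuple):
            if source_iface is not None:
                if source_iface not in item.records:
                    raise JoinError(f"upstream tuple lacks interface {source_iface!r}")
                record = item.records[source_iface]
            elif len(item.records) == 1:
                record = next(iter(item.records.values()))
            else:
                raise JoinError("multi-interface upstream tuples need a JoinSpec source")
        else:
            record = item
        key = _clause_key_source(record, clauses, source_iface or "<record>")
        if key in seen:
            continue
        seen.add(key)
        binding = {c.target: v for c, v in zip(clauses, key)}
        if extra_inputs:
            binding.update({a: canonical_value(v) for a, v in extra_inputs.items()})
        out.append(binding)
    return out
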