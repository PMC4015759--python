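"""Liquid-query exploration: expand, reweight, and navigate a history tree.

An exploration starts from a single-service query, whose ranked result the
user inspects.  Each *expansion* joins (a selected subset of) the current
result with a further service along a registered connection pattern,
producing a new ranked, globally scored result; *reweighting* re-ranks a
result under new relative weights without touching any service.  Every
action creates an immutable node in a **history tree**: moving backward and
forward is pure pointer navigation, and a backward step followed by a
different expansion creates a sibling branch rather than overwriting
history.  Intermediate service responses are cached per tree keyed by
(interface, canonicalized input bindings), so no sub-query is ever sent to
a service twice within one exploration, regardless of navigation.

The tree holds a pristine root node (empty state, no result) whose children
are the ``start`` nodes; it is structural only and cannot be navigated to.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence, Union

from .adapters import TableService
from .errors import ExplorationError
from .rank_join import (
    CombinedTuple,
    JoinSpec,
    RankedStream,
    TopKResult,
    _side_from_stream,
    _side_from_tuples,
    _ta_join,
    bind_subquery,
    passthrough_tuples,
)
from .scoring import (
    COMPLEMENT,
    NormalizationStrategy,
    PartialScore,
    WeightConfig,
    reweight as score_reweight,
    sort_ranked,
)
from .service_model import Registry, canonical_value

__all__ = [
    "Step",
    "QueryState",
    "ExplorationNode",
    "HistoryTree",
    "AtomGroup",
    "AtomView",
    "start",
    "expand",
    "back",
    "forward",
    "reweight_node",
    "atom_view",
    "serialize_history",
    "load_history",
]

DEFAULT_K = 50


@dataclass(frozen=True)
class Step:
    """One service of a query chain and how it was attached."""

    interface: str
    connection: Optional[str] = None        # None for the start step
    source_interface: Optional[str] = None  # earlier interface feeding the join
    extra_inputs: tuple[tuple[str, str], ...] = ()
    selection: Optional[tuple[str, ...]] = None  # upstream row ids this step used
    k: int = DEFAULT_K


@dataclass(frozen=True)
class QueryState:
    """Immutable snapshot of the query a node represents."""

    steps: tuple[Step, ...]
    weights: WeightConfig

    @property
    def interfaces(self) -> tuple[str, ...]:
        return tuple(s.interface for s in self.steps)


@dataclass
class ExplorationNode:
    """One state of the exploration; immutable once created.

    ``children`` is the only mutable field and is append-only.
    """

    node_id: str
    parent_id: Optional[str]
    action: str  # root | start | expand | reweight
    state: Optional[QueryState]
    result: Optional[TopKResult]
    children: list[str] = field(default_factory=list)


class HistoryTree:
    """Branching record of exploration states with a per-tree result cache."""

    def __init__(
        self,
        registry: Registry,
        adapters: Mapping[str, TableService],
        default_strategy: NormalizationStrategy = COMPLEMENT,
        on_invoke: Optional[Callable] = None,
    ):
        self.registry = registry
        self.adapters = dict(adapters)
        self.default_strategy = default_strategy
        self.on_invoke = on_invoke
        self.nodes: dict[str, ExplorationNode] = {}
        self._counter = 0
        root = self._new_node(None, "root", None, None)
        self.root_id = root.node_id
        self.current_id = root.node_id
        self._cache: dict[tuple, list[dict]] = {}

    # -- plumbing ---------------------------------------------------------

    def _new_node(self, parent_id, action, state, result) -> ExplorationNode:
        node = ExplorationNode(f"n{self._counter}", parent_id, action, state, result)
        self._counter += 1
        self.nodes[node.node_id] = node
        if parent_id is not None:
            self.nodes[parent_id].children.append(node.node_id)
        return node

    def node(self, node_id: str) -> ExplorationNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise ExplorationError(f"unknown node {node_id!r}") from None

    @property
    def current(self) -> ExplorationNode:
        return self.nodes[self.current_id]

    def _resolve(self, node: Union[ExplorationNode, str, None]) -> ExplorationNode:
        if node is None:
            return self.current
        if isinstance(node, ExplorationNode):
            return self.node(node.node_id)
        return self.node(node)

    def cached_invoke(self, interface: str, bindings: Mapping[str, str], k: int) -> list[dict]:
        """Invoke a service through the per-tree cache.

        Cache key: (interface, canonicalized sorted bindings, k).  Hits do
        not touch the adapter, so its call counter observes real traffic.
        """
        if interface not in self.adapters:
            raise ExplorationError(f"no adapter available for interface {interface!r}")
        key = (
            interface,
            tuple(sorted((a, canonical_value(v)) for a, v in bindings.items())),
            k,
        )
        cached = key in self._cache
        if not cached:
            self._cache[key] = self.adapters[interface].invoke(bindings, k)
        records = self._cache[key]
        if self.on_invoke is not None:
            self.on_invoke(interface, dict(bindings), len(records), cached)
        return [dict(r) for r in records]

    def adapter_calls(self) -> dict[str, int]:
        return {name: svc.descriptor.calls for name, svc in self.adapters.items()}

    def _stream(self, interface: str, records: list[dict]) -> RankedStream:
        pattern = self.registry.interface_pattern(interface)
        iface = self.registry.interfaces[interface]
        return RankedStream(
            interface,
            records,
            pattern.ranked_attribute,
            pattern.ranked_direction,
            supports_random_access=iface.adapter.supports_random_access,
        )


def start(
    registry: Registry,
    adapters: Mapping[str, TableService],
    interface: str,
    user_inputs: Mapping[str, str],
    weights: Optional[WeightConfig] = None,
    k: int = DEFAULT_K,
    strategy: NormalizationStrategy = COMPLEMENT,
    on_invoke: Optional[Callable] = None,
) -> tuple[HistoryTree, ExplorationNode]:
    """Open an exploration with a single-service query.

    The root result carries the service's normalized partial scores as
    global scores (constant 1.0 for an unranked service).  All input-role
    attributes of the interface's access pattern must be bound.
    """
    tree = HistoryTree(registry, adapters, strategy, on_invoke)
    pattern = tree.registry.interface_pattern(interface)
    missing = [a for a in pattern.input_attributes if a not in user_inputs]
    if missing:
        raise ExplorationError(f"start({interface}): missing required input(s) {missing}")
    records = tree.cached_invoke(interface, user_inputs, k)
    stream = tree._stream(interface, records)
    ranked = [interface] if stream.ranked_attribute is not None else []
    if weights is None:
        weights = WeightConfig.equal(ranked, strategy)
    weights.validate()
    eff = {interface: 1.0} if ranked else {}
    tuples = sort_ranked(passthrough_tuples(stream, weights, eff, constant_unranked_score=1.0))
    result = TopKResult(
        tuples,
        {interface: {"sorted": len(records), "random": 0}},
        {interface: len(records) < k},
    )
    step = Step(interface, extra_inputs=tuple(sorted((a, str(v)) for a, v in user_inputs.items())), k=k)
    node = tree._new_node(tree.root_id, "start", QueryState((step,), weights), result)
    tree.current_id = node.node_id
    return tree, node


def expand(
    tree: HistoryTree,
    node: Union[ExplorationNode, str, None],
    connection: str,
    downstream_interface: str,
    extra_inputs: Optional[Mapping[str, str]] = None,
    selection: Optional[Sequence[str]] = None,
    weights: Optional[WeightConfig] = None,
    k: Optional[int] = None,
) -> ExplorationNode:
    """Join a node's (selected) result with a further service.

    The connection pattern must link a mart already present in the node's
    chain (the latest matching interface feeds the join) to the downstream
    interface's mart.  Upstream responses come from the tree cache; the
    downstream service is invoked once per distinct deduplicated binding.
    """
    node = tree._resolve(node)
    if node.action == "root":
        raise ExplorationError("cannot expand the pristine root; start a query first")
    if connection not in tree.registry.connection_patterns:
        raise ExplorationError(f"unknown connection pattern {connection!r}")
    cp = tree.registry.connection_patterns[connection]
    down_pattern = tree.registry.interface_pattern(downstream_interface)
    if down_pattern.mart != cp.target_mart:
        raise ExplorationError(
            f"connection {connection!r} targets mart {cp.target_mart!r}, "
            f"but {downstream_interface!r} serves {down_pattern.mart!r}"
        )
    # latest chain interface over the connection's source mart feeds the join
    source_interface = None
    for step in reversed(node.state.steps):
        if tree.registry.interface_pattern(step.interface).mart == cp.source_mart:
            source_interface = step.interface
            break
    if source_interface is None:
        raise ExplorationError(
            f"connection {connection!r} not applicable: no interface over mart "
            f"{cp.source_mart!r} in the current chain"
        )
    spec = JoinSpec(cp, source_interface)
    k = k if k is not None else DEFAULT_K

    row_ids = {t.row_id for t in node.result.tuples}
    if selection is None:
        selected = list(node.result.tuples)
        sel_field = None
    else:
        selection = tuple(selection)
        bad = [s for s in selection if s not in row_ids]
        if bad:
            raise ExplorationError(f"selection contains unknown row id(s) {bad}")
        keep = set(selection)
        selected = [t for t in node.result.tuples if t.row_id in keep]
        sel_field = selection
        if not selected:
            warnings.warn("empty selection: expansion produces an empty result", stacklevel=2)

    bindings = bind_subquery(spec, selected, extra_inputs)
    records: list[dict] = []
    for b in bindings:
        missing = [a for a in down_pattern.input_attributes if a not in b]
        if missing:
            raise ExplorationError(
                f"expand({downstream_interface}): missing required input(s) {missing}"
            )
        records.extend(tree.cached_invoke(downstream_interface, b, k))
    down_stream = tree._stream(downstream_interface, records)

    chain_ifaces = list(node.state.interfaces) + [downstream_interface]
    ranked = [
        i for i in chain_ifaces if tree.registry.interface_pattern(i).ranked_attribute is not None
    ]
    if weights is None:
        old = node.state.weights
        weights = WeightConfig.equal(
            ranked, tree.default_strategy, strategies=dict(old.strategies)
        )
    weights.validate()
    eff = weights.effective_weights([i for i in ranked if i in weights.weights])

    # re-score the selected upstream tuples under the extended weights
    left_tuples = []
    for t in selected:
        g = sum(eff.get(i, 0.0) * p.normalized for i, p in t.partials.items())
        left_tuples.append(t.with_global_score(g))
    left = _side_from_tuples(left_tuples, [spec], random_access=True)
    right = _side_from_stream(down_stream, [spec], weights, eff)
    tuples = sort_ranked(_ta_join(left, right, k))[:k]

    stats = {i: dict(v) for i, v in node.result.access_stats.items()}
    stats[downstream_interface] = {"sorted": right.sorted_count, "random": right.random_count}
    exhausted = dict(node.result.exhausted)
    exhausted[downstream_interface] = right.exhausted
    result = TopKResult(tuples, stats, exhausted)

    step = Step(
        downstream_interface,
        connection=connection,
        source_interface=source_interface,
        extra_inputs=tuple(sorted((a, str(v)) for a, v in (extra_inputs or {}).items())),
        selection=sel_field,
        k=k,
    )
    child = tree._new_node(
        node.node_id, "expand", QueryState(node.state.steps + (step,), weights), result
    )
    tree.current_id = child.node_id
    return child


def back(tree: HistoryTree) -> ExplorationNode:
    """Move the current pointer to the parent node (no recomputation)."""
    cur = tree.current
    if cur.parent_id is None or cur.parent_id == tree.root_id:
        raise ExplorationError("already at the initial query; cannot move back")
    tree.current_id = cur.parent_id
    return tree.current


def forward(tree: HistoryTree, child_id: str) -> ExplorationNode:
    """Move the current pointer to a named child (no recomputation)."""
    cur = tree.current
    if child_id not in cur.children:
        raise ExplorationError(f"node {cur.node_id!r} has no child {child_id!r}")
    tree.current_id = child_id
    return tree.current


def reweight_node(
    tree: HistoryTree,
    node: Union[ExplorationNode, str, None],
    weights: WeightConfig,
) -> ExplorationNode:
    """Re-rank a node's tuples under new relative weights (zero invocations)."""
    node = tree._resolve(node)
    if node.result is None:
        raise ExplorationError("cannot reweight the pristine root")
    weights.validate()
    tuples = score_reweight(node.result.tuples, weights)
    result = TopKResult(tuples, {i: dict(v) for i, v in node.result.access_stats.items()},
                        dict(node.result.exhausted))
    child = tree._new_node(
        node.node_id, "reweight", replace(node.state, weights=weights), result
    )
    tree.current_id = child.node_id
    return child


# ---------------------------------------------------------------------------
# atom view


@dataclass
class AtomGroup:
    """One distinct attribute-value combination of an interface."""

    values: dict
    tuple_ids: list[str]
    ranks: list[int]  # 1-based global rank positions, ascending


@dataclass
class AtomView:
    """Distinct values per interface, cross-linked to tuples and ranks."""

    groups: dict[str, list[AtomGroup]]


def atom_view(node: ExplorationNode) -> AtomView:
    """Project a node's result into per-interface distinct value groups.

    Every tuple appears in exactly one group per interface; rank positions
    are 1-based and consistent with the node's result order.
    """
    if node.result is None:
        raise ExplorationError("the pristine root has no result to project")
    groups: dict[str, list[AtomGroup]] = {}
    for iface in node.state.interfaces if node.state else []:
        by_identity: dict[tuple, AtomGroup] = {}
        ordered: list[AtomGroup] = []
        for rank, t in enumerate(node.result.tuples, start=1):
            rec = t.records.get(iface)
            if rec is None:
                continue
            identity = tuple(sorted(rec.items()))
            grp = by_identity.get(identity)
            if grp is None:
                grp = AtomGroup(dict(rec), [], [])
                by_identity[identity] = grp
                ordered.append(grp)
            grp.tuple_ids.append(t.row_id)
            grp.ranks.append(rank)
        groups[iface] = ordered
    return AtomView(groups)


# ---------------------------------------------------------------------------
# serialization


def _weights_to_dict(w: WeightConfig) -> dict:
    return w.to_dict()


def _step_to_dict(s: Step) -> dict:
    return {
        "interface": s.interface,
        "connection": s.connection,
        "source_interface": s.source_interface,
        "extra_inputs": [list(p) for p in s.extra_inputs],
        "selection": list(s.selection) if s.selection is not None else None,
        "k": s.k,
    }


def _tuple_to_dict(t: CombinedTuple) -> dict:
    return {
        "records": {i: dict(r) for i, r in t.records.items()},
        "partials": {
            i: {"interface": p.interface, "raw_value": p.raw_value, "normalized": p.normalized}
            for i, p in t.partials.items()
        },
        "global_score": t.global_score,
        "provenance": [list(p) for p in t.provenance],
        "key": list(t.key),
    }


def _result_to_dict(r: Optional[TopKResult]) -> Optional[dict]:
    if r is None:
        return None
    return {
        "tuples": [_tuple_to_dict(t) for t in r.tuples],
        "access_stats": {i: dict(v) for i, v in r.access_stats.items()},
        "exhausted": dict(r.exhausted),
    }


def serialize_history(tree: HistoryTree) -> dict:
    """JSON-able document capturing nodes, cached results and the pointer."""
    return {
        "format": "federank-history",
        "version": 1,
        "root": tree.root_id,
        "current": tree.current_id,
        "counter": tree._counter,
        "default_strategy": tree.default_strategy.to_dict(),
        "nodes": [
            {
                "id": n.node_id,
                "parent": n.parent_id,
                "action": n.action,
                "state": None
                if n.state is None
                else {
                    "steps": [_step_to_dict(s) for s in n.state.steps],
                    "weights": _weights_to_dict(n.state.weights),
                },
                "result": _result_to_dict(n.result),
                "children": list(n.children),
            }
            for n in tree.nodes.values()
        ],
        "cache": [
            {"interface": i, "bindings": [list(p) for p in b], "k": k, "records": recs}
            for (i, b, k), recs in tree._cache.items()
        ],
    }


def history_to_json(tree: HistoryTree) -> str:
    return json.dumps(serialize_history(tree), indent=2, sort_keys=True)


def _tuple_from_dict(d: Mapping) -> CombinedTuple:
    return CombinedTuple(
        {i: dict(r) for i, r in d["records"].items()},
        {
            i: PartialScore(p["interface"], p["raw_value"], p["normalized"])
            for i, p in d["partials"].items()
        },
        d["global_score"],
        tuple((i, idx) for i, idx in d["provenance"]),
        tuple(d["key"]),
    )


def load_history(
    document: Union[Mapping, str],
    registry: Registry,
    adapters: Mapping[str, TableService],
) -> HistoryTree:
    """Rebuild a tree from a serialized document (round-trip identical)."""
    if isinstance(document, str):
        document = json.loads(document)
    try:
        if document.get("format") != "federank-history":
            raise ExplorationError("document is not a federank history (format field)")
        nodes = document["nodes"]
        if not nodes:
            raise ExplorationError("history document has no nodes")
        tree = HistoryTree(
            registry,
            adapters,
            NormalizationStrategy.from_dict(document.get("default_strategy", "complement")),
        )
        tree.nodes.clear()
        for nd in nodes:
            state = None
            if nd["state"] is not None:
                state = QueryState(
                    tuple(
                        Step(
                            s["interface"],
                            s["connection"],
                            s["source_interface"],
                            tuple(tuple(p) for p in s["extra_inputs"]),
                            tuple(s["selection"]) if s["selection"] is not None else None,
                            s["k"],
                        )
                        for s in nd["state"]["steps"]
                    ),
                    WeightConfig.from_dict(nd["state"]["weights"]),
                )
            result = None
            if nd["result"] is not None:
                result = TopKResult(
                    [_tuple_from_dict(t) for t in nd["result"]["tuples"]],
                    {i: dict(v) for i, v in nd["result"]["access_stats"].items()},
                    dict(nd["result"]["exhausted"]),
                )
            tree.nodes[nd["id"]] = ExplorationNode(
                nd["id"], nd["parent"], nd["action"], state, result, list(nd["children"])
            )
        tree.root_id = document["root"]
        tree.current_id = document["current"]
        tree._counter = document.get("counter", len(nodes))
        if tree.root_id not in tree.nodes:
            raise ExplorationError(f"history/root: unknown node {tree.root_id!r}")
        for nd in tree.nodes.values():
            if nd.parent_id is not None and nd.parent_id not in tree.nodes:
                raise ExplorationError(f"history/nodes/{nd.node_id}: missing parent {nd.parent_id!r}")
        tree._cache = {
            (
                c["interface"],
                tuple(tuple(p) for p in c["bindings"]),
                c["k"],
            ): [dict(r) for r in c["records"]]
            for c in document.get("cache", [])
        }
        return tree
    except (KeyError, TypeError) as exc:
        raise ExplorationError(f"malformed history document: {exc!r}") from exc
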