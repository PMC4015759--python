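"""Cost-based selection of service invocation orders.

A multi-service query is executed as a left-deep chain: the first service
is called once with the user's inputs, and each later service is called
once per surviving upstream binding.  The planner enumerates every feasible
left-deep order (a service can be placed when its inputs are bound by the
user or by a connection from an already-placed service) and picks the order
with the smallest expected invocation cost.

Cost model (a declared choice — multiplicative cascade):

* the first step performs 1 invocation;
* step *i* performs ``prod_{j<i} size_j  ×  prod_{2<=j<=i} sel_j``
  invocations, where ``size_j`` is the expected result size of the service
  at step *j* and ``sel_j`` the selectivity of the connection that binds
  step *j* (1 for a user-bound step);
* total cost is the sum over steps of invocations × unit invocation cost.

Defaults when statistics are not supplied: expected result size = the
adapter's declared ``max_k`` or 10, selectivity = 0.5, unit cost = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import PlanError

__all__ = ["ConnectionRef", "Query", "ServiceStats", "QueryPlan", "PlanStep",
           "enumerate_plans", "estimate_cost", "choose_plan"]

DEFAULT_RESULT_SIZE = 10.0
DEFAULT_SELECTIVITY = 0.5
DEFAULT_UNIT_COST = 1.0


@dataclass(frozen=True)
class ConnectionRef:
    """A usable join edge between two interfaces of the query."""

    name: str
    source: str
    target: str


@dataclass(frozen=True)
class Query:
    """The sub-queries of a global query and how they can be bound."""

    interfaces: tuple[str, ...]
    connections: tuple[ConnectionRef, ...]
    user_bound: frozenset  # interfaces whose inputs the user supplies

    @classmethod
    def build(cls, interfaces, connections, user_bound) -> "Query":
        ifaces = tuple(interfaces)
        conns = tuple(
            c if isinstance(c, ConnectionRef) else ConnectionRef(**c) for c in connections
        )
        known = set(ifaces)
        for c in conns:
            if c.source not in known or c.target not in known:
                raise PlanError(f"connection {c.name!r} references unknown interface")
        bound = frozenset(user_bound)
        unknown = bound - known
        if unknown:
            raise PlanError(f"user-bound interfaces not in query: {sorted(unknown)}")
        return cls(ifaces, conns, bound)


@dataclass(frozen=True)
class ServiceStats:
    """Expected sizes, selectivities and unit costs for cost estimation."""

    result_size: Mapping[str, float] = field(default_factory=dict)
    selectivity: Mapping[str, float] = field(default_factory=dict)  # by connection name
    unit_cost: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, v in self.result_size.items():
            if not (v >= 0):
                raise PlanError(f"result_size[{name!r}] must be >= 0")
        for name, v in self.selectivity.items():
            if not (0.0 <= v <= 1.0):
                raise PlanError(f"selectivity[{name!r}] must be in [0, 1]")
        for name, v in self.unit_cost.items():
            if not (v > 0):
                raise PlanError(f"unit_cost[{name!r}] must be > 0")

    def size(self, interface: str) -> float:
        return float(self.result_size.get(interface, DEFAULT_RESULT_SIZE))

    def sel(self, connection: Optional[str]) -> float:
        if connection is None:
            return 1.0
        return float(self.selectivity.get(connection, DEFAULT_SELECTIVITY))

    def cost(self, interface: str) -> float:
        return float(self.unit_cost.get(interface, DEFAULT_UNIT_COST))


@dataclass(frozen=True)
class PlanStep:
    interface: str
    connection: Optional[str]  # None when bound by user inputs


@dataclass(frozen=True)
class QueryPlan:
    steps: tuple[PlanStep, ...]
    cost: Optional[float] = None

    @property
    def order(self) -> tuple[str, ...]:
        return tuple(s.interface for s in self.steps)


def _connected(query: Query) -> bool:
    if len(query.interfaces) <= 1:
        return True
    adj: dict[str, set] = {i: set() for i in query.interfaces}
    for c in query.connections:
        adj[c.source].add(c.target)
        adj[c.target].add(c.source)
    seen = {query.interfaces[0]}
    frontier = [query.interfaces[0]]
    while frontier:
        nxt = frontier.pop()
        for m in adj[nxt]:
            if m not in seen:
                seen.add(m)
                frontier.append(m)
    return len(seen) == len(query.interfaces)


def enumerate_plans(query: Query) -> list[QueryPlan]:
    """All feasible left-deep invocation orders, lexicographically ordered.

    A step is feasible if its interface is user-bound or some connection
    reaches it (as target) from an already-placed interface; the step
    records the lexicographically first such connection as its binding.
    """
    if not query.interfaces:
        raise PlanError("empty query")
    if not _connected(query):
        raise PlanError("query connection graph is disconnected")
    plans: list[QueryPlan] = []

    def binder(iface: str, placed: Sequence[str]) -> Optional[PlanStep]:
        if not placed:
            return PlanStep(iface, None) if iface in query.user_bound else None
        usable = sorted(
            c.name for c in query.connections if c.target == iface and c.source in set(placed)
        )
        if usable:
            return PlanStep(iface, usable[0])
        if iface in query.user_bound:
            return PlanStep(iface, None)
        return None

    def rec(placed: list[PlanStep]):
        if len(placed) == len(query.interfaces):
            plans.append(QueryPlan(tuple(placed)))
            return
        names = [s.interface for s in placed]
        for iface in sorted(set(query.interfaces) - set(names)):
            step = binder(iface, names)
            if step is not None:
                placed.append(step)
                rec(placed)
                placed.pop()

    rec([])
    if not plans:
        raise PlanError("no feasible invocation order (unbindable inputs)")
    return plans


def estimate_cost(plan: QueryPlan, stats: ServiceStats) -> float:
    """Expected total invocation cost of a plan under the cascade model."""
    total = 0.0
    invocations = 1.0
    for i, step in enumerate(plan.steps):
        if i > 0:
            invocations *= stats.size(plan.steps[i - 1].interface) * stats.sel(step.connection)
        total += invocations * stats.cost(step.interface)
    return total


def choose_plan(query: Query, stats: Optional[ServiceStats] = None) -> QueryPlan:
    """Minimum-cost feasible plan; ties broken by interface-name sequence."""
    stats = stats or ServiceStats()
    plans = enumerate_plans(query)
    best = min(plans, key=lambda p: (estimate_cost(p, stats), p.order))
    return QueryPlan(best.steps, estimate_cost(best, stats))
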