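"""Registry of search services and their semantic connections.

A federated ranked-search engine needs a static description of the services
it can call before it can join their results.  The description has three
levels:

* a **service mart** is the normalized conceptual description of a class of
  search services (a topic such as *Protein* or *Gene Expression*), carrying
  the union of the normalized attribute names those services expose;
* an **access pattern** is a signature of a mart marking each attribute as
  input, output, or ranked output (a service that returns its records
  ordered by an attribute, e.g. a sequence-similarity expectation value);
* a **service interface** binds an access pattern to a concrete callable
  adapter (a wrapped endpoint, here usually a table-backed mock).

Marts are coupled pair-wise by **connection patterns**: conjunctions of
attribute-equality clauses that define the join semantics between two
topics.  The marts and connection patterns form a topic graph (the semantic
resource framework) that exploratory queries navigate, and concrete
service-level connections are *derived* from the conceptual patterns by
checking the input/output roles of the interfaces on either side.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx
import yaml

from .errors import RegistryError

__all__ = [
    "Role",
    "Direction",
    "AttributeSpec",
    "ServiceMart",
    "AccessPattern",
    "AdapterDescriptor",
    "ServiceInterface",
    "Clause",
    "ConnectionPattern",
    "ServiceConnection",
    "Registry",
    "load_registry",
    "dump_registry",
    "validate_registry",
    "canonical_value",
]

VALUE_KINDS = ("identifier", "text", "number")


def canonical_value(value) -> str:
    """Canonical string form of an attribute value for joining.

    Identifier-style values are compared case-sensitively after trimming
    surrounding whitespace (UniProt-style accessions are case-significant;
    trimming guards values sourced from hand-edited tables).
    """
    return str(value).strip()


class Role(str, Enum):
    INPUT = "input"
    OUTPUT = "output"
    OUTPUT_RANKED = "output_ranked"
    #: attribute both submitted to the service and echoed in its records
    #: (e.g. an annotation-term filter that is also an output column)
    INPUT_OUTPUT = "input_output"

    @property
    def is_input(self) -> bool:
        return self in (Role.INPUT, Role.INPUT_OUTPUT)

    @property
    def is_output(self) -> bool:
        return self in (Role.OUTPUT, Role.OUTPUT_RANKED, Role.INPUT_OUTPUT)


class Direction(str, Enum):
    """Orientation of a ranked attribute: which raw values are better."""

    ASCENDING_BETTER = "ascending_better"   # e-values, p-values: smaller wins
    DESCENDING_BETTER = "descending_better"  # similarity scores: larger wins


@dataclass(frozen=True)
class AttributeSpec:
    """One normalized attribute of a service mart."""

    name: str
    value_kind: str = "text"
    units: str = ""


@dataclass(frozen=True)
class ServiceMart:
    """Conceptual description of a class of search services (a topic)."""

    name: str
    attributes: tuple[AttributeSpec, ...]

    @property
    def attribute_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)


@dataclass(frozen=True)
class AccessPattern:
    """A signature of a mart: per-attribute input/output/ranked roles.

    ``mart`` is the mart *name*; all cross-references in the registry are by
    name so that documents round-trip structurally.
    """

    name: str
    mart: str
    roles: Mapping[str, Role]
    ranked_direction: Optional[Direction] = None

    @property
    def input_attributes(self) -> tuple[str, ...]:
        return tuple(a for a, r in self.roles.items() if r.is_input)

    @property
    def output_attributes(self) -> tuple[str, ...]:
        return tuple(a for a, r in self.roles.items() if r.is_output)

    @property
    def ranked_attribute(self) -> Optional[str]:
        for a, r in self.roles.items():
            if r is Role.OUTPUT_RANKED:
                return a
        return None


@dataclass(eq=False)
class AdapterDescriptor:
    """Capabilities of a wrapped endpoint, plus an observable call counter.

    ``max_k`` is the endpoint's hard truncation limit (``None`` = unbounded).
    ``calls`` counts real invocations; cached replays do not increment it.
    """

    endpoint: str
    supports_sorted_access: bool = True
    supports_random_access: bool = False
    max_k: Optional[int] = None
    calls: int = 0

    def __post_init__(self):
        if self.max_k is not None and self.max_k < 1:
            raise RegistryError(f"adapter {self.endpoint!r}: max_k must be >= 1 or None")

    def __eq__(self, other):  # the counter is runtime state, not identity
        if not isinstance(other, AdapterDescriptor):
            return NotImplemented
        return (
            self.endpoint == other.endpoint
            and self.supports_sorted_access == other.supports_sorted_access
            and self.supports_random_access == other.supports_random_access
            and self.max_k == other.max_k
        )


@dataclass(frozen=True)
class ServiceInterface:
    """Binding of an access pattern to a concrete adapter."""

    name: str
    access_pattern: str
    adapter: AdapterDescriptor


@dataclass(frozen=True)
class Clause:
    """One attribute-equality clause of a connection predicate.

    Only the EQUALS comparator is implemented; the slot is kept for
    extension.
    """

    source: str
    target: str
    comparator: str = "EQ"


@dataclass(frozen=True)
class ConnectionPattern:
    """Pair-wise semantic coupling of two marts (conjunction of clauses).

    Stored directed source->target: binding derivation feeds outputs of a
    source-mart interface into inputs of a target-mart interface.  The topic
    graph treats the edge as undirected for neighbourhood navigation.
    """

    name: str
    source_mart: str
    target_mart: str
    clauses: tuple[Clause, ...]


@dataclass(frozen=True)
class ServiceConnection:
    """A concrete interface-level join derived from a connection pattern."""

    connection_pattern: str
    source_interface: str
    target_interface: str
    bindings: tuple[tuple[str, str], ...]  # (source output attr, target input attr)


class Registry:
    """Container for marts, patterns, interfaces and connection patterns."""

    def __init__(self):
        self.marts: dict[str, ServiceMart] = {}
        self.access_patterns: dict[str, AccessPattern] = {}
        self.interfaces: dict[str, ServiceInterface] = {}
        self.connection_patterns: dict[str, ConnectionPattern] = {}

    # -- registration -----------------------------------------------------

    def register_mart(self, name: str, attributes: Iterable[AttributeSpec]) -> ServiceMart:
        attrs = tuple(
            a if isinstance(a, AttributeSpec) else AttributeSpec(**a) for a in attributes
        )
        if not name:
            raise RegistryError("mart name must be non-empty")
        if name in self.marts:
            raise RegistryError(f"duplicate mart name {name!r}")
        if not attrs:
            raise RegistryError(f"mart {name!r}: at least one attribute is required")
        seen = set()
        for a in attrs:
            if not a.name:
                raise RegistryError(f"mart {name!r}: empty attribute name")
            if a.name in seen:
                raise RegistryError(f"mart {name!r}: duplicate attribute {a.name!r}")
            if a.value_kind not in VALUE_KINDS:
                raise RegistryError(
                    f"mart {name!r}: attribute {a.name!r} has unknown value kind {a.value_kind!r}"
                )
            seen.add(a.name)
        mart = ServiceMart(name, attrs)
        self.marts[name] = mart
        return mart

    def register_access_pattern(
        self,
        name: str,
        mart: str,
        roles: Mapping[str, Union[Role, str]],
        ranked_direction: Union[Direction, str, None] = None,
    ) -> AccessPattern:
        if name in self.access_patterns:
            raise RegistryError(f"duplicate access pattern name {name!r}")
        if mart not in self.marts:
            raise RegistryError(f"access pattern {name!r}: unknown mart {mart!r}")
        mart_attrs = set(self.marts[mart].attribute_names)
        parsed: dict[str, Role] = {}
        for attr, role in roles.items():
            if attr not in mart_attrs:
                raise RegistryError(
                    f"access pattern {name!r}: attribute {attr!r} not in mart {mart!r}"
                )
            parsed[attr] = Role(role)
        outputs = [a for a, r in parsed.items() if r.is_output]
        if not outputs:
            raise RegistryError(f"access pattern {name!r}: no output attributes")
        ranked = [a for a, r in parsed.items() if r is Role.OUTPUT_RANKED]
        if len(ranked) > 1:
            raise RegistryError(
                f"access pattern {name!r}: more than one ranked attribute ({ranked})"
            )
        direction = Direction(ranked_direction) if ranked_direction is not None else None
        if ranked and direction is None:
            direction = Direction.ASCENDING_BETTER
        if not ranked:
            direction = None
        pattern = AccessPattern(name, mart, dict(parsed), direction)
        self.access_patterns[name] = pattern
        return pattern

    def register_interface(
        self, name: str, access_pattern: str, adapter: AdapterDescriptor
    ) -> ServiceInterface:
        if name in self.interfaces:
            raise RegistryError(f"duplicate interface name {name!r}")
        if access_pattern not in self.access_patterns:
            raise RegistryError(f"interface {name!r}: unknown access pattern {access_pattern!r}")
        ap = self.access_patterns[access_pattern]
        if ap.ranked_attribute is not None and not adapter.supports_sorted_access:
            raise RegistryError(
                f"interface {name!r}: ranked access pattern requires sorted access support"
            )
        iface = ServiceInterface(name, access_pattern, adapter)
        self.interfaces[name] = iface
        return iface

    def register_connection_pattern(
        self,
        name: str,
        source_mart: str,
        target_mart: str,
        predicate: Sequence[Union[Clause, Mapping]],
    ) -> ConnectionPattern:
        if name in self.connection_patterns:
            raise RegistryError(f"duplicate connection pattern name {name!r}")
        for m in (source_mart, target_mart):
            if m not in self.marts:
                raise RegistryError(f"connection {name!r}: unknown mart {m!r}")
        clauses = tuple(
            c if isinstance(c, Clause) else Clause(**c) for c in predicate
        )
        if not clauses:
            raise RegistryError(f"connection {name!r}: empty predicate")
        src_attrs = set(self.marts[source_mart].attribute_names)
        tgt_attrs = set(self.marts[target_mart].attribute_names)
        for c in clauses:
            if c.comparator != "EQ":
                raise RegistryError(f"connection {name!r}: unsupported comparator {c.comparator!r}")
            if c.source not in src_attrs:
                raise RegistryError(
                    f"connection {name!r}: attribute {c.source!r} not in mart {source_mart!r}"
                )
            if c.target not in tgt_attrs:
                raise RegistryError(
                    f"connection {name!r}: attribute {c.target!r} not in mart {target_mart!r}"
                )
        cp = ConnectionPattern(name, source_mart, target_mart, clauses)
        self.connection_patterns[name] = cp
        return cp

    # -- queries ----------------------------------------------------------

    def interface_pattern(self, interface: str) -> AccessPattern:
        try:
            iface = self.interfaces[interface]
        except KeyError:
            raise RegistryError(f"unknown interface {interface!r}") from None
        return self.access_patterns[iface.access_pattern]

    def derive_service_connections(self) -> list[ServiceConnection]:
        """Interface-level joins implied by the conceptual connection patterns.

        For every pattern and every ordered pair of interfaces over its
        source/target marts, a connection exists iff each clause's source
        attribute is an output of the source interface's pattern and its
        target attribute is an input of the target interface's pattern.
        Derivation is attempted only in the declared direction.
        """
        out: list[ServiceConnection] = []
        for cp_name in sorted(self.connection_patterns):
            cp = self.connection_patterns[cp_name]
            for si_name in sorted(self.interfaces):
                si_ap = self.interface_pattern(si_name)
                if si_ap.mart != cp.source_mart:
                    continue
                for ti_name in sorted(self.interfaces):
                    if ti_name == si_name:
                        continue
                    ti_ap = self.interface_pattern(ti_name)
                    if ti_ap.mart != cp.target_mart:
                        continue
                    ok = all(
                        si_ap.roles.get(c.source, Role.INPUT).is_output
                        and c.source in si_ap.roles
                        and c.target in ti_ap.roles
                        and ti_ap.roles[c.target].is_input
                        for c in cp.clauses
                    )
                    if ok:
                        out.append(
                            ServiceConnection(
                                cp.name,
                                si_name,
                                ti_name,
                                tuple((c.source, c.target) for c in cp.clauses),
                            )
                        )
        return out

    def graph(self) -> nx.MultiGraph:
        """Topic graph: nodes are marts, edges are connection patterns."""
        g = nx.MultiGraph()
        g.add_nodes_from(self.marts)
        for cp in self.connection_patterns.values():
            if cp.source_mart in self.marts and cp.target_mart in self.marts:
                g.add_edge(cp.source_mart, cp.target_mart, key=cp.name)
        return g

    def neighbors(self, mart: str) -> list[tuple[ConnectionPattern, str]]:
        """Edges incident to a mart, as (pattern, adjacent-mart) pairs."""
        if mart not in self.marts:
            raise RegistryError(f"unknown mart {mart!r}")
        out = []
        for name in sorted(self.connection_patterns):
            cp = self.connection_patterns[name]
            if cp.source_mart == mart:
                out.append((cp, cp.target_mart))
            elif cp.target_mart == mart:
                out.append((cp, cp.source_mart))
        return out

    # -- validation -------------------------------------------------------

    def validate(self) -> list[str]:
        """All invariant violations, as human-readable strings with paths."""
        v: list[str] = []
        for name, mart in self.marts.items():
            if not mart.attributes:
                v.append(f"marts/{name}: no attributes")
            names = [a.name for a in mart.attributes]
            if len(set(names)) != len(names):
                v.append(f"marts/{name}: duplicate attribute names")
        for name, ap in self.access_patterns.items():
            if ap.mart not in self.marts:
                v.append(f"access_patterns/{name}: unknown mart {ap.mart!r}")
                continue
            mart_attrs = set(self.marts[ap.mart].attribute_names)
            for attr in ap.roles:
                if attr not in mart_attrs:
                    v.append(f"access_patterns/{name}: attribute {attr!r} not in mart {ap.mart!r}")
            if not ap.output_attributes:
                v.append(f"access_patterns/{name}: no output attributes")
            ranked = [a for a, r in ap.roles.items() if r is Role.OUTPUT_RANKED]
            if len(ranked) > 1:
                v.append(f"access_patterns/{name}: more than one ranked attribute")
            if ranked and ap.ranked_direction is None:
                v.append(f"access_patterns/{name}: ranked attribute without direction")
        for name, iface in self.interfaces.items():
            if iface.access_pattern not in self.access_patterns:
                v.append(f"interfaces/{name}: unknown access pattern {iface.access_pattern!r}")
                continue
            ap = self.access_patterns[iface.access_pattern]
            if ap.ranked_attribute is not None and not iface.adapter.supports_sorted_access:
                v.append(f"interfaces/{name}: ranked pattern without sorted access support")
        for name, cp in self.connection_patterns.items():
            for side, mart in (("source", cp.source_mart), ("target", cp.target_mart)):
                if mart not in self.marts:
                    v.append(f"connections/{name}: unknown {side} mart {mart!r}")
            if not cp.clauses:
                v.append(f"connections/{name}: empty predicate")
            for i, c in enumerate(cp.clauses):
                if cp.source_mart in self.marts and c.source not in self.marts[cp.source_mart].attribute_names:
                    v.append(f"connections/{name}/predicate[{i}]: {c.source!r} not in {cp.source_mart!r}")
                if cp.target_mart in self.marts and c.target not in self.marts[cp.target_mart].attribute_names:
                    v.append(f"connections/{name}/predicate[{i}]: {c.target!r} not in {cp.target_mart!r}")
        return v

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "marts": [
                {
                    "name": m.name,
                    "attributes": [
                        {"name": a.name, "kind": a.value_kind, "units": a.units}
                        for a in m.attributes
                    ],
                }
                for m in self.marts.values()
            ],
            "access_patterns": [
                {
                    "name": ap.name,
                    "mart": ap.mart,
                    "roles": {a: r.value for a, r in ap.roles.items()},
                    **(
                        {"ranked_direction": ap.ranked_direction.value}
                        if ap.ranked_direction is not None
                        else {}
                    ),
                }
                for ap in self.access_patterns.values()
            ],
            "interfaces": [
                {
                    "name": i.name,
                    "access_pattern": i.access_pattern,
                    "adapter": {
                        "endpoint": i.adapter.endpoint,
                        "supports_sorted_access": i.adapter.supports_sorted_access,
                        "supports_random_access": i.adapter.supports_random_access,
                        "max_k": i.adapter.max_k,
                    },
                }
                for i in self.interfaces.values()
            ],
            "connections": [
                {
                    "name": cp.name,
                    "source_mart": cp.source_mart,
                    "target_mart": cp.target_mart,
                    "predicate": [
                        {"source": c.source, "comparator": c.comparator, "target": c.target}
                        for c in cp.clauses
                    ],
                }
                for cp in self.connection_patterns.values()
            ],
        }

    @classmethod
    def from_dict(cls, doc: Optional[dict], strict: bool = True) -> "Registry":
        """Build a registry from a parsed document.

        With ``strict`` (default), invariant violations raise
        :class:`RegistryError`; otherwise the registry is built as-is and
        :meth:`validate` reports the violations.
        """
        reg = cls()
        doc = doc or {}
        if not isinstance(doc, Mapping):
            raise RegistryError("registry document must be a mapping")
        try:
            for m in doc.get("marts", []) or []:
                reg.marts[m["name"]] = ServiceMart(
                    m["name"],
                    tuple(
                        AttributeSpec(a["name"], a.get("kind", "text"), a.get("units", ""))
                        for a in m.get("attributes", []) or []
                    ),
                )
            for ap in doc.get("access_patterns", []) or []:
                direction = ap.get("ranked_direction")
                reg.access_patterns[ap["name"]] = AccessPattern(
                    ap["name"],
                    ap["mart"],
                    {a: Role(r) for a, r in (ap.get("roles") or {}).items()},
                    Direction(direction) if direction else None,
                )
            for i in doc.get("interfaces", []) or []:
                ad = i.get("adapter") or {}
                reg.interfaces[i["name"]] = ServiceInterface(
                    i["name"],
                    i["access_pattern"],
                    AdapterDescriptor(
                        ad.get("endpoint", i["name"]),
                        ad.get("supports_sorted_access", True),
                        ad.get("supports_random_access", False),
                        ad.get("max_k"),
                    ),
                )
            for cp in doc.get("connections", []) or []:
                reg.connection_patterns[cp["name"]] = ConnectionPattern(
                    cp["name"],
                    cp["source_mart"],
                    cp["target_mart"],
                    tuple(
                        Clause(c["source"], c["target"], c.get("comparator", "EQ"))
                        for c in cp.get("predicate", []) or []
                    ),
                )
        except (KeyError, TypeError, ValueError) as exc:
            raise RegistryError(f"malformed registry document: {exc!r}") from exc
        if strict:
            violations = reg.validate()
            if violations:
                raise RegistryError("invalid registry: " + "; ".join(violations))
        return reg

    def __eq__(self, other):
        if not isinstance(other, Registry):
            return NotImplemented
        return (
            self.marts == other.marts
            and self.access_patterns == other.access_patterns
            and self.interfaces == other.interfaces
            and self.connection_patterns == other.connection_patterns
        )


def load_registry(source, strict: bool = True) -> Registry:
    """Load a registry from a YAML/JSON document (path, stream or text)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text and (text.endswith((".yaml", ".yml", ".json")) or "/" in text):
            with open(text, "r", encoding="utf-8") as fh:
                text = fh.read()
    try:
        doc = yaml.safe_load(io.StringIO(text))
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise RegistryError(f"registry parse error{where}: {exc}") from exc
    return Registry.from_dict(doc, strict=strict)


def dump_registry(registry: Registry) -> str:
    """YAML text for a registry; ``load_registry(dump_registry(r)) == r``."""
    return yaml.safe_dump(registry.to_dict(), sort_keys=False)


def validate_registry(registry: Registry) -> list[str]:
    return registry.validate()
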