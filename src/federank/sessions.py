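"""Replayable exploration sessions.

A session script is a YAML document naming a world (the shipped PAX
fixture, a seeded synthetic world, or a registry file plus TSV tables) and
an ordered list of actions — start / expand / back / forward / reweight /
export / export_history — so an entire exploration is reproducible from one
file.  Every service invocation emits one machine-parseable ``key=value``
log line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional

import yaml

from .adapters import TableService, load_table
from .errors import FederankError, SessionError
from .exploration import (
    HistoryTree,
    back,
    expand,
    forward,
    history_to_json,
    reweight_node,
    start,
)
from .fixtures import load_pax_fixture
from .io import export_results
from .scoring import NormalizationStrategy, WeightConfig
from .service_model import load_registry
from .synthetic import make_synthetic_world

__all__ = ["SessionScript", "load_session", "run_session"]

_ACTIONS = ("start", "expand", "back", "forward", "reweight", "export", "export_history")


@dataclass
class SessionScript:
    world: object
    actions: list
    options: dict = field(default_factory=dict)
    base_dir: Path = Path(".")


def load_session(source) -> SessionScript:
    """Load and statically validate a session script."""
    base_dir = Path(".")
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        base_dir = Path(source).parent
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        doc = yaml.safe_load(str(source))
    if not isinstance(doc, Mapping):
        raise SessionError("session script must be a mapping")
    if "world" not in doc and "registry" not in doc:
        raise SessionError("session script needs a 'world' or 'registry' entry")
    actions = doc.get("actions") or []
    if not actions:
        raise SessionError("session script has no actions")
    for idx, action in enumerate(actions, start=1):
        if not isinstance(action, Mapping) or len(action) != 1:
            raise SessionError(f"action {idx} must be a single-key mapping", idx)
        kind = next(iter(action))
        if kind not in _ACTIONS:
            raise SessionError(f"action {idx}: unknown action {kind!r}", idx)
    first = next(iter(actions[0]))
    if first != "start":
        raise SessionError("the first action must be 'start'", 1)
    world = doc.get("world")
    if world is None:
        world = {"registry": doc["registry"], "tables": doc.get("tables") or {}}
    return SessionScript(world, list(actions), dict(doc.get("options") or {}), base_dir)


def _resolve_world(script: SessionScript):
    w = script.world
    if w == "pax":
        return load_pax_fixture()
    if isinstance(w, Mapping) and "synthetic" in w:
        params = dict(w["synthetic"] or {})
        return make_synthetic_world(**params)
    if isinstance(w, Mapping) and "registry" in w:
        reg_path = script.base_dir / w["registry"]
        registry = load_registry(str(reg_path))
        adapters = {}
        for iface_name, table_path in (w.get("tables") or {}).items():
            iface = registry.interfaces[iface_name]
            pattern = registry.access_patterns[iface.access_pattern]
            with open(script.base_dir / table_path, "r", encoding="utf-8") as fh:
                adapters[iface_name] = TableService(iface, pattern, load_table(fh))
        return registry, adapters
    raise SessionError(f"unknown world specification {w!r}")


def _parse_weights(spec: Mapping, default_strategy) -> WeightConfig:
    strategies = {}
    weights = {}
    for name, entry in spec.items():
        if isinstance(entry, Mapping):
            strategies[name] = NormalizationStrategy.from_dict(
                entry.get("strategy", default_strategy)
            )
            weights[name] = float(entry.get("relative_weight", 0.0))
        else:
            strategies[name] = default_strategy
            weights[name] = float(entry)
    return WeightConfig(strategies, weights).normalized()


def run_session(
    script: SessionScript,
    out_dir: Optional[Path] = None,
    log: Optional[Callable[[str], None]] = None,
) -> dict[str, Path]:
    """Execute a session's actions in order; returns the written exports.

    Failures raise :class:`SessionError` carrying the 1-based index of the
    failing action.
    """
    out_dir = Path(out_dir) if out_dir is not None else Path(".")
    log = log or (lambda line: None)
    registry, adapters = _resolve_world(script)
    options = script.options
    default_k = int(options.get("k", 50))
    strategy = NormalizationStrategy.from_dict(options.get("strategy", "complement"))

    def on_invoke(iface, bindings, n_records, cached):
        payload = json.dumps(sorted(bindings.items()), separators=(",", ":"))
        log(
            f"invoke interface={iface} bindings={payload} records={n_records} "
            f"cached={str(cached).lower()}"
        )

    tree: Optional[HistoryTree] = None
    exports: dict[str, Path] = {}
    for idx, action in enumerate(script.actions, start=1):
        kind, params = next(iter(action.items()))
        params = dict(params or {})
        try:
            if kind == "start":
                tree, _ = start(
                    registry,
                    adapters,
                    params["interface"],
                    {str(a): str(v) for a, v in (params.get("inputs") or {}).items()},
                    weights=_parse_weights(params["weights"], strategy)
                    if "weights" in params
                    else None,
                    k=int(params.get("k", default_k)),
                    strategy=strategy,
                    on_invoke=on_invoke,
                )
            elif tree is None:
                raise SessionError("no exploration started", idx)
            elif kind == "expand":
                expand(
                    tree,
                    None,
                    params["connection"],
                    params["interface"],
                    extra_inputs={str(a): str(v) for a, v in (params.get("inputs") or {}).items()},
                    selection=params.get("selection"),
                    weights=_parse_weights(params["weights"], strategy)
                    if "weights" in params
                    else None,
                    k=int(params.get("k", default_k)),
                )
            elif kind == "back":
                back(tree)
            elif kind == "forward":
                forward(tree, params["node"])
            elif kind == "reweight":
                reweight_node(tree, None, _parse_weights(params["weights"], strategy))
            elif kind == "export":
                fmt = params.get("format", "tsv")
                text = export_results(tree, tree.current, fmt)
                path = out_dir / params["path"]
                path.parent.mkdir(parents=True, exist_ok=True)
                path.write_text(text, encoding="utf-8")
                exports[params["path"]] = path
                log(f"export path={path} format={fmt} rows={len(tree.current.result.tuples)}")
            elif kind == "export_history":
                path = out_dir / params["path"]
                path.parent.mkdir(parents=True, exist_ok=True)
                path.write_text(history_to_json(tree), encoding="utf-8")
                exports[params["path"]] = path
                log(f"export_history path={path} nodes={len(tree.nodes)}")
        except SessionError as exc:
            if exc.action_index is None:
                raise SessionError(f"action {idx} ({kind}): {exc}", idx) from exc
            raise
        except (FederankError, KeyError) as exc:
            raise SessionError(f"action {idx} ({kind}) failed: {exc}", idx) from exc
    return exports
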