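"""Result export: TSV and JSON projections of a node's combined results.

One row per combined tuple: the global score (printed with 5 decimal
places), each ranked service's raw ranked value, every output attribute of
every service in chain order, and the provenance string.  The JSON export
mirrors the same columns as a list of objects.
"""

from __future__ import annotations

import csv
import io as _io
import json
from typing import TYPE_CHECKING

from .errors import SessionError
from .service_model import Registry

if TYPE_CHECKING:  # pragma: no cover
    from .exploration import ExplorationNode, HistoryTree

__all__ = ["export_results", "result_columns"]

FORMATS = ("tsv", "json")


def result_columns(registry: Registry, interfaces) -> list[str]:
    """Export column names for a chain of interfaces."""
    columns = ["global_score"]
    for iface in interfaces:
        ap = registry.interface_pattern(iface)
        if ap.ranked_attribute is not None:
            columns.append(f"{iface}.{ap.ranked_attribute}")
    for iface in interfaces:
        ap = registry.interface_pattern(iface)
        for attr in ap.output_attributes:
            if attr == ap.ranked_attribute:
                continue
            columns.append(f"{iface}.{attr}")
    columns.append("provenance")
    return columns


def export_results(tree: "HistoryTree", node: "ExplorationNode", fmt: str) -> str:
    """Serialize a node's result as a TSV or JSON document."""
    if fmt not in FORMATS:
        raise SessionError(f"unknown export format {fmt!r}; expected one of {FORMATS}")
    registry = tree.registry
    interfaces = list(node.state.interfaces) if node.state else []
    columns = result_columns(registry, interfaces)
    rows = []
    for t in node.result.tuples if node.result else []:
        row = {"global_score": f"{t.global_score:.5f}", "provenance": t.row_id}
        for iface in interfaces:
            ap = registry.interface_pattern(iface)
            rec = t.records.get(iface, {})
            for attr in ap.output_attributes:
                row[f"{iface}.{attr}"] = rec.get(attr, "")
        rows.append(row)
    if fmt == "tsv":
        out = _io.StringIO()
        writer = csv.DictWriter(out, fieldnames=columns, delimiter="\t", lineterminator="\n")
        writer.writeheader()
        for row in rows:
            writer.writerow({c: row.get(c, "") for c in columns})
        return out.getvalue()
    doc = {
        "columns": columns,
        "rows": [
            {c: (float(r["global_score"]) if c == "global_score" else r.get(c, "")) for c in columns}
            for r in rows
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=True)
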