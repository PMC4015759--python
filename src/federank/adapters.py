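"""Service adapter contract and table-backed mock services.

A :class:`TableService` stands behind the same contract a live wrapper
would implement: ``invoke(inputs, k)`` returns the records matching all
input bindings, sorted by the declared ranked attribute (stable under
ties) and truncated to ``min(k, max_k)``.  The backing table is a list of
attribute-value maps, loadable from a TSV with a one-line header of
normalized attribute names.  Invocations increment the observable call
counter on the interface's adapter descriptor; cached replays at the
exploration layer do not.

Live adapters for real endpoints can implement the same ``invoke``
signature; none are exercised here (tests are hermetic).
"""

from __future__ import annotations

import csv
import io
from typing import Mapping, Optional, Sequence

from .errors import AdapterError
from .rank_join import RankedStream
from .service_model import (
    AccessPattern,
    Direction,
    Registry,
    ServiceInterface,
    canonical_value,
)

__all__ = ["TableService", "load_table", "dump_table"]


def load_table(text_or_stream) -> list[dict]:
    """Parse a TSV document (one-line header) into record maps."""
    if hasattr(text_or_stream, "read"):
        text = text_or_stream.read()
    else:
        text = str(text_or_stream)
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    return [dict(row) for row in reader]


def dump_table(rows: Sequence[Mapping[str, str]], columns: Optional[Sequence[str]] = None) -> str:
    """Serialize record maps to TSV (deterministic column order)."""
    if columns is None:
        columns = list(rows[0]) if rows else []
    out = io.StringIO()
    writer = csv.DictWriter(out, fieldnames=list(columns), delimiter="\t", lineterminator="\n")
    writer.writeheader()
    for r in rows:
        writer.writerow({c: r.get(c, "") for c in columns})
    return out.getvalue()


class TableService:
    """A mock search service backed by an in-memory table."""

    def __init__(self, interface: ServiceInterface, pattern: AccessPattern, rows: Sequence[Mapping]):
        self.interface = interface
        self.pattern = pattern
        self.rows = [dict(r) for r in rows]
        self.ranked_attribute = pattern.ranked_attribute
        self.direction = pattern.ranked_direction

    @property
    def name(self) -> str:
        return self.interface.name

    @property
    def descriptor(self):
        return self.interface.adapter

    def invoke(self, inputs: Mapping[str, str], k: int) -> list[dict]:
        """Records matching every input binding, ordered and truncated.

        All input-role attributes of the access pattern must be bound;
        bindings whose attribute is not a table column act as free
        parameters (accepted, not matched).
        """
        if k < 1:
            raise AdapterError(f"{self.name}: k must be >= 1, got {k}")
        missing = [a for a in self.pattern.input_attributes if a not in inputs]
        if missing:
            raise AdapterError(f"{self.name}: missing required input(s) {missing}")
        self.descriptor.calls += 1
        columns = set(self.rows[0]) if self.rows else set()
        bound = {
            a: canonical_value(v) for a, v in inputs.items() if a in columns
        }
        matched = [
            dict(r)
            for r in self.rows
            if all(canonical_value(r.get(a, "")) == v for a, v in bound.items())
        ]
        if self.ranked_attribute is not None:
            reverse = self.direction is Direction.DESCENDING_BETTER
            try:
                matched.sort(
                    key=lambda r: (-float(r[self.ranked_attribute]) if reverse else float(r[self.ranked_attribute]))
                )
            except (KeyError, ValueError) as exc:
                raise AdapterError(f"{self.name}: bad ranked column: {exc!r}") from exc
        limit = k if self.descriptor.max_k is None else min(k, self.descriptor.max_k)
        return matched[:limit]

    def stream(self, inputs: Mapping[str, str], k: int) -> RankedStream:
        """Invoke and wrap the answer as a :class:`RankedStream`."""
        records = self.invoke(inputs, k)
        return RankedStream(
            self.name,
            records,
            self.ranked_attribute,
            self.direction,
            truncation=None,
            supports_random_access=self.descriptor.supports_random_access,
        )
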