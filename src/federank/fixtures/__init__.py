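"""Canonical shipped fixtures: the five-topic registry and the PAX world.

The PAX world embeds the reference values of its worked use case: a
protein-similarity search for the human Pax-6 protein (UniProt P26367)
returning hits for the human PAX7, PAX2, PAX8 and mouse Pax8 proteins
(expectations 1.3658E-76, 1.73781E-70, 3.2506E-69, 1.17479E-67) plus the
self-hit; the coding genes of those proteins; tumor up-regulation records
with p-values 1.0E-11, 1.0E-11, 0.0030 and 0.041 for the four non-query
genes; and "regulation of apoptotic process" annotations for those four
genes — deliberately absent for PAX6's own gene, which is why it drops out
of the expanded query.
"""

from __future__ import annotations

from importlib import resources

from ..adapters import TableService, load_table
from ..service_model import Registry, load_registry

__all__ = ["fig1_registry", "load_pax_fixture", "registry_path", "pax_session_path"]

_TABLE_FILES = {
    "ncbi_blast": "pax_ncbi_blast.tsv",
    "gpdw_protein_coding_gene": "pax_coding_gene.tsv",
    "array_express_gene_expression": "pax_gene_expression.tsv",
    "gpdw_gene_biological_function": "pax_gene_function.tsv",
    "gpdw_protein_biological_function": "pax_protein_function.tsv",
    "gpdw_protein_genetic_disorder": "pax_protein_disorder.tsv",
}


def _data(name: str) -> str:
    return (resources.files(__package__) / "data" / name).read_text(encoding="utf-8")


def registry_path() -> str:
    """Filesystem path of the shipped five-topic registry document."""
    return str(resources.files(__package__) / "data" / "fig1_registry.yaml")


def pax_session_path() -> str:
    """Filesystem path of the shipped PAX exploration session script."""
    return str(resources.files(__package__) / "data" / "pax_session.yaml")


def fig1_registry() -> Registry:
    """The five-topic registry: Protein, Gene, Gene Expression,
    Biological Function, Genetic Disorder and their connection patterns."""
    return load_registry(_data("fig1_registry.yaml"))


def load_pax_fixture() -> tuple[Registry, dict[str, TableService]]:
    """Registry plus table-backed services replaying the PAX use case."""
    registry = fig1_registry()
    adapters = {}
    for iface_name, filename in _TABLE_FILES.items():
        iface = registry.interfaces[iface_name]
        pattern = registry.access_patterns[iface.access_pattern]
        adapters[iface_name] = TableService(iface, pattern, load_table(_data(filename)))
    return registry, adapters
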