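"""Bundled example data.

``load_milk_fat_table`` is the 45-gene bovine milk-fat panel with
EST-derived TPM values in mammary, skin and muscle tissue, annotated with
the nine lipid-metabolism bioprocesses.  ``load_synthetic_network`` is a
small hand-curated, synthetic interaction network over the same gene
panel for demonstrating the graph operations; it imitates the schema and
rough topology of a STRING export but is not real interaction evidence
and must never be used as one.
"""

from __future__ import annotations

from importlib import resources

from .model import StudyTable, read_study_table
from .network import InteractionGraph, read_edge_list

__all__ = ["load_milk_fat_table", "load_synthetic_network"]


def _data_path(name: str):
    return resources.files("enorthern.data").joinpath(name)


def load_milk_fat_table() -> StudyTable:
    """The bundled 45-gene milk-fat expression panel."""
    with resources.as_file(_data_path("table2.tsv")) as path:
        table = read_study_table(path)
    table.source_label = "milk-fat 45-gene panel"
    return table


def load_synthetic_network(include_all_panel_genes: bool = True) -> InteractionGraph:
    """A synthetic, illustrative interaction network over the milk-fat panel.

    Hand-curated stand-in for a real protein-association export (the
    database version used in the original analysis is retired); suitable
    for demonstrations and plumbing tests only, never as biological
    ground truth.  With ``include_all_panel_genes`` the 45 panel genes are
    all present, edge-free genes as isolated nodes.
    """
    nodes = load_milk_fat_table().gene_symbols if include_all_panel_genes else None
    with resources.as_file(_data_path("string_synthetic.tsv")) as path:
        return read_edge_list(path, nodes=nodes)
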