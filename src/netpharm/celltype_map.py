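"""Target → brain-cell-type mapping and the compound–target–cell-type network.

Single-cell expression resources assign genes to the cell types that express
them (neurons, astrocytes, microglia, endothelial cells, ...).  This module
consumes a gene × cell-type association table — either pre-thresholded
binary calls or continuous scores plus a cutoff — maps a screened target set
onto cell types, and assembles the tripartite
compound → target → cell-type network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .netcore import Network, ParseError, normalize_symbol
from .target_assembly import CompoundTargetTable, TargetSet, build_bipartite, restrict_table


@dataclass
class CellTypeTable:
    """Boolean gene × cell-type association matrix (rows: genes)."""

    frame: pd.DataFrame  # bool dtype, index = gene symbols

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.frame.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.frame.columns)

    def associations_of(self, gene: str) -> list[str]:
        if gene not in self.frame.index:
            return []
        row = self.frame.loc[gene]
        return [ct for ct in self.frame.columns if bool(row[ct])]


def read_celltype_table(
    path: str | Path,
    binary: bool = False,
    threshold: float = 0.5,
) -> CellTypeTable:
    """Read a TSV with gene rows and cell-type columns.

    Continuous scores become associations at ``score >= threshold`` unless
    ``binary`` is set (then non-zero means associated).  Duplicate gene rows
    are merged by per-column maximum before thresholding.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a gene column plus >=1 cell-type column")
    gene_col = df.columns[0]
    df[gene_col] = [normalize_symbol(g) for g in df[gene_col]]
    try:
        scores = df.set_index(gene_col).astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric score cell ({exc})") from exc
    # duplicate gene rows: keep the strongest call per cell type
    scores = scores.groupby(level=0).max()
    flags = (scores != 0.0) if binary else (scores >= threshold)
    return CellTypeTable(frame=flags)


def map_targets(
    targets: TargetSet, table: CellTypeTable
) -> tuple[Network, dict[str, int], frozenset[str]]:
    """Bipartite target ↔ cell-type network plus per-cell-type counts.

    A target may map to several cell types; targets absent from the table
    (or with no association) are returned as the unmapped set.  Cell-type
    counts sum to the number of association edges.
    """
    if not targets.members:
        raise ValueError("empty target set")
    g = nx.Graph()
    counts: dict[str, int] = {ct: 0 for ct in table.cell_types}
    mapped: set[str] = set()
    for gene in sorted(targets.members):
        for ct in table.associations_of(gene):
            g.add_edge(gene, ct)
            counts[ct] += 1
            mapped.add(gene)
    unmapped = frozenset(targets.members - mapped)
    return Network(graph=g, name="target-celltype"), counts, unmapped


def build_compound_target_celltype(
    table: CompoundTargetTable,
    targets: TargetSet,
    ct: CellTypeTable,
) -> tuple[Network, dict[str, str]]:
    """Tripartite compound → target → cell-type network with node roles.

    Compound–target edges are restricted to ``targets`` (which must all be
    known to the compound-target table); target–cell-type edges come from
    the association table.  Roles partition the node set into
    compound/target/celltype.
    """
    missing = targets.members - table.targets
    if missing:
        raise ValueError(
            f"targets not present in the compound-target table: {sorted(missing)}"
        )
    restricted = restrict_table(table, targets.members)
    bipartite, roles = build_bipartite(restricted)
    g = nx.Graph(bipartite.graph)
    for gene in sorted(targets.members):
        for cell_type in ct.associations_of(gene):
            g.add_edge(gene, cell_type)
            roles[cell_type] = "celltype"
    return Network(graph=g, name="compound-target-celltype"), roles


def write_roles(roles: dict[str, str], path: str | Path) -> None:
    """Node-role sidecar TSV (node, role)."""
    with Path(path).open("w") as fh:
        fh.write("node\trole\n")
        for node in sorted(roles):
            fh.write(f"{node}\t{roles[node]}\n")


def write_celltype_table(table: CellTypeTable, path: str | Path) -> None:
    out = table.frame.astype(int).copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep="\t", index=False)
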