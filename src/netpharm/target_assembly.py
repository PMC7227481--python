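"""Compound-target and disease-target set assembly.

A multi-compound preparation is characterised by the union of the predicted
protein targets of its individual compounds.  This module ingests
(compound, target) interaction tables, deduplicates them, extracts
per-compound target sets, computes k-way intersections and pairwise overlaps
(the Venn-diagram layer of the analysis), and builds the compound–target
bipartite network.

Gene symbols are whitespace-stripped and uppercased at ingest; no alias /
HGNC resolution is attempted — records merged from heterogeneous source
databases are reconciled by symbol only, and duplicate rows with different
provenance collapse to one record with concatenated sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .netcore import Network, normalize_symbol

#: pseudo-compound label used when a plain disease-target list is ingested
#: through the same tabular reader.
DISEASE_LABEL = "DISEASE"


@dataclass(frozen=True)
class TargetSet:
    """A labelled set of gene symbols (one compound's targets, a disease
    target list, a Venn region, a screened core...)."""

    label: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: str) -> bool:
        return item in self.members


@dataclass
class CompoundTargetTable:
    """Deduplicated (compound, target) interaction records.

    ``sources`` maps a record to the sorted, ``;``-joined provenance strings
    of all raw rows that collapsed into it (empty string if none given).
    """

    records: frozenset[tuple[str, str]]
    sources: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def compounds(self) -> list[str]:
        return sorted({c for c, _ in self.records})

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(t for _, t in self.records)

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_unique_targets(self) -> int:
        return len(self.targets)

    def per_compound_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {c: 0 for c in self.compounds}
        for c, _ in self.records:
            counts[c] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.records)
        return pd.DataFrame(
            {
                "compound": [c for c, _ in rows],
                "target": [t for _, t in rows],
                "source": [self.sources.get(r, "") for r in rows],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_target_table(
    path: str | Path,
    compound_col: str = "compound",
    target_col: str = "target",
    source_col: str | None = "source",
) -> CompoundTargetTable:
    """Read a headered TSV of compound-target interactions.

    Rows with blank target cells are dropped; exact duplicate
    (compound, target) pairs collapse to one record with their source
    strings merged.  Raises ``KeyError`` for missing columns and
    ``ValueError`` for an empty table.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in (compound_col, target_col):
        if col not in df.columns:
            raise KeyError(
                f"{path}: missing required column {col!r}; found {list(df.columns)}"
            )
    if df.empty:
        raise ValueError(f"{path}: empty target table")
    records: set[tuple[str, str]] = set()
    sources: dict[tuple[str, str], set[str]] = {}
    for _, row in df.iterrows():
        target_raw = row[target_col]
        if pd.isna(target_raw) or not str(target_raw).strip():
            continue
        compound = str(row[compound_col]).strip()
        target = normalize_symbol(str(target_raw))
        rec = (compound, target)
        records.add(rec)
        if source_col and source_col in df.columns and pd.notna(row.get(source_col)):
            sources.setdefault(rec, set()).add(str(row[source_col]).strip())
    if not records:
        raise ValueError(f"{path}: no usable records (all target cells blank?)")
    return CompoundTargetTable(
        records=frozenset(records),
        sources={r: ";".join(sorted(s)) for r, s in sources.items()},
    )


def read_target_list(path: str | Path, target_col: str = "target", label: str = DISEASE_LABEL) -> TargetSet:
    """Read a single-set target list (e.g. disease targets) from a TSV."""
    table = read_target_table(
        path, compound_col=target_col, target_col=target_col, source_col=None
    )
    return TargetSet(label=label, members=table.targets)


def targets_of(table: CompoundTargetTable, compound: str) -> TargetSet:
    """The exact target set of one compound; raises on unknown compounds."""
    known = table.compounds
    if compound not in known:
        raise KeyError(f"unknown compound {compound!r}; known compounds: {known}")
    return TargetSet(
        label=compound,
        members=frozenset(t for c, t in table.records if c == compound),
    )


def union_targets(table: CompoundTargetTable, label: str = "union") -> TargetSet:
    """Union of all compounds' targets (the "non-repetitive" target set)."""
    return TargetSet(label=label, members=table.targets)


def kway_intersection(sets: Sequence[TargetSet]) -> TargetSet:
    """Members present in every input set (needs >= 2 sets)."""
    if len(sets) < 2:
        raise ValueError(f"k-way intersection needs >= 2 sets, got {len(sets)}")
    members = reduce(lambda acc, s: acc & s.members, sets[1:], sets[0].members)
    return TargetSet(label="&".join(s.label for s in sets), members=frozenset(members))


def overlap(a: TargetSet, b: TargetSet) -> TargetSet:
    """Pairwise intersection (the two-circle Venn region)."""
    return TargetSet(label=f"{a.label}&{b.label}", members=a.members & b.members)


def venn_counts(sets: Sequence[TargetSet]) -> dict[str, int]:
    """Exclusive-region membership counts for a Venn diagram over the sets.

    Region keys are '&'-joined labels of the sets the region belongs to.
    """
    if not sets:
        return {}
    universe = frozenset().union(*(s.members for s in sets))
    regions: dict[str, int] = {}
    for gene in universe:
        key = "&".join(s.label for s in sets if gene in s.members)
        regions[key] = regions.get(key, 0) + 1
    return regions


def build_bipartite(
    table: CompoundTargetTable,
    prefix_compounds: bool = False,
    compound_prefix: str = "CPD:",
) -> tuple[Network, dict[str, str]]:
    """Compound–target bipartite network plus a node→role attribute map.

    One edge per interaction record; roles are ``"compound"`` / ``"target"``.
    A compound name colliding with a target symbol is an error unless
    ``prefix_compounds`` is set (then compound node IDs get ``compound_prefix``).
    """
    if not table.records:
        raise ValueError("empty compound-target table")
    collisions = {c.upper() for c in table.compounds} & set(table.targets)
    if collisions and not prefix_compounds:
        raise ValueError(
            f"compound names collide with target symbols: {sorted(collisions)}; "
            "enable prefix_compounds to disambiguate"
        )

    def cpd_node(c: str) -> str:
        return f"{compound_prefix}{c}" if prefix_compounds else c

    edges = [(cpd_node(c), t) for c, t in sorted(table.records)]
    net = Network.from_edges(edges, name="compound-target", uppercase=False)
    roles = {normalize_symbol(cpd_node(c), uppercase=False): "compound" for c in table.compounds}
    roles.update({t: "target" for t in table.targets})
    return net, roles


def restrict_table(table: CompoundTargetTable, targets: Iterable[str]) -> CompoundTargetTable:
    """Table restricted to records whose target lies in ``targets``."""
    keep = set(targets)
    records = frozenset(r for r in table.records if r[1] in keep)
    return CompoundTargetTable(
        records=records,
        sources={r: s for r, s in table.sources.items() if r in records},
    )


def write_venn_report(regions: Mapping[str, int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("region\tcount\n")
        for key in sorted(regions):
            fh.write(f"{key}\t{regions[key]}\n")
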