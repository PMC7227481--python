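"""Seeded generators for every pipeline input, with planted ground truth.

The live inputs of a network-pharmacology study — compound-target predictions
merged from many web databases, a curated disease-target list, a merged
protein–protein interactome, annotation term collections, single-cell
cell-type calls — are emulated here by generators that *plant* the structure
the pipeline is supposed to recover:

* compound target sets with an exact k-way intersection (and, optionally, an
  exact union size, so interaction and non-repetitive-target counts are both
  controlled);
* a disease target list with an exact overlap against the compound union;
* a PPI network with a planted dense module engineered to dominate all six
  topological measures under the two-stage screen;
* annotation collections with terms enriched in a query set at a stated fold;
* a gene × cell-type table with exact per-cell-type association counts;
* a synthetic six-measure feature table with a chosen per-column median and
  an exact number of rows exceeding a fixed threshold vector (a stand-in for
  a published supplementary feature table).

Every generator is a pure function of the spec: the single master seed is
combined with a fixed per-generator stream index through
``numpy.random.default_rng([seed, index])``, so each input can be regenerated
independently and reruns are byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .netcore import Network, write_network
from .target_assembly import CompoundTargetTable, TargetSet
from .enrichment import AnnotationDB
from .celltype_map import CellTypeTable, write_celltype_table
from .topology import MEASURES, CentralityTable

# fixed sub-stream indices of the master seed (one per generator)
_STREAM = {
    "compound": 0,
    "disease": 1,
    "ppi": 2,
    "annotation": 3,
    "celltype": 4,
    "features": 5,
}

#: Published cutoff vector of the reference screen this generator family
#: emulates (median values of the six measures on its 564-node hub network).
DEFAULT_FEATURE_THRESHOLDS = {
    "DC": 95.0,
    "BC": 240.7,
    "CC": 0.53,
    "EC": 0.3,
    "NC": 19.74,
    "LAC": 17.77,
}

DEFAULT_COMPOUNDS = ("baicalin", "geniposide", "cholic-acid", "hyodeoxycholic-acid")
DEFAULT_CELLTYPE_COUNTS = {
    "neuron": 31,
    "astrocyte": 14,
    "endothelial": 13,
    "microglia": 11,
}


def _rng(spec_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([spec_seed, _STREAM[stream]])


def gene_universe(size: int) -> list[str]:
    """Deterministic synthetic gene-symbol universe G00000, G00001, ..."""
    return [f"G{i:05d}" for i in range(size)]


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for the synthetic inputs.

    Defaults mirror the four-compound study design this pipeline was built
    around: four compounds with 156/129/226/141 predicted targets (652
    interactions), 438 distinct targets in the union, a 16-gene four-way
    intersection, a 321-gene disease list overlapping the union in 47 genes,
    a 2,000-node PPI with a planted 16-node dense module inside the overlap,
    one 10-fold enriched annotation term, and cell-type association counts
    31/14/13/11 for neuron/astrocyte/endothelial/microglia.
    """

    seed: int = 0
    compounds: tuple[str, ...] = DEFAULT_COMPOUNDS
    per_compound_sizes: tuple[int, ...] = (156, 129, 226, 141)
    planted_kway: int = 16
    n_unique_targets: int | None = 438
    universe_size: int = 5000
    disease_size: int = 321
    planted_disease_overlap: int = 47
    ppi_nodes: int = 2000
    ppi_model: str = "planted-clique"  # or "erdos-renyi", "preferential-attachment"
    er_p: float = 0.01
    ba_m: int = 2
    clique_size: int = 16
    periphery_mean_degree: float = 3.0
    clique_periphery_degree: int = 4
    n_terms: int = 50
    planted_terms: tuple[tuple[int, float], ...] = ((20, 10.0),)
    term_size_range: tuple[int, int] = (15, 60)
    annotation_universe_size: int = 1000
    celltype_planted_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CELLTYPE_COUNTS)
    )

    def __post_init__(self) -> None:
        if len(self.compounds) != len(self.per_compound_sizes):
            raise ValueError("compounds and per_compound_sizes length mismatch")
        if len(self.compounds) < 2:
            raise ValueError("need >= 2 compounds")
        if self.planted_kway > min(self.per_compound_sizes):
            raise ValueError(
                f"planted_kway ({self.planted_kway}) exceeds the smallest "
                f"compound target set ({min(self.per_compound_sizes)})"
            )
        if self.n_unique_targets is not None:
            total = sum(self.per_compound_sizes)
            n_c = len(self.compounds)
            free = self.n_unique_targets - self.planted_kway
            rem = total - self.planted_kway * n_c
            if free < 0 or rem < free or rem > free * (n_c - 1):
                raise ValueError(
                    f"n_unique_targets={self.n_unique_targets} infeasible for "
                    f"sizes {self.per_compound_sizes} with planted_kway="
                    f"{self.planted_kway}: need kway <= U and "
                    f"U-kway <= total-kway*n <= (U-kway)*(n-1)"
                )
            if self.n_unique_targets > self.universe_size:
                raise ValueError("n_unique_targets exceeds universe_size")
        if self.disease_size > self.universe_size:
            raise ValueError("disease_size exceeds universe_size")
        if self.planted_disease_overlap > self.disease_size:
            raise ValueError("planted_disease_overlap exceeds disease_size")
        if self.ppi_model not in ("planted-clique", "erdos-renyi", "preferential-attachment"):
            raise ValueError(f"unknown ppi_model {self.ppi_model!r}")
        if self.ppi_model == "planted-clique":
            if self.clique_size > self.ppi_nodes:
                raise ValueError("clique_size exceeds ppi_nodes")
            if self.clique_size < 6:
                raise ValueError("planted-clique model needs clique_size >= 6")


# ---------------------------------------------------------------------------
# compound / disease target sets
# ---------------------------------------------------------------------------

def gen_compound_targets(spec: SynthSpec) -> tuple[CompoundTargetTable, dict]:
    """Compound-target table with an exact k-way intersection.

    Exactly ``planted_kway`` genes are shared by *all* compounds (no
    accidental extras: every other gene is assigned to at most
    n_compounds − 1 compounds), per-compound set sizes are exact, and — when
    ``n_unique_targets`` is set — the union size is exact too.
    """
    rng = _rng(spec.seed, "compound")
    universe = gene_universe(spec.universe_size)
    n_c = len(spec.compounds)
    shared = list(rng.choice(universe, size=spec.planted_kway, replace=False))
    pool = [g for g in universe if g not in set(shared)]

    per_compound: dict[str, set[str]] = {c: set(shared) for c in spec.compounds}
    if spec.n_unique_targets is None:
        for c, size in zip(spec.compounds, spec.per_compound_sizes):
            extra = rng.choice(pool, size=size - spec.planted_kway, replace=False)
            per_compound[c].update(extra)
        # break any accidental all-compound gene (keeps set sizes by swapping)
        accidental = set.intersection(*per_compound.values()) - set(shared)
        for g in sorted(accidental):
            c0 = spec.compounds[0]
            used = set().union(*per_compound.values())
            repl = next(x for x in pool if x not in used)
            per_compound[c0].discard(g)
            per_compound[c0].add(repl)
    else:
        free = spec.n_unique_targets - spec.planted_kway
        others = list(rng.choice(pool, size=free, replace=False))
        # multiplicities: every non-shared gene in 1..n_c-1 compounds,
        # summing to the remaining interaction count
        rem = sum(spec.per_compound_sizes) - spec.planted_kway * n_c
        mult = np.ones(free, dtype=int)
        extra = rem - free
        while extra > 0:
            open_idx = np.flatnonzero(mult < n_c - 1)
            take = min(extra, len(open_idx))
            chosen = rng.choice(open_idx, size=take, replace=False)
            mult[chosen] += 1
            extra -= take
        # assign each gene to its `mult` compounds, most-capacity-first
        capacity = {
            c: size - spec.planted_kway
            for c, size in zip(spec.compounds, spec.per_compound_sizes)
        }
        order = np.argsort(-mult, kind="stable")
        for idx in order:
            g, m = others[idx], int(mult[idx])
            ranked = sorted(
                spec.compounds, key=lambda c: (-capacity[c], rng.random())
            )
            chosen_c = ranked[:m]
            if any(capacity[c] <= 0 for c in chosen_c):
                raise ValueError(
                    "compound capacity exhausted while planting union size; "
                    "spec is infeasible"
                )
            for c in chosen_c:
                per_compound[c].add(g)
                capacity[c] -= 1
        if any(v != 0 for v in capacity.values()):  # pragma: no cover - guarded by spec checks
            raise ValueError(f"capacity not exhausted: {capacity}")

    records = frozenset(
        (c, g) for c, members in per_compound.items() for g in members
    )
    table = CompoundTargetTable(
        records=records, sources={r: "synthetic" for r in records}
    )
    truth = {
        "planted_kway": sorted(shared),
        "per_compound": {c: sorted(m) for c, m in per_compound.items()},
        "union": sorted(set().union(*per_compound.values())),
    }
    return table, truth


def gen_disease_targets(
    spec: SynthSpec, compound_union: TargetSet
) -> tuple[TargetSet, dict]:
    """Disease target list with an exact overlap against the compound union."""
    rng = _rng(spec.seed, "disease")
    union = sorted(compound_union.members)
    if spec.planted_disease_overlap > len(union):
        raise ValueError(
            f"planted_disease_overlap ({spec.planted_disease_overlap}) exceeds "
            f"the compound union size ({len(union)})"
        )
    inside = list(rng.choice(union, size=spec.planted_disease_overlap, replace=False))
    outside_pool = [g for g in gene_universe(spec.universe_size) if g not in compound_union.members]
    n_outside = spec.disease_size - spec.planted_disease_overlap
    if n_outside > len(outside_pool):
        raise ValueError("universe too small for the requested disease set")
    outside = list(rng.choice(outside_pool, size=n_outside, replace=False))
    members = frozenset(inside) | frozenset(outside)
    truth = {"planted_overlap": sorted(inside), "outside": sorted(outside)}
    return TargetSet(label="disease", members=members), truth


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

def _decoy_plan(q: int, n: int) -> int:
    """Number of decoy hubs for the planted-module construction.

    Each decoy is adjacent to every clique member: degree q comfortably
    clears the stage-1 cutoff (2x the sparse-periphery median degree).  The
    decoy count must dominate the stage-1 survivor set — q clique members
    plus the weak Erdős–Rényi degree-tail survivors (a few percent of n) —
    so that every stage-2 per-measure median lands inside the constant decoy
    block, strictly below the corresponding clique value.
    """
    return q + math.ceil(0.1 * n)


def gen_ppi(
    spec: SynthSpec,
    node_names: Sequence[str] | None = None,
    clique_members: Sequence[str] | None = None,
    coverage_seeds: Sequence[Sequence[str]] = (),
) -> tuple[Network, dict]:
    """Synthetic PPI network; the planted-clique model embeds a dense module.

    Planted-clique construction (see docs for the full rationale):

    * ordinary periphery: Erdős–Rényi with mean degree
      ``periphery_mean_degree``;
    * the module: a complete ``clique_size``-clique, each member also wired
      to ``clique_periphery_degree`` random periphery nodes (so the stage-1
      degree filter is non-trivial);
    * decoy hubs: ``clique_size`` nodes adjacent to *every* clique member and
      to nothing else.  Decoys pass the stage-1 degree filter, but because
      their neighbourhoods are mutually adjacent they carry exactly zero
      betweenness and are rejected by the strict stage-2 median screen —
      while guaranteeing every clique member lies on decoy↔network shortest
      paths (strictly positive betweenness).

    ``coverage_seeds`` (used by the end-to-end pipeline) is a list of seed
    sets; every node not already adjacent to (or member of) a seed set gets
    one edge to a random seed from it, so 1-hop seed expansion covers the
    whole network and the screen operates on the full planted structure.
    """
    rng = _rng(spec.seed, "ppi")
    n = spec.ppi_nodes
    if node_names is None:
        node_names = [f"N{i:05d}" for i in range(n)]
    if len(node_names) != n:
        raise ValueError(f"need {n} node names, got {len(node_names)}")
    names = list(node_names)

    if spec.ppi_model == "erdos-renyi":
        g_int = nx.gnp_random_graph(n, spec.er_p, seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g_int, dict(enumerate(names)))
        return Network(graph=g, name="ppi-er"), {"model": "erdos-renyi"}

    if spec.ppi_model == "preferential-attachment":
        g_int = nx.barabasi_albert_graph(n, spec.ba_m, seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g_int, dict(enumerate(names)))
        return Network(graph=g, name="ppi-ba"), {"model": "preferential-attachment"}

    # planted-clique model
    q = spec.clique_size
    if clique_members is None:
        clique = list(rng.choice(names, size=q, replace=False))
    else:
        clique = list(clique_members)
        if len(clique) != q:
            raise ValueError(f"clique_members must have length {q}")
        missing = set(clique) - set(names)
        if missing:
            raise ValueError(f"clique members absent from node names: {sorted(missing)}")
    non_clique = [x for x in names if x not in set(clique)]
    n_d = _decoy_plan(q, n)
    if len(non_clique) < n_d + 1:
        raise ValueError("ppi_nodes too small for the planted-clique construction")
    decoys = list(rng.choice(non_clique, size=n_d, replace=False))
    periphery = [x for x in non_clique if x not in set(decoys)]

    g = nx.Graph()
    g.add_nodes_from(names)
    # Erdős–Rényi periphery (decoys excluded: they must stay clique-pendant)
    p_er = min(1.0, spec.periphery_mean_degree / max(1, len(periphery) - 1))
    er_int = nx.gnp_random_graph(len(periphery), p_er, seed=int(rng.integers(2**31)))
    g.add_edges_from(
        (periphery[a], periphery[b]) for a, b in er_int.edges
    )
    # the complete planted module
    for i in range(q):
        for j in range(i + 1, q):
            g.add_edge(clique[i], clique[j])
    # member → periphery attachments
    for c in clique:
        targets = rng.choice(periphery, size=spec.clique_periphery_degree, replace=False)
        for t in targets:
            g.add_edge(c, t)
    # decoy hubs: each adjacent to the full module, and to nothing else
    for d in decoys:
        for c in clique:
            g.add_edge(d, c)
    # optional coverage wiring for 1-hop seed expansions
    for seed_set in coverage_seeds:
        seed_list = sorted(set(seed_set) & set(names))
        if not seed_list:
            continue
        seeds = set(seed_list)
        for v in names:
            if v in seeds or v in set(decoys):
                continue
            if not seeds.intersection(g[v]):
                g.add_edge(v, seed_list[int(rng.integers(len(seed_list)))])

    truth = {
        "model": "planted-clique",
        "clique": sorted(clique),
        "decoys": sorted(decoys),
        "n_decoys": n_d,
    }
    return Network(graph=g, name="ppi-planted"), truth


# ---------------------------------------------------------------------------
# annotation DB / cell-type table
# ---------------------------------------------------------------------------

def gen_annotation_db(
    spec: SynthSpec, query: TargetSet
) -> tuple[AnnotationDB, dict]:
    """Annotation collection with planted enriched terms.

    Each planted ``(size, fold)`` term draws its members so the query overlap
    sits at ``fold`` times the background expectation ``size·|query|/N``;
    background terms draw members uniformly from the universe.

    The annotation background is its own (smaller) universe —
    ``annotation_universe_size`` genes plus the query — mimicking the fact
    that annotated genomes are far smaller than the symbol space; a term of
    modest size can then actually reach the stated enrichment fold.
    """
    rng = _rng(spec.seed, "annotation")
    base = gene_universe(spec.universe_size)
    q_all = sorted(query.members & frozenset(base))
    if not q_all:
        raise ValueError("query has no genes inside the synthetic universe")
    uni_set = frozenset(base[: spec.annotation_universe_size]) | frozenset(q_all)
    universe = sorted(uni_set)
    q = q_all
    non_query = [g for g in universe if g not in set(q)]
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    planted_ids = []
    for i, (size, fold) in enumerate(spec.planted_terms):
        k = round(size * fold * len(q) / len(universe))
        if k > min(size, len(q)):
            raise ValueError(
                f"planted term {i}: fold {fold} infeasible for size {size} "
                f"(needs overlap {k} > min(size, |query|))"
            )
        members = set(rng.choice(q, size=k, replace=False))
        members |= set(rng.choice(non_query, size=size - k, replace=False))
        tid = f"PLANTED{i + 1}"
        terms[tid] = (f"planted term (fold {fold})", frozenset(members))
        planted_ids.append(tid)
    lo, hi = spec.term_size_range
    for i in range(spec.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(universe, size=size, replace=False))
        terms[f"TERM{i + 1:04d}"] = (f"background term {i + 1}", members)
    db = AnnotationDB(terms=terms, universe=uni_set)
    return db, {"planted_terms": planted_ids}


def gen_celltype_table(
    spec: SynthSpec, targets: TargetSet
) -> tuple[CellTypeTable, dict]:
    """Gene × cell-type table with exact per-cell-type association counts."""
    rng = _rng(spec.seed, "celltype")
    genes = sorted(targets.members)
    counts = dict(spec.celltype_planted_counts)
    for ct, c in counts.items():
        if c > len(genes):
            raise ValueError(
                f"celltype {ct!r}: planted count {c} exceeds target-set size {len(genes)}"
            )
    frame = pd.DataFrame(False, index=pd.Index(genes, name="gene"), columns=list(counts))
    truth_members: dict[str, list[str]] = {}
    for ct, c in counts.items():
        chosen = sorted(rng.choice(genes, size=c, replace=False))
        frame.loc[chosen, ct] = True
        truth_members[ct] = chosen
    return CellTypeTable(frame=frame), {"per_celltype": truth_members}


# ---------------------------------------------------------------------------
# synthetic feature table (supplementary-table stand-in)
# ---------------------------------------------------------------------------

def gen_feature_table(
    seed: int,
    n_rows: int = 564,
    n_core: int = 189,
    thresholds: Mapping[str, float] = DEFAULT_FEATURE_THRESHOLDS,
) -> tuple[CentralityTable, dict]:
    """Synthetic six-measure feature table (stand-in for a published
    supplementary table that is not redistributable here).

    Planted structure, per column: the median equals the corresponding
    threshold exactly, and exactly ``n_core`` rows exceed *all* thresholds
    strictly (every other row is held at-or-below threshold in at least one
    designated measure).  Requires even ``n_rows`` with
    ``n_core <= n_rows/2 − 1``.
    """
    if n_rows % 2:
        raise ValueError("n_rows must be even (median = mean of two middle ranks)")
    n_above = n_rows // 2 - 1  # rows strictly above threshold, per column
    if n_core > n_above:
        raise ValueError(f"n_core ({n_core}) must be <= n_rows/2 - 1 ({n_above})")
    rng = np.random.default_rng([seed, _STREAM["features"]])
    nodes = [f"NODE{i:04d}" for i in range(n_rows)]
    core_idx = np.array(sorted(rng.choice(n_rows, size=n_core, replace=False)))
    noncore_idx = np.array([i for i in range(n_rows) if i not in set(core_idx.tolist())])
    # every non-core row gets a designated measure in which it never exceeds
    # the threshold, so no non-core row can pass the full screen by accident
    fail_measure = {
        int(i): MEASURES[int(rng.integers(len(MEASURES)))] for i in noncore_idx
    }
    frame = pd.DataFrame(index=pd.Index(nodes, name="node"), columns=list(MEASURES), dtype=float)
    for m in MEASURES:
        t = float(thresholds[m])
        upper = 1.0 if m == "CC" else 3.0 * t  # CC is bounded by 1
        eligible = np.array([i for i in noncore_idx if fail_measure[int(i)] != m])
        extra_above = rng.choice(eligible, size=n_above - n_core, replace=False)
        above = np.concatenate([core_idx, extra_above])
        rest = np.array([i for i in noncore_idx if i not in set(above.tolist())])
        at_t = rng.choice(rest, size=2, replace=False)
        below = np.array([i for i in rest if i not in set(at_t.tolist())])
        col = np.empty(n_rows)
        col[above] = t + (upper - t) * rng.uniform(0.02, 0.98, size=above.size)
        col[at_t] = t
        col[below] = t * rng.uniform(0.05, 0.98, size=below.size)
        if m == "DC":  # degrees are integers; keep the planted order statistics
            col[above] = np.maximum(np.rint(col[above]), t + 1)
            col[below] = np.clip(np.rint(col[below]), 1, t - 1)
        frame[m] = col
    table = CentralityTable(frame=frame)
    truth = {"core_nodes": sorted(nodes[int(i)] for i in core_idx)}
    return table, truth


# ---------------------------------------------------------------------------
# writing a full input bundle
# ---------------------------------------------------------------------------

def write_inputs(spec: SynthSpec, outdir: str | Path) -> dict:
    """Generate and write every pipeline input to ``outdir`` (standard
    dialects) plus a ``truth.json`` sidecar; returns the truth record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, truth_ct = gen_compound_targets(spec)
    table.write_tsv(outdir / "compound_targets.tsv")
    union = TargetSet(label="compound-union", members=table.targets)
    disease, truth_dis = gen_disease_targets(spec, union)
    with (outdir / "disease_targets.tsv").open("w") as fh:
        fh.write("target\n")
        for g in sorted(disease.members):
            fh.write(f"{g}\n")
    overlap_members = union.members & disease.members
    clique = sorted(overlap_members)[: spec.clique_size] if spec.ppi_model == "planted-clique" else None
    seeds_all = sorted(union.members | disease.members)
    fillers = [g for g in gene_universe(spec.universe_size) if g not in set(seeds_all)]
    names = (seeds_all + fillers)[: spec.ppi_nodes]
    ppi, truth_ppi = gen_ppi(
        spec,
        node_names=names,
        clique_members=clique,
        coverage_seeds=[sorted(union.members), sorted(disease.members)],
    )
    write_network(ppi, outdir / "ppi.tsv", format="tsv-2col")
    query = TargetSet(label="overlap", members=overlap_members)
    db, truth_db = gen_annotation_db(spec, query)
    with (outdir / "annotations.gmt").open("w") as fh:
        for tid in sorted(db.terms):
            desc, members = db.terms[tid]
            fh.write("\t".join([tid, desc, *sorted(members)]) + "\n")
    ct_table, truth_cell = gen_celltype_table(spec, query)
    write_celltype_table(ct_table, outdir / "celltype.tsv")
    truth = {
        "spec": {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in asdict(spec).items()},
        "compound_targets": truth_ct,
        "disease_targets": truth_dis,
        "ppi": truth_ppi,
        "annotation": truth_db,
        "celltype": truth_cell,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return truth
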