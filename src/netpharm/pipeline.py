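"""Config-driven orchestration of the full screening analysis.

One call — :func:`run_all` — executes the computational arm of the study
design: assemble compound/disease target sets, report the Venn layer, build
and intersect seed-expanded PPI networks, run the two-stage topological
screen, test the screened targets for term over-representation (per GMT
collection), and map them onto cell types.  Every artifact is written under
the output directory::

    networks/     compound-target bipartite, expanded/intersected/screened PPI,
                  target-cell-type and compound-target-cell-type networks
    tables/       target tables, Venn region counts, centrality features,
                  core target list, cell-type counts
    enrichment/   per-collection result + bubble-chart TSVs
    report.json   every count, threshold, median and parameter of the run

Inputs come either from files (``RunConfig`` paths) or from the synthetic
generator (``RunConfig.synth``); exactly one source must be supplied.
Identical configs produce byte-identical TSV outputs (all randomness flows
from the single master seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import synthetic_data as synth
from .netcore import Network, read_edge_list, write_network, write_node_list, induced_subgraph
from .target_assembly import (
    CompoundTargetTable,
    TargetSet,
    build_bipartite,
    kway_intersection,
    overlap,
    read_target_list,
    read_target_table,
    targets_of,
    union_targets,
    venn_counts,
    write_venn_report,
)
from .core_screen import ScreenParams, screen_pipeline
from .enrichment import read_gmt, enrich
from .celltype_map import (
    build_compound_target_celltype,
    map_targets,
    read_celltype_table,
    write_roles,
)

logger = logging.getLogger("netpharm")


@dataclass
class RunConfig:
    """Full description of one pipeline run.

    Exactly one of ``synth`` / the file-path group must be supplied.
    """

    outdir: str = "netpharm-out"
    seed: int = 0
    synth: synth.SynthSpec | None = None
    compound_table: str | None = None
    disease_table: str | None = None
    ppi: str | None = None
    gmt_collections: dict[str, str] = field(default_factory=dict)
    celltype_table: str | None = None
    celltype_binary: bool = True
    celltype_threshold: float = 0.5
    screen: ScreenParams = field(default_factory=ScreenParams)
    alpha: float = 0.05
    min_overlap: int = 1
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_files = any(
            x is not None for x in (self.compound_table, self.disease_table, self.ppi)
        )
        if self.synth is not None and has_files:
            raise ValueError("supply either synth spec or input files, not both")
        if self.synth is None and not has_files:
            # default: fully synthetic run at the configured seed
            self.synth = synth.SynthSpec(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synth" in raw and raw["synth"] is not None:
            s = dict(raw["synth"])
            for key in ("compounds", "per_compound_sizes"):
                if key in s:
                    s[key] = tuple(s[key])
            if "planted_terms" in s:
                s["planted_terms"] = tuple(tuple(t) for t in s["planted_terms"])
            raw["synth"] = synth.SynthSpec(**s)
        if "screen" in raw and raw["screen"] is not None:
            sc = dict(raw["screen"])
            if "measures" in sc:
                sc["measures"] = tuple(sc["measures"])
            raw["screen"] = ScreenParams(**sc)
        return cls(**raw)


def _load_inputs(config: RunConfig, outdir: Path):
    """Returns (table, disease, ppi, gmt_dbs, celltype_table, truth|None)."""
    if config.synth is not None:
        spec = config.synth
        if spec.seed != config.seed:
            spec = synth.SynthSpec(**{**asdict(spec), "seed": config.seed})
        inputs_dir = outdir / "inputs"
        truth = synth.write_inputs(spec, inputs_dir)
        table = read_target_table(inputs_dir / "compound_targets.tsv")
        disease = read_target_list(inputs_dir / "disease_targets.tsv")
        ppi = read_edge_list(inputs_dir / "ppi.tsv", format="tsv-2col")
        dbs = {"synthetic": read_gmt(inputs_dir / "annotations.gmt")}
        ct = read_celltype_table(inputs_dir / "celltype.tsv", binary=True)
        return table, disease, ppi, dbs, ct, truth
    table = read_target_table(config.compound_table)
    disease = read_target_list(config.disease_table)
    fmt = "sif" if str(config.ppi).endswith(".sif") else "tsv-2col"
    ppi = read_edge_list(config.ppi, format=fmt)
    dbs = {name: read_gmt(path) for name, path in config.gmt_collections.items()}
    ct = (
        read_celltype_table(
            config.celltype_table,
            binary=config.celltype_binary,
            threshold=config.celltype_threshold,
        )
        if config.celltype_table
        else None
    )
    return table, disease, ppi, dbs, ct, None


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    for sub in ("networks", "tables", "enrichment"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "params": {
        "screen": asdict(config.screen),
        "alpha": config.alpha,
        "min_overlap": config.min_overlap,
    }}
    try:
        table, disease, ppi, dbs, ct_table, truth = _load_inputs(config, outdir)

        # --- target assembly + Venn layer -------------------------------
        logger.info("[assemble] %d interactions, %d unique targets",
                    table.n_records, table.n_unique_targets)
        per_compound = {c: targets_of(table, c) for c in table.compounds}
        union = union_targets(table)
        kway = kway_intersection(list(per_compound.values()))
        ov = overlap(union, disease)
        report["interactions"] = table.n_records
        report["unique_targets"] = table.n_unique_targets
        report["per_compound_targets"] = table.per_compound_counts()
        report["kway_intersection"] = len(kway)
        report["disease_targets"] = len(disease)
        report["disease_overlap"] = len(ov)
        table.write_tsv(outdir / "tables" / "compound_targets.tsv")
        write_venn_report(
            venn_counts(list(per_compound.values())), outdir / "tables" / "venn_compounds.tsv"
        )
        write_venn_report(
            venn_counts([union, disease]), outdir / "tables" / "venn_disease.tsv"
        )
        bipartite, roles = build_bipartite(table)
        write_network(bipartite, outdir / "networks" / "compound_target.tsv")
        write_roles(roles, outdir / "networks" / "compound_target_roles.tsv")

        # --- PPI screen ---------------------------------------------------
        core, screen_report = screen_pipeline(ppi, union, disease, config.screen)
        report["screen"] = screen_report.to_dict()
        report["core_targets"] = len(core)
        screen_report.write_json(outdir / "tables" / "screen_report.json")
        write_node_list(core.members, outdir / "tables" / "core_targets.tsv")
        core_net = induced_subgraph(ppi, core.members)
        write_network(core_net, outdir / "networks" / "core_ppi.tsv")
        if truth is not None and truth["ppi"].get("clique"):
            planted = set(truth["ppi"]["clique"])
            got = set(core.members)
            jacc = len(planted & got) / len(planted | got) if planted | got else 0.0
            report["planted_clique_jaccard"] = jacc

        # --- enrichment ---------------------------------------------------
        report["enrichment"] = {}
        for name, db in dbs.items():
            res = enrich(core, db, alpha=config.alpha, min_overlap=config.min_overlap)
            res.write_tsv(outdir / "enrichment" / f"{name}.tsv")
            res.write_bubble_tsv(outdir / "enrichment" / f"{name}_bubble.tsv")
            report["enrichment"][name] = {
                "n_terms_tested": len(res.frame),
                "n_significant": res.n_significant,
                "top_terms": res.top_terms(5),
            }

        # --- cell-type mapping -------------------------------------------
        if ct_table is not None:
            map_query = overlap(union, disease) if truth is not None else core
            net_ct, counts, unmapped = map_targets(map_query, ct_table)
            write_network(net_ct, outdir / "networks" / "target_celltype.tsv")
            report["celltype_counts"] = counts
            report["celltype_unmapped"] = len(unmapped)
            tri, tri_roles = build_compound_target_celltype(table, map_query, ct_table)
            write_network(tri, outdir / "networks" / "compound_target_celltype.tsv")
            write_roles(tri_roles, outdir / "networks" / "compound_target_celltype_roles.tsv")
            with (outdir / "tables" / "celltype_counts.tsv").open("w") as fh:
                fh.write("celltype\tcount\n")
                for ctype in sorted(counts):
                    fh.write(f"{ctype}\t{counts[ctype]}\n")
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("[run-all] report written to %s", report_path)
    return report
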