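"""Two-stage topological screen for core targets in a PPI network.

The screen mirrors the standard network-pharmacology funnel:

1. build a compound-target PPI neighbourhood and a disease-target PPI
   neighbourhood by seed expansion (seeds plus their direct interactors,
   induced subgraph);
2. intersect the two networks edge-wise;
3. **stage 1** — keep nodes whose degree exceeds ``degree_multiplier`` times
   the median degree of all nodes (default: more than twice the median);
4. **stage 2** — on the stage-1 survivor network, recompute all six
   centrality measures and keep nodes that beat the survivor-network median
   in *every* measure (strict ``>`` by default, mirroring stage 1's
   "more than"; the non-strict variant is exposed because on small or highly
   tied graphs the strict screen can legitimately come back empty).

Stage-2 medians are recomputed on the survivor network rather than inherited
from the full network; alternatively a fixed external threshold vector can be
supplied, which is how a published feature table with published cutoffs is
replayed (see :func:`select_by_thresholds`).
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

from .netcore import Network, induced_subgraph, intersect_networks
from .target_assembly import TargetSet
from . import topology
from .topology import CentralityTable, compute_all

MEASURES = topology.MEASURES


class EmptyStageError(RuntimeError):
    """A screening stage produced an empty network/set; names the stage."""

    def __init__(self, stage: str, detail: str = ""):
        self.stage = stage
        msg = f"screening stage {stage!r} produced an empty result"
        super().__init__(msg + (f": {detail}" if detail else ""))


@dataclass(frozen=True)
class ScreenParams:
    """Tunables of the two-stage screen.

    degree_multiplier : stage-1 cutoff is ``degree_multiplier * median degree``
                        (strictly exceeded); 2.0 reproduces "more than twice
                        the median degree".
    stage2_strict     : strict ``>`` (default) vs ``>=`` against the stage-2
                        medians.
    measures          : which of DC/BC/CC/EC/NC/LAC a node must beat; all six
                        by default.
    expansion_hops    : 0 = induced subgraph on the seeds themselves,
                        1 = seeds plus direct interactors (default).
    """

    degree_multiplier: float = 2.0
    stage2_strict: bool = True
    measures: tuple[str, ...] = MEASURES
    expansion_hops: int = 1

    def __post_init__(self) -> None:
        if self.degree_multiplier < 0:
            raise ValueError("degree_multiplier must be >= 0")
        if not self.measures:
            raise ValueError("measures must be non-empty")
        bad = [m for m in self.measures if m not in MEASURES]
        if bad:
            raise ValueError(f"unknown measures {bad}; valid: {MEASURES}")
        if self.expansion_hops not in (0, 1):
            raise ValueError("expansion_hops must be 0 or 1")


@dataclass
class StageCount:
    stage: str
    n_nodes: int
    n_edges: int


@dataclass
class ScreenReport:
    """Per-stage bookkeeping of the full screen (the Fig-style funnel)."""

    stages: list[StageCount] = field(default_factory=list)
    seeds_missing_from_ppi: dict[str, int] = field(default_factory=dict)
    stage1_median_degree: float | None = None
    stage1_threshold: float | None = None
    stage2_medians: dict[str, float] | None = None
    params: ScreenParams | None = None
    core_targets: list[str] = field(default_factory=list)

    def add_stage(self, stage: str, net: Network) -> None:
        self.stages.append(StageCount(stage, net.n_nodes, net.n_edges))

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.params is not None:
            d["params"] = asdict(self.params)
        return d

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def expand_seeds(
    ppi: Network, seeds: TargetSet, params: ScreenParams = ScreenParams()
) -> tuple[Network, int]:
    """Seed-expanded PPI neighbourhood.

    hops=0: induced subgraph on ``seeds ∩ V(ppi)``; hops=1: induced subgraph
    on seeds plus their direct interactors (so interactor–interactor edges
    are included).  Returns the network and the number of seeds absent from
    the PPI.  Raises if no seed is present at all.
    """
    if not seeds.members:
        raise ValueError("empty seed set")
    present = seeds.members & ppi.nodes
    n_missing = len(seeds.members) - len(present)
    if not present:
        raise ValueError(
            f"none of the {len(seeds.members)} seeds in {seeds.label!r} "
            "are present in the PPI network"
        )
    keep = set(present)
    if params.expansion_hops == 1:
        for s in present:
            keep.update(ppi.graph.neighbors(s))
    net = induced_subgraph(ppi, keep)
    net.name = f"{seeds.label}-expanded"
    return net, n_missing


def stage1_filter(
    net: Network, params: ScreenParams = ScreenParams()
) -> tuple[Network, float, float]:
    """Degree filter: keep nodes with degree > multiplier × median degree.

    The median is taken over *all* nodes of the input network.  Returns the
    induced survivor subgraph plus (median, threshold).  An all-tied degree
    distribution can legitimately empty the result (a warning case handled
    by the caller / pipeline).
    """
    if net.n_nodes == 0:
        raise ValueError("stage-1 filter on an empty network")
    degrees = [net.graph.degree[v] for v in net.graph.nodes]
    median = float(statistics.median(degrees))
    threshold = params.degree_multiplier * median
    keep = {v for v in net.graph.nodes if net.graph.degree[v] > threshold}
    survivor = induced_subgraph(net, keep)
    survivor.name = f"{net.name}-stage1"
    return survivor, median, threshold


def select_by_thresholds(
    table: CentralityTable,
    thresholds: Mapping[str, float],
    strict: bool = True,
    measures: Sequence[str] = MEASURES,
) -> frozenset[str]:
    """Nodes of a feature table beating a fixed threshold in every measure.

    This is the replay path for a published feature table with published
    cutoff values; :func:`stage2_filter` uses it with freshly computed
    medians.
    """
    mask = None
    for m in measures:
        if m not in thresholds:
            raise KeyError(f"no threshold supplied for measure {m!r}")
        col = table.frame[m]
        m_mask = col > thresholds[m] if strict else col >= thresholds[m]
        mask = m_mask if mask is None else (mask & m_mask)
    return frozenset(table.frame.index[mask])


def stage2_filter(
    net: Network,
    params: ScreenParams = ScreenParams(),
    thresholds: Mapping[str, float] | None = None,
) -> tuple[TargetSet, dict[str, float], CentralityTable]:
    """Centrality filter: nodes above the median in every selected measure.

    Computes the six-measure table on ``net``, takes each measure's median
    over ``net``'s nodes (or uses the supplied fixed ``thresholds``), and
    keeps nodes strictly above (or ``>=`` when ``params.stage2_strict`` is
    False) in every measure of ``params.measures``.  Returns the selected
    set, the thresholds used, and the feature table.
    """
    if net.n_nodes < 2 or net.n_edges < 1:
        raise ValueError(
            "stage-2 filter needs a network with >=2 nodes and >=1 edge "
            "(eigenvector centrality is undefined otherwise)"
        )
    table = compute_all(net)
    if thresholds is None:
        med = table.medians
        thresholds = {m: float(med[m]) for m in params.measures}
    selected = select_by_thresholds(
        table, thresholds, strict=params.stage2_strict, measures=params.measures
    )
    return (
        TargetSet(label="core", members=selected),
        dict(thresholds),
        table,
    )


def screen_pipeline(
    ppi: Network,
    compound_targets: TargetSet,
    disease_targets: TargetSet,
    params: ScreenParams = ScreenParams(),
) -> tuple[TargetSet, ScreenReport]:
    """Full funnel: expand both seed sets, intersect, stage 1, stage 2.

    Raises :class:`EmptyStageError` naming the first stage that empties the
    funnel; otherwise returns the core target set plus a report holding every
    stage's node/edge counts and all thresholds/medians used.
    """
    report = ScreenReport(params=params)
    report.add_stage("ppi", ppi)

    cpd_net, cpd_missing = expand_seeds(ppi, compound_targets, params)
    report.seeds_missing_from_ppi[compound_targets.label] = cpd_missing
    report.add_stage("compound-expansion", cpd_net)
    if cpd_net.n_nodes == 0:
        raise EmptyStageError("compound-expansion")

    dis_net, dis_missing = expand_seeds(ppi, disease_targets, params)
    report.seeds_missing_from_ppi[disease_targets.label] = dis_missing
    report.add_stage("disease-expansion", dis_net)
    if dis_net.n_nodes == 0:
        raise EmptyStageError("disease-expansion")

    inter = intersect_networks(cpd_net, dis_net)
    report.add_stage("intersection", inter)
    if inter.n_nodes == 0:
        raise EmptyStageError("intersection")

    survivors, median_deg, threshold = stage1_filter(inter, params)
    report.stage1_median_degree = median_deg
    report.stage1_threshold = threshold
    report.add_stage("stage1", survivors)
    if survivors.n_nodes == 0:
        raise EmptyStageError(
            "stage1", f"no node degree exceeds {threshold} (median {median_deg})"
        )

    core, medians, _table = stage2_filter(survivors, params)
    report.stage2_medians = medians
    report.core_targets = sorted(core.members)
    core_net = induced_subgraph(survivors, core.members)
    report.add_stage("stage2", core_net)
    if not core.members:
        raise EmptyStageError("stage2", "no node beats the median in every measure")
    return core, report
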