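"""Planted-structure generators: exactness, determinism, feasibility errors."""

import numpy as np
import pytest

from netpharm import (
    SynthSpec,
    TargetSet,
    enrich,
    gen_annotation_db,
    gen_celltype_table,
    gen_compound_targets,
    gen_disease_targets,
    gen_feature_table,
    gen_ppi,
    kway_intersection,
    map_targets,
    targets_of,
    union_targets,
)
from netpharm.core_screen import select_by_thresholds
from netpharm.synthetic_data import DEFAULT_FEATURE_THRESHOLDS, gene_universe
from netpharm.topology import MEASURES, local_avg_connectivity


SMALL = dict(ppi_nodes=300, clique_size=12)


class TestCompoundTargets:
    def test_planted_counts_exact(self):
        spec = SynthSpec(seed=7)
        table, truth = gen_compound_targets(spec)
        assert table.n_records == 652
        assert table.n_unique_targets == 438
        counts = table.per_compound_counts()
        assert [counts[c] for c in spec.compounds] == [156, 129, 226, 141]
        sets = [targets_of(table, c) for c in spec.compounds]
        inter = kway_intersection(sets)
        assert inter.members == frozenset(truth["planted_kway"])
        assert len(inter) == 16

    def test_same_seed_identical(self):
        a, _ = gen_compound_targets(SynthSpec(seed=3))
        b, _ = gen_compound_targets(SynthSpec(seed=3))
        assert a.records == b.records

    def test_different_seed_differs(self):
        a, _ = gen_compound_targets(SynthSpec(seed=3))
        b, _ = gen_compound_targets(SynthSpec(seed=4))
        assert a.records != b.records

    def test_kway_zero_means_empty_intersection(self):
        spec = SynthSpec(
            seed=1, planted_kway=0, n_unique_targets=None,
            per_compound_sizes=(30, 30, 30, 30),
        )
        table, _ = gen_compound_targets(spec)
        sets = [targets_of(table, c) for c in spec.compounds]
        assert len(kway_intersection(sets)) == 0

    def test_infeasible_union_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            SynthSpec(per_compound_sizes=(10, 10, 10, 10), planted_kway=5,
                      n_unique_targets=400)

    def test_kway_larger_than_smallest_set_raises(self):
        with pytest.raises(ValueError, match="planted_kway"):
            SynthSpec(per_compound_sizes=(10, 129, 226, 141), planted_kway=16,
                      n_unique_targets=None)


class TestDiseaseTargets:
    def test_planted_overlap_exact(self):
        spec = SynthSpec(seed=5)
        table, _ = gen_compound_targets(spec)
        union = union_targets(table)
        disease, truth = gen_disease_targets(spec, union)
        assert len(disease) == 321
        assert len(disease.members & union.members) == 47
        assert frozenset(truth["planted_overlap"]) == disease.members & union.members

    def test_zero_overlap_disjoint(self):
        spec = SynthSpec(seed=5, planted_disease_overlap=0)
        table, _ = gen_compound_targets(spec)
        union = union_targets(table)
        disease, _ = gen_disease_targets(spec, union)
        assert disease.members.isdisjoint(union.members)

    def test_full_overlap_subset(self):
        spec = SynthSpec(seed=5, disease_size=47, planted_disease_overlap=47)
        table, _ = gen_compound_targets(spec)
        union = union_targets(table)
        disease, _ = gen_disease_targets(spec, union)
        assert disease.members <= union.members


class TestPPI:
    def test_complete_er_has_all_edges(self):
        spec = SynthSpec(seed=0, ppi_model="erdos-renyi", er_p=1.0, ppi_nodes=5)
        net, _ = gen_ppi(spec)
        assert net.n_edges == 10

    def test_planted_clique_arithmetic(self):
        spec = SynthSpec(seed=2, **SMALL)
        net, truth = gen_ppi(spec)
        lac = local_avg_connectivity(net)
        q = spec.clique_size
        for c in truth["clique"]:
            deg = net.degree(c)
            assert deg >= q - 1
            # neighbours include the q-1 other members, fully interconnected
            assert lac[c] >= (q - 1) * (q - 2) / deg

    def test_decoys_only_touch_clique(self):
        net, truth = gen_ppi(SynthSpec(seed=2, **SMALL))
        clique = set(truth["clique"])
        for d in truth["decoys"]:
            assert net.neighbors(d) == clique

    def test_same_seed_identical_edges(self):
        a, _ = gen_ppi(SynthSpec(seed=9, **SMALL))
        b, _ = gen_ppi(SynthSpec(seed=9, **SMALL))
        assert a == b

    def test_clique_larger_than_network_raises(self):
        with pytest.raises(ValueError, match="clique_size"):
            SynthSpec(ppi_nodes=10, clique_size=12)

    def test_coverage_seeds_make_expansion_span(self):
        from netpharm import expand_seeds

        spec = SynthSpec(seed=4, **SMALL)
        names = [f"N{i:05d}" for i in range(spec.ppi_nodes)]
        seeds = names[:40]
        net, _ = gen_ppi(spec, node_names=names, coverage_seeds=[seeds])
        expanded, _ = expand_seeds(net, TargetSet("s", frozenset(seeds)))
        # decoys may sit outside the seed neighbourhood; everything else is in
        uncovered = net.nodes - expanded.nodes
        _, truth = gen_ppi(spec, node_names=names, coverage_seeds=[seeds])
        assert uncovered <= set(truth["decoys"])


class TestAnnotationDB:
    def test_planted_term_ranks_first_across_seeds(self):
        wins = 0
        for seed in range(10):
            spec = SynthSpec(seed=seed)
            rng = np.random.default_rng([seed, 77])
            q = TargetSet(
                "q", frozenset(rng.choice(gene_universe(spec.universe_size),
                                          size=47, replace=False))
            )
            db, truth = gen_annotation_db(spec, q)
            res = enrich(q, db)
            wins += res.frame.iloc[0]["term"] in truth["planted_terms"]
        assert wins >= 9

    def test_infeasible_fold_raises(self):
        spec = SynthSpec(seed=0, planted_terms=((20, 100.0),))
        q = TargetSet("q", frozenset(gene_universe(5000)[:200]))
        with pytest.raises(ValueError, match="infeasible"):
            gen_annotation_db(spec, q)

    def test_no_planted_terms_type_one_control(self):
        # with no planted signal, the smallest raw p should usually stay
        # above the Bonferroni line (hypergeometric discreteness makes the
        # test conservative)
        clean = 0
        n_seeds = 10
        for seed in range(n_seeds):
            spec = SynthSpec(seed=seed, planted_terms=())
            rng = np.random.default_rng([seed, 78])
            q = TargetSet(
                "q", frozenset(rng.choice(gene_universe(spec.universe_size),
                                          size=47, replace=False))
            )
            db, _ = gen_annotation_db(spec, q)
            res = enrich(q, db)
            if len(res.frame) == 0 or res.frame["p"].min() > 0.05 / db.n_terms:
                clean += 1
        assert clean >= 0.8 * n_seeds


class TestCellTypeTable:
    def test_planted_counts_recovered_exactly(self):
        spec = SynthSpec(seed=11)
        targets = TargetSet("q", frozenset(gene_universe(5000)[:47]))
        table, truth = gen_celltype_table(spec, targets)
        _, counts, _ = map_targets(targets, table)
        assert counts == {"neuron": 31, "astrocyte": 14, "endothelial": 13,
                          "microglia": 11}
        for ct, members in truth["per_celltype"].items():
            assert len(members) == counts[ct]

    def test_all_zero_counts_empty_mapping(self):
        spec = SynthSpec(seed=1, celltype_planted_counts={"neuron": 0})
        targets = TargetSet("q", frozenset(gene_universe(5000)[:10]))
        table, _ = gen_celltype_table(spec, targets)
        _, counts, unmapped = map_targets(targets, table)
        assert counts == {"neuron": 0} and unmapped == targets.members

    def test_infeasible_count_raises(self):
        spec = SynthSpec(seed=1, celltype_planted_counts={"neuron": 99})
        targets = TargetSet("q", frozenset(gene_universe(5000)[:10]))
        with pytest.raises(ValueError, match="neuron"):
            gen_celltype_table(spec, targets)

    def test_same_seed_identical(self):
        spec = SynthSpec(seed=6)
        targets = TargetSet("q", frozenset(gene_universe(5000)[:47]))
        a, _ = gen_celltype_table(spec, targets)
        b, _ = gen_celltype_table(spec, targets)
        assert a.frame.equals(b.frame)


class TestFeatureTable:
    def test_medians_and_core_count_planted(self):
        table, truth = gen_feature_table(seed=3)
        med = table.medians
        for m in MEASURES:
            assert med[m] == pytest.approx(DEFAULT_FEATURE_THRESHOLDS[m])
        selected = select_by_thresholds(table, DEFAULT_FEATURE_THRESHOLDS, strict=True)
        assert len(selected) == 189
        assert selected == frozenset(truth["core_nodes"])
        assert len(table.frame) == 564

    def test_cc_stays_in_unit_interval(self):
        table, _ = gen_feature_table(seed=5)
        assert table.frame["CC"].between(0, 1).all()

    def test_core_budget_validation(self):
        with pytest.raises(ValueError, match="n_core"):
            gen_feature_table(seed=0, n_rows=100, n_core=60)
        with pytest.raises(ValueError, match="even"):
            gen_feature_table(seed=0, n_rows=101, n_core=10)
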