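import numpy as np
import pytest

from embolocate.ontology_assignment import (
    NOT_AT_LEVEL,
    UNACCOUNTED,
    AnnotationVolume,
    AtlasOntology,
    aggregate_counts,
    assign_region,
    compile_report,
    region_density,
    region_volume_mm3,
    select_terminal_branches,
)


class TestOntologyTree:
    def test_levels(self, hand_ontology):
        assert hand_ontology.level(1) == 1
        assert hand_ontology.level(3) == 2
        assert hand_ontology.level(8) == 5

    def test_single_root_enforced(self):
        with pytest.raises(ValueError, match="root"):
            AtlasOntology(
                [
                    {"id": 1, "name": "a", "parent_structure_id": None},
                    {"id": 2, "name": "b", "parent_structure_id": None},
                ]
            )

    def test_ancestor_at_level_vs_brute_force_walk(self, hand_ontology):
        ont = hand_ontology
        for nid in ont.nodes:
            chain = ont.path_to_root(nid)  # root..nid
            for k in range(1, 7):
                expected = chain[k - 1] if k <= len(chain) else NOT_AT_LEVEL
                assert ont.ancestor_at_level(nid, k) == expected

    def test_ancestor_of_shallow_node_at_deep_level(self, hand_ontology):
        assert hand_ontology.ancestor_at_level(5, 5) == NOT_AT_LEVEL

    def test_any_node_at_level_1_is_root(self, hand_ontology):
        for nid in hand_ontology.nodes:
            assert hand_ontology.ancestor_at_level(nid, 1) == 1

    def test_unknown_id_rejected(self, hand_ontology):
        with pytest.raises(KeyError):
            hand_ontology.ancestor_at_level(999, 3)

    def test_json_roundtrip(self, hand_ontology, tmp_path):
        p = tmp_path / "ontology.json"
        hand_ontology.to_json(p)
        loaded = AtlasOntology.from_json(p)
        assert set(loaded.nodes) == set(hand_ontology.nodes)
        assert loaded.level(8) == 5


class TestAssignRegion:
    def test_inside_labelled_voxel(self):
        labels = np.zeros((4, 4, 4), np.int32)
        labels[1, 2, 3] = 42
        ann = AnnotationVolume(labels, voxel_size_um=50.0)
        assert assign_region((1.2, 2.4, 2.6), ann) == 42

    def test_outside_volume_is_unaccounted(self):
        ann = AnnotationVolume(np.ones((4, 4, 4), np.int32), 50.0)
        assert assign_region((10, 0, 0), ann) == UNACCOUNTED
        assert assign_region((-1.0, 0, 0), ann) == UNACCOUNTED

    def test_label_zero_is_unaccounted(self):
        ann = AnnotationVolume(np.zeros((4, 4, 4), np.int32), 50.0)
        assert assign_region((1, 1, 1), ann) == UNACCOUNTED


class TestAggregation:
    def test_counts_roll_up_to_parent(self, hand_ontology):
        cum = aggregate_counts(hand_ontology, {8: 3, 9: 2})
        assert cum[7] == 5
        assert cum[4] == 5
        assert cum[1] == 5

    def test_root_count_conserves_total(self, hand_ontology):
        cum = aggregate_counts(hand_ontology, {6: 4, 8: 1, 3: 2, 5: 7})
        assert cum[1] == 14

    def test_empty_counts_all_zero(self, hand_ontology):
        cum = aggregate_counts(hand_ontology, {})
        assert all(v == 0 for v in cum.values())

    def test_unknown_id_rejected(self, hand_ontology):
        with pytest.raises(KeyError):
            aggregate_counts(hand_ontology, {999: 1})


class TestTerminalBranches:
    def test_below_threshold_node_is_terminal(self, hand_ontology):
        # 4 spheres in "nuclei": not enough to expand into its children,
        # while well-funded sibling branches keep the ancestors expanding
        cum = aggregate_counts(hand_ontology, {8: 2, 9: 2, 6: 30, 3: 10})
        terms = select_terminal_branches(hand_ontology, cum, min_count=5)
        assert 7 in terms and 8 not in terms and 9 not in terms

    def test_at_threshold_node_is_expanded(self, hand_ontology):
        cum = aggregate_counts(hand_ontology, {8: 3, 9: 2})
        terms = select_terminal_branches(hand_ontology, cum, min_count=5)
        assert 7 not in terms and 8 in terms and 9 in terms

    def test_leaf_is_always_terminal(self, hand_ontology):
        cum = aggregate_counts(hand_ontology, {6: 100})
        terms = select_terminal_branches(hand_ontology, cum, min_count=5)
        assert 6 in terms

    def test_partition_is_exclusive_and_exhaustive(self, toy_atlas):
        ontology, annotation = toy_atlas
        rng = np.random.default_rng(0)
        leaves = [n for n in ontology.nodes if ontology.is_leaf(n)]
        direct = {int(l): int(c) for l, c in zip(leaves, rng.integers(0, 30, len(leaves)))}
        cum = aggregate_counts(ontology, direct)
        terms = select_terminal_branches(ontology, cum, min_count=5)
        # no terminal is an ancestor of another
        for t in terms:
            path = set(ontology.path_to_root(t)) - {t}
            assert not path & set(terms)
        # every counted sphere is inside exactly one terminal subtree
        assert sum(cum[t] for t in terms) == cum[ontology.root_id]

    def test_max_level_caps_expansion(self, hand_ontology):
        cum = aggregate_counts(hand_ontology, {8: 10, 9: 10})
        terms = select_terminal_branches(hand_ontology, cum, min_count=5, max_level=3)
        assert terms == [4]


class TestDensity:
    def test_simple_ratio(self):
        assert region_density(10, 5.0) == 2.0

    def test_zero_count(self):
        assert region_density(0, 5.0) == 0.0

    def test_zero_volume_with_count_rejected(self):
        with pytest.raises(ValueError):
            region_density(3, 0.0)

    def test_8000_voxels_at_50um_is_one_mm3(self):
        ont = AtlasOntology(
            [
                {"id": 1, "name": "root", "parent_structure_id": None},
                {"id": 2, "name": "box", "parent_structure_id": 1},
            ]
        )
        labels = np.zeros((30, 30, 30), np.int32)
        labels[:20, :20, :20] = 2
        ann = AnnotationVolume(labels, voxel_size_um=50.0)
        assert region_volume_mm3(ont, ann, 2) == pytest.approx(1.0)

    def test_parent_volume_includes_descendants(self, toy_atlas):
        ontology, annotation = toy_atlas
        root_vol = region_volume_mm3(ontology, annotation, ontology.root_id)
        brain_voxels = int((annotation.labels > 0).sum())
        assert root_vol == pytest.approx(brain_voxels * annotation.voxel_volume_mm3)


class TestCompileReport:
    def _assignments(self, hand_ontology):
        return [6] * 7 + [8] * 3 + [9] * 3 + [5] * 2 + [UNACCOUNTED] * 2

    def test_proportions_sum_to_100(self, hand_ontology):
        rep = compile_report(self._assignments(hand_ontology), hand_ontology)
        totals = rep.regions[rep.regions["region"] == "Total, all regions combined"]
        assert totals["proportion_pct"].iloc[0] == pytest.approx(100.0, abs=0.1)

    def test_totals_row_count_is_sum(self, hand_ontology):
        rep = compile_report(self._assignments(hand_ontology), hand_ontology)
        regions = rep.regions[rep.regions["region_id"] > 0]
        totals = rep.regions[rep.regions["region"] == "Total, all regions combined"]
        assert totals["count"].iloc[0] == regions["count"].sum() + rep.unaccounted

    def test_totals_row_density_is_mean(self, toy_atlas):
        ontology, annotation = toy_atlas
        rng = np.random.default_rng(1)
        leaves = [n for n in ontology.nodes if ontology.is_leaf(n)]
        assignments = rng.choice(leaves, 200).tolist()
        rep = compile_report(assignments, ontology, annotation)
        regions = rep.regions[rep.regions["region_id"] > 0]
        totals = rep.regions[rep.regions["region"] == "Total, all regions combined"]
        assert totals["density_per_mm3"].iloc[0] == pytest.approx(
            regions["density_per_mm3"].mean()
        )

    def test_count_conservation(self, toy_atlas):
        ontology, annotation = toy_atlas
        rng = np.random.default_rng(2)
        leaves = [n for n in ontology.nodes if ontology.is_leaf(n)]
        assignments = rng.choice(leaves, 150).tolist() + [UNACCOUNTED] * 7
        rep = compile_report(assignments, ontology, annotation)
        regions = rep.regions[rep.regions["region_id"] > 0]
        assert regions["count"].sum() + rep.unaccounted == rep.total_detections
        assert rep.unaccounted == 7

    def test_level_table_marks_missing_levels(self, hand_ontology):
        rep = compile_report([5, 8], hand_ontology)
        row_brainstem = rep.level_table.iloc[0]
        assert row_brainstem["level_3"] == "brainstem"
        assert row_brainstem["level_4"] == NOT_AT_LEVEL
        row_nucleus = rep.level_table.iloc[1]
        assert row_nucleus["level_5"] == "nucleus a"
        assert row_nucleus["level_1"] == "root"

    def test_density_convergence_uniform_in_one_region(self, toy_atlas):
        """Spheres placed uniformly in one region estimate density n/V."""
        from embolocate.synthetic_data import generate_scene

        ontology, annotation = toy_atlas
        # pick a decently sized leaf region
        counts = annotation.label_voxel_counts()
        leaf = max(
            (n for n in ontology.nodes if ontology.is_leaf(n) and counts.get(n, 0) > 0),
            key=lambda n: counts.get(n, 0),
        )
        n = 500
        scene = generate_scene(
            ontology, annotation, n, placement="weighted", weights={leaf: 1.0},
            seed=5, min_separation_um=0.0,
        )
        assigned = [assign_region(p, annotation) for p in scene.positions]
        vol = region_volume_mm3(ontology, annotation, leaf)
        density = sum(a == leaf for a in assigned) / vol
        assert density == pytest.approx(n / vol, rel=0.05)
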