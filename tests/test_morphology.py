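"""Morphology data model, SWC round trips, curation and morphometrics."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import microcortex as mc
from microcortex.morphology import NeuriteTree

from conftest import chain_tree, y_tree, comb_axon, simple_neuron

MINIMAL_SWC = """# soma (3-point) + one axon
1 1 0 0 0 5 -1
2 1 0 -5 0 5 1
3 1 0 5 0 5 1
4 2 0 -6 0 0.4 1
5 2 0 -30 0 0.4 4
"""


class TestSWC:
    def test_minimal_soma_and_axon(self, tmp_path):
        p = tmp_path / "m.swc"
        p.write_text(MINIMAL_SWC)
        m = mc.read_swc(p)
        assert len(m.neurites) == 1
        tree = m.neurites[0]
        assert tree.neurite_type == "axon"
        assert tree.n_nodes == 2
        assert np.allclose(m.soma_center, [0, 0, 0])
        assert m.soma_radius == pytest.approx(5.0)
        assert tree.total_length == pytest.approx(24.0)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 2 0 0 nonsense 0.4 1\n")
        with pytest.raises(mc.SWCFormatError, match="bad.swc:2"):
            mc.read_swc(p)

    def test_wrong_column_count(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 5\n")
        with pytest.raises(mc.SWCFormatError, match="7 columns"):
            mc.read_swc(p)

    def test_multiple_somata_rejected(self, tmp_path):
        p = tmp_path / "twosoma.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 1 100 0 0 5 -1\n")
        with pytest.raises(mc.SWCFormatError, match="multiple somata"):
            mc.read_swc(p)

    def test_roundtrip_preserves_geometry_and_morphometrics(self, tmp_path, human_preset):
        pop = mc.generate_population(human_preset, 4, seed=7)
        for i, m in enumerate(pop):
            path = tmp_path / f"n{i}.swc"
            mc.write_swc(m, path, with_meta=True)
            m2 = mc.read_swc(path)
            assert len(m2.neurites) == len(m.neurites)
            for a, b in zip(m.neurites, m2.neurites):
                assert a.neurite_type == b.neurite_type
                assert np.allclose(a.points, b.points, atol=1e-6)
                assert np.allclose(a.diameters, b.diameters, atol=1e-6)
                assert np.array_equal(a.parent, b.parent)
            ra = mc.morphometrics(m).to_flat_dict()
            rb = mc.morphometrics(m2).to_flat_dict()
            assert ra.keys() == rb.keys()
            for k in ra:
                assert ra[k] == pytest.approx(rb[k], abs=1e-4)
            assert m2.meta.species == m.meta.species


class TestCuration:
    def test_disconnected_root_reconnected(self):
        tree = chain_tree().translated([0.0, 10.0, 0.0])  # root 10 um from center
        m = simple_neuron([tree], cell_class="IN", soma_radius=5.0)
        cured = mc.curate_morphology(m)
        root = cured.neurites[0].points[0]
        assert np.linalg.norm(root - m.soma_center) == pytest.approx(5.0)
        # rigid translation: length preserved
        assert cured.neurites[0].total_length == pytest.approx(tree.total_length)

    def test_identity_when_clean(self):
        m = simple_neuron([chain_tree(neurite_type="apical", direction=(0, 1, 0)).translated([0, 5, 0])])
        cured = mc.curate_morphology(m)
        assert np.allclose(cured.neurites[0].points, m.neurites[0].points, atol=1e-9)

    def test_apical_flipped_to_positive_y(self):
        down = chain_tree(neurite_type="apical", direction=(0, -1, 0)).translated([0, -5, 0])
        m = simple_neuron([down])
        cured = mc.curate_morphology(m)
        centroid_y = np.vstack([t.points for t in cured.trees("apical")])[:, 1].mean()
        assert centroid_y > 0

    def test_idempotent(self, human_preset):
        m = mc.generate_population(human_preset, 1, seed=3)[0]
        once = mc.curate_morphology(m)
        twice = mc.curate_morphology(once)
        for a, b in zip(once.neurites, twice.neurites):
            assert np.allclose(a.points, b.points, atol=1e-6)

    def test_zero_diameters_filled_from_neighbors(self):
        tree = chain_tree(diameter=0.5)
        d = tree.diameters.copy()
        d[3] = 0.0
        tree = NeuriteTree(tree.parent, tree.points, d, tree.neurite_type)
        m = simple_neuron([tree], cell_class="IN")
        cured = mc.curate_morphology(m)
        assert cured.neurites[0].diameters[3] == pytest.approx(0.5)

    def test_pc_without_apical_warns(self):
        m = simple_neuron([chain_tree(neurite_type="basal")], cell_class="PC")
        with pytest.warns(UserWarning, match="no apical"):
            mc.curate_morphology(m)


class TestMorphometrics:
    def test_straight_basal(self):
        rec = mc.morphometrics(simple_neuron([chain_tree(length=100.0)]))
        assert rec.total_length_per_type["basal"] == pytest.approx(100.0)
        assert rec.branch_count_per_type["basal"] == 1

    def test_y_tree_counts_three_branches(self):
        rec = mc.morphometrics(simple_neuron([y_tree(50, 50, 50)]))
        assert rec.total_length_per_type["basal"] == pytest.approx(150.0)
        assert rec.branch_count_per_type["basal"] == 3

    def test_branch_count_equals_leaves_plus_bifurcations(self, human_pc_pop):
        for m in human_pc_pop[:3]:
            for tree in m.neurites:
                assert tree.branch_count == tree.n_leaves + tree.n_bifurcations

    def test_human_population_longer_than_mouse(self, human_pc_pop, mouse_pc_pop):
        h = np.mean([m.total_dendritic_length for m in human_pc_pop])
        mo = np.mean([m.total_dendritic_length for m in mouse_pc_pop])
        assert h > mo


class TestDiameterProfile:
    def test_constant_diameter(self):
        prof = mc.diameter_profile([simple_neuron([chain_tree(diameter=0.5)])], bin_width=10.0)
        filled = prof[prof["count"] > 0]
        assert np.allclose(filled["mean"], 0.5)
        assert np.allclose(filled["sd"], 0.0)

    def test_tapering_tree_decreasing(self):
        n = 21
        tree = chain_tree(length=200.0, n_nodes=n)
        d = np.linspace(1.0, 0.2, n)
        tree = NeuriteTree(tree.parent, tree.points, d, tree.neurite_type)
        prof = mc.diameter_profile([simple_neuron([tree])], bin_width=40.0)
        means = prof[prof["count"] > 0]["mean"].to_numpy()
        assert np.all(np.diff(means) < 0)

    def test_two_trees_average(self):
        m1 = simple_neuron([chain_tree(diameter=0.4)])
        m2 = simple_neuron([chain_tree(diameter=0.6)])
        prof = mc.diameter_profile([m1, m2], bin_width=25.0)
        filled = prof[prof["count"] > 0]
        assert np.allclose(filled["mean"], 0.5)

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            mc.diameter_profile([simple_neuron()], bin_width=0.0)


class TestScaling:
    def test_identity(self):
        m = simple_neuron([y_tree()])
        s = mc.scale_morphology(m, 1.0)
        assert np.allclose(s.neurites[0].points, m.neurites[0].points)

    def test_doubling_length(self):
        m = simple_neuron([y_tree(50, 50, 50)])
        s = mc.scale_morphology(m, 2.0)
        assert s.total_dendritic_length == pytest.approx(300.0)

    @settings(deadline=None, max_examples=25)
    @given(st.floats(min_value=0.05, max_value=20.0))
    def test_length_scales_linearly(self, factor):
        m = simple_neuron([y_tree(40, 60, 25)])
        s = mc.scale_morphology(m, factor)
        assert s.total_dendritic_length == pytest.approx(factor * m.total_dendritic_length, rel=1e-9)

    def test_diameters_untouched(self):
        m = simple_neuron([chain_tree(diameter=0.7)])
        s = mc.scale_morphology(m, 3.0)
        assert np.allclose(s.neurites[0].diameters, 0.7)

    @pytest.mark.parametrize("factor", [0.0, -1.0])
    def test_invalid_factor(self, factor):
        with pytest.raises(ValueError):
            mc.scale_morphology(simple_neuron(), factor)


class TestGrafting:
    def test_self_graft_is_identity_on_morphometrics(self, human_pc_pop):
        m = human_pc_pop[0]
        g = mc.graft_axon(m, m)
        a, b = mc.morphometrics(m).to_flat_dict(), mc.morphometrics(g).to_flat_dict()
        for k in a:
            assert a[k] == pytest.approx(b[k])

    def test_cross_graft_composition(self):
        a = simple_neuron([y_tree(neurite_type="basal"), comb_axon(5)])
        b = simple_neuron([chain_tree(neurite_type="basal"), comb_axon(21)])
        g = mc.graft_axon(a, b)
        assert g.branch_count("axon") == 21
        assert g.total_dendritic_length == pytest.approx(a.total_dendritic_length)

    def test_graft_without_axon_raises(self):
        with pytest.raises(ValueError, match="no axon"):
            mc.graft_axon(simple_neuron(), simple_neuron())


class TestAxonFilter:
    def test_threshold_is_strict(self):
        keep = simple_neuron([comb_axon(21)])
        drop = simple_neuron([comb_axon(19)])
        # 21 branches > 20 retained; <= 20 dropped
        assert mc.filter_axon_pool([keep, drop]) == [keep]

    def test_empty_pool(self):
        assert mc.filter_axon_pool([]) == []

    def test_matches_brute_count(self):
        rng = np.random.default_rng(0)
        pool = [simple_neuron([comb_axon(int(2 * k + 1))]) for k in rng.integers(2, 30, size=50)]
        kept = mc.filter_axon_pool(pool, min_branches=20)
        expected = sum(1 for m in pool if m.neurites[0].branch_count > 20)
        assert len(kept) == expected
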