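"""Hexagonal columns, morphology cloning and apposition detection."""
import numpy as np
import pytest
from scipy import stats

import microcortex as mc
from microcortex.circuit import points_in_hexagon, hex_tile_centers, segment_distances
from microcortex.morphology import NeuriteTree, NeuronMorphology, NeuronMeta

from conftest import chain_tree, simple_neuron
from microcortex.synthetic import NeuriteSpec, SpeciesPreset, Geometry, _diag_mixture


def tiny_preset(name="tiny"):
    """Small morphologies so brute-force apposition oracles stay cheap."""
    dend = NeuriteSpec(
        mixture=_diag_mixture([(15, 60), (40, 120)], [(8, 15), (15, 25)], [0.6, 0.4]),
        bar_count_mean=5,
        bar_count_sd=1,
        n_trees=2,
        min_bars=3,
    )
    axon = NeuriteSpec(
        mixture=_diag_mixture([(20, 90), (50, 160)], [(10, 20), (20, 30)], [0.6, 0.4]),
        bar_count_mean=6,
        bar_count_sd=1,
        min_bars=4,
    )
    return SpeciesPreset(
        name=name,
        pc={"basal": dend, "axon": axon},
        interneuron={"basal": dend, "axon": axon},
        pc_fraction=0.7,
        soma_radius=5.0,
        geometry=Geometry(segment_length=20.0),
    )


class TestHexGeometry:
    def test_volume_human_column(self):
        v = mc.hex_prism_volume(476, 1070)
        assert v == pytest.approx(0.6299, abs=0.0005)
        assert round(v, 1) == 0.6

    def test_volume_mouse_column(self):
        assert mc.hex_prism_volume(476, 235) == pytest.approx(0.1383, abs=0.0005)

    def test_unit_prism(self):
        assert mc.hex_prism_volume(1, 1) * 1e9 == pytest.approx(3 * np.sqrt(3) / 2)

    def test_point_membership(self):
        assert points_in_hexagon(np.array([[0.0, 0.0]]), 10.0)[0]
        assert points_in_hexagon(np.array([[9.9, 0.0]]), 10.0)[0]  # near vertex
        assert not points_in_hexagon(np.array([[0.0, 9.9]]), 10.0)[0]  # beyond apothem
        assert not points_in_hexagon(np.array([[11.0, 0.0]]), 10.0)[0]

    def test_tiles_do_not_overlap(self):
        centers = hex_tile_centers(100.0)
        assert len(centers) == 7
        rng = np.random.default_rng(0)
        pts = rng.uniform(-300, 300, size=(2000, 2))
        membership = np.sum(
            [points_in_hexagon(pts, 100.0, center=c) for c in centers], axis=0
        )
        assert membership.max() <= 1


class TestBuildCircuit:
    def test_counts_and_membership(self):
        spec = mc.ColumnSpec(side=100, height=200, n_pc=40, n_in=10)
        circ = mc.build_circuit(spec, seed=1)
        assert circ.n_cells == 7 * 50
        assert (circ.cells["cell_class"] == "PC").sum() == 7 * 40
        assert len(circ.central_column_ids) == 50
        centers = hex_tile_centers(spec.side)
        for col in range(7):
            sub = circ.cells[circ.cells["column"] == col]
            assert points_in_hexagon(
                sub[["x", "z"]].to_numpy(), spec.side, center=centers[col]
            ).all()
            assert ((sub["y"] >= 0) & (sub["y"] <= spec.height)).all()

    def test_deterministic(self):
        spec = mc.ColumnSpec(side=80, height=100, n_pc=20, n_in=5)
        a = mc.build_circuit(spec, seed=3).cells
        b = mc.build_circuit(spec, seed=3).cells
        assert a.equals(b)

    def test_placement_uniformity_chi_square(self):
        spec = mc.ColumnSpec(side=200, height=400, n_pc=10000, n_in=0, n_columns=1)
        circ = mc.build_circuit(spec, seed=7)
        cells = circ.cells
        # octants by sign of (x, z) around apothem axes and height halves
        octant = (
            (cells["x"] > 0).astype(int)
            + 2 * (cells["z"] > 0).astype(int)
            + 4 * (cells["y"] > spec.height / 2).astype(int)
        )
        observed = np.bincount(octant, minlength=8)
        chi2, p = stats.chisquare(observed)
        assert p > 0.01

    def test_empirical_density_matches_spec(self):
        spec = mc.ColumnSpec(side=150, height=300, n_pc=4000, n_in=1000, n_columns=1)
        circ = mc.build_circuit(spec, seed=2)
        density = circ.n_cells / spec.column_volume_mm3
        assert density == pytest.approx(5000 / spec.column_volume_mm3, rel=1e-12)


class TestAssignMorphologies:
    def test_zero_jitter_no_rotation_is_exact_clone(self):
        pool = [simple_neuron([chain_tree(neurite_type="basal"), chain_tree(neurite_type="axon", direction=(1, 0, 0))], cell_class="PC")]
        spec = mc.ColumnSpec(side=100, height=100, n_pc=3, n_in=0, n_columns=1)
        circ = mc.assign_morphologies(mc.build_circuit(spec, seed=1), pool, jitter_sd=0.0, rotate=False)
        cid = circ.central_column_ids[0]
        clone = circ.morphology_of(cid)
        pos = circ.cells.loc[cid, ["x", "y", "z"]].to_numpy(dtype=float)
        assert np.allclose(clone.neurites[0].points, pool[0].neurites[0].points + pos)

    def test_clone_morphometrics_close_at_small_jitter(self, human_pc_pop):
        spec = mc.ColumnSpec(side=100, height=100, n_pc=4, n_in=0, n_columns=1)
        circ = mc.assign_morphologies(
            mc.build_circuit(spec, seed=2), human_pc_pop, jitter_sd=1.0, seed=2
        )
        for cid in circ.central_column_ids:
            clone = circ.morphology_of(cid)
            donor = circ.pools["PC"][int(circ.cells.loc[cid, "pool_index"])]
            # independent per-node jitter inflates each segment length by
            # ~3*sigma^2/(2*L): about 3% for sigma=1 um on 10-um segments
            assert clone.total_dendritic_length == pytest.approx(
                donor.total_dendritic_length, rel=0.04
            )

    def test_deterministic_assignment(self, human_pc_pop):
        spec = mc.ColumnSpec(side=100, height=100, n_pc=5, n_in=0, n_columns=1)
        a = mc.assign_morphologies(mc.build_circuit(spec, seed=4), human_pc_pop, seed=9)
        b = mc.assign_morphologies(mc.build_circuit(spec, seed=4), human_pc_pop, seed=9)
        assert a.cells.equals(b.cells)
        cid = a.central_column_ids[0]
        assert np.allclose(a.morphology_of(cid).neurites[0].points, b.morphology_of(cid).neurites[0].points)

    def test_missing_class_raises(self, human_pc_pop):
        spec = mc.ColumnSpec(side=100, height=100, n_pc=2, n_in=2, n_columns=1)
        with pytest.raises(ValueError, match="IN"):
            mc.assign_morphologies(mc.build_circuit(spec, seed=1), human_pc_pop)


class TestSegmentDistances:
    def test_crossing_perpendicular(self):
        d = segment_distances([(-5, 0, 0)], [(5, 0, 0)], [(0, -5, 1)], [(0, 5, 1)])
        assert d[0] == pytest.approx(1.0)

    def test_parallel_offset(self):
        d = segment_distances([(0, 0, 0)], [(10, 0, 0)], [(0, 3, 0)], [(10, 3, 0)])
        assert d[0] == pytest.approx(3.0)

    def test_endpoint_to_endpoint(self):
        d = segment_distances([(0, 0, 0)], [(1, 0, 0)], [(3, 0, 0)], [(4, 0, 0)])
        assert d[0] == pytest.approx(2.0)

    def test_degenerate_points(self):
        d = segment_distances([(0, 0, 0)], [(0, 0, 0)], [(0, 0, 5)], [(0, 0, 5)])
        assert d[0] == pytest.approx(5.0)

    def test_matches_dense_sampling_oracle(self):
        rng = np.random.default_rng(0)
        p1, q1, p2, q2 = (rng.uniform(-10, 10, size=(50, 3)) for _ in range(4))
        fast = segment_distances(p1, q1, p2, q2)
        ts = np.linspace(0, 1, 201)
        for i in range(50):
            a = p1[i] + np.outer(ts, q1[i] - p1[i])
            b = p2[i] + np.outer(ts, q2[i] - p2[i])
            brute = np.linalg.norm(a[:, None] - b[None, :], axis=2).min()
            assert fast[i] <= brute + 1e-9
            assert fast[i] == pytest.approx(brute, abs=0.05)


def _two_cell_circuit(axon_offset):
    """Cell 0: horizontal axon; cell 1: vertical dendrite at given offset."""
    ax = NeuriteTree(
        np.array([-1, 0]), np.array([[0.0, 0.0, 0.0], [40.0, 0.0, 0.0]]), np.full(2, 0.5), "axon"
    )
    de = NeuriteTree(
        np.array([-1, 0]), np.array([[0.0, -20.0, 0.0], [0.0, 20.0, 0.0]]), np.full(2, 0.5), "basal"
    )
    m0 = NeuronMorphology(np.zeros(3), 1.0, [ax], NeuronMeta(cell_class="PC"))
    m1 = NeuronMorphology(np.zeros(3), 1.0, [de], NeuronMeta(cell_class="PC"))
    import pandas as pd

    cells = pd.DataFrame(
        {
            "x": [0.0, 20.0],
            "y": [0.0, 0.0],
            "z": [0.0, axon_offset],
            "cell_class": ["PC", "PC"],
            "column": [0, 0],
            "pool_index": [0, 1],
            "angle": [0.0, 0.0],
        }
    )
    cells.index.name = "cell_id"
    spec = mc.ColumnSpec(side=100, height=100, n_pc=2, n_in=0, n_columns=1)
    return mc.Circuit(cells, spec, seed=0, pools={"PC": [m0, m1]}, jitter_sd=0.0)


class TestAppositions:
    @pytest.mark.parametrize("offset,expected", [(1.0, 1), (3.0, 0)])
    def test_two_micron_threshold(self, offset, expected):
        conn = mc.compute_appositions(_two_cell_circuit(offset), threshold=2.0)
        assert conn.n_edges == expected
        if expected:
            assert conn.edge_list().iloc[0].to_dict() == {"src": 0, "dst": 1, "appositions": 1}

    def test_index_equals_brute_force(self):
        pool = mc.generate_population(tiny_preset(), 8, seed=21)
        spec = mc.ColumnSpec(side=80, height=150, n_pc=10, n_in=4, n_columns=1)
        circ = mc.assign_morphologies(mc.build_circuit(spec, seed=13), pool, jitter_sd=1.0, seed=13)
        a = mc.compute_appositions(circ, method="index").edge_list()
        b = mc.compute_appositions(circ, method="brute").edge_list()
        assert a.equals(b)

    def test_edges_depend_only_on_axon_and_target_dendrites(self):
        circ = _two_cell_circuit(1.0)
        conn_full = mc.compute_appositions(circ)
        # remove the axon of the *target* cell: edges unchanged
        pools = dict(circ.pools)
        m1 = pools["PC"][1]
        pools["PC"] = [pools["PC"][0], NeuronMorphology(m1.soma_center, 1.0, m1.trees(("basal", "apical")), m1.meta)]
        circ2 = mc.Circuit(circ.cells, circ.spec, 0, pools, 0.0)
        assert mc.compute_appositions(circ2).edge_list().equals(conn_full.edge_list())

    def test_no_axons_raises(self):
        circ = _two_cell_circuit(1.0)
        pools = {"PC": [mc.NeuronMorphology(m.soma_center, 1.0, m.trees(("basal",)), m.meta) for m in circ.pools["PC"]]}
        circ2 = mc.Circuit(circ.cells, circ.spec, 0, pools, 0.0)
        with pytest.raises(ValueError, match="no axons"):
            mc.compute_appositions(circ2)


@pytest.fixture(scope="module")
def dense_circuit():
    spec = mc.ColumnSpec(side=300, height=500, n_pc=2000, n_in=0)
    return mc.build_circuit(spec, seed=5)


class TestNeighborCounts:

    def test_zero_radius(self, dense_circuit):
        out = mc.neighbor_counts(dense_circuit, [0.0])
        assert out["mean_count"].iloc[0] == 0.0

    def test_matches_closed_form_at_mid_radius(self, dense_circuit):
        spec = dense_circuit.spec
        density = 2000 / spec.column_volume_mm3
        out = mc.neighbor_counts(dense_circuit, [100.0])
        expected = mc.expected_neighbor_count(density, 100.0, layer_thickness=spec.height)
        assert out["mean_count"].iloc[0] == pytest.approx(expected, rel=0.10)

    def test_mouse_denser_than_human(self):
        reg = mc.load_species_registry()
        h = mc.desk_scale_spec(reg["human"], scale=0.01)
        m = mc.desk_scale_spec(reg["mouse"], scale=0.01)
        ch = mc.build_circuit(h, seed=1)
        cm = mc.build_circuit(m, seed=1)
        rh = mc.neighbor_counts(ch, [50.0])["mean_count"].iloc[0]
        rm = mc.neighbor_counts(cm, [50.0])["mean_count"].iloc[0]
        assert rm > rh


class TestHybrid:
    def test_hybrid_pool_lengths_and_axons(self, human_pc_pop, mouse_pc_pop):
        pool = mc.make_hybrid_pool(mouse_pc_pop, human_pc_pop)
        target = np.mean([h.total_dendritic_length for h in human_pc_pop])
        for hy in pool:
            assert hy.total_dendritic_length == pytest.approx(target, rel=0.01)
            assert hy.meta.species == "hybrid"
        # axon branch counts come from the human pool
        human_axon_counts = {h.branch_count("axon") for h in human_pc_pop}
        assert {hy.branch_count("axon") for hy in pool} <= human_axon_counts

    def test_hybrid_circuit_counts_follow_human_spec(self, human_pc_pop, mouse_pc_pop):
        spec = mc.ColumnSpec(side=60, height=100, n_pc=5, n_in=0, n_columns=1)
        circ = mc.build_hybrid_circuit(spec, mouse_pc_pop, human_pc_pop, seed=3)
        assert (circ.cells["cell_class"] == "PC").sum() == 5
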