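"""Build a small hexagonal-column circuit and compute apposition connectivity.

Places somata uniformly in a 7-column hexagonal tiling, clones synthetic
morphologies onto them, detects axo-dendritic appositions (2 um threshold)
among central-column cells, and prunes the connectome to 4% density.
"""
import microcortex as mc

registry = mc.load_species_registry()
# 1/200 desk scale: ~75 cells in the central human column
spec = mc.desk_scale_spec(registry["human"], scale=0.005)
print(f"column: side {spec.side:.0f} um, height {spec.height:.0f} um, "
      f"{spec.n_pc} PC + {spec.n_in} IN per column")

pool = mc.generate_population(mc.human_like(), 12, seed=3)
circuit = mc.assign_morphologies(mc.build_circuit(spec, seed=3), pool, jitter_sd=1.0)
conn = mc.compute_appositions(circuit, threshold=2.0)
print(f"appositions: {conn.n_edges} directed edges among {conn.n_cells} cells "
      f"(density {conn.density:.3f})")

pruned = mc.prune_to_density(conn, target_density=0.04, seed=3)
print(f"pruned to 4%: {pruned.n_edges} edges")
degs = mc.in_degree_distribution(pruned)
print(f"in-degree mean {degs.mean():.1f}, max {degs.max()}")
# The raw apposition graph vastly overestimates connectivity (appositions are
# potential synapses); random pruning to ~4% emulates realistic density.
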