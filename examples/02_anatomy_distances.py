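"""Nearest-neighbor distances and neuropil densities from printed anatomy.

Uses only the registered species parameters (densities, fractions, synapse
statistics) to derive inter-neuron distances (closed form + simulation) and
dendritic cable length per tissue volume.
"""
import microcortex as mc

registry = mc.load_species_registry()
for name, sp in registry.items():
    box = (1000.0, 1000.0, sp.layer_thickness)
    sim_all, _ = mc.nn_distance_simulated(sp.neuron_density, box, n_instances=20, seed=0)
    print(f"{name}:")
    print(
        f"  nearest neighbor (all neurons): formula "
        f"{mc.nn_distance_formula(sp.neuron_density):5.1f} um, simulated {sim_all:5.1f} um"
    )
    print(f"  nearest neighbor (PC only):     formula {mc.nn_distance_formula(sp.pc_density):5.1f} um")
    print(f"  nearest neighbor (IN only):     formula {mc.nn_distance_formula(sp.in_density):5.1f} um")
    dend = mc.dendrite_length_density(sp.synapse_volume_density, sp.synapse_linear_density)
    print(f"  dendritic cable per volume:     {dend / 1e6:7.0f} m/mm^3")
# Human neurons sit nearly twice as far apart as mouse neurons, yet the two
# species pack almost the same total dendritic cable into a cubic millimeter.
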