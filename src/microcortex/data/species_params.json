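{
  "version": "1.0",
  "notes": "Layer 2/3 temporal cortex parameters. Units: densities per mm^3, linear densities per um, thickness um.",
  "human": {
    "neuron_density": 25700,
    "neuron_density_provenance": "temporal cortex L2/3 neuron density, ~25,700/mm^3 (DeFelipe et al. stereology)",
    "excitatory_fraction": 0.70,
    "excitatory_fraction_provenance": "70% excitatory / 30% interneurons in human temporal cortex",
    "interneuron_fraction": 0.30,
    "layer_thickness": 1070,
    "layer_thickness_provenance": "combined layer 2/3 thickness, um",
    "synapse_volume_density": 1.18e9,
    "synapse_volume_density_provenance": "11.8e8 synapses/mm^3",
    "synapse_linear_density": 0.88,
    "synapse_linear_density_provenance": "synapses per um of dendrite",
    "bouton_density": null,
    "bouton_density_provenance": "experimental data inconclusive; no value asserted",
    "synapses_per_neuron": 15000,
    "synapses_per_neuron_provenance": "total synapses per pyramidal neuron",
    "synapses_per_connection": 4,
    "synapses_per_connection_provenance": "mean synapses per connection",
    "column_side": 476,
    "column_pc_count": 10500,
    "column_in_count": 4500,
    "column_counts_provenance": "methods values; results text reports 10621 PC / 4503 IN for the realized circuit"
  },
  "mouse": {
    "neuron_density": 137600,
    "neuron_density_provenance": "temporal cortex L2/3 neuron density, ~137,600/mm^3",
    "excitatory_fraction": 0.85,
    "excitatory_fraction_provenance": "methods value 85%; results text implies 88% (12% interneurons)",
    "excitatory_fraction_alternate": 0.88,
    "interneuron_fraction": 0.12,
    "interneuron_fraction_provenance": "12% interneurons printed in results; inconsistent with the 85% methods value",
    "layer_thickness": 235,
    "layer_thickness_provenance": "combined layer 2/3 thickness, um",
    "synapse_volume_density": 2.656e9,
    "synapse_volume_density_provenance": "26.56e8 synapses/mm^3",
    "synapse_linear_density": 2.15,
    "synapse_linear_density_provenance": "synapses per um of dendrite",
    "bouton_density": null,
    "bouton_density_provenance": "experimental data inconclusive; no value asserted",
    "synapses_per_neuron": 12000,
    "synapses_per_neuron_provenance": "total synapses per pyramidal neuron",
    "synapses_per_connection": 3.2,
    "synapses_per_connection_provenance": "mean synapses per connection",
    "column_side": 476,
    "column_pc_count": 15200,
    "column_in_count": 2700,
    "column_counts_provenance": "methods values; results text reports 14377 PC / 2724 IN for the realized circuit"
  }
}
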