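"""Topological morphology descriptor on synthetic pyramidal cells.

Generates small human-like and mouse-like populations, extracts persistence
barcodes of their dendrites, and compares bar counts, entropies and the
perisomatic (200-500 um) branch density band in which human dendrites are
distinctively enriched.
"""
import numpy as np

import microcortex as mc

human = mc.generate_population(mc.human_like(), 10, seed=1, cell_class="PC")
mouse = mc.generate_population(mc.mouse_like(), 10, seed=2, cell_class="PC")

for name, pop in [("human-like", human), ("mouse-like", mouse)]:
    pbs = [mc.extract_morphology_barcode(m, filtration="path") for m in pop]
    bars = np.mean([pb.n_bars for pb in pbs])
    ent = np.mean([mc.barcode_entropy(pb) for pb in pbs])
    prof = mc.complexity_profile(pbs, np.arange(0, 801, 100))
    band = prof[(prof.bin_left >= 200) & (prof.bin_right <= 500)]["mean_bars_alive"].mean()
    print(
        f"{name:11s}  dendritic bars/cell {bars:5.1f}   entropy {ent:.2f}   "
        f"bars alive in 200-500 um band {band:5.1f}"
    )

# Entropy is scale-invariant: doubling a neuron changes nothing.
pb = mc.extract_morphology_barcode(human[0], filtration="path")
print(
    "entropy original vs doubled barcode:",
    round(mc.barcode_entropy(pb), 6),
    round(mc.barcode_entropy(mc.scale_barcode(pb, 2.0)), 6),
)
# More bars alive in the perisomatic band for the human-like population is
# the generator's realization of the species-specific topological signature.
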