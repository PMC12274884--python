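"""Anatomy-derived spatial statistics from species parameters.

Closed-form and simulated nearest-neighbor distances for homogeneously
distributed neurons, neuropil cable-length densities derived from synapse
counts, and expected neighbor counts around a central neuron.

Unit convention at the interface: lengths in μm, volumes in mm³ (densities
per mm³), matching how the source quantities are printed; conversions to μm³
happen internally.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

MM3_TO_UM3 = 1e9


@dataclass
class SpeciesParams:
    """Anatomical parameters of one species (layer 2/3)."""

    name: str
    neuron_density: float  # count / mm^3
    excitatory_fraction: float
    layer_thickness: float  # um
    synapse_volume_density: float  # count / mm^3
    synapse_linear_density: float  # count / um of dendrite
    synapses_per_neuron: float
    synapses_per_connection: float
    bouton_density: float | None = None  # count / um of axon, if known
    interneuron_fraction: float | None = None  # printed separately; may not equal 1 - excitatory_fraction
    column_side: float = 476.0  # um
    column_pc_count: int = 0
    column_in_count: int = 0

    def __post_init__(self):
        if not 0 <= self.excitatory_fraction <= 1:
            raise ValueError("excitatory_fraction must lie in [0, 1]")
        for attr in (
            "neuron_density",
            "layer_thickness",
            "synapse_volume_density",
            "synapse_linear_density",
            "synapses_per_neuron",
            "synapses_per_connection",
        ):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")

    @property
    def pc_density(self) -> float:
        return self.excitatory_fraction * self.neuron_density

    @property
    def in_density(self) -> float:
        frac = (
            self.interneuron_fraction
            if self.interneuron_fraction is not None
            else 1.0 - self.excitatory_fraction
        )
        return frac * self.neuron_density


def load_species_registry() -> dict:
    """Species registry shipped with the package (versioned JSON, with a
    provenance string per field)."""
    raw = json.loads(
        resources.files("microcortex.data").joinpath("species_params.json").read_text()
    )
    out = {}
    for name in ("human", "mouse"):
        d = raw[name]
        out[name] = SpeciesParams(
            name=name,
            neuron_density=d["neuron_density"],
            excitatory_fraction=d["excitatory_fraction"],
            layer_thickness=d["layer_thickness"],
            synapse_volume_density=d["synapse_volume_density"],
            synapse_linear_density=d["synapse_linear_density"],
            synapses_per_neuron=d["synapses_per_neuron"],
            synapses_per_connection=d["synapses_per_connection"],
            bouton_density=d.get("bouton_density"),
            interneuron_fraction=d.get("interneuron_fraction"),
            column_side=d.get("column_side", 476.0),
            column_pc_count=d.get("column_pc_count", 0),
            column_in_count=d.get("column_in_count", 0),
        )
    return out


# ---------------------------------------------------------------------------
# Nearest-neighbor distances


def nn_distance_formula(density: float, units: str = "mm3") -> float:
    """Mean nearest-neighbor distance <R_v> = 0.554 · N_v^(-1/3) (μm) for a
    uniform point process of the given density (per mm³ by default)."""
    if density <= 0:
        raise ValueError("density must be positive")
    if units == "mm3":
        nv = density / MM3_TO_UM3
    elif units == "um3":
        nv = density
    else:
        raise ValueError(f"unknown units {units!r}")
    return 0.554 * nv ** (-1.0 / 3.0)


def nn_distance_simulated(
    density: float,
    box: tuple,
    n_instances: int = 100,
    seed: int = 0,
    units: str = "mm3",
) -> tuple[float, float]:
    """Simulated mean nearest-neighbor distance in a box (μm dimensions).

    Generates ``n_instances`` uniform point processes at the given density,
    computes each point's distance to its nearest neighbor within the same
    instance, averages per instance, and returns (mean, sd) over instances.
    No edge correction is applied, so boundary effects are included (they
    bias the mean slightly upward relative to the unbounded closed form).
    """
    box = np.asarray(box, dtype=np.float64)
    if units == "mm3":
        density_um = density / MM3_TO_UM3
    elif units == "um3":
        density_um = density
    else:
        raise ValueError(f"unknown units {units!r}")
    volume = float(np.prod(box))
    n_points = int(round(density_um * volume))
    if n_points < 2:
        raise ValueError(
            f"box too small: expected {n_points} points, need at least 2"
        )
    rng = np.random.default_rng(seed)
    means = np.empty(n_instances)
    for k in range(n_instances):
        pts = rng.random((n_points, 3)) * box
        tree = cKDTree(pts)
        dists, _ = tree.query(pts, k=2)
        means[k] = dists[:, 1].mean()
    return float(means.mean()), float(means.std())


# ---------------------------------------------------------------------------
# Neuropil length densities


def dendrite_length_density(synapse_volume_density: float, synapse_linear_density: float) -> float:
    """Dendritic cable length per tissue volume (μm/mm³): S_v / d_syn."""
    if synapse_linear_density <= 0:
        raise ValueError("synapse_linear_density must be positive")
    if synapse_volume_density < 0:
        raise ValueError("synapse_volume_density must be non-negative")
    return synapse_volume_density / synapse_linear_density


def axon_length_density(
    synapse_volume_density: float, bouton_density: float, synapses_per_bouton: float
) -> float:
    """Axonal cable length per tissue volume (μm/mm³):
    S_v / (d_bouton · n_syn_per_bouton).

    Provided as a formula only; the experimental data on synapses per bouton
    are inconclusive, so no species value is asserted anywhere in the
    registry."""
    if bouton_density <= 0 or synapses_per_bouton <= 0:
        raise ValueError("bouton_density and synapses_per_bouton must be positive")
    return synapse_volume_density / (bouton_density * synapses_per_bouton)


# ---------------------------------------------------------------------------
# Neighbor counts


def expected_neighbor_count(
    density: float, radius: float, layer_thickness: float | None = None
) -> float:
    """Expected number of neurons within ``radius`` μm of a central neuron.

    Unbounded medium: (4/3)·π·r³·ρ. With ``layer_thickness`` given, the
    central neuron is taken at mid-layer and the sphere is clipped to the
    slab (spherical caps outside the layer removed)."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    rho = density / MM3_TO_UM3
    r = radius
    if layer_thickness is None:
        volume = 4.0 / 3.0 * np.pi * r**3
    else:
        h = layer_thickness / 2.0  # distance from mid-layer to each face
        if r <= h:
            volume = 4.0 / 3.0 * np.pi * r**3
        else:
            cap = np.pi * (r - h) ** 2 * (2 * r + h) / 3.0  # spherical cap beyond a face
            volume = 4.0 / 3.0 * np.pi * r**3 - 2.0 * cap
    return float(volume * rho)


def species_summary_table() -> "pd.DataFrame":
    """Derived anatomy table for both species: nearest-neighbor distances
    (all/PC/IN, closed form) and dendritic length density."""
    import pandas as pd

    registry = load_species_registry()
    rows = []
    for name, sp in registry.items():
        rows.append(
            {
                "species": name,
                "nn_all_um": nn_distance_formula(sp.neuron_density),
                "nn_pc_um": nn_distance_formula(sp.pc_density),
                "nn_in_um": nn_distance_formula(sp.in_density),
                "dendrite_length_m_per_mm3": dendrite_length_density(
                    sp.synapse_volume_density, sp.synapse_linear_density
                )
                / 1e6,
            }
        )
    return pd.DataFrame(rows)
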