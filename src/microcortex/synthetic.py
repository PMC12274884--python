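"""Seeded synthetic neuron populations with species-specific topology.

The generator inverts the topological description of dendrites: species
presets specify Gaussian-kernel mixtures over persistence-diagram points
(birth, death) together with bar-count statistics; barcodes sampled from a
preset are then realized as 3D trees whose path-distance barcode reproduces
the sampled barcode exactly. This makes every downstream stage (morphometrics,
topology, circuits, networks, capacity) testable without any reconstruction
downloads.

The default presets encode the printed species statistics: human layer-2/3
pyramidal cells have more dendritic branches (apical 54±21 vs mouse 36±11;
basal 61±34 vs 46±19), larger extents (692±272 μm vs 349±96 μm), longer
total dendritic cable (≈11,600 μm vs ≈5,500 μm), and — the signature
feature — an elevated perisomatic branch density at 200–500 μm realized by a
dedicated mixture center absent from the mouse preset.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .morphology import NeuriteTree, NeuronMorphology, NeuronMeta, write_swc, read_swc
from .topology import DiagramMixture, PersistenceBarcode


class UnrealizableBarcodeError(ValueError):
    """Raised when no tree can realize a barcode (a bar's birth lies outside
    the span of every longer-lived bar)."""


@dataclass
class NeuriteSpec:
    """Sampling recipe for one neurite type of one cell class."""

    mixture: DiagramMixture
    bar_count_mean: float
    bar_count_sd: float
    n_trees: int = 1
    min_bars: int = 2


@dataclass
class Geometry:
    segment_length: float = 10.0  # μm
    direction_persistence: float = 0.85  # 0 = random walk, 1 = straight
    branch_angle_spread: float = 0.7  # rad


@dataclass
class DiameterModel:
    initial: float = 1.0  # μm at the soma
    taper: float = 0.7  # fractional drop over the tree extent
    minimum: float = 0.2  # μm floor


@dataclass
class SpeciesPreset:
    name: str
    pc: dict  # neurite type -> NeuriteSpec, keys: apical, basal, axon
    interneuron: dict  # keys: basal, axon
    pc_fraction: float = 0.7
    soma_radius: float = 8.0
    geometry: Geometry = field(default_factory=Geometry)
    diameters: DiameterModel = field(default_factory=DiameterModel)

    def specs_for(self, cell_class: str) -> dict:
        if cell_class == "PC":
            return self.pc
        if cell_class == "IN":
            return self.interneuron
        raise ValueError(f"unknown cell class {cell_class!r}")


def _diag_mixture(means, sigmas, weights) -> DiagramMixture:
    covs = [np.diag([sx**2, sy**2]) for sx, sy in sigmas]
    return DiagramMixture(np.asarray(weights, float), np.asarray(means, float), covs)


def human_like() -> SpeciesPreset:
    """Human-like preset: more branches, larger extent, and a dedicated
    perisomatic mixture center at (≈300, ≈480) μm producing the elevated
    branch density in the 200–500 μm band."""
    apical = NeuriteSpec(
        mixture=_diag_mixture(
            means=[(35, 105), (300, 470), (120, 620)],
            sigmas=[(20, 28), (45, 55), (50, 70)],
            weights=[0.58, 0.35, 0.07],
        ),
        bar_count_mean=54,
        bar_count_sd=21,
        min_bars=8,
    )
    basal = NeuriteSpec(
        mixture=_diag_mixture(
            means=[(25, 90), (230, 380), (60, 330)],
            sigmas=[(15, 24), (42, 50), (40, 55)],
            weights=[0.62, 0.30, 0.08],
        ),
        bar_count_mean=12.2,
        bar_count_sd=5,
        n_trees=5,
        min_bars=3,
    )
    axon = NeuriteSpec(
        mixture=_diag_mixture(
            means=[(50, 200), (130, 400)],
            sigmas=[(35, 55), (65, 80)],
            weights=[0.60, 0.40],
        ),
        bar_count_mean=28,
        bar_count_sd=6,
        min_bars=11,
    )
    in_basal = NeuriteSpec(
        mixture=_diag_mixture(
            means=[(15, 95), (60, 200)],
            sigmas=[(12, 26), (30, 45)],
            weights=[0.7, 0.3],
        ),
        bar_count_mean=8,
        bar_count_sd=3,
        n_trees=6,
        min_bars=2,
    )
    return SpeciesPreset(
        name="human_like",
        pc={"apical": apical, "basal": basal, "axon": axon},
        interneuron={"basal": in_basal, "axon": axon},
        pc_fraction=0.70,
        soma_radius=8.0,
    )


def mouse_like() -> SpeciesPreset:
    """Mouse-like preset: fewer branches, smaller extent, no perisomatic
    200–500 μm center."""
    apical = NeuriteSpec(
        mixture=_diag_mixture(
            means=[(30, 85), (100, 180), (60, 310)],
            sigmas=[(18, 22), (32, 40), (30, 40)],
            weights=[0.70, 0.28, 0.02],
        ),
        bar_count_mean=36,
        bar_count_sd=11,
        min_bars=6,
    )
    basal = NeuriteSpec(
        mixture=_diag_mixture(
            means=[(20, 70), (80, 150), (40, 240)],
            sigmas=[(13, 18), (30, 36), (28, 38)],
            weights=[0.72, 0.26, 0.02],
        ),
        bar_count_mean=9.2,
        bar_count_sd=4,
        n_trees=5,
        min_bars=2,
    )
    axon = NeuriteSpec(
        mixture=_diag_mixture(
            means=[(40, 150), (90, 260)],
            sigmas=[(25, 40), (45, 55)],
            weights=[0.60, 0.40],
        ),
        bar_count_mean=30,
        bar_count_sd=6,
        min_bars=11,
    )
    in_basal = NeuriteSpec(
        mixture=_diag_mixture(
            means=[(15, 80), (50, 160)],
            sigmas=[(12, 22), (25, 38)],
            weights=[0.7, 0.3],
        ),
        bar_count_mean=7,
        bar_count_sd=3,
        n_trees=6,
        min_bars=2,
    )
    return SpeciesPreset(
        name="mouse_like",
        pc={"apical": apical, "basal": basal, "axon": axon},
        interneuron={"basal": in_basal, "axon": axon},
        pc_fraction=0.85,
        soma_radius=6.0,
    )


PRESETS = {"human_like": human_like, "mouse_like": mouse_like}


# ---------------------------------------------------------------------------
# Barcode sampling


def sample_barcode(
    spec: NeuriteSpec,
    rng: np.random.Generator,
    n_bars: int | None = None,
    max_attempts: int = 1000,
) -> PersistenceBarcode:
    """Draw a realizable barcode from a neurite spec.

    The bar count follows a truncated normal; (birth, death) points are drawn
    from the diagram mixture with rejection of draws violating t > b >= 0.
    One essential bar is forced with birth 0 and death 5% beyond the largest
    sampled death, so it strictly dominates every other bar.
    """
    if n_bars is None:
        n_bars = max(spec.min_bars, int(round(rng.normal(spec.bar_count_mean, spec.bar_count_sd))))
    pts = []
    for _ in range(n_bars - 1):
        for attempt in range(max_attempts):
            b, t = spec.mixture.sample(1, rng)[0]
            if t > b >= 0:
                pts.append((b, t))
                break
        else:
            raise RuntimeError(
                f"rejection sampling failed after {max_attempts} attempts for "
                f"mixture with means {spec.mixture.means.tolist()}"
            )
    max_death = max((t for _, t in pts), default=spec.mixture.means[:, 1].max())
    bars = np.array([(0.0, 1.05 * max_death)] + pts)
    return PersistenceBarcode(bars, filtration="path")


# ---------------------------------------------------------------------------
# Tree synthesis


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _perturbed_direction(
    direction: np.ndarray, spread: float, rng: np.random.Generator
) -> np.ndarray:
    v = direction + spread * rng.normal(size=3)
    n = np.linalg.norm(v)
    return v / n if n > 0 else direction


def synthesize_tree(
    pb: PersistenceBarcode,
    geometry: Geometry | None = None,
    rng: np.random.Generator | None = None,
    neurite_type: str = "basal",
    initial_direction: np.ndarray | None = None,
    diameters: DiameterModel | None = None,
) -> NeuriteTree:
    """Realize a barcode as a 3D tree whose path-distance barcode equals it.

    Bars are placed longest-death first; every bar attaches at path distance
    ``birth`` on a previously placed bar whose span contains it (uniformly
    chosen among the eligible parents). Because the attaching bar always dies
    strictly before its parent, the elder rule reproduces exactly the input
    bars. Branch geometry is a direction-persistent random walk; path
    distances are exact sums of step lengths.
    """
    geometry = geometry or Geometry()
    rng = rng if rng is not None else np.random.default_rng()
    diameters = diameters or DiameterModel()
    bars = pb.bars
    if pb.has_invalid_bars:
        raise UnrealizableBarcodeError("barcode contains bars with t < b")
    order = np.argsort(-bars[:, 1], kind="stable")
    bars = bars[order]
    n_bars = len(bars)
    parents = np.full(n_bars, -1, dtype=int)
    for i in range(1, n_bars):
        b_i, t_i = bars[i]
        eligible = [
            j
            for j in range(i)
            if bars[j, 0] <= b_i < bars[j, 1] and bars[j, 1] > t_i
        ]
        if not eligible:
            raise UnrealizableBarcodeError(
                f"bar (b={b_i:.3f}, t={t_i:.3f}) has no bar to branch from"
            )
        parents[i] = eligible[int(rng.integers(len(eligible)))]
    children: list[list[int]] = [[] for _ in range(n_bars)]
    for i in range(1, n_bars):
        children[parents[i]].append(i)

    extent = max(bars[:, 1].max(), 1e-9)
    parent_idx: list[int] = []
    points: list[np.ndarray] = []
    diams: list[float] = []

    def diameter_at(dist: float) -> float:
        return max(diameters.minimum, diameters.initial * (1 - diameters.taper * dist / extent))

    def build_chain(bar: int, attach_node: int, start_dist: float, direction):
        """Grow bar's chain from path distance start_dist to its death."""
        b, t = bars[bar]
        stops = sorted(set([bars[c][0] for c in children[bar]] + [t]))
        stops = [s for s in stops if s > start_dist + 1e-12]
        node = attach_node
        dist = start_dist
        pending = {c: bars[c][0] for c in children[bar]}
        # children born at (or numerically before) the attachment point
        for c, bc in list(pending.items()):
            if bc <= start_dist + 1e-12:
                del pending[c]
                child_dir = _perturbed_direction(direction, geometry.branch_angle_spread, rng)
                build_chain(c, node, dist, child_dir)
        for stop in stops:
            span = stop - dist
            n_steps = max(1, int(np.ceil(span / geometry.segment_length)))
            step = span / n_steps
            for _ in range(n_steps):
                direction = _perturbed_direction(
                    direction, (1 - geometry.direction_persistence) * 0.5, rng
                )
                new_pt = points[node] + step * direction
                points.append(new_pt)
                parent_idx.append(node)
                dist += step
                diams.append(diameter_at(dist))
                node = len(points) - 1
            dist = stop  # exact, avoids step-accumulation drift
            for c, bc in list(pending.items()):
                if abs(bc - stop) <= 1e-12:
                    del pending[c]
                    child_dir = _perturbed_direction(
                        direction, geometry.branch_angle_spread, rng
                    )
                    build_chain(c, node, dist, child_dir)

    root_dir = (
        np.asarray(initial_direction, float)
        if initial_direction is not None
        else _random_unit(rng)
    )
    root_dir = root_dir / np.linalg.norm(root_dir)
    points.append(np.zeros(3))
    parent_idx.append(-1)
    diams.append(diameter_at(bars[0, 0]))
    build_chain(0, 0, bars[0, 0], root_dir)
    return NeuriteTree(np.array(parent_idx), np.vstack(points), np.array(diams), neurite_type)


# ---------------------------------------------------------------------------
# Population generation


_BASAL_DIRECTIONS = np.array(
    [
        [0.8, -0.5, 0.0],
        [-0.8, -0.5, 0.0],
        [0.0, -0.5, 0.8],
        [0.0, -0.5, -0.8],
        [0.6, -0.2, -0.6],
        [-0.6, -0.2, 0.6],
        [0.6, 0.2, 0.6],
        [-0.6, 0.2, -0.6],
    ]
)


def generate_morphology(
    preset: SpeciesPreset, cell_class: str, rng: np.random.Generator, subject_id: str = ""
) -> NeuronMorphology:
    specs = preset.specs_for(cell_class)
    trees = []
    for ntype, spec in specs.items():
        for k in range(spec.n_trees):
            pb = sample_barcode(spec, rng)
            if ntype == "apical":
                direction = np.array([0.0, 1.0, 0.0])
            elif ntype == "axon":
                direction = np.array([0.2, -1.0, 0.1])
            else:
                direction = _BASAL_DIRECTIONS[k % len(_BASAL_DIRECTIONS)] + rng.normal(
                    scale=0.1, size=3
                )
            direction = direction / np.linalg.norm(direction)
            tree = synthesize_tree(
                pb,
                preset.geometry,
                rng,
                neurite_type=ntype,
                initial_direction=direction,
                diameters=preset.diameters,
            )
            trees.append(tree.translated(preset.soma_radius * direction))
    meta = NeuronMeta(
        species=preset.name, cell_class=cell_class, subject_id=subject_id
    )
    return NeuronMorphology(np.zeros(3), preset.soma_radius, trees, meta)


def generate_population(
    preset: SpeciesPreset, n: int, seed: int, cell_class: str | None = None
) -> list:
    """Generate ``n`` seeded morphologies. With ``cell_class=None`` the class
    mix follows ``preset.pc_fraction`` (PCs first, deterministically)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if cell_class is None:
        n_pc = int(round(preset.pc_fraction * n))
        classes = ["PC"] * n_pc + ["IN"] * (n - n_pc)
    else:
        classes = [cell_class] * n
    return [
        generate_morphology(preset, c, rng, subject_id=f"{preset.name}-{i:04d}")
        for i, c in enumerate(classes)
    ]


def save_population(population, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, m in enumerate(population):
        name = f"neuron_{i:04d}.swc"
        write_swc(m, directory / name, with_meta=True)
        manifest.append({"file": name, **m.meta.to_dict()})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_population(directory) -> list:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    return [read_swc(directory / entry["file"]) for entry in manifest]
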