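"""Neuron morphology data model, SWC I/O, curation and morphometrics.

Morphologies are rooted 3D trees (axon / basal / apical dendrites) attached to
a spherical soma. The representation is deliberately minimal: per-tree flat
arrays in topological order (parent precedes child), which makes barcode
extraction, scaling and cloning cheap vectorized operations.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

ROOT_PARENT = -1
NEURITE_TYPES = ("axon", "basal", "apical")
DENDRITE_TYPES = ("basal", "apical")
SWC_CODE_TO_TYPE = {2: "axon", 3: "basal", 4: "apical"}
TYPE_TO_SWC_CODE = {v: k for k, v in SWC_CODE_TO_TYPE.items()}


class SWCFormatError(ValueError):
    """Raised when an SWC file violates the 7-column dialect."""


@dataclass
class NeuriteTree:
    """A single rooted neurite as flat arrays in topological order.

    ``parent[i]`` is the index of node ``i``'s parent within this tree
    (``ROOT_PARENT`` for the unique root). Parents always precede children,
    so prefix scans along ``parent`` are valid.
    """

    parent: np.ndarray
    points: np.ndarray
    diameters: np.ndarray
    neurite_type: str

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.diameters = np.asarray(self.diameters, dtype=np.float64)
        n = len(self.parent)
        if n == 0:
            raise ValueError("empty neurite tree")
        if self.points.shape[0] != n or self.diameters.shape[0] != n:
            raise ValueError("parent/points/diameters length mismatch")
        if self.neurite_type not in NEURITE_TYPES:
            raise ValueError(f"unknown neurite type {self.neurite_type!r}")
        roots = np.flatnonzero(self.parent == ROOT_PARENT)
        if len(roots) != 1 or roots[0] != 0:
            raise ValueError("tree must have exactly one root at index 0")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise ValueError("parent must precede child")
        if np.any(self.diameters < 0):
            raise ValueError("negative diameter")

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def child_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(counts, self.parent[1:], 1)
        return counts

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(1, self.n_nodes):
            out[self.parent[i]].append(i)
        return out

    def leaves(self) -> np.ndarray:
        return np.flatnonzero(self.child_counts() == 0)

    def bifurcations(self) -> np.ndarray:
        return np.flatnonzero(self.child_counts() >= 2)

    @property
    def n_leaves(self) -> int:
        return int(np.sum(self.child_counts() == 0))

    @property
    def n_bifurcations(self) -> int:
        return int(np.sum(self.child_counts() >= 2))

    @property
    def branch_count(self) -> int:
        """Number of branches: maximal paths between consecutive
        bifurcations/terminations, i.e. leaves + bifurcation points."""
        return self.n_leaves + self.n_bifurcations

    def segment_lengths(self) -> np.ndarray:
        """Length of the segment ending at each node (0 at the root)."""
        seg = np.zeros(self.n_nodes)
        seg[1:] = np.linalg.norm(
            self.points[1:] - self.points[self.parent[1:]], axis=1
        )
        return seg

    @property
    def total_length(self) -> float:
        return float(self.segment_lengths().sum())

    def path_distances(self) -> np.ndarray:
        """Path distance from the tree root to each node."""
        seg = self.segment_lengths()
        dist = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            dist[i] = dist[self.parent[i]] + seg[i]
        return dist

    def radial_distances(self, origin: np.ndarray | None = None) -> np.ndarray:
        if origin is None:
            origin = self.points[0]
        return np.linalg.norm(self.points - np.asarray(origin), axis=1)

    def translated(self, offset: np.ndarray) -> "NeuriteTree":
        return replace(self, points=self.points + np.asarray(offset))

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """(start, end) endpoint arrays of all segments."""
        return self.points[self.parent[1:]], self.points[1:]


@dataclass
class NeuronMeta:
    species: str = "synthetic"
    cell_class: str = "PC"
    region: str = ""
    layer: str = ""
    subject_id: str = ""

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronMeta":
        return cls(**{k: d.get(k, "") for k in cls().__dict__})


@dataclass
class NeuronMorphology:
    soma_center: np.ndarray
    soma_radius: float
    neurites: list[NeuriteTree]
    meta: NeuronMeta = field(default_factory=NeuronMeta)

    def __post_init__(self):
        self.soma_center = np.asarray(self.soma_center, dtype=np.float64).reshape(3)
        self.soma_radius = float(self.soma_radius)

    def trees(self, neurite_types=NEURITE_TYPES) -> list[NeuriteTree]:
        if isinstance(neurite_types, str):
            neurite_types = (neurite_types,)
        return [t for t in self.neurites if t.neurite_type in neurite_types]

    def total_length(self, neurite_types=NEURITE_TYPES) -> float:
        return float(sum(t.total_length for t in self.trees(neurite_types)))

    @property
    def total_dendritic_length(self) -> float:
        return self.total_length(DENDRITE_TYPES)

    def branch_count(self, neurite_types=NEURITE_TYPES) -> int:
        return int(sum(t.branch_count for t in self.trees(neurite_types)))


@dataclass
class MorphometricRecord:
    """Per-neurite-type summary features of one morphology."""

    total_length_per_type: dict
    branch_count_per_type: dict
    mean_diameter_per_type: dict
    max_radial_extent: float

    def to_flat_dict(self) -> dict:
        out = {"max_radial_extent": self.max_radial_extent}
        for t in NEURITE_TYPES:
            out[f"total_length_{t}"] = self.total_length_per_type.get(t, 0.0)
            out[f"branch_count_{t}"] = self.branch_count_per_type.get(t, 0)
            out[f"mean_diameter_{t}"] = self.mean_diameter_per_type.get(t, 0.0)
        return out


# ---------------------------------------------------------------------------
# SWC I/O


def read_swc(path) -> NeuronMorphology:
    """Read a 7-column SWC file into a :class:`NeuronMorphology`.

    Soma samples (type 1) are collapsed to a center + radius; both 1-point
    and 3-point soma conventions are accepted. Type codes 2/3/4 map to
    axon/basal/apical. A JSON sidecar ``<path>.json`` supplies metadata when
    present.
    """
    path = Path(path)
    rows: dict[int, tuple] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SWCFormatError(
                    f"{path.name}:{lineno}: expected 7 columns, got {len(fields)}"
                )
            try:
                nid = int(fields[0])
                typ = int(fields[1])
                x, y, z, r = (float(v) for v in fields[2:6])
                pid = int(fields[6])
            except ValueError as exc:
                raise SWCFormatError(f"{path.name}:{lineno}: {exc}") from None
            if nid in rows:
                raise SWCFormatError(f"{path.name}:{lineno}: duplicate node id {nid}")
            rows[nid] = (typ, x, y, z, r, pid)
    if not rows:
        raise SWCFormatError(f"{path.name}: no samples")

    soma_ids = [i for i, r in rows.items() if r[0] == 1]
    soma_roots = [i for i in soma_ids if rows[i][5] == -1 or rows[i][5] not in soma_ids]
    if len(soma_roots) > 1:
        raise SWCFormatError(f"{path.name}: multiple somata ({len(soma_roots)} roots)")
    if soma_ids:
        pts = np.array([rows[i][1:4] for i in soma_ids])
        center = pts.mean(axis=0)
        radius = float(np.mean([rows[i][4] for i in soma_ids]))
    else:
        center, radius = None, 0.0

    # neurite roots: non-soma nodes whose parent is -1 or a soma sample
    neurite_ids = sorted(i for i in rows if rows[i][0] != 1)
    trees = []
    tree_of: dict[int, int] = {}
    for nid in neurite_ids:
        typ, x, y, z, r, pid = rows[nid]
        if pid == -1 or pid in soma_ids:
            trees.append({"nodes": [nid], "type": rows[nid][0]})
            tree_of[nid] = len(trees) - 1
        else:
            if pid not in tree_of:
                raise SWCFormatError(
                    f"{path.name}: node {nid} references undefined parent {pid}"
                )
            k = tree_of[pid]
            trees[k]["nodes"].append(nid)
            tree_of[nid] = k

    neurites = []
    for tr in trees:
        ids = tr["nodes"]
        index = {nid: k for k, nid in enumerate(ids)}
        parent = np.array(
            [ROOT_PARENT if rows[i][5] not in index else index[rows[i][5]] for i in ids]
        )
        pts = np.array([rows[i][1:4] for i in ids])
        diam = np.array([2.0 * rows[i][4] for i in ids])
        ntype = SWC_CODE_TO_TYPE.get(tr["type"])
        if ntype is None:
            raise SWCFormatError(
                f"{path.name}: unsupported neurite type code {tr['type']}"
            )
        neurites.append(NeuriteTree(parent, pts, diam, ntype))
    if center is None:
        center = neurites[0].points[0] if neurites else np.zeros(3)

    meta = NeuronMeta()
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = NeuronMeta.from_dict(json.loads(sidecar.read_text()))
    return NeuronMorphology(center, radius, neurites, meta)


def write_swc(m: NeuronMorphology, path, with_meta: bool = False) -> None:
    """Write to SWC (1-point soma convention, 6-decimal coordinates)."""
    path = Path(path)
    lines = ["# SWC written by microcortex"]
    cx, cy, cz = m.soma_center
    lines.append(f"1 1 {cx:.6f} {cy:.6f} {cz:.6f} {m.soma_radius:.6f} -1")
    next_id = 2
    for tree in m.neurites:
        code = TYPE_TO_SWC_CODE[tree.neurite_type]
        base = next_id
        for k in range(tree.n_nodes):
            x, y, z = tree.points[k]
            r = tree.diameters[k] / 2.0
            pid = 1 if tree.parent[k] == ROOT_PARENT else base + int(tree.parent[k])
            lines.append(f"{base + k} {code} {x:.6f} {y:.6f} {z:.6f} {r:.6f} {pid}")
        next_id = base + tree.n_nodes
    path.write_text("\n".join(lines) + "\n")
    if with_meta:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(m.meta.to_dict(), indent=1))


# ---------------------------------------------------------------------------
# Curation


def _rotation_to_y(u: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u onto +Y (Rodrigues)."""
    y = np.array([0.0, 1.0, 0.0])
    c = float(np.dot(u, y))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:  # antiparallel: rotate pi about X
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(u, y)
    axis /= np.linalg.norm(axis)
    s = np.sqrt(max(0.0, 1.0 - c * c))
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def _fill_zero_diameters(tree: NeuriteTree) -> NeuriteTree:
    d = tree.diameters.copy()
    zero = np.flatnonzero(d <= 0)
    if len(zero) == 0:
        return tree
    kids = tree.children()
    for i in zero:
        # graph neighbors within 2 edges: parent, grandparent, children,
        # grandchildren and siblings
        neigh = set()
        p = tree.parent[i]
        if p != ROOT_PARENT:
            neigh.add(int(p))
            gp = tree.parent[p]
            if gp != ROOT_PARENT:
                neigh.add(int(gp))
            neigh.update(int(s) for s in kids[p] if s != i)
        for c in kids[i]:
            neigh.add(int(c))
            neigh.update(int(g) for g in kids[c])
        vals = [tree.diameters[j] for j in sorted(neigh) if tree.diameters[j] > 0]
        if not vals:
            vals = [v for v in tree.diameters if v > 0]
        d[i] = float(np.mean(vals)) if vals else 0.5
    return replace(tree, diameters=d)


def curate_morphology(m: NeuronMorphology, tol: float = 1e-9) -> NeuronMorphology:
    """Standard curation: reconnect detached neurite roots to the soma
    surface, replace missing (zero) diameters, and rotate pyramidal cells so
    the apical dendrite points toward +Y.

    Idempotent: applying twice equals applying once (up to float tolerance).
    """
    trees = []
    for tree in m.neurites:
        root = tree.points[0]
        offset = root - m.soma_center
        dist = float(np.linalg.norm(offset))
        if dist > m.soma_radius + tol:
            u = offset / dist if dist > 0 else np.array([0.0, 1.0, 0.0])
            target = m.soma_center + m.soma_radius * u
            tree = tree.translated(target - root)
        trees.append(_fill_zero_diameters(tree))
    out = NeuronMorphology(m.soma_center.copy(), m.soma_radius, trees, m.meta)

    if m.meta.cell_class == "PC":
        apicals = out.trees("apical")
        if not apicals:
            warnings.warn("PC morphology has no apical tree; skipping alignment")
            return out
        pts = np.vstack([t.points for t in apicals])
        centroid = pts.mean(axis=0) - out.soma_center
        norm = np.linalg.norm(centroid)
        if norm > tol:
            R = _rotation_to_y(centroid / norm)
            rotated = [
                replace(t, points=(t.points - out.soma_center) @ R.T + out.soma_center)
                for t in out.neurites
            ]
            out = NeuronMorphology(out.soma_center, out.soma_radius, rotated, out.meta)
    return out


# ---------------------------------------------------------------------------
# Morphometrics


def morphometrics(m: NeuronMorphology) -> MorphometricRecord:
    lengths = {t: 0.0 for t in NEURITE_TYPES}
    branches = {t: 0 for t in NEURITE_TYPES}
    diam_sum = {t: 0.0 for t in NEURITE_TYPES}
    diam_n = {t: 0 for t in NEURITE_TYPES}
    extent = 0.0
    for tree in m.neurites:
        lengths[tree.neurite_type] += tree.total_length
        branches[tree.neurite_type] += tree.branch_count
        diam_sum[tree.neurite_type] += float(tree.diameters.sum())
        diam_n[tree.neurite_type] += tree.n_nodes
        extent = max(extent, float(tree.radial_distances(m.soma_center).max()))
    mean_d = {
        t: (diam_sum[t] / diam_n[t] if diam_n[t] else 0.0) for t in NEURITE_TYPES
    }
    return MorphometricRecord(lengths, branches, mean_d, extent)


def population_morphometrics(population) -> pd.DataFrame:
    """One row of morphometric features per neuron."""
    rows = []
    for i, m in enumerate(population):
        rec = morphometrics(m).to_flat_dict()
        rec["neuron"] = m.meta.subject_id or str(i)
        rec["species"] = m.meta.species
        rec["cell_class"] = m.meta.cell_class
        rows.append(rec)
    return pd.DataFrame(rows)


def diameter_profile(
    population, bin_width: float, neurite_types=DENDRITE_TYPES
) -> pd.DataFrame:
    """Mean and sd of diameter vs path distance from the soma, binned.

    Mirrors population thickness profiles: every node's diameter contributes
    at its path distance; empty bins carry NaN statistics and count 0.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    dists, diams = [], []
    for m in population:
        for tree in m.trees(neurite_types):
            dists.append(tree.path_distances())
            diams.append(tree.diameters)
    if not dists:
        raise ValueError("no neurites of requested types in population")
    dists = np.concatenate(dists)
    diams = np.concatenate(diams)
    n_bins = max(1, int(np.ceil(dists.max() / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.clip(np.digitize(dists, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = diams[idx == b]
        rows.append(
            {
                "bin_left": edges[b],
                "bin_right": edges[b + 1],
                "mean": float(sel.mean()) if len(sel) else np.nan,
                "sd": float(sel.std()) if len(sel) else np.nan,
                "count": len(sel),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scaling / grafting


def scale_morphology(m: NeuronMorphology, factor: float) -> NeuronMorphology:
    """Scale coordinates about the soma center by ``factor``.

    Diameters (and the soma radius) are intentionally left unscaled: scaling
    probes the size hypothesis on extents/lengths while thickness is a
    separate feature. Total cable length scales by exactly ``factor``.
    """
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    trees = [
        replace(t, points=m.soma_center + factor * (t.points - m.soma_center))
        for t in m.neurites
    ]
    return NeuronMorphology(m.soma_center.copy(), m.soma_radius, trees, m.meta)


def graft_axon(
    dendrite_donor: NeuronMorphology, axon_donor: NeuronMorphology
) -> NeuronMorphology:
    """Combine the dendrites (and soma) of one cell with the axon of another.

    The axon is rigidly translated so its original soma-relative geometry is
    preserved around the recipient soma.
    """
    axons = axon_donor.trees("axon")
    if not axons:
        raise ValueError("axon donor has no axon")
    offset = dendrite_donor.soma_center - axon_donor.soma_center
    trees = [t for t in dendrite_donor.neurites if t.neurite_type != "axon"]
    trees += [t.translated(offset) for t in axons]
    return NeuronMorphology(
        dendrite_donor.soma_center.copy(),
        dendrite_donor.soma_radius,
        trees,
        dendrite_donor.meta,
    )


def filter_axon_pool(pool, min_branches: int = 20) -> list:
    """Keep morphologies whose axonal branch count exceeds ``min_branches``.

    Poorly reconstructed axons (few branches) make unrealistically sparse
    connectivity; the default threshold of 20 branches follows the curation
    rule used for building circuits from incomplete reconstructions.
    """
    return [m for m in pool if m.branch_count("axon") > min_branches]
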